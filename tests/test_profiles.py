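"""Radial profiles, plateau, excess and coverage closed-form oracles."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import vesibud as vb
from vesibud.forcefield import C, H, S, W
from vesibud.profiles import RadialProfile


def synth_profile(values, bin_width=0.25):
    values = np.asarray(values, dtype=float)
    r = (np.arange(len(values)) + 0.5) * bin_width
    return RadialProfile(r=r, values=values, bin_width=bin_width, types=(S,))


def shell_state(n_beads, radius, box=30.0, seed=0, types_val=S):
    """n beads spread on a thin spherical shell centered in the box."""
    rng = np.random.default_rng(seed)
    u = rng.normal(size=(n_beads, 3))
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    pos = box / 2 + radius * u
    n = n_beads
    return vb.SystemState(box=np.full(3, box), pos=pos, vel=np.zeros((n, 3)),
                          types=np.full(n, types_val, dtype=np.int8),
                          mol=np.zeros(n, dtype=np.int32))


class TestRadialDensity:
    def test_volume_integral_recovers_bead_count(self):
        state = vb.build_bulk(0.2, (12.0, 12.0, 12.0), seed=1)
        prof = vb.radial_density([state], types=(S,), center_rule="box", bin_width=0.25)
        n_s = int(np.sum(state.types == S))
        # bins cover the inscribed sphere only; compare within that radius
        assert prof.volume_integral() <= n_s
        assert prof.volume_integral() >= 0.4 * n_s

    def test_uniform_bulk_far_field_matches_3phi(self):
        state = vb.build_bulk(0.1, (14.0, 14.0, 14.0), seed=2)
        prof = vb.radial_density([state], types=(S,), center_rule="box", bin_width=0.5)
        sel = (prof.r > 2.0) & (prof.r < 6.5)
        assert prof.values[sel].mean() == pytest.approx(0.3, rel=0.1)

    def test_empty_selection_warns_and_returns_zero(self):
        state = vb.build_bulk(0.0, (6.0, 6.0, 6.0), seed=3)
        with pytest.warns(UserWarning, match="no beads"):
            prof = vb.radial_density([state], types=(S,), center_rule="box")
        assert np.all(prof.values == 0.0)

    def test_bulk_plateau_matches_three_phi(self):
        """A uniform solution at Phi_S = 0.016 has rho_S plateau 3*Phi_S =
        0.048/d^3 (averaged over realizations to beat counting noise)."""
        states = [vb.build_bulk(0.016, (14.0, 14.0, 14.0), seed=7 + k) for k in range(8)]
        prof = vb.radial_density(states, types=(S,), center_rule="box", bin_width=0.5)
        plateau = vb.bulk_plateau(prof, r_min=3.0)
        assert plateau == pytest.approx(0.048, rel=0.05)

    def test_rejects_nonpositive_bin(self):
        state = vb.build_bulk(0.0, (5.0, 5.0, 5.0))
        with pytest.raises(ValueError):
            vb.radial_density([state], bin_width=0.0)


class TestPlateauAndExcess:
    def test_flat_profile_returns_constant(self):
        prof = synth_profile(np.full(80, 0.075))
        assert vb.bulk_plateau(prof) == pytest.approx(0.075)

    def test_peak_then_plateau(self):
        v = np.full(100, 0.075)
        v[40:48] += np.exp(-0.5 * ((np.arange(8) - 4) / 1.5) ** 2)
        prof = synth_profile(v)
        assert vb.bulk_plateau(prof, r_min=15.0) == pytest.approx(0.075)

    def test_too_few_plateau_bins_rejected(self):
        prof = synth_profile(np.ones(10))
        with pytest.raises(ValueError, match="plateau"):
            vb.bulk_plateau(prof, r_min=2.4)

    def test_uniform_profile_gives_zero_excess(self):
        prof = synth_profile(np.full(50, 0.3))
        exc = vb.excess_profile(prof, 0.3)
        assert np.allclose(exc.values, 0.0)

    def test_gaussian_peak_recovered_exactly(self):
        base = np.full(60, 0.12)
        gauss = 0.8 * np.exp(-0.5 * ((np.arange(60) - 30) / 3.0) ** 2)
        exc = vb.excess_profile(synth_profile(base + gauss), 0.12)
        assert np.allclose(exc.values, gauss)


class TestCoverage:
    def test_zero_excess_gives_zero_coverage(self):
        exc = synth_profile(np.zeros(40))
        assert vb.coverage(exc, R_mid=5.0).Gamma == 0.0

    def test_synthetic_shell_oracle(self):
        """K excess beads on a shell outside R_mid -> Gamma = K/(4 pi R_mid^2)."""
        K, r_shell, r_mid, box = 500, 9.0, 6.0, 30.0
        state = shell_state(K, r_shell, box=box, seed=4)
        prof = vb.radial_density([state], types=(S,), center_rule="box", bin_width=0.25)
        cov = vb.coverage(prof, R_mid=r_mid, box=state.box)
        assert cov.Gamma == pytest.approx(K / (4 * np.pi * r_mid**2), rel=0.02)
        assert cov.A_0 == pytest.approx(4 * np.pi * r_mid**2)

    def test_coverage_invariant_under_bin_halving(self):
        state = shell_state(800, 8.0, box=28.0, seed=5)
        covs = []
        for bw in (0.25, 0.125):
            prof = vb.radial_density([state], types=(S,), center_rule="box", bin_width=bw)
            covs.append(vb.coverage(prof, R_mid=6.0, box=state.box).Gamma)
        assert covs[0] == pytest.approx(covs[1], rel=0.02)

    @given(r_mid=st.floats(2.0, 8.0))
    def test_coverage_scales_inversely_with_midsurface_area(self, r_mid):
        exc = synth_profile(np.r_[np.zeros(36), [1.0], np.zeros(23)], bin_width=0.25)
        cov = vb.coverage(exc, R_mid=r_mid)
        r_k = exc.r[36]
        expected = 1.0 * 4 * np.pi * r_k**2 * 0.25 / (4 * np.pi * r_mid**2)
        assert cov.Gamma == pytest.approx(expected, rel=1e-9)


class TestMidsurfaceAndThickness:
    def test_gaussian_chain_peak_located(self):
        r = (np.arange(160) + 0.5) * 0.25
        v = np.exp(-0.5 * ((r - 22.5) / 1.2) ** 2)
        prof = RadialProfile(r=r, values=v, bin_width=0.25, types=(C,))
        assert vb.midsurface_radius(prof) == pytest.approx(22.5, abs=0.05)

    def test_flat_profile_ambiguous(self):
        prof = synth_profile(np.ones(50))
        with pytest.raises(ValueError, match="flat|ambiguous"):
            vb.midsurface_radius(prof)

    def test_competing_peaks_ambiguous(self):
        v = np.zeros(80)
        v[20] = 1.0
        v[60] = 0.95
        with pytest.raises(ValueError, match="ambiguous"):
            vb.midsurface_radius(synth_profile(v))

    def test_top_hat_thickness(self):
        v = np.zeros(100)
        v[40:60] = 2.0  # 20 bins * 0.25 = 5 d wide
        assert vb.membrane_thickness(synth_profile(v)) == pytest.approx(5.0, abs=0.3)

    def test_zero_profile_rejected(self):
        with pytest.raises(ValueError, match="no bilayer"):
            vb.membrane_thickness(synth_profile(np.zeros(30)))
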