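"""Stress-profile integrals, elastic moduli, and tensionless-state search.

The spike-profile oracles validate the transcribed spherical integrands:
a single-bin spike s = c at radius r_k contributes c*dr*(r_k/R_mid)^2 to
the tension and an extra factor (r_k - R_mid) to the first moment.
"""

import numpy as np
import pytest

import vesibud as vb
from vesibud.engine import IntegratorConfig, run, virial_pressure
from vesibud.stress_elastic import StressProfile


def spike_profile(nbins=100, bin_width=0.2, spikes=()):
    """StressProfile with s(r) nonzero only at the given (bin, value) pairs."""
    r = (np.arange(nbins) + 0.5) * bin_width
    pn = np.zeros(nbins)
    pt = np.zeros(nbins)
    for k, val in spikes:
        pn[k] = val  # s = P_N - P_T = val
    return StressProfile(r=r, P_N=pn, P_T=pt, bin_width=bin_width)


class TestTensionAndMoment:
    def test_zero_stress_gives_zero_tension_and_moment(self):
        sp = spike_profile()
        assert vb.bilayer_tension(sp, R_mid=10.0) == 0.0
        assert vb.first_moment(sp, R_mid=10.0) == 0.0

    def test_spike_at_midsurface_tension_oracle(self):
        # spike exactly at R_mid: geometric weight (r/R)^2 = 1
        sp = spike_profile(spikes=[(49, 2.5)])
        r_mid = sp.r[49]
        assert vb.bilayer_tension(sp, r_mid) == pytest.approx(2.5 * 0.2)

    def test_offset_spike_tension_and_moment_oracle(self):
        k, c = 60, -1.7
        sp = spike_profile(spikes=[(k, c)])
        r_mid = 10.0
        w = (sp.r[k] / r_mid) ** 2
        assert vb.bilayer_tension(sp, r_mid) == pytest.approx(c * 0.2 * w)
        mom = vb.first_moment(sp, r_mid, tension_tol=None)
        assert mom == pytest.approx(c * 0.2 * w * (sp.r[k] - r_mid))

    def test_moment_sign_flips_with_antisymmetric_stress(self):
        sp_plus = spike_profile(spikes=[(45, 1.0), (55, -1.0)])
        sp_minus = spike_profile(spikes=[(45, -1.0), (55, 1.0)])
        r_mid = 0.5 * (sp_plus.r[45] + sp_plus.r[55])
        m1 = vb.first_moment(sp_plus, r_mid, tension_tol=None)
        m2 = vb.first_moment(sp_minus, r_mid, tension_tol=None)
        assert m1 == pytest.approx(-m2)
        assert m1 != 0.0

    def test_moment_refuses_tense_profile(self):
        sp = spike_profile(spikes=[(50, 5.0)])
        with pytest.raises(ValueError, match="tensionless"):
            vb.first_moment(sp, R_mid=10.0)

    def test_profile_must_cover_bilayer(self):
        sp = spike_profile(nbins=20)
        with pytest.raises(ValueError, match="cover"):
            vb.bilayer_tension(sp, R_mid=10.0)


class TestSpontaneousCurvature:
    def test_zero_moment_gives_curvature_of_midsurface(self):
        assert vb.spontaneous_curvature(0.0, kappa=10.0, R_mid=22.5) == pytest.approx(1 / 22.5)

    def test_linear_in_moment(self):
        m1 = vb.spontaneous_curvature(-1.0, kappa=8.0, R_mid=20.0)
        m2 = vb.spontaneous_curvature(-2.0, kappa=8.0, R_mid=20.0)
        assert (m2 - 1 / 20.0) == pytest.approx(2 * (m1 - 1 / 20.0))

    def test_rejects_zero_rigidity(self):
        with pytest.raises(ValueError):
            vb.spontaneous_curvature(1.0, kappa=0.0, R_mid=20.0)


class TestModuli:
    def test_exact_linear_data(self):
        x = np.array([-0.02, -0.01, 0.0, 0.01, 0.02])
        assert vb.area_compressibility(x, 20.0 * x) == pytest.approx(20.0)

    def test_two_point_fallback_is_finite_difference(self):
        assert vb.area_compressibility([0.0, 0.01], [0.0, 0.3]) == pytest.approx(30.0)

    def test_degenerate_range_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            vb.area_compressibility([0.01, 0.01], [1.0, 2.0])

    @pytest.mark.parametrize("ka,lme,expected", [(48.0, 5.0, 25.0), (48.0, 0.0, 0.0)])
    def test_bending_rigidity_arithmetic(self, ka, lme, expected):
        assert vb.bending_rigidity(ka, lme) == pytest.approx(expected)

    def test_doubling_thickness_quadruples_rigidity(self):
        assert vb.bending_rigidity(30.0, 10.0) == pytest.approx(4 * vb.bending_rigidity(30.0, 5.0))


class TestFindTensionless:
    def test_synthetic_linear_crossing(self):
        n_star = 77000.0
        n0, _ = vb.find_tensionless([70000, 75000, 80000, 85000],
                                    lambda n: 1e-4 * (n - n_star))
        assert n0 == pytest.approx(n_star, abs=1)

    def test_nu0_from_reference_count(self):
        spec = vb.mini_vesicle_spec(scale="full")
        n0, nu0 = vb.find_tensionless([80000, 90000, 100000],
                                      lambda n: 1e-4 * (n - 90400), spec=spec)
        assert nu0 == pytest.approx(n0 / 90400)

    def test_no_sign_change_reports_bracket(self):
        with pytest.raises(ValueError, match="bracket"):
            vb.find_tensionless([1000, 2000, 3000], lambda n: 1.0 + 1e-5 * n)

    def test_requires_three_points(self):
        with pytest.raises(ValueError, match="three"):
            vb.find_tensionless([1000, 2000], lambda n: n - 1500.0)


class TestBulkIsotropyAndVirialConsistency:
    @pytest.fixture(scope="class")
    def bulk_run(self, ff_good):
        state = vb.build_bulk(0.0, (8.0, 8.0, 8.0), seed=6)
        final, traj, _ = run(state, IntegratorConfig(), ff_good, 1500, stride=250)
        return final, traj.frames[2:], ff_good

    def test_stress_profile_isotropic_in_bulk(self, bulk_run):
        """Uniform fluid: P_N(r) = P_T(r), s(r) ~ 0 in every resolved bin."""
        _, frames, ff = bulk_run
        sp = vb.spherical_stress_profile(frames, ff, center_rule="box", bin_width=0.5)
        core = (sp.r > 1.0) & (sp.r < 3.5)  # well-populated shells
        assert np.abs(sp.s[core]).max() < 1.5  # ~5% of P ~ 24
        assert np.abs(sp.s[core]).mean() < 0.5

    def test_shell_summed_stress_matches_global_virial(self, bulk_run):
        """Volume integral of the binned trace equals kinetic + virial pressure."""
        final, frames, ff = bulk_run
        sp = vb.spherical_stress_profile(frames, ff, center_rule="box", bin_width=0.5)
        vols = sp.shell_volumes
        total_from_bins = float(np.sum((sp.P_N + 2 * sp.P_T) / 3.0 * vols))
        p_tots = []
        for st in frames:
            p_exc, _ = virial_pressure(st, ff)
            p_kin = np.sum(st.vel**2) / (3.0 * st.volume)
            p_tots.append(p_exc + p_kin)
        expected = np.mean(p_tots) * final.volume
        assert total_from_bins == pytest.approx(expected, rel=0.01)
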