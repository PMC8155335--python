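"""Builder bookkeeping: bulk, slab, bilayer and vesicle assembly protocols."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import vesibud as vb
from vesibud.builders import membrane_center, vesicle_bead_budget
from vesibud.forcefield import C, H, S, W


class TestBulkAndSlab:
    def test_bead_count_from_density(self):
        state = vb.build_bulk(0.0, (10.0, 10.0, 10.0))
        assert state.n_beads == 3000
        assert np.all(state.types == W)

    def test_solute_count_arithmetic(self):
        state = vb.build_bulk(0.025, (10.0, 10.0, 10.0))
        assert int(np.sum(state.types == S)) == 75

    def test_phi_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError):
            vb.build_bulk(1.2, (5.0, 5.0, 5.0))

    def test_slab_requires_elongated_box(self):
        with pytest.raises(ValueError, match="elongated"):
            vb.build_slab(0.2, (10.0, 10.0, 10.0))

    def test_slab_solute_confined_to_central_third(self):
        state = vb.build_slab(0.25, (6.0, 6.0, 18.0), seed=3)
        n = state.n_beads
        assert int(np.sum(state.types == S)) == int(round(0.25 * n))
        z = state.pos[state.types == S, 2]
        assert z.min() >= 18.0 / 3 - 1e-9
        assert z.max() <= 2 * 18.0 / 3 + 1e-9

    def test_pure_water_slab(self):
        state = vb.build_slab(0.0, (5.0, 5.0, 12.0), seed=3)
        assert not np.any(state.types == S)

    @given(phi=st.floats(0.0, 0.33), seed=st.integers(0, 100))
    def test_slab_count_bookkeeping(self, phi, seed):
        state = vb.build_slab(phi, (4.0, 4.0, 10.0), seed=seed)
        assert int(np.sum(state.types == S)) == int(round(phi * state.n_beads))


class TestPlanarBilayer:
    def test_membrane_bead_count(self):
        state = vb.build_planar_bilayer(128, (12.65, 12.65, 14.0))
        assert int(np.sum((state.types == H) | (state.types == C))) == 2 * 128 * 15

    def test_leaflets_symmetric_about_midplane(self):
        state = vb.build_planar_bilayer(64, (9.0, 9.0, 12.0))
        heads_z = state.pos[state.types == H, 2] - 6.0
        assert abs(heads_z.mean()) < 0.05

    def test_infeasible_packing_rejected(self):
        with pytest.raises(ValueError, match="packing"):
            vb.build_planar_bilayer(500, (5.0, 5.0, 10.0))


class TestVesicle:
    def test_reference_budget_reproduces_printed_counts(self):
        spec = vb.mini_vesicle_spec(scale="full")
        budget = vesicle_bead_budget(spec)
        assert budget["membrane"] == 151500
        assert budget["solvent"] == 1440400
        assert budget["total"] == 1591900

    def test_mini_vesicle_partition_sums_to_total(self):
        state = vb.build_vesicle(vb.mini_vesicle_spec(Phi_S=0.05, seed=1))
        c = state.meta["counts"]
        assert c["membrane"] + c["N_W_in"] + c["N_S"] + c["N_W_ex"] == state.n_beads
        assert c["membrane"] == int(np.sum((state.types == H) | (state.types == C)))
        part = state.meta["partition"]
        assert part["exterior"][1] == state.n_beads

    def test_interior_compartment_solute_free(self):
        state = vb.build_vesicle(vb.mini_vesicle_spec(Phi_S=0.08, seed=2))
        lo, hi = state.meta["partition"]["interior"]
        assert np.all(state.types[lo:hi] == W)

    def test_no_solute_when_phi_zero(self):
        state = vb.build_vesicle(vb.mini_vesicle_spec(Phi_S=0.0, seed=2))
        assert not np.any(state.types == S)

    def test_vesicle_must_fit_box(self):
        with pytest.raises(ValueError, match="fit the box"):
            vb.build_vesicle(vb.VesicleSpec(N_il=50, N_ol=330, box=(10.0, 10.0, 10.0)))

    def test_infeasible_packing_suggests_larger_radius(self):
        with pytest.raises(ValueError, match="radius"):
            vb.build_vesicle(vb.VesicleSpec(N_il=50, N_ol=330, box=(18.0,) * 3,
                                            area_per_lipid=0.3))


class TestProtocols:
    @pytest.fixture(scope="class")
    def vesicle(self):
        return vb.build_vesicle(vb.mini_vesicle_spec(Phi_S=0.05, seed=4))

    def test_deflation_arithmetic(self):
        # nu = 0.75 of the full-scale reference: 0.75 * 90400 = 67800
        assert int(round(0.75 * 90400)) == 67800

    def test_set_volume_conserves_total_and_sets_target(self, vesicle):
        n_ref = vesicle.meta["N_W_isp"]
        out = vb.set_volume(vesicle, 0.6)
        assert out.n_beads == vesicle.n_beads
        from vesibud.builders import classify_compartments

        interior, _, _, _ = classify_compartments(out)
        n_in = int(np.sum(interior & (out.types == W)))
        assert n_in == pytest.approx(int(round(0.6 * n_ref)), abs=2)

    def test_set_volume_identity_at_unity(self, vesicle):
        out = vb.set_volume(vesicle, 1.0)
        assert out.n_beads == vesicle.n_beads
        assert out.meta["counts"]["N_W_in"] == vesicle.meta["N_W_isp"]

    def test_set_volume_rejects_nonpositive(self, vesicle):
        with pytest.raises(ValueError):
            vb.set_volume(vesicle, 0.0)

    def test_titration_reaches_target_within_one_bead(self, vesicle):
        out = vb.set_solute_fraction(vesicle, 0.02)
        from vesibud.builders import classify_compartments

        _, exterior, _, _ = classify_compartments(out)
        n_s = int(np.sum(exterior & (out.types == S)))
        n_ex = int(np.sum(exterior))
        assert abs(n_s / n_ex - 0.02) <= 1.0 / n_ex
        # positions untouched, identities only
        assert np.array_equal(out.pos, vesicle.pos)

    def test_titration_to_zero_removes_all_exterior_solute(self, vesicle):
        out = vb.set_solute_fraction(vesicle, 0.0)
        assert not np.any(out.types == S)

    def test_mole_fraction_arithmetic(self):
        # Phi_S = N_S / (N_S + N_W_ex)
        assert 75 / (75 + 2925) == pytest.approx(0.025)


def test_membrane_center_handles_periodic_wrap():
    state = vb.build_vesicle(vb.mini_vesicle_spec(seed=5))
    shifted = state.copy()
    shifted.pos += np.array([8.5, 0.0, 0.0])  # push the vesicle across the boundary
    shifted.pos %= shifted.box
    c0 = membrane_center(state)
    c1 = membrane_center(shifted)
    d = (c1 - c0 - np.array([8.5, 0, 0]) + 9.0) % 18.0 - 9.0
    assert np.abs(d).max() < 1e-6
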