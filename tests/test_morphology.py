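"""Neck diameter, division detection and contact area on synthetic geometry."""

import numpy as np
import pytest

import vesibud as vb
from vesibud.forcefield import H
from vesibud.morphology import contact_area, detect_division, neck_diameter


@pytest.fixture(scope="module")
def dumbbell():
    return vb.make_fixture("dumbbell_shells", seed=7)


class TestNeckDiameter:
    def test_overlapping_shells_match_analytic_waist(self, dumbbell):
        """Two R-shells with centers 1.6 R apart intersect in a circle of
        diameter 2 R sqrt(1 - 0.8^2) = 1.2 R."""
        res = neck_diameter(dumbbell)
        assert res.has_neck
        # 1 d slabs overestimate the waist by up to the sphere's local slope:
        # the slab center can sit 0.5 d off the waist plane, where the shell
        # radius is sqrt(R^2 - (a/2 - 0.5)^2); the true waist is the floor
        waist = 1.2 * 8.0
        upper = 2 * np.sqrt(8.0**2 - (0.8 * 8.0 - 0.5) ** 2)
        assert waist - 0.4 <= res.D_ne <= upper + 0.4

    def test_classification_threshold(self, dumbbell):
        res = neck_diameter(dumbbell)
        assert res.state == ("closed" if res.D_ne < 10.0 else "open")
        # threshold semantics on synthetic values
        from vesibud.morphology import NECK_CLOSED_THRESHOLD

        assert 8.0 < NECK_CLOSED_THRESHOLD
        assert 12.0 > NECK_CLOSED_THRESHOLD

    def test_rotation_and_translation_invariance(self, dumbbell):
        base = neck_diameter(dumbbell).D_ne
        rng = np.random.default_rng(3)
        for _ in range(3):
            # random rotation about the box center + translation (rewrapped)
            q = rng.normal(size=(3, 3))
            rot, _ = np.linalg.qr(q)
            st = dumbbell.copy()
            c = st.box / 2
            st.pos = (st.pos - c) @ rot.T + c + rng.uniform(-3, 3, 3)
            st.pos %= st.box
            assert neck_diameter(st).D_ne == pytest.approx(base, abs=0.8)

    def test_single_sphere_has_no_neck(self):
        rng = np.random.default_rng(5)
        u = rng.normal(size=(2000, 3))
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        pos = 15.0 + 6.0 * u
        st = vb.SystemState(box=np.full(3, 30.0), pos=pos, vel=np.zeros_like(pos),
                            types=np.full(2000, H, dtype=np.int8),
                            mol=np.ones(2000, dtype=np.int32))
        res = neck_diameter(st)
        assert not res.has_neck
        assert res.state == "no neck"


class TestDivisionDetection:
    def test_intact_vesicle_single_component(self):
        st = vb.build_vesicle(vb.mini_vesicle_spec(seed=8))
        ncomp, comps = detect_division(st)
        assert ncomp == 1

    def test_separated_shells_two_components(self):
        st = vb.make_fixture("separated_shells", seed=9)
        ncomp, comps = detect_division(st)
        assert ncomp == 2
        assert len(comps[0]) + len(comps[1]) == st.n_beads

    def test_cutoff_semantics_merges_near_shells(self):
        st = vb.make_fixture("separated_shells", seed=9)
        # shrink the gap to 0.5 d by moving the second shell toward the first
        n_half = st.n_beads // 2
        st.pos[n_half:, 2] -= 4.5
        ncomp, _ = detect_division(st, cutoff=1.0)
        assert ncomp == 1

    def test_overlapping_dumbbell_is_single_component(self, dumbbell):
        ncomp, _ = detect_division(dumbbell)
        assert ncomp == 1


class TestContactArea:
    def test_well_separated_segments_zero_area(self):
        st = vb.make_fixture("separated_shells", seed=10)
        assert contact_area(st) == 0.0

    def test_single_component_zero_area(self):
        st = vb.build_vesicle(vb.mini_vesicle_spec(seed=11))
        assert contact_area(st) == 0.0

    def test_parallel_patches_recover_patch_area(self):
        """Two flat L x L head-bead patches at gap 2 d -> contact area ~ L^2."""
        L, gap, n_side = 8.0, 2.0, 16
        xs = (np.arange(n_side) + 0.5) * (L / n_side)
        gx, gy = np.meshgrid(xs, xs)
        rng = np.random.default_rng(12)
        patch = np.stack([gx.ravel(), gy.ravel(), np.zeros(n_side**2)], axis=1)
        pos = np.concatenate([
            patch + [10.0, 10.0, 14.0],
            patch + [10.0, 10.0, 14.0 + gap],
        ]) + rng.normal(0, 0.05, (2 * n_side**2, 3))
        n = pos.shape[0]
        st = vb.SystemState(box=np.full(3, 30.0), pos=pos, vel=np.zeros((n, 3)),
                            types=np.full(n, H, dtype=np.int8),
                            mol=np.repeat([1, 2], n_side**2).astype(np.int32))
        seg = [np.arange(n_side**2), np.arange(n_side**2, n)]
        area = contact_area(st, segments=seg, area_per_head=(L / n_side) ** 2)
        assert area == pytest.approx(L**2, rel=0.1)
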