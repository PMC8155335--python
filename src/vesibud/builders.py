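"""Initial-state construction: bulk solutions, slabs, bilayers, vesicles.

Vesicles are assembled by placing N_il lipids on an inner and N_ol lipids
on an outer spherical shell (heads facing the adjacent water compartment),
filling the interior with exactly N_W_in water beads and no solute, and
filling the exterior with water and solute at mole fraction Phi_S.  The
deflation/inflation protocol rescales the interior water count via the
volume parameter nu = N_W_in / N_W_isp, relocating (never deleting) the
displaced waters so global bead totals stay constant.  Solute titration
converts exterior bead identities in place.

All builders keep exact bead-count bookkeeping in ``state.meta`` under
``partition`` (membrane / interior / exterior index ranges and counts).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .engine import IntegratorConfig, SystemState, _advance_inplace
from .forcefield import C, DEFAULT_LIPID, H, S, W, ForceFieldTable, LipidTopology

BOND_SPACING = 0.45  # initial bead spacing along the lipid axis (d)

# Effective bead density inside the lipid membrane (beads/d^3).  The bilayer
# core packs denser than water; this value follows from the full-scale
# reference bookkeeping (151,500 membrane beads + 1,440,400 solvent beads at
# rho_W = 3/d^3 in an (80 d)^3 box) and sets how much box volume the
# membrane excludes when filling solvent at 3/d^3.
MEMBRANE_DENSITY = 4.75


@dataclass
class VesicleSpec:
    """Lipid numbers, compartment contents and box for one nanovesicle.

    The full-scale reference of the study is N_il = 4000, N_ol = 6100
    (asymmetry N_ol/N_il ~ 1.525), N_W_isp = 90400 interior waters
    (vesicle diameter ~45 d), box (80 d)^3 and 1,440,400 solvent beads
    in total.  Desk-scale specs shrink all of these proportionately.
    """

    N_il: int
    N_ol: int
    box: tuple = (80.0, 80.0, 80.0)
    Phi_S: float = 0.0
    N_W_in: int | None = None
    N_W_isp: int | None = None
    total_solvent_beads: int | None = None
    area_per_lipid: float = 1.25  # d^2 per lipid at the head shell
    rho: float = 3.0
    seed: int = 0
    topology: LipidTopology = field(default_factory=lambda: DEFAULT_LIPID)

    def __post_init__(self):
        if self.N_il <= 0 or self.N_ol <= 0:
            raise ValueError("leaflet lipid counts must be positive")
        if not 0.0 <= self.Phi_S <= 1.0:
            raise ValueError(f"Phi_S must be in [0, 1], got {self.Phi_S}")

    @property
    def asymmetry(self) -> float:
        """Leaflet asymmetry parameter N_ol / N_il."""
        return self.N_ol / self.N_il

    @property
    def inner_head_radius(self) -> float:
        return np.sqrt(self.N_il * self.area_per_lipid / (4.0 * np.pi))

    @property
    def outer_head_radius(self) -> float:
        return np.sqrt(self.N_ol * self.area_per_lipid / (4.0 * np.pi))

    @property
    def membrane_beads(self) -> int:
        return (self.N_il + self.N_ol) * self.topology.beads_per_lipid


def vesicle_bead_budget(spec: VesicleSpec) -> dict:
    """Exact bead accounting for a vesicle spec (no geometry needed).

    membrane = (N_il + N_ol) * beads/lipid; solvent defaults to
    round(rho * V_box) - membrane when not pinned by the spec.
    """
    membrane = spec.membrane_beads
    if spec.total_solvent_beads is not None:
        solvent = spec.total_solvent_beads
    else:
        v_solvent = float(np.prod(spec.box)) - membrane / MEMBRANE_DENSITY
        solvent = int(round(spec.rho * v_solvent))
    interior = spec.N_W_in
    if interior is None:
        interior = spec.N_W_isp
    if interior is None:
        r_in = spec.inner_head_radius - 1.0
        interior = int(round(spec.rho * 4.0 / 3.0 * np.pi * max(r_in, 0.0) ** 3))
    return {
        "membrane": membrane,
        "solvent": solvent,
        "interior_water": interior,
        "exterior": solvent - interior,
        "total": membrane + solvent,
    }


def _maxwell_velocities(rng: np.random.Generator, n: int) -> np.ndarray:
    v = rng.normal(0.0, 1.0, size=(n, 3))
    v -= v.mean(axis=0)
    return v


def build_bulk(Phi_S: float, box, rho: float = 3.0, seed: int = 0,
               n_beads: int | None = None) -> SystemState:
    """Uniform W/S solution at total density rho with solute fraction Phi_S."""
    if not 0.0 <= Phi_S <= 1.0:
        raise ValueError(f"Phi_S must be in [0, 1], got {Phi_S}")
    box = np.asarray(box, dtype=float)
    if np.prod(box) <= 0:
        raise ValueError("box volume must be positive")
    rng = np.random.default_rng(seed)
    n = int(round(rho * float(np.prod(box)))) if n_beads is None else n_beads
    n_s = int(round(Phi_S * n))
    pos = rng.uniform(0.0, 1.0, size=(n, 3)) * box
    types = np.full(n, W, dtype=np.int8)
    if n_s:
        types[rng.choice(n, size=n_s, replace=False)] = S
    return SystemState(box=box, pos=pos, vel=_maxwell_velocities(rng, n), types=types,
                       mol=np.zeros(n, dtype=np.int32), seed=seed,
                       meta={"Phi_S": Phi_S, "N_S": n_s, "N_W": n - n_s})


def build_slab(Phi_S_total: float, box, rho: float = 3.0, seed: int = 0) -> SystemState:
    """W/S system with all solute seeded in a central z-slab.

    Used to initialize liquid-liquid coexistence runs: the box must be
    elongated along z (L_z >= 2 L_x); solutes start in a slab of width
    Phi_S_total * L_z (i.e. at bulk density) centered at L_z/2.
    """
    box = np.asarray(box, dtype=float)
    if box[2] < 2.0 * box[0]:
        raise ValueError("slab box must be elongated along z (Lz >= 2 Lx)")
    state = build_bulk(0.0, box, rho=rho, seed=seed)
    rng = np.random.default_rng(seed + 1)
    n = state.n_beads
    n_s = int(round(Phi_S_total * n))
    if n_s:
        w = max(Phi_S_total * box[2], 1.0)
        lo, hi = 0.5 * (box[2] - w), 0.5 * (box[2] + w)
        idx = rng.choice(n, size=n_s, replace=False)
        state.types[idx] = S
        state.pos[idx, 2] = rng.uniform(lo, hi, size=n_s)
    state.meta.update({"Phi_S_total": Phi_S_total, "N_S": n_s})
    return state


def _lipid_beads(base: np.ndarray, axis: np.ndarray, perp: np.ndarray,
                 topo: LipidTopology) -> np.ndarray:
    """Bead positions for one lipid: H0 at ``base``, chains running along
    ``-axis`` (i.e. axis points from chain ends toward the head)."""
    pts = np.empty((topo.beads_per_lipid, 3))
    for k in range(topo.n_heads):
        pts[k] = base - k * BOND_SPACING * axis
    anchors = [1, 2]
    offs = [perp * 0.25, -perp * 0.25]
    for c in range(topo.n_chains):
        anchor = pts[anchors[c]]
        first = topo.n_heads + c * topo.chain_length
        for t in range(topo.chain_length):
            pts[first + t] = anchor - (t + 1) * BOND_SPACING * axis + offs[c]
    return pts


def _assemble_lipids(placements, topo: LipidTopology):
    """Stack per-lipid bead arrays and build global bond/angle index lists."""
    npl = topo.beads_per_lipid
    nlip = len(placements)
    pos = np.concatenate(placements) if nlip else np.empty((0, 3))
    types = np.tile(topo.bead_types, nlip)
    mol = np.repeat(np.arange(1, nlip + 1, dtype=np.int32), npl)
    offs = (np.arange(nlip, dtype=np.int32) * npl)[:, None, None]
    bonds = (topo.bonds[None, :, :] + offs).reshape(-1, 2) if nlip else np.empty((0, 2), np.int32)
    angles = (topo.angles[None, :, :] + offs).reshape(-1, 3) if nlip else np.empty((0, 3), np.int32)
    return pos, types, mol, bonds.astype(np.int32), angles.astype(np.int32)


def _fibonacci_sphere(n: int) -> np.ndarray:
    i = np.arange(n) + 0.5
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i
    z = 1.0 - 2.0 * i / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.stack([r * np.cos(phi), r * np.sin(phi), z], axis=1)


def _any_perp(u: np.ndarray) -> np.ndarray:
    ref = np.array([1.0, 0.0, 0.0]) if abs(u[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    p = np.cross(u, ref)
    return p / np.linalg.norm(p)


def build_vesicle(spec: VesicleSpec) -> SystemState:
    """Assemble a spherical nanovesicle per ``spec``.

    Lipids sit on two concentric shells (inner heads facing the interior
    water, outer heads facing the exterior solution); the interior holds
    exactly N_W_in water beads and no solute; the exterior holds W and S
    beads at mole fraction Phi_S.
    """
    topo = spec.topology
    box = np.asarray(spec.box, dtype=float)
    budget = vesicle_bead_budget(spec)
    r_in, r_out = spec.inner_head_radius, spec.outer_head_radius
    lipid_len = (topo.n_heads + topo.chain_length) * BOND_SPACING
    # outer-leaflet chains point inward, so the radial extent is the outer
    # head shell (or the tip of the inner-leaflet chains, whichever is larger)
    extent = max(r_out + 1.0, r_in + lipid_len)
    if extent + 0.5 > 0.5 * np.min(box):
        raise ValueError("vesicle does not fit the box; enlarge the box or reduce lipid counts")
    for n_leaf, r_leaf in ((spec.N_il, r_in), (spec.N_ol, r_out)):
        apl = 4.0 * np.pi * r_leaf**2 / n_leaf
        if apl < 0.7:
            raise ValueError(
                f"infeasible packing: {apl:.2f} d^2 per lipid at radius {r_leaf:.1f}; "
                "use a larger initial radius (area_per_lipid)")
    center = box / 2.0
    placements = []
    # inner leaflet: heads at r_in, chains pointing outward (axis = -u)
    for u in _fibonacci_sphere(spec.N_il):
        placements.append(_lipid_beads(center + r_in * u, -u, _any_perp(u), topo))
    # outer leaflet: heads at r_out, chains pointing inward (axis = +u)
    for u in _fibonacci_sphere(spec.N_ol):
        placements.append(_lipid_beads(center + r_out * u, u, _any_perp(u), topo))
    pos_m, types_m, mol_m, bonds, angles = _assemble_lipids(placements, topo)

    rng = np.random.default_rng(spec.seed)
    n_in = budget["interior_water"]
    n_ex = budget["exterior"]
    if n_ex < 0:
        raise ValueError("interior water count exceeds total solvent budget")
    r_core = max(r_in - 0.7, 1.0)  # interior water up to just inside the head shell
    pos_in = center + _random_in_sphere(rng, n_in, r_core)
    pos_ex = _random_outside_sphere(rng, n_ex, box, center, r_out + 0.7)
    n_s = int(round(spec.Phi_S * n_ex))
    types_ex = np.full(n_ex, W, dtype=np.int8)
    if n_s:
        types_ex[rng.choice(n_ex, size=n_s, replace=False)] = S

    pos = np.concatenate([pos_m, pos_in, pos_ex])
    types = np.concatenate([types_m, np.full(n_in, W, dtype=np.int8), types_ex])
    mol = np.concatenate([mol_m, np.zeros(n_in + n_ex, dtype=np.int32)])
    n_mem = pos_m.shape[0]
    meta = {
        "spec": {"N_il": spec.N_il, "N_ol": spec.N_ol, "Phi_S": spec.Phi_S},
        "N_W_isp": spec.N_W_isp if spec.N_W_isp is not None else n_in,
        "partition": {
            "membrane": [0, n_mem],
            "interior": [n_mem, n_mem + n_in],
            "exterior": [n_mem + n_in, n_mem + n_in + n_ex],
        },
        "counts": {"membrane": n_mem, "N_W_in": n_in, "N_S": n_s, "N_W_ex": n_ex - n_s,
                   "total": n_mem + n_in + n_ex},
    }
    assert meta["counts"]["total"] == budget["total"]
    return SystemState(box=box, pos=pos, vel=_maxwell_velocities(rng, pos.shape[0]),
                       types=types, mol=mol, bonds=bonds, angles=angles, topology=topo,
                       seed=spec.seed, meta=meta)


def _random_in_sphere(rng, n, radius):
    pts = np.empty((n, 3))
    got = 0
    while got < n:
        cand = rng.uniform(-radius, radius, size=(2 * (n - got) + 16, 3))
        cand = cand[np.sum(cand**2, axis=1) <= radius**2]
        take = min(len(cand), n - got)
        pts[got:got + take] = cand[:take]
        got += take
    return pts


def _random_outside_sphere(rng, n, box, center, radius):
    pts = np.empty((n, 3))
    got = 0
    while got < n:
        cand = rng.uniform(0.0, 1.0, size=(2 * (n - got) + 16, 3)) * box
        cand = cand[np.sum((cand - center) ** 2, axis=1) > radius**2]
        take = min(len(cand), n - got)
        pts[got:got + take] = cand[:take]
        got += take
    return pts


def build_planar_bilayer(n_lipids_per_leaflet: int, box, Phi_S: float = 0.0,
                         rho: float = 3.0, seed: int = 0,
                         topology: LipidTopology | None = None,
                         membrane_density: float = 4.1) -> SystemState:
    """Flat bilayer spanning x-y at z = Lz/2, solvated on both sides.

    ``membrane_density`` is the effective bead density of the flat membrane
    (measured ~4.1/d^3 at ~1.25 d^2 per lipid, solvent-pressure self-consistent); it sets the volume the
    membrane excludes so the solvent fills the remainder at ``rho``.
    """
    topo = topology or DEFAULT_LIPID
    box = np.asarray(box, dtype=float)
    apl = box[0] * box[1] / n_lipids_per_leaflet
    if apl < 0.7:
        raise ValueError(f"infeasible packing: {apl:.2f} d^2 per lipid; enlarge the box")
    nx = int(np.ceil(np.sqrt(n_lipids_per_leaflet * box[0] / box[1])))
    ny = int(np.ceil(n_lipids_per_leaflet / nx))
    zmid = box[2] / 2.0
    half = 2.5  # initial head-shell offset from midplane
    placements = []
    up = np.array([0.0, 0.0, 1.0])
    perp = np.array([1.0, 0.0, 0.0])
    k = 0
    for leaf, sign in ((0, 1.0), (1, -1.0)):
        k = 0
        for ix in range(nx):
            for iy in range(ny):
                if k >= n_lipids_per_leaflet:
                    break
                x = (ix + 0.25 + 0.5 * leaf) * box[0] / nx
                y = (iy + 0.25 + 0.5 * leaf) * box[1] / ny
                base = np.array([x, y, zmid + sign * half])
                placements.append(_lipid_beads(base, sign * up, perp, topo))
                k += 1
    pos_m, types_m, mol_m, bonds, angles = _assemble_lipids(placements, topo)
    rng = np.random.default_rng(seed)
    n_solv = int(round(rho * (float(np.prod(box)) - pos_m.shape[0] / membrane_density)))
    if n_solv < 0:
        raise ValueError("membrane alone exceeds the bead budget; enlarge the box")
    # solvent outside the initial membrane slab
    pts = np.empty((n_solv, 3))
    got = 0
    margin = half + 0.8
    while got < n_solv:
        cand = rng.uniform(0.0, 1.0, size=(2 * (n_solv - got) + 16, 3)) * box
        dz = np.abs(cand[:, 2] - zmid)
        cand = cand[dz > margin]
        take = min(len(cand), n_solv - got)
        pts[got:got + take] = cand[:take]
        got += take
    n_s = int(round(Phi_S * n_solv))
    types_s = np.full(n_solv, W, dtype=np.int8)
    if n_s:
        types_s[rng.choice(n_solv, size=n_s, replace=False)] = S
    pos = np.concatenate([pos_m, pts])
    types = np.concatenate([types_m, types_s])
    mol = np.concatenate([mol_m, np.zeros(n_solv, dtype=np.int32)])
    meta = {"partition": {"membrane": [0, pos_m.shape[0]],
                          "solvent": [pos_m.shape[0], pos.shape[0]]}}
    return SystemState(box=box, pos=pos, vel=_maxwell_velocities(rng, pos.shape[0]),
                       types=types, mol=mol, bonds=bonds, angles=angles, topology=topo,
                       seed=seed, meta=meta)


def membrane_center(state: SystemState) -> np.ndarray:
    """Center of mass of all lipid (H + C) beads, respecting periodic wrap.

    Uses the circular-mean trick per axis so a vesicle straddling the box
    boundary is handled correctly.
    """
    sel = (state.types == H) | (state.types == C)
    com = np.empty(3)
    for a in range(3):
        theta = state.pos[sel, a] / state.box[a] * 2.0 * np.pi
        ang = np.arctan2(np.sin(theta).mean(), np.cos(theta).mean())
        com[a] = (ang / (2.0 * np.pi)) % 1.0 * state.box[a]
    return com


def _solvent_radii(state: SystemState):
    center = membrane_center(state)
    rel = state.pos - center
    rel -= np.round(rel / state.box) * state.box
    return np.linalg.norm(rel, axis=1), center


def classify_compartments(state: SystemState, R_mid: float | None = None):
    """Split solvent beads into interior/exterior by radius about the
    membrane center, relative to the midsurface radius (chain-density peak)."""
    from .profiles import midsurface_radius, radial_density

    if R_mid is None:
        prof = radial_density([state], types=(C,), bin_width=0.5)
        R_mid = midsurface_radius(prof)
    radii, center = _solvent_radii(state)
    solvent = state.mol == 0
    interior = solvent & (radii < R_mid)
    exterior = solvent & ~interior
    return interior, exterior, R_mid, center


def set_volume(state: SystemState, nu: float, rng_seed: int | None = None) -> SystemState:
    """Deflate/inflate a vesicle to volume parameter nu = N_W_in / N_W_isp.

    Interior waters in excess of round(nu * N_W_isp) are relocated to the
    exterior compartment (and vice versa for inflation), so the total bead
    count is conserved.  Requires builder bookkeeping (N_W_isp) in meta.
    """
    if nu <= 0:
        raise ValueError(f"volume parameter must be positive, got {nu}")
    if "N_W_isp" not in state.meta:
        raise ValueError("state lacks vesicle bookkeeping (N_W_isp); build with build_vesicle")
    out = state.copy()
    n_ref = out.meta["N_W_isp"]
    target = int(round(nu * n_ref))
    interior, exterior, R_mid, center = classify_compartments(out)
    int_w = np.flatnonzero(interior & (out.types == W))
    ext_w = np.flatnonzero(exterior & (out.types == W))
    current = len(int_w)
    rng = np.random.default_rng(out.seed + 7919 if rng_seed is None else rng_seed)
    if target > current + len(ext_w):
        raise ValueError(f"nu={nu} needs {target} interior waters; only {current + len(ext_w)} available")
    if target < current:
        move = rng.choice(int_w, size=current - target, replace=False)
        out.pos[move] = _random_outside_sphere(rng, len(move), out.box, center, R_mid + 3.2)
    elif target > current:
        move = rng.choice(ext_w, size=target - current, replace=False)
        r_core = max(R_mid - 3.2, 1.0)
        out.pos[move] = center + _random_in_sphere(rng, len(move), r_core)
        out.pos[move] -= np.floor(out.pos[move] / out.box) * out.box
    out.meta.setdefault("counts", {})["N_W_in"] = target
    out.meta["nu"] = nu
    return out


def set_solute_fraction(state: SystemState, Phi_S: float, rng_seed: int | None = None) -> SystemState:
    """Titrate the exterior solution to solute mole fraction Phi_S.

    Converts exterior W <-> S bead identities in place (positions unchanged)
    until N_S / (N_S + N_W_ex) is within one bead of Phi_S; the interior
    compartment is untouched.
    """
    if not 0.0 <= Phi_S <= 1.0:
        raise ValueError(f"Phi_S must be in [0, 1], got {Phi_S}")
    out = state.copy()
    _, exterior, _, _ = classify_compartments(out)
    ext_idx = np.flatnonzero(exterior)
    n_ex = len(ext_idx)
    if n_ex == 0:
        raise ValueError("no exterior compartment identified")
    target = int(round(Phi_S * n_ex))
    cur_s = np.flatnonzero(exterior & (out.types == S))
    rng = np.random.default_rng(out.seed + 104729 if rng_seed is None else rng_seed)
    if target > len(cur_s):
        ext_w = np.flatnonzero(exterior & (out.types == W))
        flip = rng.choice(ext_w, size=target - len(cur_s), replace=False)
        out.types[flip] = S
    elif target < len(cur_s):
        flip = rng.choice(cur_s, size=len(cur_s) - target, replace=False)
        out.types[flip] = W
    out.meta.setdefault("counts", {}).update({"N_S": target, "N_W_ex": n_ex - target})
    out.meta["Phi_S"] = Phi_S
    return out


def soft_relax(state: SystemState, ff: ForceFieldTable, n_steps: int = 500,
               dt: float = 0.005) -> SystemState:
    """Short small-timestep pre-run to relieve random-insertion overlaps
    and relax bonds before production dynamics."""
    out = state.copy()
    cfg = IntegratorConfig(dt=dt)
    _advance_inplace(out, cfg, ff, n_steps, reseed=True)
    out.vel = _maxwell_velocities(np.random.default_rng(out.seed + 13), out.n_beads)
    return out
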