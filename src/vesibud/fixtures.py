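"""Seeded fixture systems for tests and examples.

Every fixture is deterministic for a given seed.  ``dumbbell_shells`` and
``separated_shells`` are synthetic geometric states (head-bead shells, no
dynamics history) used by the morphology oracles; the others are freshly
built physical systems at desk scale.
"""

from __future__ import annotations

import numpy as np

from .builders import VesicleSpec, build_bulk, build_planar_bilayer, build_slab, build_vesicle, _fibonacci_sphere
from .engine import SystemState
from .forcefield import H


def mini_vesicle_spec(Phi_S: float = 0.0, seed: int = 0, scale: str = "desk") -> VesicleSpec:
    """Desk-scale nanovesicle spec used throughout the tests and examples.

    The leaflet counts follow the same construction as the full-scale
    reference (head shells separated by one bilayer thickness, ~1.25 d^2
    per lipid), shrunk to a midsurface radius of ~4.5 d so that the vesicle
    plus an exterior solution shell fits an (18 d)^3 box.  ``scale='full'``
    returns the full-scale reference spec (4000/6100 lipids, (80 d)^3 box,
    90,400 reference interior waters, 1,440,400 solvent beads).
    """
    if scale == "full":
        return VesicleSpec(N_il=4000, N_ol=6100, box=(80.0, 80.0, 80.0), Phi_S=Phi_S,
                           N_W_isp=90400, N_W_in=90400, total_solvent_beads=1440400, seed=seed)
    return VesicleSpec(N_il=50, N_ol=330, box=(18.0, 18.0, 18.0), Phi_S=Phi_S, seed=seed)


def _shell(center, radius, n, jitter, rng):
    pts = center + radius * _fibonacci_sphere(n)
    return pts + rng.normal(0.0, jitter, size=pts.shape)


def _shell_state(centers, radius, n_per_shell, box, seed, jitter=0.05) -> SystemState:
    rng = np.random.default_rng(seed)
    pos = np.concatenate([_shell(np.asarray(c, float), radius, n_per_shell, jitter, rng)
                          for c in centers])
    n = pos.shape[0]
    mol = np.repeat(np.arange(1, len(centers) + 1, dtype=np.int32), n_per_shell)
    return SystemState(box=np.asarray(box, float), pos=pos, vel=np.zeros((n, 3)),
                       types=np.full(n, H, dtype=np.int8), mol=mol, seed=seed)


REGISTRY = ("bulk_water", "binary_bulk", "slab", "planar_bilayer", "mini_vesicle",
            "dumbbell_shells", "separated_shells")


def make_fixture(name: str, seed: int = 0) -> SystemState:
    """Construct a registered fixture system, deterministic per seed."""
    if name == "bulk_water":
        return build_bulk(0.0, box=(10.0, 10.0, 10.0), seed=seed)
    if name == "binary_bulk":
        return build_bulk(0.05, box=(8.0, 8.0, 8.0), seed=seed)
    if name == "slab":
        return build_slab(0.25, box=(8.0, 8.0, 20.0), seed=seed)
    if name == "planar_bilayer":
        return build_planar_bilayer(128, box=(12.65, 12.65, 14.0), seed=seed)
    if name == "mini_vesicle":
        return build_vesicle(mini_vesicle_spec(seed=seed))
    if name == "dumbbell_shells":
        # two overlapping spherical head-bead shells: radius R, centers 1.6 R
        # apart -> analytic waist (intersection-circle) diameter 1.2 R
        radius = 8.0
        sep = 1.6 * radius
        c = 20.0
        return _shell_state([(c, c, c - sep / 2), (c, c, c + sep / 2)], radius, 2500,
                            (40.0, 40.0, 40.0), seed)
    if name == "separated_shells":
        radius = 4.0
        gap = 5.0
        c = 15.0
        off = radius + gap / 2
        return _shell_state([(c, c, c - off), (c, c, c + off)], radius, 800,
                            (30.0, 30.0, 30.0), seed)
    raise KeyError(f"unknown fixture {name!r}; available: {REGISTRY}")
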