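"""Bead types, DPD force law, and the force-parameter table.

The model is built from four bead species — lipid head (H), lipid chain (C),
water (W) and solute (S) — interacting through the soft, purely repulsive DPD
conservative force

    F_ij(r) = f_ij (1 - r/d)  for r < d,   0 otherwise,

with the bead diameter ``d`` as the single length scale and ``k_B T`` as the
energy unit.  Lipids are H3(C6)2 molecules: a three-bead headgroup and two
six-bead hydrocarbon chains, held together by harmonic bonds and a
chain-stiffness potential.

Water-solute miscibility is controlled by the solubility ratio
``zeta = sqrt(f_WW f_SS) / f_WS``: lowering zeta (raising f_WS) makes W-S
contacts costly and eventually drives liquid-liquid demixing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "BEAD_TYPES",
    "H",
    "C",
    "W",
    "S",
    "ForceFieldTable",
    "LipidTopology",
    "pair_force_magnitude",
    "solubility",
    "default_force_table",
]

#: Bead type labels, in index order. Exactly four species exist.
BEAD_TYPES = ("H", "C", "W", "S")
H, C, W, S = range(4)

# Pairwise force parameters f_ij in k_B T/d for the H/C/W/S model.
# f_WS depends on the solvent condition and is filled in by
# default_force_table; the solute-free 3x3 block is the prior lipid/water
# model's table.
_BASE_TABLE = np.array(
    [
        # H     C     W     S
        [30.0, 50.0, 30.0, 15.0],
        [50.0, 10.0, 75.0, 75.0],
        [30.0, 75.0, 25.0, 0.0],
        [15.0, 75.0, 0.0, 25.0],
    ]
)

#: f_WS values for the two studied solvent conditions.
F_WS_BY_CONDITION = {"good": 32.0, "poor": 40.0}


@dataclass
class ForceFieldTable:
    """Pairwise and bonded interaction parameters in reduced units.

    Attributes
    ----------
    f : (4, 4) ndarray
        Symmetric conservative force parameters f_ij in k_B T/d.
    cutoff : float
        Interaction range; equals the bead diameter d (= 1 in reduced units).
    bond_k, bond_l0 : float
        Harmonic bond constant (k_B T/d^2) and rest length (d).
    bend_k : float
        Chain-stiffness constant (k_B T) for the (1 - cos phi) potential.
    gamma, sigma : float
        Dissipative and random amplitudes; fluctuation-dissipation requires
        sigma^2 = 2 gamma k_B T.
    """

    f: np.ndarray
    cutoff: float = 1.0
    bond_k: float = 128.0
    bond_l0: float = 0.5
    bend_k: float = 20.0
    gamma: float = 4.5
    sigma: float = field(default=-1.0)

    def __post_init__(self) -> None:
        self.f = np.asarray(self.f, dtype=float)
        if self.f.shape != (4, 4):
            raise ValueError("force table must be 4x4 (H, C, W, S)")
        if not np.allclose(self.f, self.f.T):
            raise ValueError("force table must be symmetric: f_ij == f_ji")
        if np.any(self.f < 0):
            raise ValueError("force parameters must be non-negative")
        if self.sigma < 0:  # derive from fluctuation-dissipation at k_B T = 1
            self.sigma = math.sqrt(2.0 * self.gamma)
        if not math.isclose(self.sigma**2, 2.0 * self.gamma, rel_tol=1e-12):
            raise ValueError("fluctuation-dissipation violated: sigma^2 != 2 gamma kT")

    def __getitem__(self, pair: tuple[int | str, int | str]) -> float:
        i, j = (BEAD_TYPES.index(k) if isinstance(k, str) else k for k in pair)
        return float(self.f[i, j])

    @property
    def zeta(self) -> float:
        """Solubility ratio of the W/S pair parameters."""
        return solubility(self.f[W, W], self.f[S, S], self.f[W, S])

    def to_dict(self) -> dict:
        labels = list(BEAD_TYPES)
        return {
            "f": {a: {b: float(self.f[i, j]) for j, b in enumerate(labels)} for i, a in enumerate(labels)},
            "cutoff": self.cutoff,
            "bond_k": self.bond_k,
            "bond_l0": self.bond_l0,
            "bend_k": self.bend_k,
            "gamma": self.gamma,
            "sigma": self.sigma,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ForceFieldTable":
        fmat = d.get("f", {})
        if isinstance(fmat, dict):
            arr = np.array([[fmat[a][b] for b in BEAD_TYPES] for a in BEAD_TYPES], dtype=float)
        else:
            arr = np.asarray(fmat, dtype=float)
        kwargs = {k: d[k] for k in ("cutoff", "bond_k", "bond_l0", "bend_k", "gamma", "sigma") if k in d}
        return cls(f=arr, **kwargs)


def pair_force_magnitude(f_ij: float, r: float, cutoff: float = 1.0) -> float:
    """Conservative DPD force magnitude f_ij (1 - r/d) for r < d, else 0.

    The force acts along the unit vector from bead j to bead i (repulsive).
    """
    if r < 0:
        raise ValueError(f"distance must be non-negative, got {r}")
    if f_ij < 0:
        raise ValueError(f"force parameter must be non-negative, got {f_ij}")
    if r >= cutoff:
        return 0.0
    return f_ij * (1.0 - r / cutoff)


def solubility(f_WW: float, f_SS: float, f_WS: float) -> float:
    """Solubility ratio zeta = sqrt(f_WW f_SS) / f_WS.

    With the standard like-pair value f_WW = f_SS = 25 this reduces to
    25/f_WS, i.e. zeta = 25/32 for good and 25/40 for poor solvent
    conditions.  Decreasing zeta (increasing f_WS) penalizes water-solute
    contacts and can drive phase separation.
    """
    if f_WW <= 0 or f_SS <= 0 or f_WS <= 0:
        raise ValueError("force parameters must be positive")
    return math.sqrt(f_WW * f_SS) / f_WS


def default_force_table(solvent_condition: str = "good", **overrides) -> ForceFieldTable:
    """Force table for the H/C/W/S model under a named solvent condition.

    Parameters
    ----------
    solvent_condition : {"good", "poor"}
        Sets f_WS = 32 (good) or 40 (poor).
    overrides
        Forwarded to :class:`ForceFieldTable` (e.g. gamma, bond_k).
    """
    try:
        f_ws = F_WS_BY_CONDITION[solvent_condition]
    except KeyError:
        raise ValueError(
            f"unknown solvent condition {solvent_condition!r}; expected one of {sorted(F_WS_BY_CONDITION)}"
        ) from None
    f = _BASE_TABLE.copy()
    f[W, S] = f[S, W] = f_ws
    return ForceFieldTable(f=f, **overrides)


@dataclass(frozen=True)
class LipidTopology:
    """Bonded layout of one H3(C6)2 lipid (15 beads).

    Bead order within a lipid: H0-H1-H2 (headgroup), then chain A beads
    C3..C8 attached to H1, then chain B beads C9..C14 attached to H2.
    Bonds connect consecutive beads along the head and each chain; angle
    triples run along each chain including the head-chain junction, which
    keeps the chains straight and the bond graph connected.
    """

    n_heads: int = 3
    n_chains: int = 2
    chain_length: int = 6

    @property
    def beads_per_lipid(self) -> int:
        return self.n_heads + self.n_chains * self.chain_length

    @property
    def bead_types(self) -> np.ndarray:
        return np.array([H] * self.n_heads + [C] * (self.n_chains * self.chain_length), dtype=np.int8)

    @property
    def bonds(self) -> np.ndarray:
        """(n_bonds, 2) intra-lipid bond index pairs (0-based within lipid)."""
        b = [(i, i + 1) for i in range(self.n_heads - 1)]  # H0-H1, H1-H2
        start = self.n_heads
        anchors = [1, 2]  # chain A on H1, chain B on H2
        for c in range(self.n_chains):
            first = start + c * self.chain_length
            b.append((anchors[c], first))
            b.extend((first + k, first + k + 1) for k in range(self.chain_length - 1))
        return np.array(b, dtype=np.int32)

    @property
    def angles(self) -> np.ndarray:
        """(n_angles, 3) stiffness triples along each chain incl. junction."""
        a = []
        start = self.n_heads
        anchors = [1, 2]
        for c in range(self.n_chains):
            first = start + c * self.chain_length
            chain = [anchors[c]] + list(range(first, first + self.chain_length))
            a.extend((chain[k], chain[k + 1], chain[k + 2]) for k in range(len(chain) - 2))
        return np.array(a, dtype=np.int32)


DEFAULT_LIPID = LipidTopology()
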