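"""Liquid-liquid coexistence (binodal) of the binary W/S fluid.

Below a threshold solubility zeta the water/solute mixture demixes into a
solute-poor and a solute-rich liquid.  The coexisting compositions are
measured with the slab method: all solute is seeded into a central slab of
an elongated box, the system is equilibrated, and the z-resolved local
mole fraction Phi_S(z) develops two plateaus whose means are the dilute
and dense binodal branches.  A zone of 3 d on either side of each
detected interface is excluded from the plateau averages to avoid
interfacial broadening bias.

For the model's two studied conditions: zeta = 25/32 (f_WS = 32) stays
uniform at all compositions (good solvent), while zeta = 25/40 (f_WS = 40)
phase-separates with a dilute branch near Phi_S ~ 0.0275 (poor solvent).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .forcefield import S, W

INTERFACE_EXCLUSION = 3.0  # d, on either side of each interface
SEM_FACTOR = 5.0           # branch separation required, in combined SEMs


@dataclass
class CoexistenceResult:
    """Coexisting solute mole fractions from one slab run."""

    zeta: float
    phase_separated: bool
    Phi_dilute: float | None = None
    Phi_dense: float | None = None
    phi_total: float | None = None
    z: np.ndarray = field(default_factory=lambda: np.empty(0))
    profile: np.ndarray = field(default_factory=lambda: np.empty(0))


def _phi_z(frames, slab_width):
    """Per-frame z-profiles of the local solute mole fraction."""
    box = frames[0].box
    L = float(box[2])
    nbins = max(int(round(L / slab_width)), 4)
    prof = np.zeros((len(frames), nbins))
    for f, st in enumerate(frames):
        solv = (st.types == W) | (st.types == S)
        z = st.pos[solv, 2] % L
        is_s = st.types[solv] == S
        tot = np.histogram(z, bins=nbins, range=(0.0, L))[0]
        sct = np.histogram(z[is_s], bins=nbins, range=(0.0, L))[0]
        with np.errstate(invalid="ignore", divide="ignore"):
            prof[f] = np.where(tot > 0, sct / np.maximum(tot, 1), 0.0)
    edges = np.linspace(0.0, L, nbins + 1)
    return 0.5 * (edges[:-1] + edges[1:]), prof


def coexistence_from_slab(traj, zeta: float, slab_width: float = 1.0,
                          exclusion: float = INTERFACE_EXCLUSION,
                          sem_factor: float = SEM_FACTOR) -> CoexistenceResult:
    """Dilute/dense coexisting mole fractions from an equilibrated slab run.

    The dense region is taken as the contiguous (periodic) set of slabs with
    Phi above the mid-range value; its two boundaries are the interfaces.
    The run is declared phase separated only if the branch difference
    exceeds ``sem_factor`` combined standard errors of the plateau means.
    """
    frames = list(traj)
    if not frames:
        raise ValueError("empty trajectory")
    z, prof = _phi_z(frames, slab_width)
    mean = prof.mean(axis=0)
    phi_total = _overall_phi(frames[-1])
    res = CoexistenceResult(zeta=zeta, phase_separated=False, phi_total=phi_total,
                            z=z, profile=mean)
    lo, hi = mean.min(), mean.max()
    if hi - lo < 1e-6:  # flat profile, e.g. pure W or fully mixed
        return res
    dense_mask = mean > 0.5 * (lo + hi)
    if dense_mask.all() or not dense_mask.any():
        return res
    nb = len(mean)
    width = z[1] - z[0]
    pad = int(np.ceil(exclusion / width))
    boundary = np.flatnonzero(dense_mask != np.roll(dense_mask, 1))

    reduced = []

    def _plateau(sel_mask):
        # shrink the exclusion if the region is too narrow to keep >= 2 bins
        # (small desk-scale boxes)
        p = pad
        while p >= 0:
            keep = np.zeros(nb, dtype=bool)
            for b in boundary:
                for k in range(-p, p + 1):
                    keep[(b + k) % nb] = True
            sel = sel_mask & ~keep
            if sel.sum() >= 2:
                if p < pad:
                    reduced.append(p * width)
                return sel
            p -= 1
        return sel_mask

    dil_sel = _plateau(~dense_mask)
    den_sel = _plateau(dense_mask)
    if dil_sel.sum() < 2 or den_sel.sum() < 2:
        return res  # interfaces not resolvable at this box size
    def _branch(sel):
        vals = prof[:, sel].mean(axis=1)  # per-frame plateau mean
        return float(vals.mean()), float(vals.std(ddof=1) / np.sqrt(max(len(vals) - 1, 1)))
    phi_dil, sem_dil = _branch(dil_sel)
    phi_den, sem_den = _branch(den_sel)
    sep = (phi_den - phi_dil) > sem_factor * np.hypot(sem_dil, sem_den)
    if sep:
        if reduced:
            warnings.warn(
                f"interface exclusion reduced to {min(reduced):.1f} d: plateau "
                "region narrower than twice the exclusion zone at this box size")
        res.phase_separated = True
        res.Phi_dilute = phi_dil
        res.Phi_dense = phi_den
    return res


def _overall_phi(state) -> float:
    n_s = int(np.sum(state.types == S))
    n_w = int(np.sum(state.types == W))
    return n_s / max(n_s + n_w, 1)


def classify_solvent(zeta: float, scan_results) -> tuple[str, float | None]:
    """Classify a solubility as good/poor from a scan of slab runs.

    ``scan_results`` is a sequence of :class:`CoexistenceResult` at
    increasing overall Phi_S.  Poor solvent iff any point phase-separates;
    the binodal estimate is the dilute branch of the lowest separating
    point.  A non-monotone separation pattern triggers a warning.
    """
    results = list(scan_results)
    if len(results) < 3:
        raise ValueError("scan at least three overall compositions")
    flags = [r.phase_separated for r in results]
    if any(flags[i] and not flags[j] for i in range(len(flags)) for j in range(i + 1, len(flags))):
        warnings.warn("non-monotone phase-separation flags across the scan; inspect raw results")
    for r in results:
        if r.phase_separated:
            return "poor", r.Phi_dilute
    return "good", None
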