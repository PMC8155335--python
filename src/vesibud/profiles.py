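"""Radial density profiles and solute coverage of spherical vesicles.

For a quasi-spherical vesicle the solute density depends only on the
radial coordinate r measured from the membrane center of mass.  The
solute coverage of the outer leaflet,

    Gamma = (1/A_0) * integral_{r > R_mid} drho_S(r) 4 pi r^2 dr,

integrates the excess density drho_S(r) = rho_S(r) - rho_S,bulk over the
exterior volume and normalizes by the midsurface area A_0 = 4 pi R_mid^2,
where R_mid is located at the peak of the hydrophobic-chain density
profile.  This avoids any arbitrary contact-length criterion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

from .builders import membrane_center
from .engine import SystemState
from .forcefield import C, H

DEFAULT_BIN = 0.25


@dataclass
class RadialProfile:
    """Shell-averaged density profile rho(r) in beads/d^3.

    ``r`` holds bin centers; ``values`` the shell-volume-normalized,
    frame-averaged densities for the selected bead types.
    """

    r: np.ndarray
    values: np.ndarray
    bin_width: float
    types: tuple
    n_frames: int = 1
    n_selected: float = 0.0

    @property
    def shell_volumes(self) -> np.ndarray:
        edges = np.arange(len(self.r) + 1) * self.bin_width
        return 4.0 / 3.0 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)

    def volume_integral(self) -> float:
        """Number of selected beads recovered from the profile."""
        return float(np.sum(self.values * self.shell_volumes))


@dataclass
class CoverageResult:
    """Solute coverage Gamma (beads/d^2) and its geometric ingredients."""

    Gamma: float
    rho_S_bulk: float
    R_mid: float
    A_0: float


def radial_density(traj, types=(C,), bin_width: float = DEFAULT_BIN,
                   center_rule: str = "lipid_com", r_max: float | None = None) -> RadialProfile:
    """Shell histogram of the selected bead types about the vesicle center.

    ``traj`` is any iterable of states sharing bead identities; frames are
    centered individually (center of mass of all H+C beads) and averaged.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    frames = list(traj)
    if not frames:
        raise ValueError("empty trajectory")
    first = frames[0]
    if r_max is None:
        r_max = 0.5 * float(np.min(first.box))
    nbins = int(np.ceil(r_max / bin_width))
    counts = np.zeros(nbins)
    tsel = np.asarray(types)
    n_sel_total = 0
    for st in frames:
        sel = np.isin(st.types, tsel)
        n_sel_total += int(sel.sum())
        if not sel.any():
            continue
        center = membrane_center(st) if center_rule == "lipid_com" else np.asarray(st.box) / 2.0
        rel = st.pos[sel] - center
        rel -= np.round(rel / st.box) * st.box
        radii = np.linalg.norm(rel, axis=1)
        counts += np.histogram(radii, bins=nbins, range=(0.0, nbins * bin_width))[0]
    if n_sel_total == 0:
        warnings.warn("selection matches no beads; returning zero profile")
    edges = np.arange(nbins + 1) * bin_width
    shells = 4.0 / 3.0 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
    values = counts / (shells * len(frames))
    r = 0.5 * (edges[:-1] + edges[1:])
    return RadialProfile(r=r, values=values, bin_width=bin_width, types=tuple(np.atleast_1d(tsel)),
                         n_frames=len(frames), n_selected=n_sel_total / len(frames))


def bulk_plateau(profile: RadialProfile, r_min: float | None = None) -> float:
    """Mean density over the far-field plateau bins (r >= r_min).

    At full scale the profile is flat for r >~ 28 d; when that radius falls
    outside the profile range, the window defaults to the outer 20% of the
    radial range.
    """
    r_hi = profile.r[-1]
    if r_min is None:
        r_min = 28.0 if r_hi > 28.0 else 0.8 * r_hi
    mask = profile.r >= r_min
    if mask.sum() < 3:
        raise ValueError(f"fewer than 3 plateau bins beyond r_min={r_min:.2f}")
    return float(np.mean(profile.values[mask]))


def excess_profile(profile: RadialProfile, rho_S_bulk: float) -> RadialProfile:
    """Excess density drho(r) = rho(r) - rho_bulk (decays to zero far out)."""
    return replace(profile, values=profile.values - rho_S_bulk)


def coverage(excess: RadialProfile, R_mid: float, r_max: float | None = None,
             box=None) -> CoverageResult:
    """Integrate the exterior excess profile into the coverage Gamma.

    Gamma = (1/A_0) sum_{R_mid < r <= r_max} drho(r) 4 pi r^2 dr with
    A_0 = 4 pi R_mid^2.  The upper limit defaults to half the smallest box
    edge minus 1 d (periodic-image guard) when a box is supplied.
    """
    if R_mid <= 0:
        raise ValueError("R_mid must be positive")
    if r_max is None:
        r_max = 0.5 * float(np.min(box)) - 1.0 if box is not None else excess.r[-1]
    mask = (excess.r > R_mid) & (excess.r <= r_max)
    a0 = 4.0 * np.pi * R_mid**2
    gamma = float(np.sum(excess.values[mask] * 4.0 * np.pi * excess.r[mask] ** 2 * excess.bin_width) / a0)
    # recover the bulk value that produced this excess, if embedded
    return CoverageResult(Gamma=gamma, rho_S_bulk=np.nan, R_mid=R_mid, A_0=a0)


def midsurface_radius(chain_profile: RadialProfile, rel_peak_tol: float = 0.8) -> float:
    """Midsurface radius from the peak of the chain-bead density profile.

    The peak bin is refined by a quadratic fit through the three bins around
    the maximum.  A flat profile, or a competing local maximum exceeding
    ``rel_peak_tol`` of the main peak more than 2 d away, raises an
    ambiguity error.
    """
    v = chain_profile.values
    if len(v) < 3:
        raise ValueError("profile too short to locate a midsurface")
    vmax = v.max()
    if vmax <= 0 or (vmax - v.min()) < 1e-12 * max(vmax, 1.0):
        raise ValueError("flat profile: no unambiguous chain-density peak")
    k = int(np.argmax(v))
    interior = (v > 1e-30)  # ignore empty bins for the flatness check
    if np.ptp(v[interior]) < 0.05 * vmax:
        raise ValueError("flat profile: no unambiguous chain-density peak")
    # competing-peak check
    local_max = np.flatnonzero((np.r_[True, v[1:] > v[:-1]] & np.r_[v[:-1] > v[1:], True]))
    for j in local_max:
        if abs(chain_profile.r[j] - chain_profile.r[k]) > 2.0 and v[j] >= rel_peak_tol * vmax:
            raise ValueError("ambiguous profile: comparable chain-density peaks "
                             f"at r={chain_profile.r[k]:.2f} and r={chain_profile.r[j]:.2f}")
    if k == 0 or k == len(v) - 1:
        return float(chain_profile.r[k])
    # parabola through up to 5 bins around the maximum: stabler than a
    # 3-point fit when the peak is flat-topped (small vesicles)
    lo, hi = max(k - 2, 0), min(k + 3, len(v))
    coef = np.polyfit(chain_profile.r[lo:hi], v[lo:hi], 2)
    if coef[0] < 0:
        vertex = -coef[1] / (2.0 * coef[0])
        if chain_profile.r[lo] <= vertex <= chain_profile.r[hi - 1]:
            return float(vertex)
    y0, y1, y2 = v[k - 1], v[k], v[k + 1]
    denom = y0 - 2.0 * y1 + y2
    shift = 0.0 if abs(denom) < 1e-30 else 0.5 * (y0 - y2) / denom
    return float(chain_profile.r[k] + shift * chain_profile.bin_width)


def membrane_thickness(membrane_profile: RadialProfile) -> float:
    """Bilayer thickness l_me as the full width at half maximum of the
    membrane (H+C) density profile; ~5 d for this lipid model."""
    v = membrane_profile.values
    vmax = v.max()
    if vmax <= 0:
        raise ValueError("no bilayer: membrane profile is empty")
    half = 0.5 * vmax
    above = np.flatnonzero(v >= half)
    if len(above) == 0:
        raise ValueError("no bilayer: profile never reaches half maximum")
    lo, hi = above[0], above[-1]
    r, bw = membrane_profile.r, membrane_profile.bin_width

    def _cross(i_out, i_in):  # linear interpolation of the half-max crossing
        if i_out < 0 or i_out >= len(v) or v[i_in] == v[i_out]:
            return r[i_in] + (0.5 if i_in > i_out else -0.5) * bw
        t = (half - v[i_in]) / (v[i_out] - v[i_in])
        return r[i_in] + t * (r[i_out] - r[i_in])

    left = _cross(lo - 1, lo)
    right = _cross(hi + 1, hi)
    width = right - left
    if width <= 0:
        raise ValueError("degenerate membrane profile (zero width)")
    return float(width)


def membrane_profile(traj, bin_width: float = DEFAULT_BIN) -> RadialProfile:
    """Convenience: radial density of all membrane (H+C) beads."""
    return radial_density(traj, types=(H, C), bin_width=bin_width)


def axial_density(traj, types=(H, C), axis: int = 2, bin_width: float = DEFAULT_BIN) -> RadialProfile:
    """Slab-averaged density along one box axis (for planar bilayers/slabs).

    Returns a profile whose ``r`` field holds the axial coordinate; suitable
    for :func:`membrane_thickness` (FWHM) but not for spherical integrals.
    """
    frames = list(traj)
    if not frames:
        raise ValueError("empty trajectory")
    box = frames[0].box
    L = float(box[axis])
    area = float(np.prod(box)) / L
    nbins = int(np.ceil(L / bin_width))
    counts = np.zeros(nbins)
    tsel = np.asarray(types)
    for st in frames:
        sel = np.isin(st.types, tsel)
        counts += np.histogram(st.pos[sel, axis] % L, bins=nbins, range=(0.0, nbins * bin_width))[0]
    values = counts / (area * bin_width * len(frames))
    edges = np.arange(nbins + 1) * bin_width
    return RadialProfile(r=0.5 * (edges[:-1] + edges[1:]), values=values, bin_width=bin_width,
                         types=tuple(np.atleast_1d(tsel)), n_frames=len(frames))
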