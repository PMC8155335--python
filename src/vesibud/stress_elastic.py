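"""Spherical pressure tensor, bilayer tension, and elastic moduli.

For a quasi-spherical vesicle the pressure tensor is diagonal in spherical
coordinates with a normal component P_N(r) and a tangential component
P_T(r); the stress profile is s(r) = P_N(r) - P_T(r).  The configurational
part is distributed over radial shells along straight Irving-Kirkwood
contours between interacting beads (conservative + bonded central forces;
the dissipative and random forces average to zero and are excluded).

Derived quantities, all in reduced units (k_B T, d):

* bilayer tension      Sigma = int dr (r/R_mid)^2 s(r)
  (the mechanical route for a spherical interface; the geometric weight is
  1 at the midsurface),
* first stress moment  <(r - R_mid) s(r)>_0 = int dr (r/R_mid)^2 (r - R_mid) s(r),
  evaluated at (near-)vanishing tension,
* spontaneous curvature m from 2 kappa (m - 1/R_mid) = - <(r - R_mid) s(r)>_0,
  so a vanishing moment gives m = 1/R_mid,
* area compressibility K_A as the slope of Sigma vs area dilation,
* bending rigidity     kappa = K_A l_me^2 / 48.

Integrals run over a window R_mid +/- 5 d by default, which spans the
bilayer (thickness ~5 d) while excluding far-field noise amplified by the
(r/R_mid)^2 weight.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from . import kernels
from .builders import membrane_center
from .engine import SystemState
from .forcefield import C, H, ForceFieldTable

DEFAULT_STRESS_BIN = 0.2
DEFAULT_WINDOW = 5.0
TENSION_TOL = 0.1  # |Sigma| below which a state counts as tensionless (kT/d^2)


@dataclass
class StressProfile:
    """Binned P_N(r), P_T(r) and s(r) = P_N - P_T in k_B T/d^3."""

    r: np.ndarray
    P_N: np.ndarray
    P_T: np.ndarray
    bin_width: float
    n_frames: int = 1

    @property
    def s(self) -> np.ndarray:
        return self.P_N - self.P_T

    @property
    def shell_volumes(self) -> np.ndarray:
        edges = np.arange(len(self.r) + 1) * self.bin_width
        return 4.0 / 3.0 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)

    def mean_pressure(self) -> float:
        """Volume average of (P_N + 2 P_T)/3 — matches the global virial
        pressure (kinetic + configurational) of the same frames."""
        trace = (self.P_N + 2.0 * self.P_T) / 3.0
        vols = self.shell_volumes
        return float(np.sum(trace * vols) / np.sum(vols))


@dataclass
class ElasticSummary:
    """Midsurface geometry, tension, moments and moduli of one vesicle."""

    R_mid: float
    Sigma: float
    first_moment: float
    K_A: float | None = None
    kappa: float | None = None
    m: float | None = None
    l_me: float | None = None
    Gamma: float | None = None


def spherical_stress_profile(traj, ff: ForceFieldTable, center_rule: str = "lipid_com",
                             bin_width: float = DEFAULT_STRESS_BIN,
                             r_max: float | None = None) -> StressProfile:
    """Frame-averaged spherical stress profile about the vesicle center.

    Frames are centered individually on the lipid center of mass (or the
    box center for bulk fluids); a center drift above 1 d between frames
    triggers a warning but per-frame centering is always applied.
    """
    frames = list(traj)
    if not frames:
        raise ValueError("empty trajectory")
    first = frames[0]
    if r_max is None:
        # cover the whole box (to the corner) so the binned virial is complete
        r_max = 0.5 * float(np.linalg.norm(first.box))
    nbins = int(np.ceil(r_max / bin_width))
    accN = np.zeros(nbins)
    accT = np.zeros(nbins)
    prev_center = None
    has_lipids = bool(np.any((first.types == H) | (first.types == C)))
    for st in frames:
        if center_rule == "lipid_com" and has_lipids:
            center = membrane_center(st)
        else:
            center = np.asarray(st.box, dtype=float) / 2.0
        if prev_center is not None:
            drift = np.linalg.norm((center - prev_center + st.box / 2) % st.box - st.box / 2)
            if drift > 1.0:
                warnings.warn(f"center drift {drift:.2f} d between frames; per-frame centering applied")
        prev_center = center
        kernels.stress_accumulate(st.pos, st.vel, st.types, st.box, center, ff.f, ff.cutoff,
                                  st.bonds, ff.bond_k, ff.bond_l0, st.angles, ff.bend_k,
                                  bin_width, accN, accT)
    edges = np.arange(nbins + 1) * bin_width
    shells = 4.0 / 3.0 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
    norm = shells * len(frames)
    return StressProfile(r=0.5 * (edges[:-1] + edges[1:]), P_N=accN / norm, P_T=accT / norm,
                         bin_width=bin_width, n_frames=len(frames))


def _window_mask(sp: StressProfile, R_mid: float, window: float):
    lo, hi = max(R_mid - window, 0.0), R_mid + window
    if sp.r[-1] + 0.5 * sp.bin_width < hi or sp.r[0] - 0.5 * sp.bin_width > lo:
        raise ValueError(
            f"stress profile [{sp.r[0]:.2f}, {sp.r[-1]:.2f}] does not cover the bilayer window "
            f"[{lo:.2f}, {hi:.2f}]")
    return (sp.r >= lo) & (sp.r <= hi)


def bilayer_tension(sp: StressProfile, R_mid: float, window: float = DEFAULT_WINDOW) -> float:
    """Sigma = int dr (r/R_mid)^2 s(r) over the bilayer window."""
    if R_mid <= 0:
        raise ValueError("R_mid must be positive")
    mask = _window_mask(sp, R_mid, window)
    w = (sp.r[mask] / R_mid) ** 2
    return float(np.sum(w * sp.s[mask]) * sp.bin_width)


def first_moment(sp: StressProfile, R_mid: float, Sigma: float | None = None,
                 window: float = DEFAULT_WINDOW, tension_tol: float = TENSION_TOL) -> float:
    """First stress moment <(r - R_mid) s(r)>_0 over the bilayer window.

    Meaningful only at (near-)vanishing bilayer tension: if the tension of
    the same profile exceeds ``tension_tol`` the call refuses, pointing to
    the tensionless-state search.  Pass ``tension_tol=None`` to skip the
    guard (e.g. for synthetic profiles).
    """
    if R_mid <= 0:
        raise ValueError("R_mid must be positive")
    if tension_tol is not None:
        if Sigma is None:
            Sigma = bilayer_tension(sp, R_mid, window=window)
        if abs(Sigma) > tension_tol:
            raise ValueError(
                f"|Sigma| = {abs(Sigma):.3f} kT/d^2 exceeds the tensionless tolerance "
                f"{tension_tol}; deflate/inflate to a tensionless state first")
    mask = _window_mask(sp, R_mid, window)
    w = (sp.r[mask] / R_mid) ** 2 * (sp.r[mask] - R_mid)
    return float(np.sum(w * sp.s[mask]) * sp.bin_width)


def spontaneous_curvature(moment: float, kappa: float, R_mid: float) -> float:
    """Invert 2 kappa (m - 1/R_mid) = -<(r - R_mid) s(r)>_0 for m."""
    if kappa <= 0:
        raise ValueError("bending rigidity must be positive")
    if R_mid <= 0:
        raise ValueError("R_mid must be positive")
    return 1.0 / R_mid - moment / (2.0 * kappa)


def area_compressibility(dilations, tensions) -> float:
    """K_A as the least-squares slope of Sigma vs (A - A_0)/A_0 near zero.

    Two points fall back to the finite-difference slope; a degenerate
    dilation range raises.
    """
    x = np.asarray(dilations, dtype=float)
    y = np.asarray(tensions, dtype=float)
    if x.size < 2:
        raise ValueError("need at least two (dilation, tension) points")
    if np.ptp(x) < 1e-12:
        raise ValueError("degenerate dilation range")
    A = np.stack([x, np.ones_like(x)], axis=1)
    slope, _ = np.linalg.lstsq(A, y, rcond=None)[0]
    return float(slope)


def bending_rigidity(K_A: float, l_me: float) -> float:
    """kappa = K_A l_me^2 / 48 (membrane thickness l_me ~ 5 d here)."""
    return K_A * l_me**2 / 48.0


def find_tensionless(waters, tension_fn, spec=None):
    """Locate the interior water count N_W0_in at which Sigma crosses zero.

    ``tension_fn(N_W_in) -> Sigma`` evaluates the bilayer tension for a
    given interior water count (typically a short deflation + relaxation
    run); ``waters`` lists at least three counts to scan.  The zero
    crossing is linearly interpolated between the bracketing pair.  Returns
    (N_W0_in, nu_0) with nu_0 = N_W0_in / N_W_isp when ``spec`` provides a
    reference count, else nu_0 = None.
    """
    waters = sorted(int(n) for n in waters)
    if len(waters) < 3:
        raise ValueError("scan at least three interior water counts")
    sig = np.array([tension_fn(n) for n in waters], dtype=float)
    signs = np.sign(sig)
    crossing = None
    for k in range(len(waters) - 1):
        if signs[k] == 0:
            crossing = float(waters[k])
            break
        if signs[k] * signs[k + 1] < 0:
            n0, n1 = waters[k], waters[k + 1]
            s0, s1 = sig[k], sig[k + 1]
            crossing = n0 - s0 * (n1 - n0) / (s1 - s0)
            break
    else:
        if signs[-1] == 0:
            crossing = float(waters[-1])
    if crossing is None:
        raise ValueError(
            f"no tension sign change in scanned bracket N_W_in={waters[0]}..{waters[-1]} "
            f"(Sigma from {sig[0]:.3f} to {sig[-1]:.3f})")
    n_w0 = int(round(crossing))
    nu_0 = None
    if spec is not None:
        n_ref = getattr(spec, "N_W_isp", None)
        if n_ref:
            nu_0 = n_w0 / n_ref
    return n_w0, nu_0


def vesicle_tension_evaluator(spec, ff: ForceFieldTable, cfg=None, n_relax: int = 400,
                              n_steps: int = 4000, stride: int = 400):
    """Build a ``tension_fn(N_W_in)`` for :func:`find_tensionless`.

    Assembles the vesicle, deflates/inflates it to the requested interior
    water count, runs short dynamics and returns the bilayer tension from
    the frame-averaged stress profile.  Run lengths are the caller's
    accuracy/cost trade-off; the defaults suit desk-scale vesicles.
    """
    from .builders import build_vesicle, set_volume, soft_relax
    from .engine import IntegratorConfig, run
    from .profiles import midsurface_radius, radial_density

    cfg = cfg or IntegratorConfig()
    base = build_vesicle(spec)
    n_ref = base.meta["N_W_isp"]

    def tension_fn(n_w_in: int) -> float:
        state = set_volume(base, n_w_in / n_ref)
        state = soft_relax(state, ff, n_steps=n_relax)
        _, traj, _ = run(state, cfg, ff, n_steps, stride=stride)
        frames = traj.frames[len(traj) // 2:]
        chain = radial_density(frames, types=(C,), bin_width=0.25)
        r_mid = midsurface_radius(chain)
        sp = spherical_stress_profile(frames, ff, bin_width=0.25)
        return bilayer_tension(sp, r_mid, window=min(DEFAULT_WINDOW, r_mid - 0.5))

    return tension_fn
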