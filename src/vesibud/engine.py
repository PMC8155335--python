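"""DPD dynamics driver: NVT/NPT integration, forces, and global pressure.

The integrator is the modified velocity-Verlet scheme customary for DPD,
in which the dissipative force at the end of a step is evaluated with
velocities predicted as v + lambda*dt*f.  NPT is a weak-coupling
(Berendsen-type) isotropic box rescaling on the total pressure; the model
uses it only to set the bulk density before NVT production, so a rigorous
barostat ensemble is not needed.

Reduced units throughout: bead diameter d = 1, k_B T = 1, bead mass = 1,
time unit tau = d sqrt(m / k_B T).
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import kernels
from .forcefield import DEFAULT_LIPID, ForceFieldTable, LipidTopology


class DivergenceError(RuntimeError):
    """Raised when the integration produces non-finite coordinates."""


_EMPTY_BONDS = np.empty((0, 2), dtype=np.int32)
_EMPTY_ANGLES = np.empty((0, 3), dtype=np.int32)


@dataclass
class SystemState:
    """Complete mechanical state of a simulation box.

    Positions are stored wrapped into [0, L) per axis; bonds/angles are
    global bead-index arrays assembled from the per-lipid topology.
    ``meta`` carries builder bookkeeping (bead partitions, reference counts)
    and is passed through untouched by the engine.
    """

    box: np.ndarray
    pos: np.ndarray
    vel: np.ndarray
    types: np.ndarray
    mol: np.ndarray
    bonds: np.ndarray = field(default_factory=lambda: _EMPTY_BONDS.copy())
    angles: np.ndarray = field(default_factory=lambda: _EMPTY_ANGLES.copy())
    topology: LipidTopology = field(default_factory=lambda: DEFAULT_LIPID)
    seed: int = 0
    step: int = 0
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.box = np.asarray(self.box, dtype=float).reshape(3)
        self.pos = np.ascontiguousarray(self.pos, dtype=float)
        self.vel = np.ascontiguousarray(self.vel, dtype=float)
        self.types = np.ascontiguousarray(self.types, dtype=np.int8)
        self.mol = np.ascontiguousarray(self.mol, dtype=np.int32)
        self.bonds = np.ascontiguousarray(self.bonds, dtype=np.int32).reshape(-1, 2)
        self.angles = np.ascontiguousarray(self.angles, dtype=np.int32).reshape(-1, 3)
        kernels.wrap_positions(self.pos, self.box)

    @property
    def n_beads(self) -> int:
        return self.pos.shape[0]

    @property
    def volume(self) -> float:
        return float(np.prod(self.box))

    @property
    def density(self) -> float:
        return self.n_beads / self.volume

    def copy(self) -> "SystemState":
        return SystemState(
            box=self.box.copy(), pos=self.pos.copy(), vel=self.vel.copy(),
            types=self.types.copy(), mol=self.mol.copy(), bonds=self.bonds.copy(),
            angles=self.angles.copy(), topology=self.topology, seed=self.seed,
            step=self.step, meta=copy.deepcopy(self.meta),
        )

    def kinetic_temperature(self) -> float:
        return float(np.sum(self.vel**2) / (3.0 * self.n_beads))

    def total_momentum(self) -> np.ndarray:
        return self.vel.sum(axis=0)


@dataclass
class IntegratorConfig:
    """Timestep, thermostat prediction parameter, and ensemble settings.

    dt in tau; lambda_v is the velocity-prediction parameter of the DPD
    velocity-Verlet scheme; NPT couples the box isotropically toward
    ``target_pressure`` (total, k_B T/d^3) with coupling time
    ``barostat_tau`` (tau).
    """

    dt: float = 0.01
    lambda_v: float = 0.65
    ensemble: str = "NVT"
    target_pressure: float = 23.7
    barostat_tau: float = 10.0

    def __post_init__(self):
        if self.dt <= 0:
            raise ValueError(f"dt must be positive, got {self.dt}")
        if not 0 < self.lambda_v < 1:
            raise ValueError(f"lambda_v must be in (0, 1), got {self.lambda_v}")
        if self.ensemble not in ("NVT", "NPT"):
            raise ValueError(f"ensemble must be NVT or NPT, got {self.ensemble!r}")


def _cell_grid(box: np.ndarray, rc: float):
    nc = np.floor(box / rc).astype(np.int64)
    if np.any(nc < 3):
        return None  # cell list degenerate -> all-pairs fallback
    return nc


def _scratch(n: int, box: np.ndarray, rc: float):
    nc = _cell_grid(box, rc)
    use_cells = nc is not None
    if not use_cells:
        nc = np.array([1, 1, 1], dtype=np.int64)
    ncells = int(np.prod(nc))
    cellid = np.zeros(n, dtype=np.int64)
    counts = np.zeros(ncells, dtype=np.int64)
    cellstart = np.zeros(ncells + 1, dtype=np.int64)
    order = np.zeros(n, dtype=np.int64)
    return use_cells, nc, (cellid, counts, cellstart, order)


def compute_forces(state: SystemState, ff: ForceFieldTable, with_thermostat: bool = False,
                   dt: float = 0.01, all_pairs: bool = False):
    """Per-bead force vectors and the conservative virial sum F.r.

    By default only conservative + bonded forces are returned; with
    ``with_thermostat`` the dissipative and random pair forces (for timestep
    ``dt``) are added.  ``all_pairs`` forces the O(N^2) reference path, which
    is also used automatically when the box is below three cutoffs.
    """
    forces = np.zeros_like(state.pos)
    inv_sqrt_dt = 1.0 / np.sqrt(dt)
    use_cells, nc, cells = _scratch(state.n_beads, state.box, ff.cutoff)
    args = (state.pos, state.vel, state.types, state.box, ff.f, ff.cutoff, ff.gamma, ff.sigma,
            inv_sqrt_dt, with_thermostat, state.bonds, ff.bond_k, ff.bond_l0, state.angles,
            ff.bend_k, forces)
    if all_pairs or not use_cells:
        vir = kernels.compute_forces_allpairs(*args)
    else:
        vir = kernels.compute_forces_cells(*args, *cells, nc[0], nc[1], nc[2])
    return forces, float(vir)


def virial_pressure(state: SystemState, ff: ForceFieldTable) -> tuple[float, float]:
    """Instantaneous (P_excess, P_total) from the global virial.

    P_excess is the isotropic configurational (virial-only) pressure
    sum(F.r)/(3V); P_total adds the ideal kinetic term rho k_B T.
    """
    if state.n_beads == 0:
        raise ValueError("empty system has no pressure")
    _, vir = compute_forces(state, ff, with_thermostat=False)
    p_excess = vir / (3.0 * state.volume)
    return p_excess, p_excess + state.density


@dataclass
class Trajectory:
    """Frames emitted by :func:`run` (positions/velocities are copies)."""

    frames: list = field(default_factory=list)  # list of SystemState snapshots

    def __len__(self):
        return len(self.frames)

    def __iter__(self):
        return iter(self.frames)

    def __getitem__(self, i):
        return self.frames[i]


def step(state: SystemState, cfg: IntegratorConfig, ff: ForceFieldTable, n_steps: int = 1,
         reseed: bool = True) -> SystemState:
    """Advance ``n_steps`` timesteps and return the new state (input untouched)."""
    out = state.copy()
    _advance_inplace(out, cfg, ff, n_steps, reseed=reseed)
    return out


def _advance_inplace(state: SystemState, cfg: IntegratorConfig, ff: ForceFieldTable,
                     n_steps: int, reseed: bool = False, sample_every: int = 10**9):
    if reseed:
        kernels.seed_rng(state.seed % 2**31)
    n = state.n_beads
    use_cells, nc, cells = _scratch(n, state.box, ff.cutoff)
    temp_out = np.zeros(n_steps + 1)
    vir_out = np.zeros(n_steps + 1)
    f = np.zeros_like(state.pos)
    fnew = np.zeros_like(state.pos)
    vpred = np.zeros_like(state.pos)
    ns = kernels.advance(
        state.pos, state.vel, state.types, state.box, ff.f, ff.cutoff, ff.gamma, ff.sigma,
        cfg.dt, cfg.lambda_v, n_steps, state.bonds, ff.bond_k, ff.bond_l0, state.angles,
        ff.bend_k, use_cells, f, fnew, vpred, *cells, nc[0], nc[1], nc[2],
        min(sample_every, max(1, n_steps)), temp_out, vir_out,
    )
    if ns < 0:
        raise DivergenceError(f"non-finite coordinates at step {state.step - ns}")
    state.step += n_steps
    # fastmath kernels cannot self-detect NaN; verify at chunk granularity
    if not np.all(np.isfinite(state.pos)):
        raise DivergenceError(f"non-finite coordinates by step {state.step}")
    return temp_out[:ns], vir_out[:ns]


def run(state: SystemState, cfg: IntegratorConfig, ff: ForceFieldTable, n_steps: int,
        stride: int = 1000, observers: tuple = (), sample_every: int = 50,
        log=None) -> tuple[SystemState, Trajectory, pd.DataFrame]:
    """Run ``n_steps`` of dynamics, emitting frames every ``stride`` steps.

    Returns (final state, trajectory, observable time series).  The series
    columns are step, time, T (kinetic), P_excess, P_total and the box edges,
    averaged over samples taken every ``sample_every`` steps within each
    stride block.  Observer callables receive (state, step) at each emitted
    frame; an observer failure is logged and the run continues.

    Determinism: the numba RNG is seeded from ``state.seed`` at entry, so
    identical (state, config) inputs reproduce identical trajectories.
    """
    state = state.copy()
    kernels.seed_rng(state.seed % 2**31)
    traj = Trajectory()
    records = []
    done = 0
    while done < n_steps:
        block = min(stride, n_steps - done)
        temps, virs = _advance_inplace(state, cfg, ff, block, sample_every=sample_every)
        done += block
        vol = state.volume
        p_exc = float(np.mean(virs)) / (3.0 * vol) if len(virs) else np.nan
        p_tot = p_exc + state.density
        records.append({
            "step": state.step, "time": state.step * cfg.dt,
            "T": float(np.mean(temps)) if len(temps) else np.nan,
            "P_excess": p_exc, "P_total": p_tot,
            "Lx": state.box[0], "Ly": state.box[1], "Lz": state.box[2],
        })
        if cfg.ensemble == "NPT":
            # weak isotropic coupling of the box toward the target pressure
            kappa = block * cfg.dt / cfg.barostat_tau
            mu = (1.0 + kappa * (p_tot - cfg.target_pressure) / cfg.target_pressure) ** (1.0 / 3.0)
            mu = min(max(mu, 0.98), 1.02)
            state.box *= mu
            state.pos *= mu
            kernels.wrap_positions(state.pos, state.box)
        traj.frames.append(state.copy())
        for obs in observers:
            try:
                obs(state, state.step)
            except Exception as exc:  # noqa: BLE001 - observer isolation by contract
                if log is not None:
                    log.warning("observer %r failed at step %d: %s", obs, state.step, exc)
        if log is not None:
            log.info("step %d T=%.3f P=%.2f", state.step, records[-1]["T"], p_tot)
    return state, traj, pd.DataFrame.from_records(records)
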