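"""Euler-Maruyama integration of the stochastic pluripotency network.

Update rule per step of length ``dt`` (minutes), independently per cell:

    X <- max(0, X + f_X dt + sigma_X X sqrt(dt) Z),   X in {OS, N, R}
    E <- max(0, E + f_E dt)                           (no noise on Erk)

with ``Z`` standard normal.  The noise is multiplicative (amplitude
proportional to the current concentration), evaluated at the pre-update
concentration, and the zero lower bound is applied after the full update.
Erk and the extrinsic signal Y carry no stochastic term.

Per-cell random streams are derived counter-style from
``SeedSequence((master_seed, cell_id))`` so populations are reproducible
bit-for-bit and independent of execution order.  The inner loop is
JIT-compiled with numba; ``_integrate.py_func`` is the identical
pure-Python code path used as a slow reference in the test suite.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from numba import njit

from .params import CellState, ParameterSet

__all__ = [
    "Trajectory",
    "PopulationRun",
    "simulate_cell",
    "simulate_population",
    "cell_seeds",
]

# indices into ParameterSet.to_vector() (canonical field order)
_I_S12, _I_S3, _I_S4, _I_S5, _I_S6, _I_S7 = 0, 1, 2, 3, 4, 5
_I_K, _I_N, _I_P = 6, 7, 8
_I_DOS, _I_DN, _I_DR, _I_DE = 9, 10, 11, 12
_I_IOS, _I_IN, _I_IR = 13, 14, 15
_I_SOS, _I_SN, _I_SR = 16, 17, 18
_I_Y, _I_KY, _I_H = 19, 20, 21


@njit(cache=True)
def _integrate(init, pvec, n_steps, dt, seeds, stride,
               use_ramp, ramp_pmax, ramp_slope, ramp_tmid, out):
    """Integrate all cells; record state every ``stride`` steps into ``out``.

    ``out`` has shape (n_cells, n_steps // stride + 1, 4) and includes the
    initial state.  When ``use_ramp`` is true the Erk repression strength of
    cell ``i`` follows the logistic ramp
    ``p_i(t) = ramp_pmax / (1 + exp(-ramp_slope (t - ramp_tmid[i])))``;
    otherwise the constant ``p`` from the parameter vector is used.
    """
    n_cells = init.shape[0]
    s12 = pvec[_I_S12]; s3 = pvec[_I_S3]; s4 = pvec[_I_S4]
    s5 = pvec[_I_S5]; s6 = pvec[_I_S6]; s7 = pvec[_I_S7]
    k = pvec[_I_K]; n_hill = pvec[_I_N]; p_const = pvec[_I_P]
    d_os = pvec[_I_DOS]; d_n = pvec[_I_DN]; d_r = pvec[_I_DR]; d_e = pvec[_I_DE]
    i_os = pvec[_I_IOS]; i_n = pvec[_I_IN]; i_r = pvec[_I_IR]
    sg_os = pvec[_I_SOS]; sg_n = pvec[_I_SN]; sg_r = pvec[_I_SR]
    y_lvl = pvec[_I_Y]; k_y = pvec[_I_KY]; h_y = pvec[_I_H]
    sqdt = np.sqrt(dt)
    quad = n_hill == 2.0  # fast path for the default dimer Hill coefficient
    quad_gate = h_y == 2.0

    for i in range(n_cells):
        np.random.seed(seeds[i])
        os_ = init[i, 0]; n_ = init[i, 1]; r_ = init[i, 2]; e_ = init[i, 3]
        out[i, 0, 0] = os_; out[i, 0, 1] = n_
        out[i, 0, 2] = r_; out[i, 0, 3] = e_
        rec = 1
        for step in range(n_steps):
            if os_ > 0.0:
                rr = (os_ / k) * (os_ / k) if quad else (os_ / k) ** n_hill
                h_os = rr / (1.0 + rr)
            else:
                h_os = 0.0
            if n_ > 0.0:
                rr = (n_ / k) * (n_ / k) if quad else (n_ / k) ** n_hill
                h_n = rr / (1.0 + rr)
            else:
                h_n = 0.0
            if use_ramp:
                t = step * dt
                p_now = ramp_pmax / (1.0 + np.exp(-ramp_slope * (t - ramp_tmid[i])))
            else:
                p_now = p_const
            if e_ > 0.0 and p_now != 0.0:
                rr = (e_ / k) * (e_ / k) if quad else (e_ / k) ** n_hill
                g_p = 1.0 / (1.0 + p_now * (rr / (1.0 + rr)))
            else:
                g_p = 1.0
            if y_lvl > 0.0:
                rr = (n_ / k_y) * (n_ / k_y) if quad_gate else (n_ / k_y) ** h_y
                y_in = y_lvl / (1.0 + rr)
            else:
                y_in = 0.0

            f_os = s12 * h_os - d_os * (1.0 + i_os * y_in) * os_
            f_n = (s3 * h_os + s4 * h_n) * g_p - d_n * (1.0 + i_n * y_in) * n_
            f_r = s5 * h_os + s6 * h_n - d_r * (1.0 + i_r * y_in) * r_
            f_e = s7 * h_os - d_e * e_

            z_os = np.random.normal(0.0, 1.0)
            z_n = np.random.normal(0.0, 1.0)
            z_r = np.random.normal(0.0, 1.0)

            os_ = max(0.0, os_ + f_os * dt + sg_os * os_ * sqdt * z_os)
            n_ = max(0.0, n_ + f_n * dt + sg_n * n_ * sqdt * z_n)
            r_ = max(0.0, r_ + f_r * dt + sg_r * r_ * sqdt * z_r)
            e_ = max(0.0, e_ + f_e * dt)

            if (step + 1) % stride == 0:
                out[i, rec, 0] = os_; out[i, rec, 1] = n_
                out[i, rec, 2] = r_; out[i, rec, 3] = e_
                rec += 1
    return out


@dataclass
class Trajectory:
    """Single-cell time course on a uniform grid (times in minutes)."""

    cell_id: int
    times: np.ndarray
    states: np.ndarray  # shape (n_times, 4): columns OS, N, R, E
    seed: int
    dt: float

    @property
    def OS(self) -> np.ndarray:
        return self.states[:, 0]

    @property
    def N(self) -> np.ndarray:
        return self.states[:, 1]

    @property
    def R(self) -> np.ndarray:
        return self.states[:, 2]

    @property
    def E(self) -> np.ndarray:
        return self.states[:, 3]

    def terminal_state(self) -> CellState:
        return CellState.from_array(self.states[-1])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cell_id": self.cell_id,
                "t_min": self.times,
                "OS": self.OS,
                "N": self.N,
                "R": self.R,
                "E": self.E,
            }
        )


@dataclass
class PopulationRun:
    """Vectorized multi-cell run: ``states[cell, time, species]``."""

    params: ParameterSet
    times: np.ndarray
    states: np.ndarray
    master_seed: int
    dt: float
    seeds: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    scenario_label: str = ""

    @property
    def n_cells(self) -> int:
        return self.states.shape[0]

    def species(self, name: str) -> np.ndarray:
        idx = {"OS": 0, "N": 1, "R": 2, "E": 3}[name]
        return self.states[:, :, idx]

    def trajectory(self, cell_id: int) -> Trajectory:
        return Trajectory(
            cell_id=cell_id,
            times=self.times,
            states=self.states[cell_id],
            seed=int(self.seeds[cell_id]) if self.seeds.size else -1,
            dt=self.dt,
        )

    def terminal_states(self) -> np.ndarray:
        return self.states[:, -1, :]

    def snapshot_frame(self, t_index: int = -1) -> pd.DataFrame:
        snap = self.states[:, t_index, :]
        return pd.DataFrame(
            {
                "cell_id": np.arange(self.n_cells),
                "t_min": self.times[t_index],
                "OS": snap[:, 0],
                "N": snap[:, 1],
                "R": snap[:, 2],
                "E": snap[:, 3],
            }
        )

    def write_snapshot_csv(self, path: str | Path, t_index: int = -1) -> None:
        _write_csv_with_header(self.snapshot_frame(t_index), path, self)

    def write_trajectories_csv(self, path: str | Path) -> None:
        frame = pd.concat(
            [self.trajectory(i).to_frame() for i in range(self.n_cells)],
            ignore_index=True,
        )
        _write_csv_with_header(frame, path, self)


def _write_csv_with_header(frame: pd.DataFrame, path: str | Path, run) -> None:
    with open(path, "w") as fh:
        fh.write(f"# master_seed = {run.master_seed}\n")
        fh.write(f"# dt_min = {run.dt}\n")
        for key, value in run.params.to_mapping().items():
            fh.write(f"# {key} = {value}\n")
        frame.to_csv(fh, index=False)


def cell_seeds(master_seed: int, n_cells: int) -> np.ndarray:
    """Counter-based per-cell seeds: ``SeedSequence((master_seed, cell_id))``.

    Independent of execution order and of ``n_cells`` (cell ``i`` always
    receives the same stream).
    """
    return np.array(
        [
            np.random.SeedSequence((master_seed, cid)).generate_state(1)[0]
            for cid in range(n_cells)
        ],
        dtype=np.int64,
    )


def _check_step(params: ParameterSet, dt: float) -> None:
    d_max = max(params.d_OS, params.d_N, params.d_R, params.d_E)
    d_max *= 1.0 + max(params.i_OS, params.i_N, params.i_R) * params.Y
    if d_max * dt > 0.5:
        warnings.warn(
            f"dt = {dt} min is large for degradation rate {d_max:.3g}/min; "
            "the explicit Euler-Maruyama update may be unstable",
            stacklevel=3,
        )


def _run_kernel(params, init, duration, dt, seeds, record_stride,
                ramp=None, use_python=False):
    n_steps = int(round(duration / dt))
    if n_steps < 1:
        raise ValueError("duration must be at least one step dt")
    _check_step(params, dt)
    init = np.ascontiguousarray(init, dtype=np.float64)
    n_cells = init.shape[0]
    n_rec = n_steps // record_stride + 1
    out = np.empty((n_cells, n_rec, 4), dtype=np.float64)
    if ramp is None:
        use_ramp, pmax, slope = False, 0.0, 0.0
        tmid = np.zeros(n_cells)
    else:
        use_ramp = True
        pmax, slope, tmid = ramp
        tmid = np.ascontiguousarray(tmid, dtype=np.float64)
    fn = _integrate.py_func if use_python else _integrate
    fn(init, params.to_vector(), n_steps, float(dt), seeds,
       int(record_stride), use_ramp, float(pmax), float(slope), tmid, out)
    if not np.all(np.isfinite(out)):
        bad = np.argwhere(~np.isfinite(out))[0]
        raise FloatingPointError(
            f"non-finite concentration for cell {bad[0]} at record index {bad[1]}"
            f" (t = {bad[1] * record_stride * dt:.1f} min); reduce dt"
        )
    times = np.arange(n_rec) * (record_stride * dt)
    return times, out


def simulate_cell(
    params: ParameterSet,
    init: CellState,
    duration: float,
    dt: float = 0.1,
    seed: int = 0,
    record_stride: int = 1,
    use_python: bool = False,
) -> Trajectory:
    """Integrate one cell for ``duration`` minutes and return its trajectory.

    The same seed always yields the identical trajectory.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    if not isinstance(init, CellState):
        init = CellState(*init)
    seeds = np.array([seed], dtype=np.int64)
    times, out = _run_kernel(
        params, init.to_array()[None, :], duration, dt, seeds, record_stride,
        use_python=use_python,
    )
    return Trajectory(cell_id=0, times=times, states=out[0], seed=seed, dt=dt)


def _resolve_init_policy(policy, params: ParameterSet, n_cells: int,
                         master_seed: int) -> np.ndarray:
    from .steady_state import find_fixed_points, stable_branch_states

    if isinstance(policy, np.ndarray):
        arr = np.asarray(policy, dtype=np.float64)
        if arr.shape != (n_cells, 4):
            raise ValueError("explicit init states must have shape (n_cells, 4)")
        return arr
    if isinstance(policy, CellState):
        return np.tile(policy.to_array(), (n_cells, 1))

    if isinstance(policy, tuple) and policy[0] == "mixed":
        nl_fraction = float(policy[1])
    elif policy in ("at_NH", "at_NL"):
        nl_fraction = None
    else:
        raise ValueError(f"unknown init policy {policy!r}")

    branches = stable_branch_states(find_fixed_points(params.replace(Y=0.0)))
    if policy == "at_NH" or nl_fraction is not None:
        if "NH" not in branches:
            raise ValueError("no NH fixed point for this parameter set")
    if policy == "at_NL" or nl_fraction is not None:
        if "NL" not in branches:
            raise ValueError("no NL fixed point for this parameter set")

    if policy == "at_NH":
        return np.tile(branches["NH"], (n_cells, 1))
    if policy == "at_NL":
        return np.tile(branches["NL"], (n_cells, 1))
    n_low = int(round(nl_fraction * n_cells))
    init = np.tile(branches["NH"], (n_cells, 1))
    init[:n_low] = branches["NL"]
    return init


def simulate_population(
    params: ParameterSet,
    n_cells: int,
    init_policy="at_NH",
    duration: float = 4320.0,
    dt: float = 0.1,
    master_seed: int = 0,
    record_stride: int = 1,
    ramp=None,
    scenario_label: str = "",
    use_python: bool = False,
) -> PopulationRun:
    """Run ``n_cells`` independent cells with per-cell derived seeds.

    ``init_policy`` is ``"at_NH"``, ``"at_NL"``, ``("mixed", nl_fraction)``,
    a single :class:`CellState`, or an explicit ``(n_cells, 4)`` array.
    ``record_stride`` thins storage to every m-th step (the initial state is
    always recorded).  ``ramp`` is an optional ``(p_max, slope, t_mid_array)``
    triple activating the per-cell logistic ramp of the repression rate p.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    if dt <= 0:
        raise ValueError("dt must be > 0")
    init = _resolve_init_policy(init_policy, params, n_cells, master_seed)
    seeds = cell_seeds(master_seed, n_cells)
    times, out = _run_kernel(
        params, init, duration, dt, seeds, record_stride, ramp=ramp,
        use_python=use_python,
    )
    return PopulationRun(
        params=params,
        times=times,
        states=out,
        master_seed=master_seed,
        dt=dt,
        seeds=seeds,
        scenario_label=scenario_label,
    )
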