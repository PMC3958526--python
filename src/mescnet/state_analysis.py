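"""Attractor-basin analysis of simulated Nanog trajectories.

A *state transition* is a stochastic switch between the Nanog-high (NH)
and Nanog-low (NL) attractor basins, the boundary being the Nanog
coordinate of the saddle that separates them.  A boundary crossing only
counts as a valid transition if the cell then stays on the destination
side continuously for at least ``min_residence`` minutes (one hour by
default), which separates substantial changes of the expression pattern
from transient fluctuations.  Shorter excursions are ignored and do not
reset the current basin.

Residence intervals are the stretches between consecutive valid
transitions; intervals truncated by the start or end of the simulation
are censored and excluded from mean residence times.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .params import ParameterSet
from .sde import PopulationRun, Trajectory, simulate_population
from .steady_state import find_fixed_points, stable_branch_states

__all__ = [
    "TransitionEvent",
    "ResidenceRecord",
    "RateReport",
    "basin_boundary",
    "detect_transitions",
    "residence_records",
    "transition_rate",
    "residence_statistics",
    "nl_fraction_sweep",
    "transitions_vs_noise",
]

MIN_RESIDENCE_MIN = 60.0
MINUTES_PER_DAY = 1440.0


@dataclass(frozen=True)
class TransitionEvent:
    """A validated basin switch of one cell."""

    cell_id: int
    time: float  # minutes, first sample on the destination side
    direction: str  # "NH->NL" or "NL->NH"
    residence_in_destination: float  # minutes until next valid switch or end


@dataclass(frozen=True)
class ResidenceRecord:
    """A (possibly censored) stay of one cell in one basin."""

    cell_id: int
    basin: str  # "NH" or "NL"
    start: float
    end: float
    censored: bool

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass(frozen=True)
class RateReport:
    """Valid-transition rate with a bootstrap confidence interval."""

    n_events: int
    n_cells: int
    duration_days: float
    per_cell_per_day: float
    per_cell_per_hour: float
    ci_low: float
    ci_high: float


def basin_boundary(params: ParameterSet) -> float:
    """Nanog coordinate of the saddle separating the NL and NH basins.

    Raises for monostable parameter sets (e.g. the 2i scenario, where
    transitions are structurally impossible).
    """
    fps = find_fixed_points(params.replace(Y=0.0))
    branches = stable_branch_states(fps)
    if "NL" not in branches or "NH" not in branches:
        raise ValueError(
            "no basin boundary: the deterministic system is not bistable "
            "on the Oct4-Sox2-positive branch (monostable scenario)"
        )
    n_lo, n_hi = branches["NL"][1], branches["NH"][1]
    os_hi = branches["NH"][0]
    saddles = [
        fp.state.N
        for fp in fps
        if not fp.is_stable
        and abs(fp.state.OS - os_hi) <= 1e-3 * (1.0 + os_hi)
        and n_lo < fp.state.N < n_hi
    ]
    if not saddles:
        raise RuntimeError("bistable branch found but no separating saddle")
    return float(saddles[0])


def _run_lengths(side: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Run-length encode a boolean series: (start indices, run sides)."""
    change = np.flatnonzero(np.diff(side.astype(np.int8))) + 1
    starts = np.concatenate(([0], change))
    return starts, side[starts]


def _detect_cell(n_series: np.ndarray, times: np.ndarray, boundary: float,
                 min_residence: float, cell_id: int) -> list[TransitionEvent]:
    dt_sample = times[1] - times[0] if times.size > 1 else 0.0
    side = n_series >= boundary  # True = NH side
    starts, sides = _run_lengths(side)
    ends = np.concatenate((starts[1:], [side.size]))
    durations = (ends - starts) * dt_sample

    basin_high = bool(sides[0])
    switch_times = []
    directions = []
    for start, run_high, dur in zip(starts[1:], sides[1:], durations[1:]):
        if run_high == basin_high:
            continue
        if dur >= min_residence:
            switch_times.append(times[start])
            directions.append("NH->NL" if basin_high else "NL->NH")
            basin_high = bool(run_high)
        # shorter opposite-side runs are unvalidated excursions: ignored
    events = []
    total = times[-1] if times.size else 0.0
    for idx, (t, d) in enumerate(zip(switch_times, directions)):
        t_next = switch_times[idx + 1] if idx + 1 < len(switch_times) else total
        events.append(
            TransitionEvent(
                cell_id=cell_id,
                time=float(t),
                direction=d,
                residence_in_destination=float(t_next - t),
            )
        )
    return events


def detect_transitions(
    traj: Trajectory,
    boundary: float,
    min_residence: float = MIN_RESIDENCE_MIN,
) -> list[TransitionEvent]:
    """Valid NH/NL switches of one trajectory (see module docstring)."""
    if traj.times[-1] < min_residence:
        warnings.warn(
            "trajectory shorter than the minimum residence window; "
            "no transition can be validated",
            stacklevel=2,
        )
        return []
    return _detect_cell(traj.N, traj.times, boundary, min_residence, traj.cell_id)


def residence_records(
    traj: Trajectory,
    boundary: float,
    min_residence: float = MIN_RESIDENCE_MIN,
) -> list[ResidenceRecord]:
    """Basin residence intervals of one cell, delimited by valid switches.

    The first and last intervals are censored by the simulation window;
    only intervals bounded by two valid transitions are uncensored.
    """
    events = detect_transitions(traj, boundary, min_residence)
    total = float(traj.times[-1])
    first_high = bool(traj.N[0] >= boundary)
    if not events:
        return [
            ResidenceRecord(traj.cell_id, "NH" if first_high else "NL",
                            0.0, total, censored=True)
        ]
    records = []
    bounds = [0.0] + [ev.time for ev in events] + [total]
    # basin during interval i: before event i it is the origin of event i
    basins = [ev.direction.split("->")[0] for ev in events]
    basins.append(events[-1].direction.split("->")[1])
    for i, basin in enumerate(basins):
        censored = i == 0 or i == len(basins) - 1
        records.append(
            ResidenceRecord(traj.cell_id, basin, bounds[i], bounds[i + 1],
                            censored=censored)
        )
    return records


def transition_rate(
    events_per_cell: list[list[TransitionEvent]],
    n_cells: int,
    duration: float,
    n_bootstrap: int = 1000,
    seed: int = 0,
) -> RateReport:
    """Valid transitions per cell per 24 h, with a bootstrap CI over cells."""
    if duration <= 0:
        raise ValueError("duration must be > 0")
    counts = np.array([len(ev) for ev in events_per_cell], dtype=float)
    if counts.size != n_cells:
        raise ValueError("need one event list per cell")
    days = duration / MINUTES_PER_DAY
    rate = counts.sum() / (n_cells * days)
    if n_cells > 1 and counts.sum() > 0:
        rng = np.random.default_rng(seed)
        idx = rng.integers(0, n_cells, size=(n_bootstrap, n_cells))
        boot = counts[idx].mean(axis=1) / days
        ci_low, ci_high = np.percentile(boot, [2.5, 97.5])
    else:
        ci_low = ci_high = rate
    return RateReport(
        n_events=int(counts.sum()),
        n_cells=n_cells,
        duration_days=days,
        per_cell_per_day=float(rate),
        per_cell_per_hour=float(rate / 24.0),
        ci_low=float(ci_low),
        ci_high=float(ci_high),
    )


def residence_statistics(
    pop: PopulationRun,
    boundary: float,
    min_residence: float = MIN_RESIDENCE_MIN,
    min_records: int = 10,
) -> dict:
    """Per-basin residence-time summary from a population run.

    For each basin: number of uncensored records, their mean in days, the
    maximum-likelihood exponential rate (1/mean) and the Kolmogorov-
    Smirnov distance between the empirical CDF and the fitted exponential.
    Basins with fewer than ``min_records`` uncensored records are flagged
    ``insufficient``.  Censored intervals are counted separately.
    """
    durations = {"NH": [], "NL": []}
    censored = {"NH": 0, "NL": 0}
    for cid in range(pop.n_cells):
        for rec in residence_records(pop.trajectory(cid), boundary, min_residence):
            if rec.censored:
                censored[rec.basin] += 1
            else:
                durations[rec.basin].append(rec.duration)
    out = {}
    for basin in ("NH", "NL"):
        durs = np.array(durations[basin], dtype=float)
        entry = {
            "n_uncensored": int(durs.size),
            "n_censored": int(censored[basin]),
            "insufficient": bool(durs.size < min_records),
        }
        if durs.size:
            mean_min = float(durs.mean())
            entry["mean_days"] = mean_min / MINUTES_PER_DAY
            entry["exp_rate_per_day"] = MINUTES_PER_DAY / mean_min
            # KS distance of the empirical CDF vs Exp(1/mean)
            xs = np.sort(durs)
            ecdf_hi = np.arange(1, durs.size + 1) / durs.size
            ecdf_lo = np.arange(0, durs.size) / durs.size
            fitted = 1.0 - np.exp(-xs / mean_min)
            entry["ks_distance"] = float(
                max(np.max(np.abs(ecdf_hi - fitted)),
                    np.max(np.abs(ecdf_lo - fitted)))
            )
        else:
            entry["mean_days"] = float("nan")
            entry["exp_rate_per_day"] = float("nan")
            entry["ks_distance"] = float("nan")
        out[basin] = entry
    return out


def nl_fraction(pop: PopulationRun, boundary: float, t_index: int = -1) -> float:
    """Fraction of cells on the NL side of the boundary at a snapshot."""
    return float(np.mean(pop.species("N")[:, t_index] < boundary))


def _default_mixed_fraction(params: ParameterSet) -> float:
    """NL share of the log-Nanog interval between the two attractors.

    Used as the default ``mixed`` initialization of the sweep when the
    base parameters are bistable: the deterministic NL basin occupies the
    log-space below the saddle.
    """
    fps = find_fixed_points(params.replace(Y=0.0))
    branches = stable_branch_states(fps)
    if "NL" not in branches or "NH" not in branches:
        return 0.0
    sad = basin_boundary(params)
    lo, hi = np.log10(branches["NL"][1]), np.log10(branches["NH"][1])
    return float(np.clip((np.log10(sad) - lo) / (hi - lo), 0.0, 1.0))


def nl_fraction_sweep(
    params_base: ParameterSet,
    s4_grid,
    sigma_grid,
    n_cells: int = 200,
    duration: float = 4320.0,
    dt: float = 0.1,
    master_seed: int = 0,
    init_policy=None,
    record_stride: int | None = None,
) -> np.ndarray:
    """NL fraction at the final time over an ``s4`` x ``sigma_N`` grid.

    Rows index ``sigma_grid``, columns ``s4_grid`` (heat-map layout).  The
    basin boundary is recomputed per ``s4``; monostable columns classify
    by proximity to the single stable state (all-NH -> fraction 0, all-NL
    -> fraction 1 in the noiseless limit).
    """
    s4_grid = np.asarray(s4_grid, dtype=float)
    sigma_grid = np.asarray(sigma_grid, dtype=float)
    if s4_grid.size == 0 or sigma_grid.size == 0:
        raise ValueError("grids must be nonempty")
    if record_stride is None:
        record_stride = max(1, int(round(10.0 / dt)))
    if init_policy is None:
        init_policy = ("mixed", _default_mixed_fraction(params_base))

    out = np.empty((sigma_grid.size, s4_grid.size))
    for j, s4 in enumerate(s4_grid):
        pset = params_base.replace(s4=float(s4))
        try:
            boundary = basin_boundary(pset)
            policy = init_policy
        except ValueError:
            # monostable column: nearest-stable-state classification via
            # the geometric midpoint between k and the single attractor
            branches = stable_branch_states(
                find_fixed_points(pset.replace(Y=0.0)))
            if "NH" in branches:
                boundary = float(np.sqrt(pset.k * branches["NH"][1]))
                policy = "at_NH"
            elif "NL" in branches:
                boundary = float(np.sqrt(pset.k * branches["NL"][1]) * 10)
                policy = "at_NL"
            else:
                raise RuntimeError(
                    f"no stable Oct4-Sox2-positive state at s4={s4}"
                ) from None
        for i, sig in enumerate(sigma_grid):
            try:
                pop = simulate_population(
                    pset.replace(sigma_N=float(sig)),
                    n_cells=n_cells,
                    init_policy=policy,
                    duration=duration,
                    dt=dt,
                    master_seed=master_seed,
                    record_stride=record_stride,
                )
            except Exception as exc:  # attach grid coordinates
                raise RuntimeError(
                    f"sweep cell (s4={s4}, sigma_N={sig}) failed: {exc}"
                ) from exc
            out[i, j] = nl_fraction(pop, boundary)
    return out


def transitions_vs_noise(
    params_base: ParameterSet,
    s4_values,
    sigma_grid,
    n_cells: int = 200,
    duration: float = 4320.0,
    dt: float = 0.1,
    master_seed: int = 0,
    min_residence: float = MIN_RESIDENCE_MIN,
    record_stride: int | None = None,
) -> dict[float, dict]:
    """Mean and SD of per-cell 24-h transition counts across a noise grid.

    One curve per ``s4`` value; each ``s4`` must lie inside the bistable
    interval (check with ``bifurcation_scan`` otherwise).
    """
    sigma_grid = np.asarray(sigma_grid, dtype=float)
    if record_stride is None:
        record_stride = max(1, int(round(2.0 / dt)))
    curves = {}
    for s4 in np.asarray(s4_values, dtype=float):
        pset = params_base.replace(s4=float(s4))
        try:
            boundary = basin_boundary(pset)
        except ValueError as exc:
            raise ValueError(
                f"s4={s4} is outside the bistable interval "
                "(see bifurcation_scan)"
            ) from exc
        means, sds = [], []
        days = duration / MINUTES_PER_DAY
        for sig in sigma_grid:
            pop = simulate_population(
                pset.replace(sigma_N=float(sig)),
                n_cells=n_cells,
                init_policy=("mixed", _default_mixed_fraction(pset)),
                duration=duration,
                dt=dt,
                master_seed=master_seed,
                record_stride=record_stride,
            )
            counts = np.array([
                len(_detect_cell(pop.species("N")[c], pop.times, boundary,
                                 min_residence, c))
                for c in range(n_cells)
            ], dtype=float) / days
            means.append(counts.mean())
            sds.append(counts.std())
        curves[float(s4)] = {
            "sigma_N": sigma_grid.copy(),
            "mean_per_day": np.array(means),
            "sd_per_day": np.array(sds),
        }
    return curves


def population_events(
    pop: PopulationRun,
    boundary: float,
    min_residence: float = MIN_RESIDENCE_MIN,
) -> list[list[TransitionEvent]]:
    """Valid transitions for every cell of a population run."""
    return [
        _detect_cell(pop.species("N")[c], pop.times, boundary, min_residence, c)
        for c in range(pop.n_cells)
    ]
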