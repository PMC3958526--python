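"""Nanog-gated differentiation experiments.

Differentiation in this model is a two-step sequence.  A cell first has
to lose Nanog (enter the NL basin); only then does the Nanog gate open
and transmit the extrinsic differentiation signal ``Y`` into the cell
(``Y_in`` rises), which enhances degradation of Oct4-Sox2, Nanog and
Rex1.  A cell whose Oct4-Sox2 level collapses is scored as
differentiated; Oct4 loss is treated as terminal, so the classification
is absorbing.

Two in-silico experiments are implemented:

* :func:`differentiated_fraction_vs_Y` — LIF/serum populations exposed to
  increasing signal strength ``Y``: at low ``Y`` every NL cell eventually
  re-expresses Nanog, at high ``Y`` NL entry commits cells to
  differentiation, in between both outcomes coexist by chance.
* :func:`simulate_differentiation` — withdrawal of the 2i inhibitors:
  Erk reaccumulates, modelled as a per-cell stochastic logistic ramp of
  the repression rate ``p`` (midpoints lognormal across cells, emulating
  cell-to-cell variation in autocrine FGF4 transduction), with reduced
  Rex1 turnover.  Nanog falls early and asynchronously, Rex1 follows
  with a delay, Oct4-Sox2 collapses last.

Absolute differentiated-cell counts should be read with care: the model
has no proliferation or cell death, which would alter those fractions in
a real culture.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .params import CellState, ParameterSet
from .sde import PopulationRun, simulate_population
from .steady_state import find_fixed_points, stable_branch_states

__all__ = [
    "RampSpec",
    "RampSample",
    "DifferentiationRun",
    "sample_ramps",
    "simulate_differentiation",
    "differentiated_fraction_vs_Y",
]

OS_THRESHOLD_FRACTION = 0.1
OS_PERSISTENCE_MIN = 60.0


@dataclass(frozen=True)
class RampSpec:
    """Per-cell logistic increase of the Erk repression rate p.

    Cell ``i`` follows ``p_i(t) = p_max / (1 + exp(-slope (t - t_mid_i)))``
    with ``t_mid_i`` drawn from a lognormal with the given median (minutes)
    and natural-log standard deviation.  ``log_sd = 0`` makes the
    population synchronous.
    """

    p_max: float = 30.0
    t_mid_median: float = 480.0  # minutes after inhibitor withdrawal
    log_sd: float = 0.5
    slope: float = 0.02  # 1/min
    seed: int = 0

    def __post_init__(self) -> None:
        if self.p_max < 0:
            raise ValueError("p_max must be >= 0")
        if self.t_mid_median <= 0:
            raise ValueError("t_mid_median must be > 0")
        if self.log_sd < 0 or self.slope <= 0:
            raise ValueError("log_sd must be >= 0 and slope > 0")


@dataclass
class RampSample:
    """Realized per-cell ramps: callable p_i(t) plus the midpoint array."""

    spec: RampSpec
    t_mid: np.ndarray

    def p_of_t(self, t, cell_id: int):
        s = self.spec
        return s.p_max / (1.0 + np.exp(-s.slope * (np.asarray(t, float)
                                                   - self.t_mid[cell_id])))

    def kernel_args(self) -> tuple[float, float, np.ndarray]:
        return self.spec.p_max, self.spec.slope, self.t_mid


def sample_ramps(spec: RampSpec, n_cells: int, master_seed: int | None = None,
                 stratified: bool = False) -> RampSample:
    """Draw the per-cell ramp midpoints (deterministic given seeds).

    With ``stratified=True`` the midpoints are the lognormal quantiles at
    mid-cell positions instead of random draws — the population then
    represents the midpoint distribution without sampling noise, which
    the ramp-fitting objective uses for variance reduction.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    if stratified:
        from scipy.stats import norm

        q = (np.arange(n_cells) + 0.5) / n_cells
        z = norm.ppf(q)
    else:
        seed = spec.seed if master_seed is None else master_seed
        rng = np.random.default_rng(np.random.SeedSequence((seed, 9001)))
        z = rng.standard_normal(n_cells)
    t_mid = spec.t_mid_median * np.exp(spec.log_sd * z)
    return RampSample(spec=spec, t_mid=t_mid)


@dataclass
class DifferentiationRun:
    """Population outcome of a differentiation experiment."""

    population: PopulationRun
    os_reference: float  # undifferentiated Oct4-Sox2 level
    os_threshold: float
    t_diff: np.ndarray  # minutes, NaN = undifferentiated
    boundary_N: float | None = None
    ramp: RampSample | None = None

    @property
    def differentiated(self) -> np.ndarray:
        return ~np.isnan(self.t_diff)

    @property
    def differentiated_fraction(self) -> float:
        return float(np.mean(self.differentiated))

    def timecourse_frame(self) -> pd.DataFrame:
        """Population means (normalized to t = 0) and dispersions."""
        pop = self.population
        os_m = pop.species("OS").mean(axis=0)
        n_m = pop.species("N").mean(axis=0)
        r_m = pop.species("R").mean(axis=0)
        frac = np.array([
            np.mean((~np.isnan(self.t_diff)) & (self.t_diff <= t))
            for t in pop.times
        ])
        return pd.DataFrame(
            {
                "t_min": pop.times,
                "mean_OS": os_m / os_m[0],
                "mean_N": n_m / n_m[0],
                "mean_R": r_m / r_m[0],
                "sd_N": pop.species("N").std(axis=0),
                "sd_R": pop.species("R").std(axis=0),
                "frac_differentiated": frac,
            }
        )

    def outcome_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cell_id": np.arange(self.population.n_cells),
                "t_diff_min": self.t_diff,
                "differentiated": self.differentiated,
            }
        )


def _differentiation_times(os_mat: np.ndarray, times: np.ndarray,
                           threshold: float,
                           persistence: float = OS_PERSISTENCE_MIN) -> np.ndarray:
    """First time Oct4-Sox2 stays below threshold for >= persistence.

    Absorbing by construction: once found, the cell keeps the label, so
    differentiation times never decrease when a run is extended.
    """
    n_cells, n_t = os_mat.shape
    dt_sample = times[1] - times[0] if n_t > 1 else 0.0
    need = max(1, int(math.ceil(persistence / dt_sample))) if dt_sample > 0 else 1
    out = np.full(n_cells, np.nan)
    below = os_mat < threshold
    for c in range(n_cells):
        run = 0
        for j in range(n_t):
            if below[c, j]:
                run += 1
                if run >= need:
                    out[c] = times[j - need + 1]
                    break
            else:
                run = 0
    return out


def _nh_state(params: ParameterSet) -> np.ndarray:
    branches = stable_branch_states(find_fixed_points(params.replace(Y=0.0)))
    if "NH" not in branches:
        raise ValueError("parameter set has no NH attractor")
    return branches["NH"]


def simulate_differentiation(
    params_2i: ParameterSet,
    ramp: RampSpec,
    Y_level: float = 1.0,
    rex1_turnover_scale: float = 0.005,
    n_cells: int = 500,
    duration: float = 2880.0,
    dt: float = 0.1,
    seed: int = 0,
    record_stride: int | None = None,
    os_threshold_fraction: float = OS_THRESHOLD_FRACTION,
    stratified_ramps: bool = False,
) -> DifferentiationRun:
    """2i-withdrawal experiment: stochastic p-ramp + differentiation signal.

    Cells start at the 2i ground-state attractor (``p = 0``); from t = 0
    the repression rate of each cell follows its own logistic ramp, the
    extrinsic signal is set to ``Y_level`` and the Rex1 rates
    ``(s5, s6, d_R)`` are scaled by ``rex1_turnover_scale`` (slower Rex1
    turnover than in LIF/serum, as needed to describe the delayed Rex1
    decay).
    """
    if params_2i.p != 0.0:
        raise ValueError("params_2i must have p = 0 (ground state)")
    if not (0.0 < rex1_turnover_scale <= 1.0):
        raise ValueError("rex1_turnover_scale must lie in (0, 1]")
    nh = _nh_state(params_2i)
    # sigma_R scales with sqrt(turnover) so the stationary width of the
    # Rex1 distribution (set by sigma_R^2 / 2 d_R) is turnover-invariant
    run_params = params_2i.replace(
        Y=float(Y_level),
        s5=params_2i.s5 * rex1_turnover_scale,
        s6=params_2i.s6 * rex1_turnover_scale,
        d_R=params_2i.d_R * rex1_turnover_scale,
        sigma_R=params_2i.sigma_R * math.sqrt(rex1_turnover_scale),
    )
    if record_stride is None:
        record_stride = max(1, int(round(10.0 / dt)))
    ramps = sample_ramps(ramp, n_cells, master_seed=seed,
                         stratified=stratified_ramps)
    pop = simulate_population(
        run_params,
        n_cells=n_cells,
        init_policy=CellState.from_array(nh),
        duration=duration,
        dt=dt,
        master_seed=seed,
        record_stride=record_stride,
        ramp=ramps.kernel_args(),
        scenario_label="N2B27_withdrawal",
    )
    threshold = os_threshold_fraction * nh[0]
    t_diff = _differentiation_times(pop.species("OS"), pop.times, threshold)
    return DifferentiationRun(
        population=pop,
        os_reference=float(nh[0]),
        os_threshold=float(threshold),
        t_diff=t_diff,
        ramp=ramps,
    )


def differentiated_fraction_vs_Y(
    params_LIF: ParameterSet,
    Y_grid,
    n_cells: int = 500,
    duration: float = 4320.0,
    dt: float = 0.1,
    seed: int = 0,
    record_stride: int | None = None,
    os_threshold_fraction: float = OS_THRESHOLD_FRACTION,
) -> pd.DataFrame:
    """Terminal cell fractions after 3 days of LIF/serum at each signal Y.

    Returns a frame with columns (Y, frac_differentiated, frac_NL,
    frac_NH); the two undifferentiated fractions classify the remaining
    cells by the Nanog basin boundary.  Seeds are shared across the Y
    grid so the curves are paired.
    """
    from .state_analysis import basin_boundary

    nh = _nh_state(params_LIF)
    boundary = basin_boundary(params_LIF)
    threshold = os_threshold_fraction * nh[0]
    if record_stride is None:
        record_stride = max(1, int(round(10.0 / dt)))
    rows = []
    for y in np.asarray(Y_grid, dtype=float):
        pop = simulate_population(
            params_LIF.replace(Y=float(y)),
            n_cells=n_cells,
            init_policy=CellState.from_array(nh),
            duration=duration,
            dt=dt,
            master_seed=seed,
            record_stride=record_stride,
            scenario_label="LIF_serum",
        )
        t_diff = _differentiation_times(pop.species("OS"), pop.times, threshold)
        diff = ~np.isnan(t_diff)
        n_term = pop.species("N")[:, -1]
        rows.append(
            {
                "Y": float(y),
                "frac_differentiated": float(np.mean(diff)),
                "frac_NL": float(np.mean(~diff & (n_term < boundary))),
                "frac_NH": float(np.mean(~diff & (n_term >= boundary))),
            }
        )
    return pd.DataFrame(rows)
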