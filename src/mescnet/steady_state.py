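"""Deterministic fixed points, stability and bifurcation structure.

With the differentiation signal off (``Y = 0``) the network has a feed-
forward structure: the Oct4-Sox2 equation is autonomous (its positive
roots solve a quadratic), Erk is slaved to Oct4-Sox2, Nanog solves a
one-dimensional problem given the Oct4-Sox2/Erk levels, and Rex1 is
slaved to both.  ``find_fixed_points`` nevertheless treats the full 4-D
system with a multi-start damped root iteration so that it stays valid
for parameter sets where the structure is less transparent; the 1-D
reduction (:func:`reduced_nanog_rhs`) serves as an independent oracle.

Bistability of Nanog (coexisting Nanog-low ``NL`` and Nanog-high ``NH``
attractors separated by a saddle) underlies the heterogeneous LIF/serum
state; removing the Erk repression (``p = 0``, the 2i condition) leaves a
single NH attractor.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize

from .model import compute_Yin, hill
from .params import CellState, ParameterSet

__all__ = [
    "FixedPoint",
    "BifurcationDiagram",
    "reduced_nanog_rhs",
    "find_fixed_points",
    "classify_stability",
    "bifurcation_scan",
    "os_branch_roots",
    "stable_branch_states",
]

logger = logging.getLogger(__name__)

DEFAULT_TOL_FP = 1e-8
DEFAULT_DEDUP_TOL = 1e-6
_TOL_EIG = 1e-9


@dataclass(frozen=True)
class FixedPoint:
    """A root of the deterministic drift with its linear stability."""

    state: CellState
    stability: str  # stable | unstable | saddle | marginal
    branch: str  # origin | NL | NH | other
    eigenvalue_max_real: float

    @property
    def is_stable(self) -> bool:
        return self.stability == "stable"


@dataclass
class BifurcationDiagram:
    """Fixed points collected along a one-parameter scan."""

    scanned_parameter: str
    grid: np.ndarray
    points: list  # list of (parameter value, FixedPoint)
    bistable_interval: tuple | None = None

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "parameter": value,
                "branch": fp.branch,
                "stability": fp.stability,
                "OS": fp.state.OS,
                "N": fp.state.N,
                "R": fp.state.R,
                "E": fp.state.E,
            }
            for value, fp in self.points
        ]
        return pd.DataFrame(rows)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def _drift_extended(x: np.ndarray, params: ParameterSet) -> np.ndarray:
    """Drift continued to negative coordinates for root finding.

    Production (Hill) terms see the state clipped at zero while the linear
    degradation sees the raw coordinate, so no spurious roots with negative
    components exist (production >= 0 forces drift > 0 there).
    """
    if not np.all(np.isfinite(x)):
        return np.full(4, 1e12)
    os_, n_, r_, e_ = x
    pr = params
    h_os = hill(max(os_, 0.0), pr.k, pr.n)
    h_n = hill(max(n_, 0.0), pr.k, pr.n)
    h_e = hill(max(e_, 0.0), pr.k, pr.n)
    g_p = 1.0 / (1.0 + pr.p * h_e)
    y_in = compute_Yin(max(n_, 0.0), pr.Y, pr.k_Y, pr.h)
    return np.array(
        [
            pr.s12 * h_os - pr.d_OS * (1.0 + pr.i_OS * y_in) * os_,
            (pr.s3 * h_os + pr.s4 * h_n) * g_p - pr.d_N * (1.0 + pr.i_N * y_in) * n_,
            pr.s5 * h_os + pr.s6 * h_n - pr.d_R * (1.0 + pr.i_R * y_in) * r_,
            pr.s7 * h_os - pr.d_E * e_,
        ]
    )


def os_branch_roots(params: ParameterSet) -> np.ndarray:
    """Positive roots of the autonomous Oct4-Sox2 sub-equation (n = 2).

    Solves ``s12 H(OS) = d_OS OS``; besides the origin there are up to two
    positive roots (the lower one a separatrix, the upper one the
    self-sustained Oct4-Sox2 level).  Only valid for Hill coefficient 2;
    for other exponents a numeric scan is used.
    """
    pr = params
    if pr.n == 2.0:
        disc = pr.s12 ** 2 - 4.0 * pr.d_OS ** 2 * pr.k ** 2
        if disc < 0 or pr.d_OS == 0:
            return np.empty(0)
        lo = (pr.s12 - math.sqrt(disc)) / (2.0 * pr.d_OS)
        hi = (pr.s12 + math.sqrt(disc)) / (2.0 * pr.d_OS)
        return np.array(sorted({lo, hi}))
    # generic fallback: bracketed sign scan
    if pr.d_OS == 0 or pr.s12 == 0:
        return np.empty(0)
    upper = 2.0 * pr.s12 / pr.d_OS
    grid = np.linspace(1e-9, upper, 4001)
    f = pr.s12 * np.array([hill(x, pr.k, pr.n) for x in grid]) - pr.d_OS * grid
    roots = []
    for a, b, fa, fb in zip(grid[:-1], grid[1:], f[:-1], f[1:]):
        if fa == 0.0:
            roots.append(a)
        if fa * fb < 0:
            roots.append(optimize.brentq(
                lambda x: pr.s12 * hill(x, pr.k, pr.n) - pr.d_OS * x, a, b))
    return np.array(roots)


def reduced_nanog_rhs(N: float, params: ParameterSet,
                      OS_star: float, E_star: float) -> float:
    """1-D Nanog rate on a fixed Oct4-Sox2/Erk branch (``Y = 0`` only).

    At steady state the OS equation is autonomous and
    ``E* = s7 H(OS*) / d_E``, so Nanog fixed points on that branch are the
    sign changes of this scalar function.  Used as the brute-force oracle
    for :func:`find_fixed_points`.
    """
    if params.Y != 0.0:
        raise ValueError(
            "the 1-D Nanog reduction requires Y = 0 (Y_in couples the equations)"
        )
    pr = params
    g_p = 1.0 / (1.0 + pr.p * hill(E_star, pr.k, pr.n))
    return (pr.s3 * hill(OS_star, pr.k, pr.n) + pr.s4 * hill(N, pr.k, pr.n)) * g_p \
        - pr.d_N * N


def _jacobian(x: np.ndarray, params: ParameterSet) -> np.ndarray:
    jac = np.empty((4, 4))
    for j in range(4):
        step = 1e-6 * max(abs(x[j]), 1.0)
        xp = x.copy(); xp[j] += step
        xm = x.copy(); xm[j] -= step
        jac[:, j] = (_drift_extended(xp, params) - _drift_extended(xm, params)) \
            / (2.0 * step)
    return jac


def classify_stability(state, params: ParameterSet,
                       tol: float = _TOL_EIG) -> tuple[str, float]:
    """Linearize at a fixed point; return (label, max real eigenvalue part).

    The Jacobian is formed by central finite differences with a relative
    step of 1e-6.  Eigenvalue real parts within ``tol`` of zero give the
    label ``marginal`` (surfaced as a warning by callers).
    """
    x = state.to_array() if isinstance(state, CellState) else np.asarray(state, float)
    real = np.real(np.linalg.eigvals(_jacobian(x, params)))
    max_real = float(real.max())
    if np.any(np.abs(real) <= tol):
        return "marginal", max_real
    if max_real < 0.0:
        return "stable", max_real
    if float(real.min()) > 0.0:
        return "unstable", max_real
    return "saddle", max_real


def _initial_guesses(params: ParameterSet, n_per_axis: int) -> np.ndarray:
    """Deterministic log lattice of starts plus the origin.

    Each coordinate takes ``n_per_axis`` log-spaced values up to twice its
    maximal production/degradation ratio.
    """
    pr = params
    scales = [
        2.0 * pr.s12 / pr.d_OS if pr.d_OS > 0 else 1.0,
        2.0 * (pr.s3 + pr.s4) / pr.d_N if pr.d_N > 0 else 1.0,
        2.0 * (pr.s5 + pr.s6) / pr.d_R if pr.d_R > 0 else 1.0,
        2.0 * pr.s7 / pr.d_E if pr.d_E > 0 else 1.0,
    ]
    axes = [
        np.geomspace(max(s, 1e-12) * 1e-3, max(s, 1e-12), n_per_axis)
        for s in scales
    ]
    lattice = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 4)
    return np.vstack([np.zeros(4), lattice])


def find_fixed_points(
    params: ParameterSet,
    tol_fp: float = DEFAULT_TOL_FP,
    dedup_tol: float = DEFAULT_DEDUP_TOL,
    n_per_axis: int = 5,
) -> list[FixedPoint]:
    """All fixed points reachable from a deterministic lattice of starts.

    Multi-start damped (Powell hybrid) root iteration, deduplicated at
    relative distance ``dedup_tol``.  The origin is always included (every
    production term has a zero numerator there).  Requires ``Y = 0``; the
    driven case is a simulation question, not a continuation one.
    """
    if params.Y != 0.0:
        raise ValueError("fixed-point analysis requires Y = 0")

    found: list[np.ndarray] = [np.zeros(4)]
    residuals: list[float] = []
    for x0 in _initial_guesses(params, n_per_axis):
        sol = optimize.root(_drift_extended, x0, args=(params,), method="hybr")
        x = np.where(np.abs(sol.x) < 1e-12, 0.0, sol.x)
        if np.any(x < 0):
            continue
        res = float(np.linalg.norm(_drift_extended(x, params)))
        if res > tol_fp:
            residuals.append(res)
            continue
        if not any(
            np.linalg.norm(x - y) <= dedup_tol * (1.0 + np.linalg.norm(y))
            for y in found
        ):
            found.append(x)
    if len(found) == 1 and residuals and params.s12 > 0:
        # only the origin: fine if nothing converged is genuinely expected,
        # but if every start failed to meet tol_fp report the residuals
        if len(residuals) == len(_initial_guesses(params, n_per_axis)):
            raise RuntimeError(
                "root iteration failed from all starts; residual norms: "
                f"min {min(residuals):.3g}, max {max(residuals):.3g}"
            )

    # classify stability
    classified = []
    for x in found:
        label, max_real = classify_stability(x, params)
        if label == "marginal":
            logger.warning("fixed point %s has a marginal eigenvalue", x)
        classified.append((x, label, max_real))

    # branch labels
    os_roots = os_branch_roots(params)
    os_high = os_roots[-1] if os_roots.size else 0.0
    on_branch = [
        i for i, (x, _, _) in enumerate(classified)
        if os_high > 0 and abs(x[0] - os_high) <= 1e-3 * (1.0 + os_high)
    ]
    stable_n = sorted(
        (classified[i][0][1], i) for i in on_branch if classified[i][1] == "stable"
    )
    branch_of = {}
    if len(stable_n) >= 2:
        branch_of[stable_n[0][1]] = "NL"
        branch_of[stable_n[-1][1]] = "NH"
    elif len(stable_n) == 1:
        n_val, i = stable_n[0]
        branch_of[i] = "NH" if n_val >= params.k else "NL"

    points = []
    for i, (x, label, max_real) in enumerate(classified):
        if np.linalg.norm(x) == 0.0:
            branch = "origin"
        else:
            branch = branch_of.get(i, "other")
        points.append(
            FixedPoint(
                state=CellState.from_array(x),
                stability=label,
                branch=branch,
                eigenvalue_max_real=max_real,
            )
        )
    points.sort(key=lambda fp: (fp.state.OS, fp.state.N))
    return points


def stable_branch_states(fps: list[FixedPoint]) -> dict[str, np.ndarray]:
    """Map branch label -> state array for the stable NL/NH points."""
    return {
        fp.branch: fp.state.to_array()
        for fp in fps
        if fp.is_stable and fp.branch in ("NL", "NH")
    }


def _count_bistable(fps: list[FixedPoint]) -> int:
    return sum(1 for fp in fps if fp.is_stable and fp.branch in ("NL", "NH"))


def bifurcation_scan(
    params: ParameterSet,
    parameter: str,
    grid,
    n_per_axis: int = 5,
) -> BifurcationDiagram:
    """One-parameter scan (over ``s4`` or ``p``) of the fixed-point set.

    Independent solves per grid value linked by branch labels; the
    bistable interval is the maximal contiguous sub-range of the grid with
    two coexisting stable Oct4-Sox2-positive states.
    """
    if parameter not in ("s4", "p"):
        raise ValueError("scan parameter must be 's4' or 'p'")
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0 or np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be nonempty and sorted ascending")

    points = []
    bistable_mask = np.zeros(grid.size, dtype=bool)
    for idx, value in enumerate(grid):
        fps = find_fixed_points(params.replace(**{parameter: float(value)}),
                                n_per_axis=n_per_axis)
        bistable_mask[idx] = _count_bistable(fps) == 2
        for fp in fps:
            points.append((float(value), fp))

    interval = None
    best_len = 0
    run_start = None
    for idx, flag in enumerate(np.append(bistable_mask, False)):
        if flag and run_start is None:
            run_start = idx
        elif not flag and run_start is not None:
            if idx - run_start > best_len:
                best_len = idx - run_start
                interval = (float(grid[run_start]), float(grid[idx - 1]))
            run_start = None
    return BifurcationDiagram(
        scanned_parameter=parameter,
        grid=grid,
        points=points,
        bistable_interval=interval,
    )
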