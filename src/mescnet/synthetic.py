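"""Surrogate observed data with the structure the analysis assumes.

The measurements this model is compared against are (a) flow-cytometry
intensity samples of the Rex1GFPd2 reporter — log-normal-like, bimodal
under LIF/serum (a low mode of roughly 20% of cells about two decades
below the high mode) and unimodal under 2i — and (b) Taqman qRT-PCR
population time courses of Nanog and Rex1 after 2i withdrawal, sampled
every 3 h and normalized to 1 at the moment of withdrawal, with Nanog
declining promptly and Rex1 after a delay.  The generators here emulate
those two data shapes; none of the default numbers claim to be measured
values.  Log-normal mixtures are the natural choice because reporter
distributions appear equally wide per mode on the log scale, which is
also what motivates the model's multiplicative noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "MixtureSpec",
    "TimecourseSpec",
    "gen_flow_sample",
    "gen_qpcr_timecourse",
    "distribution_distance",
    "LIF_SERUM_REX1_MIXTURE",
    "TWO_I_REX1_MIXTURE",
]


@dataclass(frozen=True)
class MixtureSpec:
    """Log-normal mixture emulating a reporter fluorescence distribution.

    Medians are in arbitrary intensity units; widths are standard
    deviations of log10 intensity per mode.
    """

    medians: tuple = (1.5, 150.0)
    log10_sds: tuple = (0.25, 0.25)
    weights: tuple = (0.2, 0.8)
    n_cells: int = 10000
    seed: int = 0

    def __post_init__(self) -> None:
        if not (len(self.medians) == len(self.log10_sds) == len(self.weights)):
            raise ValueError("medians, log10_sds and weights must have equal length")
        if abs(sum(self.weights) - 1.0) > 1e-9:
            raise ValueError("weights must sum to 1")
        if any(m <= 0 for m in self.medians):
            raise ValueError("medians must be positive")
        if any(s < 0 for s in self.log10_sds):
            raise ValueError("log10 sds must be >= 0")
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")


#: bimodal LIF/serum shape: ~20% low mode, two decades below the high mode
LIF_SERUM_REX1_MIXTURE = MixtureSpec()
#: unimodal 2i ground-state shape
TWO_I_REX1_MIXTURE = MixtureSpec(medians=(150.0,), log10_sds=(0.25,), weights=(1.0,))


def gen_flow_sample(spec: MixtureSpec) -> np.ndarray:
    """Draw one positive intensity per cell from the log-normal mixture."""
    rng = np.random.default_rng(spec.seed)
    comp = rng.choice(len(spec.weights), size=spec.n_cells, p=spec.weights)
    med = np.asarray(spec.medians)[comp]
    sd = np.asarray(spec.log10_sds)[comp]
    return 10.0 ** (np.log10(med) + sd * rng.standard_normal(spec.n_cells))


def flow_sample_frame(spec: MixtureSpec) -> pd.DataFrame:
    sample = gen_flow_sample(spec)
    return pd.DataFrame({"cell_id": np.arange(sample.size), "intensity": sample})


@dataclass(frozen=True)
class TimecourseSpec:
    """Delayed-exponential population time course with multiplicative noise.

    Each species decays as ``exp(-rate * max(0, t - delay))`` (times in
    hours) times log-normal measurement noise, renormalized to exactly 1
    at t = 0.  Default grid: every 3 h for 48 h; default laws give Nanog
    a shorter delay than Rex1 so Rex1 persists while Nanog falls.
    """

    species: tuple = ("nanog", "rex1")
    delays_h: tuple = (2.0, 14.0)
    rates_per_h: tuple = (0.22, 0.18)
    t_grid_h: tuple = field(default_factory=lambda: tuple(range(0, 49, 3)))
    noise_sd: float = 0.05  # sd of log-normal measurement noise
    seed: int = 0

    def __post_init__(self) -> None:
        if not (len(self.species) == len(self.delays_h) == len(self.rates_per_h)):
            raise ValueError("species, delays and rates must have equal length")
        if any(r < 0 for r in self.rates_per_h) or any(d < 0 for d in self.delays_h):
            raise ValueError("rates and delays must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.t_grid_h[0] != 0:
            raise ValueError("time grid must start at 0 (normalization point)")


def gen_qpcr_timecourse(spec: TimecourseSpec) -> pd.DataFrame:
    """Relative-expression table (column ``t_h`` plus one per species)."""
    rng = np.random.default_rng(spec.seed)
    t = np.asarray(spec.t_grid_h, dtype=float)
    out = {"t_h": t}
    for name, delay, rate in zip(spec.species, spec.delays_h, spec.rates_per_h):
        clean = np.exp(-rate * np.maximum(0.0, t - delay))
        noisy = clean * np.exp(spec.noise_sd * rng.standard_normal(t.size))
        out[f"{name}_rel"] = noisy / noisy[0]
    return pd.DataFrame(out)


def distribution_distance(sample_a, sample_b) -> float:
    """Two-sample empirical-CDF max distance on log10 intensities, in [0, 1].

    Quantifies how well a simulated reporter distribution overlays an
    observed (or surrogate) one; 0 for identical samples, 1 for disjoint
    supports.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    if np.any(a <= 0) or np.any(b <= 0):
        raise ValueError("intensities must be positive for the log10 scale")
    return float(stats.ks_2samp(np.log10(a), np.log10(b)).statistic)


def write_flow_csv(spec: MixtureSpec, path: str | Path) -> None:
    flow_sample_frame(spec).to_csv(path, index=False)


def write_qpcr_csv(spec: TimecourseSpec, path: str | Path) -> None:
    gen_qpcr_timecourse(spec).to_csv(path, index=False)
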