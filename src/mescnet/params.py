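"""Domain types for the pluripotency network model.

The model follows four intracellular species of a single mouse embryonic
stem cell: the Oct4-Sox2 heterodimer (``OS``), Nanog (``N``), Rex1 (``R``)
and Erk activity downstream of autocrine FGF4 (``E``).  All concentrations
are in arbitrary units (a.u.); time is in minutes.

:class:`ParameterSet` collects every rate constant of the network.
:class:`Scenario` maps the three culture conditions onto parameter
overrides: LIF/serum (active Erk repression of Nanog, ``p > 0``), the 2i
ground state (Erk blocked, ``p = 0``) and 2i withdrawal into N2B27 basal
medium (a per-cell stochastic ramp of ``p`` plus a differentiation signal
``Y`` and reduced Rex1 turnover).
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import yaml

__all__ = [
    "ParameterSet",
    "CellState",
    "Scenario",
    "ConfigError",
]


class ConfigError(ValueError):
    """Raised when a parameter configuration is invalid or incomplete."""


# order matters: it is the canonical field order for config files and
# for the packed parameter vector consumed by the integration kernel
_FIELDS = (
    "s12", "s3", "s4", "s5", "s6", "s7",
    "k", "n", "p",
    "d_OS", "d_N", "d_R", "d_E",
    "i_OS", "i_N", "i_R",
    "sigma_OS", "sigma_N", "sigma_R",
    "Y", "k_Y", "h",
)


@dataclass(frozen=True)
class ParameterSet:
    """All rate constants, noise amplitudes and signal levels of the network.

    Parameters
    ----------
    s12
        Combined Oct4-Sox2 autoactivation transcription rate (a.u./min),
        subsuming the individual Oct4 and Sox2 rates and heterodimer
        formation.
    s3, s4
        Nanog transcription rates: basal activation by Oct4-Sox2 and
        autoregulation (a.u./min).
    s5, s6
        Rex1 transcription rates: activation by Oct4-Sox2 and by Nanog.
    s7
        Erk production rate via Oct4-Sox2 -> FGF4 (a.u./min).
    k
        Shared Hill half-saturation constant (a.u.) of all transcriptional
        inputs.
    n
        Hill coefficient, 2 by default (Nanog and Oct4-Sox2 act as dimers).
    p
        Erk -> Nanog repression strength (dimensionless, >= 0); 0 in 2i.
    d_OS, d_N, d_R, d_E
        First-order degradation rates (1/min).
    i_OS, i_N, i_R
        Inhibition factors (dimensionless, >= 0) scaling the degradation
        enhancement by the intracellular differentiation activity Y_in.
        Erk is not a Y_in target (``i_E = 0`` implicitly).
    sigma_OS, sigma_N, sigma_R
        Multiplicative transcriptional-noise amplitudes (1/sqrt(min));
        Erk carries no noise.
    Y
        Extrinsic differentiation-signal level (dimensionless, >= 0).
    k_Y
        Half-saturation constant (a.u.) of the Nanog gate on Y
        transmission.
    h
        Hill coefficient of the Y gate.
    """

    s12: float
    s3: float
    s4: float
    s5: float
    s6: float
    s7: float
    k: float
    n: float = 2.0
    p: float = 0.0
    d_OS: float = 0.1
    d_N: float = 0.1
    d_R: float = 0.1
    d_E: float = 0.1
    i_OS: float = 0.0
    i_N: float = 0.0
    i_R: float = 0.0
    sigma_OS: float = 0.0
    sigma_N: float = 0.0
    sigma_R: float = 0.0
    Y: float = 0.0
    k_Y: float = 20.0
    h: float = 2.0

    def __post_init__(self) -> None:
        for name in _FIELDS:
            value = getattr(self, name)
            if not math.isfinite(value) or value < 0.0:
                raise ConfigError(
                    f"parameter {name!r} must be finite and >= 0, got {value!r}"
                )
        if self.k <= 0:
            raise ConfigError("Hill constant k must be > 0")
        if self.k_Y <= 0:
            raise ConfigError("gate constant k_Y must be > 0")
        if self.h < 1:
            raise ConfigError("gate Hill coefficient h must be >= 1")

    # -- derived helpers -------------------------------------------------

    def replace(self, **changes: float) -> "ParameterSet":
        """Return a copy with the given fields replaced."""
        return dataclasses.replace(self, **changes)

    def to_vector(self) -> np.ndarray:
        """Pack into the canonical float64 vector used by the SDE kernel."""
        return np.array([getattr(self, f) for f in _FIELDS], dtype=np.float64)

    # -- config file I/O -------------------------------------------------

    def to_mapping(self) -> dict:
        return {f: float(getattr(self, f)) for f in _FIELDS}

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, float]) -> "ParameterSet":
        missing = [f for f in _FIELDS if f not in mapping]
        if missing:
            raise ConfigError(
                "missing parameter keys: " + ", ".join(sorted(missing))
            )
        unknown = sorted(set(mapping) - set(_FIELDS))
        if unknown:
            warnings.warn(
                "ignoring unknown parameter keys: " + ", ".join(unknown),
                stacklevel=2,
            )
        return cls(**{f: float(mapping[f]) for f in _FIELDS})

    def to_config(self, path: str | Path) -> None:
        Path(path).write_text(self.to_config_text())

    def to_config_text(self) -> str:
        return yaml.safe_dump(self.to_mapping(), sort_keys=True)

    @classmethod
    def from_config(cls, path: str | Path) -> "ParameterSet":
        mapping = yaml.safe_load(Path(path).read_text())
        if not isinstance(mapping, Mapping):
            raise ConfigError(f"config {path} is not a flat key/value mapping")
        return cls.from_mapping(mapping)


@dataclass(frozen=True)
class CellState:
    """Protein concentrations of one cell (all a.u., all >= 0)."""

    OS: float
    N: float
    R: float
    E: float

    def __post_init__(self) -> None:
        for name in ("OS", "N", "R", "E"):
            value = getattr(self, name)
            if not math.isfinite(value) or value < 0.0:
                raise ValueError(
                    f"concentration {name} must be finite and >= 0, got {value!r}"
                )

    def to_array(self) -> np.ndarray:
        return np.array([self.OS, self.N, self.R, self.E], dtype=np.float64)

    @classmethod
    def from_array(cls, arr: Iterable[float]) -> "CellState":
        os_, n, r, e = (float(v) for v in arr)
        return cls(os_, n, r, e)


_SCENARIO_LABELS = ("LIF_serum", "TwoI", "N2B27_withdrawal")


@dataclass(frozen=True)
class Scenario:
    """A culture condition expressed as parameter overrides.

    ``p_override`` is the Erk repression strength for the static scenarios;
    the withdrawal scenario instead uses a per-cell stochastic ramp of ``p``
    (see :mod:`mescnet.differentiation`) and ``p_override`` holds its
    terminal value.
    """

    label: str
    p_override: float | None = None
    Y_level: float = 0.0
    rex1_turnover_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.label not in _SCENARIO_LABELS:
            raise ConfigError(
                f"scenario label must be one of {_SCENARIO_LABELS}, got {self.label!r}"
            )
        if self.label == "TwoI" and self.p_override not in (None, 0.0):
            raise ConfigError("the 2i scenario forces p = 0")
        if self.label != "N2B27_withdrawal" and self.rex1_turnover_scale != 1.0:
            raise ConfigError(
                "rex1_turnover_scale applies only to the N2B27_withdrawal scenario"
            )
        if not (0.0 < self.rex1_turnover_scale <= 1.0):
            raise ConfigError("rex1_turnover_scale must lie in (0, 1]")

    def apply(self, params: ParameterSet) -> ParameterSet:
        """Return ``params`` with this scenario's overrides applied."""
        changes: dict[str, float] = {"Y": self.Y_level}
        if self.label == "TwoI":
            changes["p"] = 0.0
        elif self.p_override is not None:
            changes["p"] = float(self.p_override)
        if self.rex1_turnover_scale != 1.0:
            changes["s5"] = params.s5 * self.rex1_turnover_scale
            changes["s6"] = params.s6 * self.rex1_turnover_scale
            changes["d_R"] = params.d_R * self.rex1_turnover_scale
            # keep the stationary Rex1 spread invariant under slower turnover
            changes["sigma_R"] = params.sigma_R * math.sqrt(self.rex1_turnover_scale)
        out = params.replace(**changes)
        if self.label == "LIF_serum" and out.p <= 0:
            raise ConfigError("a LIF/serum scenario requires p > 0")
        return out
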