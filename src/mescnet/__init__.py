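"""mescnet: stochastic model of the mESC pluripotency network.

A simulation-and-analysis pipeline for the four-variable stochastic
gene-regulatory network of mouse embryonic stem cell pluripotency
(Oct4-Sox2, Nanog, Rex1 and FGF4/Erk coupled by Hill kinetics with
multiplicative transcriptional noise and a Nanog-gated differentiation
signal), reproducing the culture-dependent phenotypes: Nanog/Rex1
bimodality under LIF/serum, the homogeneous 2i ground state, rare
stochastic NH/NL state transitions, and asynchronous differentiation
after 2i withdrawal.
"""

from importlib import resources

from .params import CellState, ParameterSet, Scenario
from .model import compute_Yin, deterministic_drift
from .sde import PopulationRun, Trajectory, simulate_cell, simulate_population
from .steady_state import (
    BifurcationDiagram,
    FixedPoint,
    bifurcation_scan,
    find_fixed_points,
)
from .state_analysis import (
    basin_boundary,
    detect_transitions,
    nl_fraction_sweep,
    residence_statistics,
    transition_rate,
    transitions_vs_noise,
)
from .differentiation import (
    RampSpec,
    differentiated_fraction_vs_Y,
    simulate_differentiation,
)
from .calibration import ConstraintSet, calibrate, fit_ramp
from .synthetic import (
    MixtureSpec,
    TimecourseSpec,
    distribution_distance,
    gen_flow_sample,
    gen_qpcr_timecourse,
)

__version__ = "0.1.0"

__all__ = [
    "CellState",
    "ParameterSet",
    "Scenario",
    "compute_Yin",
    "deterministic_drift",
    "Trajectory",
    "PopulationRun",
    "simulate_cell",
    "simulate_population",
    "FixedPoint",
    "BifurcationDiagram",
    "find_fixed_points",
    "bifurcation_scan",
    "basin_boundary",
    "detect_transitions",
    "transition_rate",
    "residence_statistics",
    "nl_fraction_sweep",
    "transitions_vs_noise",
    "RampSpec",
    "simulate_differentiation",
    "differentiated_fraction_vs_Y",
    "ConstraintSet",
    "calibrate",
    "fit_ramp",
    "MixtureSpec",
    "TimecourseSpec",
    "gen_flow_sample",
    "gen_qpcr_timecourse",
    "distribution_distance",
    "reference_parameters",
]


def reference_parameters() -> ParameterSet:
    """The calibrated LIF/serum reference parameter set (p = 15, Y = 0).

    Produced by the calibration pipeline against the published phenotype
    constraints; the 2i set is the same with ``p = 0``.
    """
    path = resources.files("mescnet").joinpath("data/reference_params.yaml")
    return ParameterSet.from_config(str(path))
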