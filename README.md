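# mescnet

A stochastic gene-regulatory-network model of mouse embryonic stem cell
(mESC) pluripotency, built as a tested simulation-and-analysis pipeline.
It is intended for systems biologists who want to explore how autocrine
FGF4/Erk signalling shapes the culture-dependent phenotypes of mESCs:
heterogeneous, bimodal Nanog/Rex1 expression under LIF/serum, the
homogeneous "ground state" under 2i, rare stochastic switches between
Nanog-high and Nanog-low subpopulations, and asynchronous differentiation
after withdrawal of the 2i inhibitors.

## The model

Four intracellular species per cell — the Oct4-Sox2 heterodimer [OS],
Nanog [N], Rex1 [R] and Erk activity [E] — evolve by coupled stochastic
differential equations with Hill-kinetic transcription (shared binding
constant k, Hill coefficient n = 2 for the dimer-mediated loops) and
first-order degradation:

```
d[OS]/dt = s12·H([OS])                       − d_OS·(1 + i_OS·Y_in)·[OS] + σ_OS·[OS]·ξ
d[N]/dt  = (s3·H([OS]) + s4·H([N]))·G_p([E]) − d_N ·(1 + i_N ·Y_in)·[N]  + σ_N ·[N] ·ξ
d[R]/dt  = s5·H([OS]) + s6·H([N])            − d_R ·(1 + i_R ·Y_in)·[R]  + σ_R ·[R] ·ξ
d[E]/dt  = s7·H([OS])                        − d_E·[E]
```

with `H(x) = xⁿ/(kⁿ + xⁿ)`, the Erk-mediated repression of Nanog
transcription `G_p(E) = 1/(1 + p·H(E))`, and the Nanog-gated intracellular
activity of an extrinsic differentiation signal Y,

```
Y_in(N) = Y · k_Yʰ / (k_Yʰ + Nʰ),
```

a decreasing S-shaped gate: only cells that have lost Nanog transmit the
differentiation signal, which then accelerates degradation of OS, N and R
("gate-keeper" role of Nanog).  The noise ξ is zero-mean Gaussian and
multiplicative; concentrations are clamped at zero.  Culture conditions
map onto parameters: LIF/serum has active Erk repression (p > 0, Nanog
bistable: NL and NH attractors), 2i removes it (p = 0, monostable NH),
and 2i withdrawal ramps p up per cell with random timing.

The integrator is Euler–Maruyama (numba-accelerated, counter-seeded per
cell, bit-reproducible).  Deterministic fixed points, stability and
one-parameter bifurcation diagrams come from multi-start root finding
with an independent 1-D reduction as oracle.  Attractor-basin analysis
counts a basin switch as a *valid transition* only when the cell stays on
the destination side for at least one hour.  A calibration module
recovers the packaged reference parameter set from the published
phenotype constraints, and a fitting module estimates the withdrawal
p-ramp from population mRNA time courses.

## Worked example

```python
import numpy as np
from mescnet import (reference_parameters, find_fixed_points,
                     simulate_population, basin_boundary)
from mescnet.state_analysis import nl_fraction, population_events, transition_rate

params = reference_parameters()          # calibrated LIF/serum set (p = 15)
for fp in find_fixed_points(params):
    if fp.branch in ("NL", "NH"):
        print(f"{fp.branch}: N = {fp.state.N:7.2f}  ({fp.stability})")
boundary = basin_boundary(params)
print(f"basin boundary: N = {boundary:.2f}")

pop = simulate_population(params, n_cells=1000, init_policy="at_NH",
                          duration=4320.0, dt=0.1, master_seed=1,
                          record_stride=10)
print(f"NL fraction after 3 days: {100 * nl_fraction(pop, boundary):.1f}%")
rate = transition_rate(population_events(pop, boundary), 1000, 4320.0)
print(f"transition rate: {rate.per_cell_per_day:.3f} per cell per 24 h "
      f"(95% CI {rate.ci_low:.3f}-{rate.ci_high:.3f})")
```

prints

```
NL: N =    1.51  (stable)
NH: N =  172.34  (stable)
basin boundary: N = 12.89
NL fraction after 3 days: 21.0%
transition rate: 0.088 per cell per 24 h (95% CI 0.077-0.098)
```

The two stable Nanog levels differ by about two orders of magnitude (the
bimodal LIF/serum pattern); a population seeded in the NH state
re-establishes roughly 20% Nanog-low cells within three days of in-silico
culture, and validated basin switches remain rare events.

A command-line interface exposes the same machinery
(`mescnet simulate`, `bifurcate`, `sweep`, `transitions`,
`transitions-vs-noise`, `differentiate`, `fraction-vs-y`, `calibrate`,
`fit-ramp`, `synth-flow`, `synth-qpcr`, `distance`); every run writes its
artifacts as CSV together with a manifest of the resolved configuration,
seeds and checksums.

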