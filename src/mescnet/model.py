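r"""Deterministic drift of the pluripotency network and the Nanog gate.

The four coupled equations (concentrations in a.u., time in minutes) are

.. math::

    d[OS]/dt &= s_{12} H([OS]) - d_{OS}(1 + i_{OS} Y_{in})[OS] \\
    d[N]/dt  &= (s_3 H([OS]) + s_4 H([N]))\,G_p([E])
                - d_N (1 + i_N Y_{in})[N] \\
    d[R]/dt  &= s_5 H([OS]) + s_6 H([N]) - d_R (1 + i_R Y_{in})[R] \\
    d[E]/dt  &= s_7 H([OS]) - d_E [E]

with the activating Hill function ``H(x) = x^n / (k^n + x^n)`` (one shared
binding constant ``k``, ``n = 2`` for the dimer-mediated loops), the Erk
repression factor ``G_p(E) = 1 / (1 + p H(E))`` acting on Nanog
transcription, and the intracellular differentiation activity

.. math::

    Y_{in}(N) = Y \, k_Y^h / (k_Y^h + N^h),

an S-shaped *decreasing* function of Nanog: only cells that have lost
Nanog transmit the extrinsic differentiation signal ``Y`` (the
"gate-keeper" role of Nanog).  ``Y_in`` enhances the degradation of
Oct4-Sox2, Nanog and Rex1 by the factors ``1 + i_j * Y_in``.
"""

from __future__ import annotations

import math

import numpy as np

from .params import CellState, ParameterSet

__all__ = ["hill", "compute_Yin", "deterministic_drift", "drift_array"]


def hill(x: float, k: float, n: float) -> float:
    """Activating Hill term ``x^n / (k^n + x^n)``; 0 at x=0, saturates at 1."""
    if x <= 0.0:
        return 0.0
    with np.errstate(over="ignore"):
        r = (x / k) ** n
    if not math.isfinite(r):
        return 1.0
    return r / (1.0 + r)


def compute_Yin(N: float, Y: float, k_Y: float, h: float) -> float:
    """Intracellular activity of the differentiation signal Y.

    Decreasing Hill gate of the Nanog concentration: ``Y_in(0) = Y``
    (in the absence of Nanog the signal is fully transmitted) and
    ``Y_in -> 0`` for high Nanog (the gate blocks transmission).
    Bounded in ``[0, Y]``; at ``N = k_Y`` exactly ``Y/2``.
    """
    for name, v in (("N", N), ("Y", Y), ("k_Y", k_Y), ("h", h)):
        if not math.isfinite(v):
            raise ValueError(f"{name} must be finite, got {v!r}")
    if N < 0 or Y < 0:
        raise ValueError("N and Y must be >= 0")
    if k_Y <= 0:
        raise ValueError("k_Y must be > 0")
    if h < 1:
        raise ValueError("h must be >= 1")
    if N == 0.0:
        return Y
    # evaluate via (N/k_Y)^h for numerical range safety
    r = (N / k_Y) ** h
    return Y / (1.0 + r)


def deterministic_drift(state: CellState, params: ParameterSet) -> np.ndarray:
    """Drift vector ``(f_OS, f_N, f_R, f_E)`` in a.u./min.

    Negative concentrations are rejected here: clamping to the zero lower
    bound is the integrator's job, not the drift's.
    """
    if not isinstance(state, CellState):
        state = CellState(*state)
    return drift_array(state.to_array(), params)


def drift_array(x: np.ndarray, params: ParameterSet) -> np.ndarray:
    """Drift evaluated on a raw length-4 array ``[OS, N, R, E]``."""
    x = np.asarray(x, dtype=float)
    if x.shape != (4,):
        raise ValueError("state must have exactly four components")
    if not np.all(np.isfinite(x)) or np.any(x < 0):
        raise ValueError("concentrations must be finite and >= 0")
    os_, n_, r_, e_ = x
    pr = params
    h_os = hill(os_, pr.k, pr.n)
    h_n = hill(n_, pr.k, pr.n)
    h_e = hill(e_, pr.k, pr.n)
    g_p = 1.0 / (1.0 + pr.p * h_e)
    y_in = compute_Yin(n_, pr.Y, pr.k_Y, pr.h)
    f_os = pr.s12 * h_os - pr.d_OS * (1.0 + pr.i_OS * y_in) * os_
    f_n = (pr.s3 * h_os + pr.s4 * h_n) * g_p - pr.d_N * (1.0 + pr.i_N * y_in) * n_
    f_r = pr.s5 * h_os + pr.s6 * h_n - pr.d_R * (1.0 + pr.i_R * y_in) * r_
    f_e = pr.s7 * h_os - pr.d_E * e_
    return np.array([f_os, f_n, f_r, f_e])
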