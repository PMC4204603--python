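"""Deterministic skeleton of the reduced model.

Transfer function, input-current composition, synaptic drift and its analytic
Jacobian. All functions are vectorized over numpy arrays; the drift is in
ms^-1 (rates in Hz are scaled by 1e-3 where they enter dS/dt).
"""

from __future__ import annotations

import numpy as np

from .params import ConditionSpec, ModelParameters

__all__ = [
    "transfer_rate",
    "transfer_rate_deriv",
    "input_currents",
    "drift",
    "jacobian",
]

# Below this |d*(a*x - b)| the transfer function and its derivative switch to
# series expansions around the removable singularity at a*x = b.
_SERIES_CUTOFF = 1e-6


def _check_finite(x, name: str) -> None:
    if not np.all(np.isfinite(x)):
        raise FloatingPointError(
            f"non-finite {name} encountered (numerical blow-up upstream?)"
        )


def transfer_rate(x, params: ModelParameters):
    """Effective frequency-current curve H(x), Hz.

    ``H(x) = (a*x - b) / (1 - exp(-d*(a*x - b)))`` with the removable
    singularity at ``a*x = b`` filled by its limit ``1/d``. Monotonically
    increasing, non-negative, continuous.
    """
    x = np.asarray(x, dtype=float)
    _check_finite(x, "input current")
    y = params.a * x - params.b
    u = params.d * y
    small = np.abs(u) < _SERIES_CUTOFF
    # exp(-u) overflows for u << 0; H underflows to ~|y|exp(u) there anyway
    u_safe = np.where(small, 1.0, np.clip(u, -700.0, None))
    with np.errstate(over="ignore"):
        out = np.where(small,
                       (1.0 + u / 2.0 + u * u / 12.0) / params.d,
                       y / (1.0 - np.exp(-u_safe)))
    return out if out.ndim else float(out)


def transfer_rate_deriv(x, params: ModelParameters):
    """dH/dx in Hz/nA (slope of the f-I curve)."""
    x = np.asarray(x, dtype=float)
    _check_finite(x, "input current")
    u = params.d * (params.a * x - params.b)
    small = np.abs(u) < 1e-4
    u_safe = np.where(small, 1.0, np.clip(u, -700.0, None))
    with np.errstate(over="ignore"):
        e = np.exp(-u_safe)
        g = np.where(small,
                     0.5 + u / 6.0 - u ** 3 / 360.0,
                     (1.0 - e - u_safe * e) / (1.0 - e) ** 2)
    out = params.a * g
    return out if out.ndim else float(out)


def _stimulus_currents(c: float, params: ModelParameters) -> tuple[float, float]:
    if not 0.0 <= c <= 100.0:
        raise ValueError(f"coherence must lie in [0, 100] percent, got {c}")
    base = params.J_ext * params.mu0
    return base * (1.0 + c / 100.0), base * (1.0 - c / 100.0)


def input_currents(S1, S2, c: float, stim_on: bool, params: ModelParameters,
                   I_noise1=0.0, I_noise2=0.0):
    """Total synaptic input currents (x1, x2) to the two populations, nA.

    ``x1 = J_self*S1 - J_cross*S2 + I0 + I_stim1 + I_noise1`` and
    symmetrically for x2. Population 1 is the target (receives the stronger
    stimulus for c > 0).
    """
    if stim_on:
        Is1, Is2 = _stimulus_currents(c, params)
    else:
        Is1 = Is2 = 0.0
    x1 = params.J_self * np.asarray(S1) - params.J_cross * np.asarray(S2) \
        + params.I0 + Is1 + I_noise1
    x2 = params.J_self * np.asarray(S2) - params.J_cross * np.asarray(S1) \
        + params.I0 + Is2 + I_noise2
    return x1, x2


def drift(S1, S2, c: float, stim_on: bool, params: ModelParameters,
          I_noise1=0.0, I_noise2=0.0):
    """Gating-variable drift (dS1/dt, dS2/dt) in ms^-1.

    ``dS_i/dt = -S_i/tau_S + (1 - S_i) * gamma * H(x_i)`` with H in Hz
    converted to ms^-1.
    """
    x1, x2 = input_currents(S1, S2, c, stim_on, params, I_noise1, I_noise2)
    r1 = transfer_rate(x1, params)
    r2 = transfer_rate(x2, params)
    g = params.gamma * 1e-3
    dS1 = -np.asarray(S1) / params.tau_S + (1.0 - np.asarray(S1)) * g * r1
    dS2 = -np.asarray(S2) / params.tau_S + (1.0 - np.asarray(S2)) * g * r2
    return dS1, dS2


def jacobian(S1: float, S2: float, c: float, stim_on: bool,
             params: ModelParameters) -> np.ndarray:
    """Analytic Jacobian of the noise-free drift w.r.t. (S1, S2).

    Entries are in ms^-1 per unit S. Noise currents are treated as zero.
    """
    x1, x2 = input_currents(S1, S2, c, stim_on, params)
    r1 = transfer_rate(x1, params)
    r2 = transfer_rate(x2, params)
    h1 = transfer_rate_deriv(x1, params)
    h2 = transfer_rate_deriv(x2, params)
    g = params.gamma * 1e-3
    J = np.empty((2, 2))
    J[0, 0] = -1.0 / params.tau_S - g * r1 + (1.0 - S1) * g * h1 * params.J_self
    J[0, 1] = (1.0 - S1) * g * h1 * (-params.J_cross)
    J[1, 0] = (1.0 - S2) * g * h2 * (-params.J_cross)
    J[1, 1] = -1.0 / params.tau_S - g * r2 + (1.0 - S2) * g * h2 * params.J_self
    return J


def rates_for_states(S1, S2, c: float, stim_on: bool,
                     params: ModelParameters):
    """Noise-free population rates (r1, r2) in Hz for gating states."""
    x1, x2 = input_currents(S1, S2, c, stim_on, params)
    return transfer_rate(x1, params), transfer_rate(x2, params)


def condition_params(params: ModelParameters, cond: ConditionSpec) -> ModelParameters:
    """Model parameters with a condition's background current applied."""
    return params.with_condition(cond)
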