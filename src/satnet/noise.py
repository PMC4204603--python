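"""Synthetic stochastic inputs: Ornstein-Uhlenbeck noise currents and the
coherence-dependent stimulus schedule.

The noise current to each population is a mean-reverting Gaussian process
with correlation time ``tau`` (2 ms by default) and stationary standard
deviation ``sigma`` (0.02 nA by default), discretized with the explicit
Euler-Maruyama update

    I <- I + dt*(-I/tau) + sigma*sqrt(2*dt/tau)*xi,   xi ~ N(0, 1),

whose stationary law matches the continuous process to O(dt). The two
populations receive independent streams.

Seed policy: one master seed per experiment; per-trial seeds derive
deterministically from (master, condition index, coherence index, trial
index), so any single trial is reproducible in isolation.
"""

from __future__ import annotations

import numpy as np

from .params import EpochSchedule, ModelParameters, NoiseSpec

__all__ = [
    "ou_coefficients",
    "ou_step",
    "ou_trace",
    "stationary_init",
    "stimulus_schedule",
    "trial_seed",
    "trial_generator",
]


def ou_coefficients(dt: float, spec: NoiseSpec) -> tuple[float, float]:
    """(decay fraction dt/tau, innovation amplitude).

    The amplitude ``sigma*sqrt(1 - (1 - dt/tau)^2)`` makes the stationary
    standard deviation of the discrete recursion exactly ``sigma``; it
    equals the Euler-Maruyama amplitude ``sigma*sqrt(2*dt/tau)`` to O(dt).
    Raises if the explicit scheme would be unstable (dt > tau/2).
    """
    if dt > spec.tau / 2.0:
        raise ValueError(
            f"dt={dt} ms exceeds tau/2={spec.tau / 2.0} ms: explicit OU "
            "update unstable; reduce the integration step"
        )
    dec = dt / spec.tau
    return dec, spec.sigma * np.sqrt(1.0 - (1.0 - dec) ** 2)


def ou_step(I_noise, dt: float, spec: NoiseSpec, rng_draw):
    """One Euler-Maruyama update of the noise current (nA).

    ``rng_draw`` is a standard-normal deviate (scalar or array matching
    ``I_noise``).
    """
    dec, amp = ou_coefficients(dt, spec)
    return I_noise + dt * (-I_noise / spec.tau) + amp * np.asarray(rng_draw)


def stationary_init(spec: NoiseSpec, rng: np.random.Generator, size=None):
    """Draw the noise current from its stationary law N(0, sigma^2)."""
    return rng.normal(0.0, spec.sigma, size)


def ou_trace(n_steps: int, dt: float, spec: NoiseSpec,
             rng: np.random.Generator, I0: float | None = None) -> np.ndarray:
    """Simulate ``n_steps`` of the discrete OU process; returns shape (n_steps,).

    Starts from the stationary distribution unless ``I0`` is given.
    """
    dec, amp = ou_coefficients(dt, spec)
    out = np.empty(n_steps)
    I = stationary_init(spec, rng) if I0 is None else float(I0)
    xi = rng.standard_normal(n_steps)
    for k in range(n_steps):
        I = I * (1.0 - dec) + amp * xi[k]
        out[k] = I
    return out


def stimulus_schedule(t: float, c: float, sched: EpochSchedule,
                      params: ModelParameters) -> tuple[float, float]:
    """Stimulus currents (I_stim1, I_stim2) in nA at time ``t`` (ms from
    trial start).

    Zero during the pre-stimulus epoch; during the stimulus the target
    (population 1) receives ``J_ext*mu0*(1 + c/100)`` and the distractor
    ``J_ext*mu0*(1 - c/100)``.
    """
    if not 0.0 <= t <= sched.t_prestim + sched.t_stim:
        raise ValueError(f"t={t} ms lies outside the trial")
    if not 0.0 <= c <= 100.0:
        raise ValueError(f"coherence must lie in [0, 100] percent, got {c}")
    if t < sched.t_prestim:
        return 0.0, 0.0
    base = params.J_ext * params.mu0
    return base * (1.0 + c / 100.0), base * (1.0 - c / 100.0)


def trial_seed(master_seed: int, cond_index: int, coh_index: int,
               trial_index: int) -> np.random.SeedSequence:
    """Deterministic per-trial seed derived from the experiment master seed."""
    return np.random.SeedSequence((master_seed, cond_index, coh_index,
                                   trial_index))


def trial_generator(master_seed: int, cond_index: int, coh_index: int,
                    trial_index: int) -> np.random.Generator:
    """Per-trial RNG; both populations' streams are drawn from it interleaved."""
    return np.random.default_rng(
        trial_seed(master_seed, cond_index, coh_index, trial_index))
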