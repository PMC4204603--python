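"""Parameter containers for the reduced two-population attractor model.

The model is the two-variable mean-field reduction of a biophysically based
cortical decision network (Wong & Wang, 2006): two populations selective for
the decision alternatives, each described by a slow NMDA-type synaptic gating
variable ``S`` that self-excites and cross-inhibits the other. Speed, neutral
and accuracy regimes are produced by a spatially nonselective background
current ``I0`` common to both populations.

Units convention (used throughout the package): time in ms, firing rates in
Hz, currents in nA. Configuration files accept ``I0`` in pA and convert.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace


@dataclass(frozen=True)
class ModelParameters:
    """Biophysical constants of the reduced model.

    Defaults are the canonical published values of the reduced two-variable
    model, except ``I0`` / ``sigma_noise`` which parameterize the background
    (nonselective) input manipulated across speed/neutral/accuracy conditions.

    Attributes
    ----------
    a, b, d : float
        Parameters of the effective frequency-current curve
        ``H(x) = (a*x - b) / (1 - exp(-d*(a*x - b)))`` with ``a`` in Hz/nA,
        ``b`` in Hz, ``d`` in s.
    gamma : float
        Coupling of presynaptic rate to gating-variable opening
        (dimensionless).
    tau_S : float
        Gating-variable (NMDA) decay time constant, ms.
    tau_noise : float
        Background noise-current correlation time, ms.
    J_self, J_cross : float
        Effective self-excitation and cross-inhibition strengths, nA;
        identical for the two populations (symmetric network).
    J_ext : float
        External input scaling, nA per Hz of stimulus drive.
    mu0 : float
        Stimulus reference rate, Hz; at motion coherence ``c`` (percent) the
        target and distractor populations receive ``J_ext*mu0*(1 +/- c/100)``.
    I0 : float
        Mean nonselective background current, nA.
    sigma_noise : float
        Stationary standard deviation of the background noise current, nA.
    """

    a: float = 270.0
    b: float = 108.0
    d: float = 0.154
    gamma: float = 0.641
    tau_S: float = 100.0
    tau_noise: float = 2.0
    J_self: float = 0.2609
    J_cross: float = 0.0497
    J_ext: float = 5.2e-4
    mu0: float = 30.0
    I0: float = 0.321
    sigma_noise: float = 0.02

    def __post_init__(self) -> None:
        for name in ("a", "b", "d", "gamma", "J_self", "J_cross", "J_ext", "mu0"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.tau_S <= 0 or self.tau_noise <= 0:
            raise ValueError("time constants must be strictly positive")
        if not self.tau_noise < self.tau_S:
            raise ValueError("tau_noise must be smaller than tau_S")
        if not 0.0 < self.I0 < 1.0:
            raise ValueError("I0 must lie in (0, 1) nA")
        if self.sigma_noise < 0:
            raise ValueError("sigma_noise must be non-negative")

    def with_condition(self, cond: "ConditionSpec") -> "ModelParameters":
        """Return a copy with ``I0``/``sigma_noise`` taken from a condition."""
        return replace(self, I0=cond.I0, sigma_noise=cond.sigma_noise)


@dataclass(frozen=True)
class ConditionSpec:
    """One speed-accuracy regime: a named setting of the background current.

    The study's three regimes differ only in the mean nonselective current
    (and, optionally, its noise amplitude): accuracy < neutral < speed.
    """

    name: str
    I0: float
    sigma_noise: float = 0.02

    def __post_init__(self) -> None:
        if not 0.0 < self.I0 < 1.0:
            raise ValueError("I0 must lie in (0, 1) nA")
        if self.sigma_noise < 0:
            raise ValueError("sigma_noise must be non-negative")


def default_conditions(sigma_noise: float = 0.02) -> tuple[ConditionSpec, ...]:
    """The study's three background-current conditions (I0 in nA).

    accuracy: 316 pA, neutral: 321 pA, speed: 325 pA.
    """
    return (
        ConditionSpec("speed", 0.325, sigma_noise),
        ConditionSpec("neutral", 0.321, sigma_noise),
        ConditionSpec("accuracy", 0.316, sigma_noise),
    )


@dataclass(frozen=True)
class EpochSchedule:
    """Trial timing: pre-stimulus epoch, stimulus epoch, integration step.

    Default trial: 2500 ms pre-stimulus followed by 5000 ms of stimulus,
    integrated at dt = 0.1 ms.
    """

    t_prestim: float = 2500.0
    t_stim: float = 5000.0
    dt: float = 0.1

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        for name in ("t_prestim", "t_stim"):
            t = getattr(self, name)
            if t <= 0:
                raise ValueError(f"{name} must be positive")
            n = t / self.dt
            if abs(n - round(n)) > 1e-9:
                raise ValueError(f"{name} must be a positive multiple of dt")

    @property
    def n_prestim(self) -> int:
        return int(round(self.t_prestim / self.dt))

    @property
    def n_stim(self) -> int:
        return int(round(self.t_stim / self.dt))

    @property
    def n_total(self) -> int:
        return self.n_prestim + self.n_stim


@dataclass(frozen=True)
class NoiseSpec:
    """Ornstein-Uhlenbeck noise-current settings for one population.

    The discrete update ``I <- I + dt*(-I/tau) + sigma*sqrt(2*dt/tau)*xi``
    has stationary mean 0, stationary std ``sigma`` and correlation time
    ``tau``. Each population receives an independent stream.
    """

    sigma: float = 0.02
    tau: float = 2.0
    seed: int | tuple[int, ...] = 0

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")
        if self.tau <= 0:
            raise ValueError("tau must be positive")


#: Default choice threshold applied to population firing rates, Hz.
DEFAULT_THETA: float = 15.0

#: Default coherence grid of the random-dot-motion study, percent.
DEFAULT_COHERENCES: tuple[float, ...] = (0.0, 1.0, 2.0, 4.0, 8.0, 16.0, 32.0)
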