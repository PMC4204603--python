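"""Noise-free phase-plane analysis of the reduced model.

Fixed points and their classification, the saddle between the two choice
attractors, its stable/unstable manifolds, the effective time constant of
integration (reciprocal of the saddle's positive eigenvalue), and the
geometric position of the network's initial state relative to the stable
manifold (the basin boundary whose crossing by noise produces errors).

Manifolds are traced as arclength-parameterized polylines: the unstable
manifold by forward integration of the unit-speed drift field from the
saddle displaced along its unstable eigenvector (both signs), the stable
manifold by backward-time integration along the stable eigenvector.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import root

from .model import drift, jacobian, rates_for_states
from .params import ConditionSpec, ModelParameters

__all__ = [
    "FixedPoint",
    "PhasePortrait",
    "find_fixed_points",
    "effective_time_constant",
    "trace_manifolds",
    "initial_state_distance",
    "compute_phase_portrait",
]

KIND_STABLE = "stable"
KIND_SADDLE = "saddle"
KIND_UNSTABLE = "unstable"

#: Drift-norm tolerance certifying a fixed point, ms^-1.
FP_TOL = 1e-9
#: Fixed points closer than this in S-space are considered duplicates.
DEDUP_TOL = 1e-6
#: Displacement along eigenvectors when seeding manifold integration.
MANIFOLD_EPS = 1e-4


@dataclass
class FixedPoint:
    """A steady state of the noise-free system with its eigenstructure."""

    S: np.ndarray  # (2,) gating coordinates
    rates: np.ndarray  # (2,) Hz
    eigenvalues: np.ndarray  # (2,) ms^-1 (may be complex)
    eigenvectors: np.ndarray  # (2, 2), columns matching eigenvalues
    kind: str  # stable | saddle | unstable

    @property
    def lambda_plus(self) -> float:
        """Largest real eigenvalue part (positive at a saddle), ms^-1."""
        return float(np.max(self.eigenvalues.real))


@dataclass
class PhasePortrait:
    """Fixed points, manifolds and derived geometry for one cell."""

    condition: str
    coherence: float
    stim_on: bool
    fixed_points: list[FixedPoint]
    saddle: FixedPoint | None
    tau_eff: float | None  # ms
    # each manifold: list of branches; each branch (n_pts, 2) in S-space
    unstable_branches_S: list[np.ndarray]
    stable_branches_S: list[np.ndarray]
    unstable_branches_rates: list[np.ndarray]
    stable_branches_rates: list[np.ndarray]
    truncated_flags: dict[str, bool]
    initial_state_S: np.ndarray | None = None
    initial_state_rates: np.ndarray | None = None
    init_distance: float | None = None  # Hz

    @property
    def attractors(self) -> list[FixedPoint]:
        return [fp for fp in self.fixed_points if fp.kind == KIND_STABLE]


def _classify(eigvals: np.ndarray) -> str:
    if np.all(eigvals.real < 0):
        return KIND_STABLE
    if (np.all(np.abs(eigvals.imag) < 1e-12)
            and eigvals.real[0] * eigvals.real[1] < 0):
        return KIND_SADDLE
    return KIND_UNSTABLE


def _make_fixed_point(S: np.ndarray, c: float, stim_on: bool,
                      params: ModelParameters) -> FixedPoint:
    J = jacobian(S[0], S[1], c, stim_on, params)
    w, v = np.linalg.eig(J)
    order = np.argsort(w.real)  # stable direction first
    w, v = w[order], v[:, order]
    r1, r2 = rates_for_states(S[0], S[1], c, stim_on, params)
    return FixedPoint(S=S.copy(), rates=np.array([float(r1), float(r2)]),
                      eigenvalues=w, eigenvectors=v, kind=_classify(w))


def find_fixed_points(params: ModelParameters, cond: ConditionSpec | None,
                      c: float, stim_on: bool, grid_n: int = 21,
                      ) -> list[FixedPoint]:
    """Locate all fixed points of the noise-free system.

    Newton refinement (via ``scipy.optimize.root``) from a ``grid_n`` x
    ``grid_n`` lattice of initial guesses over [0, 1]^2; converged roots are
    certified (drift norm < 1e-9 ms^-1), deduplicated within 1e-6 and
    classified by the analytic Jacobian's eigenvalues.
    """
    p = params.with_condition(cond) if cond is not None else params

    def fun(S):
        d1, d2 = drift(S[0], S[1], c, stim_on, p)
        return np.array([float(d1), float(d2)])

    def jac(S):
        return jacobian(S[0], S[1], c, stim_on, p)

    found: list[np.ndarray] = []
    guesses = np.linspace(0.001, 0.999, grid_n)
    for s1 in guesses:
        for s2 in guesses:
            sol = root(fun, np.array([s1, s2]), jac=jac, method="hybr",
                       tol=1e-13)
            if not sol.success:
                continue
            S = np.clip(sol.x, 0.0, 1.0)
            if np.linalg.norm(fun(S)) >= FP_TOL:
                continue
            if any(np.linalg.norm(S - q) < DEDUP_TOL for q in found):
                continue
            found.append(S)
    if not found:
        raise RuntimeError(
            f"no fixed points converged from a {grid_n}x{grid_n} grid "
            f"(c={c}, stim_on={stim_on}, I0={p.I0})")
    found.sort(key=lambda S: (round(S[0] + S[1], 9), round(S[0], 9)))
    return [_make_fixed_point(S, c, stim_on, p) for S in found]


def effective_time_constant(saddle: FixedPoint) -> float:
    """Time constant of the saddle's unstable manifold, 1/lambda_plus (ms).

    This is the effective time constant of evidence integration: the time
    scale over which the network is repelled from the saddle toward a choice
    attractor.
    """
    if saddle.kind != KIND_SADDLE:
        raise ValueError(f"effective_time_constant requires a saddle, "
                         f"got {saddle.kind}")
    return 1.0 / saddle.lambda_plus


def _integrate_unit_speed(start: np.ndarray, c: float, stim_on: bool,
                          params: ModelParameters, forward: bool,
                          max_arclength: float = 4.0,
                          n_samples: int = 800) -> tuple[np.ndarray, bool]:
    """Integrate dS/dl = +/- f/||f|| until a fixed point or the unit square.

    Returns (polyline (n, 2), truncated_at_boundary).
    """
    sign = 1.0 if forward else -1.0

    def rhs(_l, S):
        d1, d2 = drift(S[0], S[1], c, stim_on, params)
        f = np.array([float(d1), float(d2)])
        n = np.linalg.norm(f)
        return sign * f / max(n, 1e-300)

    def ev_fixed_point(_l, S):
        d1, d2 = drift(S[0], S[1], c, stim_on, params)
        return float(np.hypot(d1, d2)) - 1e-9

    ev_fixed_point.terminal = True
    ev_fixed_point.direction = -1

    def ev_domain(_l, S):
        return float(min(S[0], S[1], 1.0 - S[0], 1.0 - S[1]))

    ev_domain.terminal = True
    ev_domain.direction = -1

    sol = solve_ivp(rhs, (0.0, max_arclength), start, method="RK45",
                    rtol=1e-8, atol=1e-10, max_step=0.02,
                    dense_output=True, events=[ev_fixed_point, ev_domain])
    l_end = sol.t[-1]
    ls = np.linspace(0.0, l_end, n_samples)
    pts = sol.sol(ls).T
    truncated = len(sol.t_events[1]) > 0
    return pts, truncated


def trace_manifolds(saddle: FixedPoint, params: ModelParameters,
                    cond: ConditionSpec | None, c: float,
                    stim_on: bool = True, eps: float = MANIFOLD_EPS,
                    ) -> dict:
    """Trace the saddle's stable and unstable manifolds as polylines.

    Unstable: forward integration from ``saddle +/- eps * e_unstable`` (each
    branch terminates near a choice attractor). Stable: backward-time
    integration from ``saddle +/- eps * e_stable`` (branches are truncated at
    the boundary of [0, 1]^2 and flagged). Returns branches in S-space and
    their images in rate space.
    """
    if saddle.kind != KIND_SADDLE:
        raise ValueError("trace_manifolds requires a saddle")
    p = params.with_condition(cond) if cond is not None else params
    e_stable = saddle.eigenvectors[:, 0].real
    e_unstable = saddle.eigenvectors[:, 1].real

    unstable, stable, flags = [], [], {}
    for i, sgn in enumerate((1.0, -1.0)):
        pts, trunc = _integrate_unit_speed(saddle.S + sgn * eps * e_unstable,
                                           c, stim_on, p, forward=True)
        unstable.append(np.vstack([saddle.S, pts]))
        flags[f"unstable_{i}"] = trunc
    for i, sgn in enumerate((1.0, -1.0)):
        pts, trunc = _integrate_unit_speed(saddle.S + sgn * eps * e_stable,
                                           c, stim_on, p, forward=False)
        stable.append(np.vstack([saddle.S, pts]))
        flags[f"stable_{i}"] = trunc

    def to_rates(branch):
        r1, r2 = rates_for_states(branch[:, 0], branch[:, 1], c, stim_on, p)
        return np.column_stack([r1, r2])

    return {
        "unstable_S": unstable,
        "stable_S": stable,
        "unstable_rates": [to_rates(b) for b in unstable],
        "stable_rates": [to_rates(b) for b in stable],
        "truncated": flags,
    }


def _point_to_polyline_distance(point: np.ndarray,
                                polyline: np.ndarray) -> float:
    """Minimal Euclidean distance from a point to a polyline's segments."""
    P = np.asarray(point, dtype=float)
    A = polyline[:-1]
    B = polyline[1:]
    AB = B - A
    denom = np.einsum("ij,ij->i", AB, AB)
    denom = np.where(denom == 0.0, 1.0, denom)
    t = np.clip(np.einsum("ij,ij->i", P - A, AB) / denom, 0.0, 1.0)
    proj = A + t[:, None] * AB
    d = np.linalg.norm(proj - P, axis=1)
    return float(d.min())


def initial_state_distance(portrait: "PhasePortrait",
                           initial_rates: np.ndarray) -> float:
    """Distance (Hz) from an initial state to the stable manifold, rate space.

    The initial state is the mean network state at the end of the
    pre-stimulus epoch, mapped to rate coordinates; the distance quantifies
    how precariously close the resting state sits to the basin boundary.
    """
    branches = portrait.stable_branches_rates
    if not branches or all(len(b) == 0 for b in branches):
        raise ValueError("portrait has no stable-manifold polyline")
    return min(_point_to_polyline_distance(np.asarray(initial_rates, float), b)
               for b in branches if len(b) >= 2)


def _select_decision_saddle(fps: list[FixedPoint], params: ModelParameters,
                            c: float, stim_on: bool) -> FixedPoint | None:
    """The saddle separating the two choice attractors.

    If several saddles exist, prefer the one whose unstable-manifold branches
    terminate at two distinct attractors; fall back on proximity to the
    diagonal S1 = S2.
    """
    saddles = [fp for fp in fps if fp.kind == KIND_SADDLE]
    if not saddles:
        return None
    if len(saddles) == 1:
        return saddles[0]
    attractors = [fp for fp in fps if fp.kind == KIND_STABLE]

    def connects_two(s: FixedPoint) -> bool:
        ends = []
        for sgn in (1.0, -1.0):
            e_u = s.eigenvectors[:, 1].real
            pts, _ = _integrate_unit_speed(s.S + sgn * MANIFOLD_EPS * e_u,
                                           c, stim_on, params, forward=True,
                                           n_samples=4)
            end = pts[-1]
            hit = [i for i, a in enumerate(attractors)
                   if np.linalg.norm(end - a.S) < 1e-2]
            ends.append(hit[0] if hit else None)
        return ends[0] is not None and ends[1] is not None \
            and ends[0] != ends[1]

    connected = [s for s in saddles if connects_two(s)]
    pool = connected if connected else saddles
    return min(pool, key=lambda s: abs(s.S[0] - s.S[1]))


def compute_phase_portrait(params: ModelParameters, cond: ConditionSpec,
                           c: float, stim_on: bool = True,
                           initial_state_S: np.ndarray | None = None,
                           ) -> PhasePortrait:
    """Full phase-plane summary for one (condition, coherence) cell.

    If ``initial_state_S`` (mean pre-stimulus gating state) is given, it is
    mapped to rate space under the same (stimulus-on) currents as the
    manifolds, and its distance to the stable manifold is computed.
    """
    p = params.with_condition(cond)
    fps = find_fixed_points(p, None, c, stim_on)
    saddle = _select_decision_saddle(fps, p, c, stim_on)
    tau_eff = effective_time_constant(saddle) if saddle is not None else None
    if saddle is not None:
        man = trace_manifolds(saddle, p, None, c, stim_on)
        unstable_S, stable_S = man["unstable_S"], man["stable_S"]
        unstable_r, stable_r = man["unstable_rates"], man["stable_rates"]
        flags = man["truncated"]
    else:
        unstable_S = stable_S = unstable_r = stable_r = []
        flags = {}
    portrait = PhasePortrait(
        condition=cond.name, coherence=c, stim_on=stim_on,
        fixed_points=fps, saddle=saddle, tau_eff=tau_eff,
        unstable_branches_S=unstable_S, stable_branches_S=stable_S,
        unstable_branches_rates=unstable_r, stable_branches_rates=stable_r,
        truncated_flags=flags)
    if initial_state_S is not None:
        S0 = np.asarray(initial_state_S, dtype=float)
        r1, r2 = rates_for_states(S0[0], S0[1], c, stim_on, p)
        portrait.initial_state_S = S0
        portrait.initial_state_rates = np.array([float(r1), float(r2)])
        portrait.init_distance = initial_state_distance(
            portrait, portrait.initial_state_rates)
    return portrait
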