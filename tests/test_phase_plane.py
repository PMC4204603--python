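"""Fixed points, manifolds and the effective time constant of integration."""

import numpy as np
import pytest
from scipy.optimize import root

from satnet import (ModelParameters, compute_phase_portrait, drift,
                    effective_time_constant, find_fixed_points,
                    initial_state_distance, jacobian, trace_manifolds)
from satnet.phase import (FixedPoint, KIND_SADDLE, KIND_STABLE,
                          _point_to_polyline_distance)


@pytest.fixture(scope="module")
def neutral_portrait(conditions_mod):
    return compute_phase_portrait(ModelParameters(), conditions_mod[1], 4.0,
                                  stim_on=True)


@pytest.fixture(scope="module")
def conditions_mod():
    from satnet import default_conditions
    return default_conditions()


def grid_scan_fixed_points(params, c, stim_on, n=2001):
    """Independent oracle: nullcline sign-change scan + local refinement.

    Marks every grid cell over [0,1]^2 in which both drift components change
    sign, then refines each candidate with a root solve from the cell
    center; deduplicates.
    """
    s = np.linspace(0.0, 1.0, n)
    S1, S2 = np.meshgrid(s, s, indexing="ij")
    d1, d2 = drift(S1, S2, c, stim_on, params)
    sign1, sign2 = np.sign(d1), np.sign(d2)

    def changes(sgn):
        ch = np.zeros((n - 1, n - 1), dtype=bool)
        for a, b in ((sgn[:-1, :-1], sgn[1:, :-1]),
                     (sgn[:-1, :-1], sgn[:-1, 1:]),
                     (sgn[:-1, :-1], sgn[1:, 1:])):
            ch |= a != b
        return ch

    candidates = np.argwhere(changes(sign1) & changes(sign2))
    found = []
    for i, j in candidates:
        guess = np.array([(s[i] + s[i + 1]) / 2, (s[j] + s[j + 1]) / 2])
        sol = root(lambda S: np.array(drift(S[0], S[1], c, stim_on, params),
                                      dtype=float), guess, tol=1e-13)
        if not sol.success:
            continue
        p = np.clip(sol.x, 0, 1)
        if np.linalg.norm(np.array(drift(p[0], p[1], c, stim_on, params),
                                   dtype=float)) > 1e-11:
            continue
        if not any(np.linalg.norm(p - q) < 1e-5 for q in found):
            found.append(p)
    return sorted(found, key=lambda p: (round(p[0] + p[1], 8), p[0]))


class TestFixedPoints:
    def test_zero_coherence_set_is_swap_symmetric(self, conditions_mod):
        p = ModelParameters()
        fps = find_fixed_points(p, conditions_mod[1], 0.0, True)
        coords = [fp.S for fp in fps]
        for S in coords:
            swapped = S[::-1]
            assert any(np.linalg.norm(swapped - T) < 1e-8 for T in coords)
        saddles = [fp for fp in fps if fp.kind == KIND_SADDLE]
        assert len(saddles) == 1
        assert abs(saddles[0].S[0] - saddles[0].S[1]) < 1e-8

    def test_drift_vanishes_at_every_returned_point(self, conditions_mod):
        p = ModelParameters()
        for cond in conditions_mod:
            for fp in find_fixed_points(p, cond, 4.0, True):
                d = np.array(drift(fp.S[0], fp.S[1], 4.0, True,
                                   p.with_condition(cond)), dtype=float)
                assert np.linalg.norm(d) < 1e-9

    @pytest.mark.parametrize("cond_idx", [0, 1, 2])
    def test_matches_grid_scan_oracle(self, conditions_mod, cond_idx):
        cond = conditions_mod[cond_idx]
        p = ModelParameters().with_condition(cond)
        ours = sorted([fp.S for fp in find_fixed_points(p, None, 4.0, True)],
                      key=lambda S: (round(S[0] + S[1], 8), S[0]))
        oracle = grid_scan_fixed_points(p, 4.0, True)
        assert len(ours) == len(oracle)
        for a, b in zip(ours, oracle):
            assert np.linalg.norm(a - b) < 1e-4

    def test_classification_eigenstructure(self, neutral_portrait):
        for fp in neutral_portrait.fixed_points:
            if fp.kind == KIND_STABLE:
                assert np.all(fp.eigenvalues.real < 0)
            elif fp.kind == KIND_SADDLE:
                assert np.all(np.abs(fp.eigenvalues.imag) < 1e-12)
                assert fp.eigenvalues.real[0] * fp.eigenvalues.real[1] < 0


class TestEffectiveTimeConstant:
    def test_reciprocal_of_positive_eigenvalue(self):
        fp = FixedPoint(S=np.array([0.3, 0.3]), rates=np.array([5.0, 5.0]),
                        eigenvalues=np.array([-0.002, 0.005]),
                        eigenvectors=np.eye(2), kind=KIND_SADDLE)
        assert effective_time_constant(fp) == pytest.approx(200.0)

    def test_rejects_non_saddle(self):
        fp = FixedPoint(S=np.array([0.1, 0.1]), rates=np.array([2.0, 2.0]),
                        eigenvalues=np.array([-0.002, -0.005]),
                        eigenvectors=np.eye(2), kind=KIND_STABLE)
        with pytest.raises(ValueError):
            effective_time_constant(fp)

    def test_analytic_eigenvalue_matches_finite_difference_jacobian(
            self, neutral_portrait, conditions_mod):
        saddle = neutral_portrait.saddle
        p = ModelParameters().with_condition(conditions_mod[1])
        h = 1e-6
        J = np.empty((2, 2))
        for j, (e1, e2) in enumerate([(h, 0.0), (0.0, h)]):
            fp_ = drift(saddle.S[0] + e1, saddle.S[1] + e2, 4.0, True, p)
            fm_ = drift(saddle.S[0] - e1, saddle.S[1] - e2, 4.0, True, p)
            J[0, j] = (float(fp_[0]) - float(fm_[0])) / (2 * h)
            J[1, j] = (float(fp_[1]) - float(fm_[1])) / (2 * h)
        lam_fd = np.max(np.linalg.eigvals(J).real)
        assert saddle.lambda_plus == pytest.approx(lam_fd, rel=1e-3)


class TestManifolds:
    def test_zero_coherence_unstable_branches_mirror(self, conditions_mod):
        p = ModelParameters()
        fps = find_fixed_points(p, conditions_mod[1], 0.0, True)
        saddle = [fp for fp in fps if fp.kind == KIND_SADDLE][0]
        man = trace_manifolds(saddle, p, conditions_mod[1], 0.0, True)
        b0, b1 = man["unstable_S"]
        # branch 0 reflected through the diagonal reproduces branch 1
        m = min(len(b0), len(b1))
        assert np.allclose(b0[:m], b1[:m][:, ::-1], atol=2e-3)

    def test_zero_coherence_stable_manifold_is_diagonal(self, conditions_mod):
        p = ModelParameters()
        fps = find_fixed_points(p, conditions_mod[1], 0.0, True)
        saddle = [fp for fp in fps if fp.kind == KIND_SADDLE][0]
        man = trace_manifolds(saddle, p, conditions_mod[1], 0.0, True)
        for branch in man["stable_S"]:
            assert np.max(np.abs(branch[:, 0] - branch[:, 1])) < 1e-6

    def test_unstable_branches_terminate_at_attractors(self, neutral_portrait):
        attractors = [fp.S for fp in neutral_portrait.attractors]
        ends = [b[-1] for b in neutral_portrait.unstable_branches_S]
        hit = []
        for end in ends:
            d = [np.linalg.norm(end - a) for a in attractors]
            assert min(d) < 1e-3
            hit.append(int(np.argmin(d)))
        assert hit[0] != hit[1]  # the two branches reach the two choices

    def test_drift_tangent_to_polylines(self, neutral_portrait, conditions_mod):
        p = ModelParameters().with_condition(conditions_mod[1])
        for branch in (neutral_portrait.unstable_branches_S
                       + neutral_portrait.stable_branches_S):
            pts = branch[len(branch) // 4: -len(branch) // 4: 20]
            segs = np.diff(branch[len(branch) // 4: -len(branch) // 4: 20],
                           axis=0)
            for q, seg in zip(pts[:-1], segs):
                f = np.array(drift(q[0], q[1], 4.0, True, p), dtype=float)
                cosang = abs(f @ seg) / (np.linalg.norm(f)
                                         * np.linalg.norm(seg))
                assert cosang > np.cos(np.deg2rad(1.0))


class TestInitialStateDistance:
    def test_point_on_polyline_has_zero_distance(self, neutral_portrait):
        branch = neutral_portrait.stable_branches_rates[0]
        mid = branch[len(branch) // 2]
        assert initial_state_distance(neutral_portrait, mid) < 1e-9

    def test_agrees_with_densified_polyline_scan(self, neutral_portrait):
        point = np.array([3.0, 3.0])
        d = initial_state_distance(neutral_portrait, point)
        brute = np.inf
        for branch in neutral_portrait.stable_branches_rates:
            a, b = branch[:-1], branch[1:]
            for t in np.linspace(0, 1, 10):
                pts = a + t * (b - a)
                brute = min(brute, np.linalg.norm(pts - point,
                                                  axis=1).min())
        assert d == pytest.approx(brute, rel=0.01)

    def test_segment_distance_helper(self):
        line = np.array([[0.0, 0.0], [1.0, 0.0]])
        assert _point_to_polyline_distance(np.array([0.5, 2.0]), line) \
            == pytest.approx(2.0)
        assert _point_to_polyline_distance(np.array([3.0, 0.0]), line) \
            == pytest.approx(2.0)
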