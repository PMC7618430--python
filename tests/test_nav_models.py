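"""Analytic navigational models: linearization, combination rules, maps."""

import numpy as np
import pytest

from gridmapnav.angles import abs_diff, angle_of, unit_vector, wrap_signed
from gridmapnav.environments import (
    Environment,
    GradientSpec,
    goal_direction,
    make_environment,
)
from gridmapnav.nav_models import (
    LinearizedField,
    NavModelSpec,
    SingularGeometryError,
    UndefinedHeadingError,
    all_model_specs,
    combine_approximate,
    combine_correct,
    combine_directional,
    displacement_estimate,
    linearize,
    model_heading,
    prediction_map,
)

LINEAR = ("B1", "B2i", "B2ii")


def identity_env(b_case):
    """Environment with k1 zeroing the goal and k2 = 1 (unscaled fields)."""
    raw_goal = {"B1": 0.0, "B2i": 0.0, "B2ii": 0.0, "B3i": -1.0, "B3ii": -0.8, "B4i": 1.0, "B4ii": 216.0}
    return Environment(
        field_A=GradientSpec("A", 0.0, 1.0),
        field_B=GradientSpec(b_case, raw_goal[b_case], 1.0),
        label=f"{b_case}-identity",
    )


class TestLinearize:
    def test_linear_field_all_modes_identical(self, locset):
        env = identity_env("B2i")
        p = np.array([1.7, -0.3])
        gvecs = [
            linearize(env, "B", mode, p, locset.training).gvec
            for mode in ("TARGET", "RELEASE", "TRAINING")
        ]
        for g in gvecs[1:]:
            assert g == pytest.approx(gvecs[0], abs=1e-12)

    def test_b3i_target_gradient(self):
        env = identity_env("B3i")
        lin = linearize(env, "B", "TARGET", np.array([2.0, 2.0]))
        assert lin.gvec == pytest.approx([1.0, 2.0])
        # delta is the true sensed field offset, not a linearization
        assert lin.delta == pytest.approx(2.0 - (2.0 - 1.0) ** 2 + 1.0)

    def test_b4i_training_mean_matches_brute_force(self, locset):
        env = identity_env("B4i")
        lin = linearize(env, "B", "TRAINING", np.zeros(2), locset.training)
        expected = np.mean(
            [env.field_B.gradient(p) for p in locset.training], axis=0
        )
        assert lin.gvec == pytest.approx(expected, abs=1e-12)
        assert lin.gvec[0] == 0.0  # varies along y only

    def test_training_mode_requires_training_set(self):
        env = identity_env("B3i")
        with pytest.raises(ValueError, match="non-empty training"):
            linearize(env, "B", "TRAINING", np.zeros(2), training=[])


class TestDisplacementEstimate:
    @pytest.mark.parametrize(
        "delta, gvec, expected",
        [
            (3.0, (1, 0), (3, 0)),
            (2.0, (1, -1), (1, -1)),
            (0.0, (5, 2), (0, 0)),
        ],
    )
    def test_examples(self, delta, gvec, expected):
        lin = LinearizedField(base_value=delta, delta=delta, gvec=np.array(gvec, float))
        d = displacement_estimate(lin)
        assert d == pytest.approx(expected)
        # the displacement accounts exactly for the observed value offset
        assert float(d @ lin.gvec) == pytest.approx(delta)

    def test_zero_gradient_error(self):
        lin = LinearizedField(1.0, 1.0, np.zeros(2))
        with pytest.raises(ValueError, match="zero extrapolation gradient"):
            displacement_estimate(lin)


class TestCombinationRules:
    def test_approx_exact_in_orthogonal_grid(self):
        # B1 at (3, 4): per-field displacements recover the true location
        heading = combine_approximate(np.array([3.0, 0.0]), np.array([0.0, 4.0]))
        assert abs_diff(heading, goal_direction(np.array([3.0, 4.0]))) < 1e-12

    def test_approx_bias_in_oblique_grid(self):
        # frozen from the two-argument arctangent oracle:
        # heading = angle(-(dA+dB)) = angle((-3, 1)); true = angle((-2, 0))
        heading = combine_approximate(np.array([2.0, 0.0]), np.array([1.0, -1.0]))
        expected = float(angle_of(-3.0, 1.0))
        assert heading == pytest.approx(expected)
        err = wrap_signed(heading - goal_direction(np.array([2.0, 0.0])))
        assert err == pytest.approx(0.32175055439664219)

    def test_antiparallel_cancellation_is_undefined(self):
        with pytest.raises(UndefinedHeadingError):
            combine_approximate(np.array([1.0, 0.0]), np.array([-1.0, 0.0]))

    def _lin(self, delta, gvec):
        return LinearizedField(delta, delta, np.array(gvec, float))

    def test_directional_error_in_b1(self):
        # at (3, 4) the equal-weight direction is the diagonal
        h = combine_directional(self._lin(3.0, (1, 0)), self._lin(4.0, (0, 1)))
        assert h == pytest.approx(float(angle_of(-1.0, -1.0)))
        err = wrap_signed(h - goal_direction(np.array([3.0, 4.0])))
        assert err == pytest.approx(0.14189705460416438)
        # on the diagonal the directional model is exact
        h = combine_directional(self._lin(1.0, (1, 0)), self._lin(1.0, (0, 1)))
        assert abs_diff(h, goal_direction(np.array([1.0, 1.0]))) < 1e-12

    def test_directional_ignores_gradient_magnitude(self):
        a, b = self._lin(0.5, (1, 0)), self._lin(2.0, (1, -1))
        h1 = combine_directional(a, b)
        h2 = combine_directional(self._lin(0.5, (10, 0)), self._lin(2.0, (10, -10)))
        assert h1 == pytest.approx(h2)

    def test_directional_zero_delta_contributes_nothing(self):
        h = combine_directional(self._lin(0.0, (1, 0)), self._lin(1.0, (0, 1)))
        assert h == pytest.approx(float(angle_of(0.0, -1.0)))
        with pytest.raises(UndefinedHeadingError):
            combine_directional(self._lin(0.0, (1, 0)), self._lin(0.0, (0, 1)))

    def test_correct_solves_oblique_linear_grid_exactly(self):
        h = combine_correct(self._lin(2.0, (1, 0)), self._lin(2.0, (1, -1)))
        assert abs_diff(h, goal_direction(np.array([2.0, 0.0]))) < 1e-12

    def test_correct_rejects_parallel_gradients(self):
        with pytest.raises(SingularGeometryError):
            combine_correct(self._lin(1.0, (1, 0)), self._lin(1.0, (2, 0)))


class TestPredictionMaps:
    def test_approx_and_correct_zero_error_in_b1(self, envs, locset):
        for comb in ("APPROX", "CORRECT"):
            pm = prediction_map(
                envs["B1"], NavModelSpec(comb, "TARGET"), locset.test, locset.training
            )
            assert np.all(np.abs(pm.signed_errors[pm.defined]) < 1e-9)
            assert not pm.defined[locset.test_is_goal][0]

    @pytest.mark.parametrize("case", ["B4i", "B4ii"])
    def test_approx_equals_correct_in_orthogonal_nonlinear(self, envs, locset, case):
        maps = {
            c: prediction_map(envs[case], NavModelSpec(c, "RELEASE"), locset.test, locset.training)
            for c in ("APPROX", "CORRECT")
        }
        both = maps["APPROX"].defined & maps["CORRECT"].defined
        diff = wrap_signed(maps["APPROX"].headings[both] - maps["CORRECT"].headings[both])
        assert np.max(np.abs(diff)) < 1e-9

    def test_directional_extrapolations_coincide_in_b4i(self, envs, locset):
        maps = [
            prediction_map(envs["B4i"], NavModelSpec("DIRECTIONAL", e), locset.test, locset.training)
            for e in ("TARGET", "RELEASE", "TRAINING")
        ]
        for pm in maps[1:]:
            both = maps[0].defined & pm.defined
            assert np.max(np.abs(wrap_signed(maps[0].headings[both] - pm.headings[both]))) < 1e-12

    @pytest.mark.parametrize("case", LINEAR)
    def test_linear_envs_invariant_to_extrapolation(self, envs, locset, case):
        for comb in ("APPROX", "DIRECTIONAL", "CORRECT"):
            maps = [
                prediction_map(envs[case], NavModelSpec(comb, e), locset.test, locset.training)
                for e in ("TARGET", "RELEASE", "TRAINING")
            ]
            for pm in maps[1:]:
                both = maps[0].defined & pm.defined
                assert np.array_equal(maps[0].defined, pm.defined)
                assert np.max(np.abs(wrap_signed(maps[0].headings[both] - pm.headings[both]))) < 1e-12

    @pytest.mark.parametrize("case", LINEAR)
    def test_correct_recovers_goal_direction_in_linear_envs(self, envs, locset, case):
        pm = prediction_map(envs[case], NavModelSpec("CORRECT", "TARGET"), locset.test, locset.training)
        true = goal_direction(locset.test)
        ok = pm.defined
        assert np.max(abs_diff(pm.headings[ok], true[ok])) < 1e-9

    def test_directional_invariant_to_field_rescaling(self, locset):
        base = identity_env("B2ii")
        scaled = Environment(
            field_A=GradientSpec("A", 0.0, 7.0),
            field_B=GradientSpec("B2ii", 0.0, 3.0),
            label="B2ii-scaled",
        )
        pts = locset.test[::37]
        m1 = prediction_map(base, NavModelSpec("DIRECTIONAL", "RELEASE"), pts)
        m2 = prediction_map(scaled, NavModelSpec("DIRECTIONAL", "RELEASE"), pts)
        both = m1.defined & m2.defined
        assert np.max(np.abs(wrap_signed(m1.headings[both] - m2.headings[both]))) < 1e-12

    def test_signed_error_symmetric_under_point_reflection_in_b2i(self, envs, locset):
        # negating the location negates all field offsets, hence all
        # displacement estimates: heading and true direction both rotate by
        # pi, so the signed error is preserved (two-fold rotational symmetry)
        pm = prediction_map(envs["B2i"], NavModelSpec("APPROX", "TARGET"), locset.test, locset.training)
        n = 101
        errs = pm.signed_errors.reshape(n, n)
        flipped = errs[::-1, ::-1]  # point reflection through the goal
        both = ~np.isnan(errs) & ~np.isnan(flipped)
        assert np.max(np.abs(errs[both] - flipped[both])) < 1e-9
        # the map carries genuinely signed structure: both senses occur
        assert np.nanmin(errs) < -0.1 and np.nanmax(errs) > 0.1

    def test_model_heading_matches_map(self, envs, locset):
        env = envs["B3ii"]
        p = np.array([2.3, -1.1])
        for spec in all_model_specs():
            h = model_heading(env, spec, p, locset.training)
            pm = prediction_map(env, spec, p[None, :], locset.training)
            assert abs_diff(h, pm.headings[0]) < 1e-9


def brute_force_correct_heading(env, p, n_candidates=3600):
    """Independent oracle: search candidate headings for the displacement
    direction whose back-projection best reproduces both sensed offsets."""
    deltas = env.field_values(p) - env.field_values(env.goal)
    ga = env.field_A.gradient(p)  # linear envs: gradient constant anyway
    gb = env.field_B.gradient(p)
    G = np.stack([ga, gb])
    best, best_res = None, np.inf
    for theta in np.arange(n_candidates) * (2 * np.pi / n_candidates):
        d_hat = -unit_vector(theta)  # displacement from goal opposite the heading
        proj = G @ d_hat
        denom = float(proj @ proj)
        if denom < 1e-15:
            continue
        r = float(proj @ deltas) / denom
        if r < 0:
            continue
        res = float(np.sum((r * proj - deltas) ** 2))
        if res < best_res:
            best, best_res = theta, res
    return best


@pytest.mark.parametrize("case", LINEAR)
def test_brute_force_oracle_matches_correct_model(envs, case, rng):
    env = envs[case]
    step = 2 * np.pi / 3600
    for p in rng.uniform(-4.5, 4.5, size=(5, 2)):
        if np.hypot(*p) < 0.5:
            continue
        expected = brute_force_correct_heading(env, p)
        got = model_heading(env, NavModelSpec("CORRECT", "RELEASE"), p)
        assert abs_diff(got, expected) <= step
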