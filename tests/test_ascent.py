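import numpy as np
import pytest

from gpascent import (
    ConfigurationError,
    ConvergenceSignal,
    Factor,
    FirstOrderFit,
    build_path,
    choose_basis,
    coded_step_sizes,
    evaluate_path,
    natural_increments,
    path_coordinates,
    run_ascent,
)
from gpascent.surface import yield_surface

# printed first-order fits for the two responses of the study: the
# SVM-minus-BLUP difference and the BLUP accuracy itself
DIFF_FIT = FirstOrderFit(
    -0.130, {"ind": 0.019, "m": -0.004, "qtl": -0.003, "epi": 0.043, "h": 0.020}, 0.0
)
BLUP_FIT = FirstOrderFit(
    0.462, {"ind": 0.039, "m": -0.005, "qtl": 0.025, "epi": -0.285, "h": 0.144}, 0.0
)


class TestChooseBasis:
    def test_largest_absolute_slope_wins(self):
        assert choose_basis(DIFF_FIT) == "epi"
        assert choose_basis(BLUP_FIT) == "epi"

    def test_single_factor_fit(self):
        assert choose_basis(FirstOrderFit(0.0, {"x": -0.5}, 0.0)) == "x"

    def test_all_zero_slopes_signal_convergence(self):
        with pytest.raises(ConvergenceSignal):
            choose_basis(FirstOrderFit(1.0, {"x": 0.0, "y": 0.0}, 0.0))

    def test_override(self):
        assert choose_basis(DIFF_FIT, override="h") == "h"


class TestCodedSteps:
    def test_ascent_steps_follow_coefficient_ratios(self, study_factors):
        steps = coded_step_sizes(DIFF_FIT, "epi", 0.25, study_factors, ndigits=2)
        assert steps == {"ind": 0.74, "m": -0.16, "qtl": -0.12, "epi": 1.67, "h": 0.78}

    def test_descent_side_steps_with_negative_basis_coefficient(self, study_factors):
        # maximizing a response whose basis coefficient is negative: the
        # basis step carries the coefficient's sign
        steps = coded_step_sizes(BLUP_FIT, "epi", 0.25, study_factors, ndigits=3)
        assert steps == {"ind": 0.228, "m": -0.029, "qtl": 0.146, "epi": -1.667, "h": 0.842}

    def test_zero_coefficient_gives_zero_step(self, study_factors):
        fit = FirstOrderFit(0.0, {"ind": 0.0, "m": 0.0, "qtl": 0.0, "epi": 0.05, "h": 0.0}, 0.0)
        steps = coded_step_sizes(fit, "epi", 0.25, study_factors)
        assert steps["ind"] == steps["m"] == steps["qtl"] == steps["h"] == 0.0

    def test_zero_basis_coefficient_rejected(self, study_factors):
        fit = FirstOrderFit(0.0, {"ind": 0.1, "epi": 0.0}, 0.0)
        with pytest.raises(ConfigurationError):
            coded_step_sizes(fit, "epi", 0.25, study_factors)

    def test_step_ratios_equal_coefficient_ratios_before_rounding(self, study_factors):
        steps = coded_step_sizes(DIFF_FIT, "epi", 0.25, study_factors)
        for name, b in DIFF_FIT.slopes.items():
            assert steps[name] / steps["epi"] == pytest.approx(b / 0.043, rel=1e-12)


class TestNaturalIncrements:
    def test_increments_are_half_range_times_coded_step(self, study_factors):
        steps = {"ind": 0.74, "m": -0.16, "qtl": 0.0}
        deltas = natural_increments(steps, study_factors)
        assert deltas["ind"] == pytest.approx(400 * 0.74)  # 296
        assert deltas["m"] == pytest.approx(150 * -0.16)  # -24
        assert deltas["qtl"] == 0.0

    def test_compat_rounding_keeps_integers_and_two_sig_figs_otherwise(self, study_factors):
        deltas = natural_increments(
            {"ind": 0.228, "m": -0.029, "qtl": 0.146, "h": 0.842}, study_factors, compat=True
        )
        assert deltas == {"ind": 91.0, "m": -4.4, "qtl": 6.6, "h": 0.13}


class TestPathCoordinates:
    def test_coordinates_accumulate_round_and_clamp(self, study_factors):
        deltas = {"ind": 296.0, "m": -24.0, "qtl": -5.4, "epi": 0.25, "h": 0.12}
        coords = path_coordinates(study_factors, deltas, k_max=9)
        assert coords[2] == {"ind": 1488, "m": 178, "qtl": 39, "epi": 1.0, "h": 0.71}
        # epistasis hits its operability ceiling from the third step onward
        assert all(c["epi"] == 1.0 for c in coords[2:])
        assert coords[8] == {"ind": 3264, "m": 34, "qtl": 6, "epi": 1.0, "h": 1.0}

    def test_descent_path_first_coordinate(self, study_factors):
        deltas = {"ind": 91.0, "m": -4.4, "qtl": 6.6, "epi": -0.25, "h": 0.13}
        coords = path_coordinates(study_factors, deltas, k_max=2)
        assert coords[0] == {"ind": 691, "m": 246, "qtl": 62, "epi": 0.10, "h": 0.48}
        assert coords[1]["epi"] == 0.0  # clamped at the floor

    def test_scale_equivariance_of_the_coded_path(self):
        # rescaling a factor's natural units scales its increments but not
        # the visited coded points
        fit = FirstOrderFit(0.0, {"x": 0.4, "y": 0.2}, 0.0)
        f1 = {"x": Factor("x", 0.0, 1.0), "y": Factor("y", 0.0, 1.0)}
        f10 = {"x": Factor("x", 0.0, 10.0), "y": Factor("y", 0.0, 1.0)}
        p1 = build_path(fit, f1, basis_step_natural=0.1, k_max=4)
        p10 = build_path(fit, f10, basis_step_natural=1.0, k_max=4)
        assert p10.coded_steps == pytest.approx(p1.coded_steps)
        for c1, c10 in zip(p1.coordinates, p10.coordinates):
            assert c10["x"] == pytest.approx(10 * c1["x"], abs=0.02)
            assert c10["y"] == pytest.approx(c1["y"], abs=1e-9)

    def test_descent_equals_ascent_on_negated_response(self, study_factors):
        down = coded_step_sizes(DIFF_FIT, "epi", 0.25, study_factors, direction="descent")
        neg = FirstOrderFit(0.0, {k: -v for k, v in DIFF_FIT.slopes.items()}, 0.0)
        up = coded_step_sizes(neg, "epi", 0.25, study_factors, direction="ascent")
        assert down == pytest.approx(up)


class TestEvaluatePath:
    def test_constant_response_is_flat(self, study_factors):
        path = build_path(DIFF_FIT, study_factors, 0.25, k_max=3)
        evaluate_path(path, lambda pt: 1.0)
        assert path.responses == [1.0, 1.0, 1.0]

    def test_failures_become_nan_without_aborting(self, study_factors):
        path = build_path(DIFF_FIT, study_factors, 0.25, k_max=3)

        def sometimes_fails(pt):
            if pt["ind"] > 1000:
                raise RuntimeError("boom")
            return 0.5

        evaluate_path(path, sometimes_fails)
        assert path.responses[0] == 0.5
        assert np.isnan(path.responses[1]) and np.isnan(path.responses[2])

    def test_quadratic_toy_has_interior_maximum_along_path(self, study_factors):
        # a concave response peaking mid-path must rise then fall
        path = build_path(DIFF_FIT, study_factors, 0.25, k_max=9)
        evaluate_path(path, lambda pt: -((pt["ind"] - 1800) / 1000) ** 2)
        r = np.array(path.responses)
        k = int(np.argmax(r))
        assert 0 < k < len(r) - 1
        assert np.all(np.diff(r[: k + 1]) > 0) and np.all(np.diff(r[k:]) < 0)

    def test_path_table_mirrors_base_increment_and_steps(self, study_factors):
        path = build_path(DIFF_FIT, study_factors, 0.25, k_max=2, compat=True,
                          coded_step_decimals=2)
        table = path.path_table()
        assert list(table.index) == ["Base", "Delta", "Base+1D", "Base+2D"]
        assert table.loc["Base", "ind"] == 600
        assert table.loc["Delta", "ind"] == 296


class TestRunAscent:
    def test_quadratic_surface_optimum_found(self):
        factors = {
            "x": Factor("x", -1.0, 0.0, operability_min=-5, operability_max=5),
            "y": Factor("y", -1.0, 0.0, operability_min=-5, operability_max=5),
        }
        truth = lambda pt: -((pt["x"] - 3.0) ** 2) - (pt["y"] + 2.0) ** 2
        res = run_ascent(factors, truth, basis_step=0.5, max_iterations=6, k_max=12)
        assert res.best_response > -0.6
        assert abs(res.best_point["x"] - 3.0) < 0.8
        assert abs(res.best_point["y"] + 2.0) < 0.8

    def test_yield_demo_reaches_printed_optimum_neighborhood(self):
        # starting from the cold/dry corner of the region, the ascent should
        # climb to the temperature band where the yield surface peaks
        factors = {
            "temperature": Factor("temperature", 64.0, 68.0,
                                  operability_min=64.0, operability_max=80.0),
            "drought": Factor("drought", -4.0, -2.0,
                              operability_min=-4.0, operability_max=4.0),
        }
        truth = lambda pt: yield_surface(pt["temperature"], pt["drought"])
        res = run_ascent(factors, truth, basis_step=1.0, max_iterations=6, k_max=12)
        best = yield_surface(73.3, 1.6)
        assert res.best_response > best - 0.1
        assert 71.0 <= res.best_point["temperature"] <= 76.0
        # far fewer evaluations than a dense grid of the region
        assert res.n_evaluations < 120

    def test_flat_response_converges_immediately(self):
        factors = {"x": Factor("x", 0.0, 1.0), "y": Factor("y", 0.0, 1.0)}
        res = run_ascent(factors, lambda pt: 1.0, basis_step=0.1, max_iterations=3)
        assert res.converged
        assert res.best_point == {"x": 0.5, "y": 0.5}
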