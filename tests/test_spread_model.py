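"""The complement-product recurrence, its oracle, and trajectory invariants."""

import numpy as np
import pytest

from eabspread.geo_network import DistanceMatrix, ValidationError
from eabspread.kernels import Kernel, evaluate
from eabspread.spread_model import (
    ProbabilityTrajectory,
    annual_step,
    condition_on_detections,
    forecast,
    simulate,
)

from conftest import enumerate_spread_probability, random_distance_matrix


def matrix_from_distances(d):
    d = np.asarray(d, dtype=float)
    return DistanceMatrix(ids=tuple(f"x{i}" for i in range(len(d))), d=d)


# cauchy with gamma=1: f(3)=0.1, a convenient round number
K01 = Kernel("cauchy", 1.0)


class TestAnnualStep:
    def test_single_source_transfers_kernel_probability(self):
        D = matrix_from_distances([[0, 3], [3, 0]])
        out = annual_step(np.array([1.0, 0.0]), D, K01)
        assert out == pytest.approx([1.0, 0.1])

    def test_three_sources_complement_product(self):
        # three certain sources each at f = 0.1 from the target
        d = np.zeros((4, 4))
        d[:3, 3] = d[3, :3] = 3.0
        d[0, 1] = d[1, 0] = d[0, 2] = d[2, 0] = d[1, 2] = d[2, 1] = 1e-9
        D = matrix_from_distances(d)
        out = annual_step(np.array([1.0, 1.0, 1.0, 0.0]), D, K01)
        assert out[3] == pytest.approx(1 - 0.9**3)

    def test_no_source_stays_empty(self, rng):
        D = random_distance_matrix(rng, 6)
        out = annual_step(np.zeros(6), D, Kernel("cauchy", 10.0))
        assert np.all(out == 0.0)

    def test_certain_source_keeps_itself_certain(self, rng):
        D = random_distance_matrix(rng, 5)
        out = annual_step(np.array([1.0, 0, 0, 0, 0]), D, Kernel("cauchy", 5.0))
        assert out[0] == 1.0

    def test_output_never_below_input(self, rng):
        for _ in range(20):
            D = random_distance_matrix(rng, 10)
            P = rng.uniform(0, 1, 10)
            out = annual_step(P, D, Kernel("cauchy", rng.uniform(1, 50)))
            assert np.all(out >= P - 1e-15)
            assert np.all((0 <= out) & (out <= 1))

    def test_misaligned_vector_rejected(self, rng):
        D = random_distance_matrix(rng, 5)
        with pytest.raises(ValidationError):
            annual_step(np.zeros(4), D, K01)

    def test_log_space_matches_direct_product(self, rng):
        """Accumulating in log space equals the direct complement product."""
        for _ in range(10):
            D = random_distance_matrix(rng, 50)
            P = rng.uniform(0, 0.9, 50)
            k = Kernel("cauchy", rng.uniform(5, 100))
            F = evaluate(k, D.d)
            direct = 1.0 - np.prod(1.0 - P[:, None] * F, axis=0)
            out = annual_step(P, D, k)
            assert out == pytest.approx(direct, rel=1e-12, abs=1e-15)


class TestEnumerationOracle:
    """The deterministic recurrence must equal exact event enumeration."""

    @pytest.mark.parametrize("steps", [1, 2])
    def test_three_node_network(self, rng, steps):
        D = random_distance_matrix(rng, 3)
        k = Kernel("cauchy", 60.0)
        traj = simulate(D, k, "x0", 2003, 2003 + steps)
        expected = enumerate_spread_probability(evaluate(k, D.d), 0, steps)
        assert traj.at_year(2003 + steps) == pytest.approx(expected, abs=1e-12)

    def test_two_node_two_steps_closed_form(self):
        # P2 = 1 - (1-p)^2: the seed gets two independent yearly chances
        D = matrix_from_distances([[0, 3], [3, 0]])
        p = 0.1
        traj = simulate(D, K01, "x0", 2000, 2002)
        assert traj.at_year(2002)[1] == pytest.approx(1 - (1 - p) ** 2, abs=1e-14)


class TestSimulate:
    def test_zero_horizon_is_seed_indicator(self, rng):
        D = random_distance_matrix(rng, 8)
        traj = simulate(D, K01, "x2", 2003, 2003)
        expected = np.zeros(8)
        expected[2] = 1.0
        assert np.array_equal(traj.P[0], expected)

    def test_unknown_seed_rejected(self, rng):
        D = random_distance_matrix(rng, 4)
        with pytest.raises(KeyError):
            simulate(D, K01, "nope", 2003, 2010)

    def test_years_before_start_rejected(self, rng):
        D = random_distance_matrix(rng, 4)
        with pytest.raises(ValidationError):
            simulate(D, K01, "x0", 2010, 2003)

    def test_monotone_in_time(self, rng):
        for _ in range(10):
            D = random_distance_matrix(rng, 15)
            traj = simulate(D, Kernel("cauchy", rng.uniform(5, 80)), "x0", 2003, 2012)
            assert np.all(np.diff(traj.P, axis=0) >= -1e-15)

    def test_permutation_invariance(self, rng):
        D = random_distance_matrix(rng, 12)
        k = Kernel("cauchy", 40.0)
        perm = rng.permutation(12)
        Dp = DistanceMatrix(
            ids=tuple(D.ids[i] for i in perm), d=D.d[np.ix_(perm, perm)]
        )
        t1 = simulate(D, k, "x0", 2003, 2010)
        t2 = simulate(Dp, k, "x0", 2003, 2010)
        for lid in D.ids:
            i, j = D.ids.index(lid), Dp.ids.index(lid)
            assert t1.P[:, i] == pytest.approx(t2.P[:, j], rel=1e-12)

    def test_adding_a_city_never_hurts(self, rng):
        pts = rng.uniform(0, 300, size=(9, 2))
        k = Kernel("cauchy", 30.0)

        def matrix(points):
            d = np.sqrt(((points[:, None] - points[None]) ** 2).sum(-1))
            np.fill_diagonal(d, 0.0)
            return DistanceMatrix(
                ids=tuple(f"x{i}" for i in range(len(points))), d=(d + d.T) / 2
            )

        t_small = simulate(matrix(pts[:8]), k, "x0", 2003, 2010)
        t_big = simulate(matrix(pts), k, "x0", 2003, 2010)
        assert np.all(t_big.P[:, :8] >= t_small.P - 1e-15)

    def test_multiple_seeds(self, rng):
        D = random_distance_matrix(rng, 6)
        traj = simulate(D, K01, ["x1", "x4"], 2003, 2003)
        assert traj.P[0, 1] == 1.0 and traj.P[0, 4] == 1.0


class TestConditioningAndForecast:
    @pytest.fixture
    def traj(self, rng):
        D = random_distance_matrix(rng, 10)
        return D, simulate(D, Kernel("cauchy", 40.0), "x0", 2003, 2017)

    def test_empty_detection_set_is_identity(self, traj):
        _, t = traj
        assert np.array_equal(condition_on_detections(t, [], 2017), t.at_year(2017))

    def test_all_detected_gives_all_ones(self, traj):
        _, t = traj
        assert np.all(condition_on_detections(t, list(t.ids), 2017) == 1.0)

    def test_detected_cities_forced_to_one_others_untouched(self, traj):
        _, t = traj
        vec = condition_on_detections(t, ["x3", "x7"], 2017)
        base = t.at_year(2017)
        assert vec[3] == 1.0 and vec[7] == 1.0
        mask = np.ones(10, bool)
        mask[[3, 7]] = False
        assert np.array_equal(vec[mask], base[mask])

    def test_label_mapping_accepted(self, traj):
        _, t = traj
        vec = condition_on_detections(t, {"x2": 1, "x5": 0}, 2017)
        assert vec[2] == 1.0 and vec[5] == t.at_year(2017)[5]

    def test_unknown_detection_id_rejected(self, traj):
        _, t = traj
        with pytest.raises(ValidationError):
            condition_on_detections(t, ["nope"], 2017)

    def test_year_outside_span_rejected(self, traj):
        _, t = traj
        with pytest.raises(ValidationError):
            condition_on_detections(t, [], 1999)

    def test_forecast_zero_horizon_is_identity(self, traj):
        D, t = traj
        vec = condition_on_detections(t, ["x3"], 2017)
        fc = forecast(vec, D, Kernel("cauchy", 40.0), 2017, 2017)
        assert np.array_equal(fc.at_year(2017), vec)

    def test_all_ones_is_absorbing(self, traj):
        D, _ = traj
        fc = forecast(np.ones(10), D, Kernel("cauchy", 40.0), 2017, 2022)
        assert np.all(fc.P == 1.0)

    def test_forecast_continues_recursion(self, traj):
        D, t = traj
        k = Kernel("cauchy", 40.0)
        fc = forecast(t.at_year(2017), D, k, 2017, 2019)
        full = simulate(D, k, "x0", 2003, 2019)
        assert fc.at_year(2019) == pytest.approx(full.at_year(2019), rel=1e-12)


class TestTrajectoryContainer:
    def test_non_consecutive_years_rejected(self):
        with pytest.raises(ValidationError):
            ProbabilityTrajectory(("a",), (2003, 2005), np.zeros((2, 1)))

    def test_out_of_range_probabilities_rejected(self):
        with pytest.raises(ValidationError):
            ProbabilityTrajectory(("a",), (2003,), np.array([[1.5]]))

    def test_long_frame_round_percent(self, rng):
        D = random_distance_matrix(rng, 4)
        t = simulate(D, Kernel("cauchy", 100.0), "x0", 2003, 2005)
        df = t.to_long_frame()
        assert len(df) == 3 * 4
        assert np.array_equal(
            df["percent"].to_numpy(),
            np.floor(df["probability"].to_numpy() * 100 + 0.5).astype(int),
        )
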