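"""Food diversity, nutritional diversity and redundancy in both families."""

import numpy as np
import pytest

from nutrired.diversity import (
    gini_simpson,
    hill_fd,
    hill_nd,
    hill_nr,
    modified_distance,
    nr_gsi,
    rao_q,
    record_nr,
)


def naive_rao(f, d):
    """Double-loop oracle for Rao's quadratic entropy."""
    total = 0.0
    for i in range(len(f)):
        for j in range(len(f)):
            if i != j:
                total += d[i, j] * f[i] * f[j]
    return total


def _three_food_distance():
    d = np.zeros((3, 3))
    d[0, 1] = d[1, 0] = 0.2
    d[0, 2] = d[2, 0] = 0.4
    d[1, 2] = d[2, 1] = 0.6
    return d


def _random_distance(rng, n):
    d = rng.uniform(0, 1, (n, n))
    d = (d + d.T) / 2
    np.fill_diagonal(d, 0.0)
    return d


class TestGiniSimpson:
    @pytest.mark.parametrize(
        "f,expected",
        [([1.0], 0.0), ([0.5, 0.5], 0.5), ([0.25] * 4, 0.75)],
    )
    def test_hand_cases(self, f, expected):
        assert gini_simpson(np.array(f)) == pytest.approx(expected)

    def test_non_simplex_rejected(self):
        with pytest.raises(ValueError):
            gini_simpson(np.array([0.5, 0.6]))
        with pytest.raises(ValueError):
            gini_simpson(np.array([1.5, -0.5]))


class TestRao:
    def test_zero_distances(self):
        assert rao_q(np.array([0.3, 0.7]), np.zeros((2, 2))) == 0.0

    def test_two_foods(self):
        d = np.array([[0.0, 1.0], [1.0, 0.0]])
        assert rao_q(np.array([0.5, 0.5]), d) == pytest.approx(0.5)

    def test_three_food_case_against_oracle(self):
        f = np.array([0.5, 0.3, 0.2])
        d = _three_food_distance()
        assert rao_q(f, d) == pytest.approx(0.212)
        assert rao_q(f, d) == pytest.approx(naive_rao(f, d), abs=1e-12)

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            rao_q(np.array([0.5, 0.5]), np.zeros((3, 3)))


class TestGsiRedundancy:
    def test_identical_foods_extreme(self):
        # all foods nutritionally identical: ND = 0, NR = FD
        res = nr_gsi(np.array([0.5, 0.5]), np.zeros((2, 2)))
        assert res.nd == 0.0
        assert res.nr == pytest.approx(res.fd) == pytest.approx(0.5)

    def test_unique_foods_extreme(self):
        d = np.array([[0.0, 1.0], [1.0, 0.0]])
        res = nr_gsi(np.array([0.5, 0.5]), d)
        assert res.nr == pytest.approx(0.0)

    def test_three_food_case(self):
        res = nr_gsi(np.array([0.5, 0.3, 0.2]), _three_food_distance())
        assert res.fd == pytest.approx(0.62)
        assert res.nd == pytest.approx(0.212)
        assert res.nr == pytest.approx(0.408)

    def test_nr_decreases_as_distances_grow(self):
        rng = np.random.default_rng(0)
        f = rng.dirichlet(np.ones(10))
        d = _random_distance(rng, 10)
        nrs = [nr_gsi(f, t * d).nr for t in np.linspace(0, 1, 6)]
        assert all(a >= b - 1e-12 for a, b in zip(nrs, nrs[1:]))

    def test_nr_bounded_by_gsi(self):
        rng = np.random.default_rng(1)
        for _ in range(200):
            n = rng.integers(2, 15)
            f = rng.dirichlet(np.ones(n))
            res = nr_gsi(f, _random_distance(rng, n))
            assert -1e-12 <= res.nr <= res.fd + 1e-12


class TestHillFd:
    def test_uniform_profile_gives_richness(self):
        for q in (0.0, 0.5, 1.0, 2.0, 3.0):
            assert hill_fd(np.full(7, 1 / 7), q) == pytest.approx(7.0)

    def test_order_two_and_gsi_link(self):
        f = np.array([0.5, 0.5])
        assert hill_fd(f, 2) == pytest.approx(2.0)
        assert gini_simpson(f) == pytest.approx(1 - 1 / hill_fd(f, 2))

    def test_skewed_profile_order_two(self):
        assert hill_fd(np.array([0.7, 0.3]), 2) == pytest.approx(1 / 0.58)

    def test_gsi_identity_on_random_profiles(self):
        rng = np.random.default_rng(2)
        for _ in range(200):
            f = rng.dirichlet(np.ones(rng.integers(2, 30)))
            assert gini_simpson(f) == pytest.approx(
                1 - 1 / hill_fd(f, 2), abs=1e-12
            )

    def test_non_increasing_in_q(self):
        rng = np.random.default_rng(3)
        qs = [0.0, 0.5, 1.0, 1.5, 2.0, 3.0]
        for _ in range(50):
            f = rng.dirichlet(np.ones(10))
            vals = [hill_fd(f, q) for q in qs]
            assert all(a >= b - 1e-9 for a, b in zip(vals, vals[1:]))

    def test_negative_order_rejected(self):
        with pytest.raises(ValueError):
            hill_fd(np.array([1.0]), -0.5)


class TestModifiedDistance:
    def test_two_food_diagonal(self):
        d = np.array([[0.0, 0.6], [0.6, 0.0]])
        dp = modified_distance(d)
        assert np.diag(dp.values) == pytest.approx([0.6, 0.6])

    def test_constant_distance_diagonal(self):
        c = 0.37
        d = np.full((5, 5), c)
        np.fill_diagonal(d, 0.0)
        assert np.diag(modified_distance(d).values) == pytest.approx([c] * 5)

    def test_row_means(self):
        dp = modified_distance(_three_food_distance())
        assert np.diag(dp.values) == pytest.approx([0.3, 0.4, 0.5])
        # off-diagonals untouched
        assert dp.values[0, 1] == pytest.approx(0.2)

    def test_single_food_degenerate(self):
        dp = modified_distance(np.zeros((1, 1)))
        assert dp.degenerate


class TestHillNdNr:
    def test_fully_distinct_two_foods(self):
        d = np.array([[0.0, 1.0], [1.0, 0.0]])
        dp = modified_distance(d)
        f = np.array([0.5, 0.5])
        assert dp.Q_prime(f) == pytest.approx(1.0)
        assert hill_nd(f, dp, 2) == pytest.approx(2.0)
        assert hill_nr(f, dp, 2).nr == pytest.approx(0.0)

    def test_zero_distances_give_zero_nd(self):
        dp = modified_distance(np.zeros((4, 4)))
        f = np.full(4, 0.25)
        for q in (0.0, 1.0, 2.0):
            assert hill_nd(f, dp, q) == 0.0
            assert hill_nr(f, dp, q).nr == pytest.approx(hill_fd(f, q))

    def test_single_food_record(self):
        dp = modified_distance(np.zeros((1, 1)))
        assert hill_nd(np.array([1.0]), dp, 2) == 0.0

    def test_continuity_at_order_one(self):
        # the closed form at q = 1 is the limit of the q != 1 form: the
        # finite difference shrinks linearly with the offset from q = 1
        rng = np.random.default_rng(4)
        for _ in range(20):
            f = rng.dirichlet(np.ones(20))
            dp = modified_distance(_random_distance(rng, 20))
            nr1 = hill_nr(f, dp, 1.0).nr
            for delta in (1e-3, 1e-4, 1e-5):
                for q in (1.0 - delta, 1.0 + delta):
                    assert abs(hill_nr(f, dp, q).nr - nr1) < 5.0 * delta

    def test_decomposition_identity_both_forms(self):
        rng = np.random.default_rng(5)
        for _ in range(300):
            n = rng.integers(2, 20)
            f = rng.dirichlet(np.ones(n))
            d = _random_distance(rng, n)
            g = nr_gsi(f, d)
            assert g.fd - g.nd == pytest.approx(g.nr, abs=1e-12)
            h = hill_nr(f, modified_distance(d), rng.uniform(0, 3))
            assert h.fd - h.nd == pytest.approx(h.nr, abs=1e-12)


class TestRecordNr:
    def test_single_food_record(self, nested_net, small_records):
        import pandas as pd
        from nutrired.io_units import DietRecordSet

        rec = DietRecordSet(
            pd.DataFrame(
                [("s1", 1, "f1", 50.0)],
                columns=["subject_id", "timepoint", "food_id", "grams"],
            )
        )
        out = record_nr(rec, nested_net, mode="GSI")
        assert out.iloc[0][["FD", "ND", "NR"]].tolist() == [0.0, 0.0, 0.0]

    def test_identical_profiles_identical_results(self, nested_net):
        import pandas as pd
        from nutrired.io_units import DietRecordSet

        rows = [
            ("a", 1, "f1", 30.0), ("a", 1, "f2", 10.0),
            ("b", 1, "f1", 60.0), ("b", 1, "f2", 20.0),  # same profile, scaled
        ]
        rec = DietRecordSet(
            pd.DataFrame(rows, columns=["subject_id", "timepoint", "food_id", "grams"])
        )
        out = record_nr(rec, nested_net, mode="GSI")
        assert out.iloc[0]["NR"] == pytest.approx(out.iloc[1]["NR"], abs=1e-15)

    @pytest.mark.parametrize("mode", ["GSI", 2.0, 1.0])
    def test_composes_from_per_record_calls(self, desk_net, desk_records, mode):
        from nutrired.fnn import jaccard_distance_matrix

        out = record_nr(desk_records, desk_net, mode=mode)
        D = jaccard_distance_matrix(desk_net).values
        keys, _, F = desk_records.to_matrix(food_ids=list(desk_net.foods))
        by_key = out.set_index(["subject_id", "timepoint"])
        for key, f in list(zip(keys, F))[:10]:
            sup = np.where(f > 0)[0]
            fsub = f[sup]
            dsub = D[np.ix_(sup, sup)]
            if mode == "GSI":
                expected = nr_gsi(fsub, dsub).nr
            else:
                expected = hill_nr(fsub, modified_distance(dsub), mode).nr
            assert by_key.loc[key, "NR"] == pytest.approx(expected, abs=1e-12)

    def test_identity_holds_across_cohort(self, desk_net, desk_records):
        out = record_nr(desk_records, desk_net, mode="GSI")
        assert np.allclose(out["FD"] - out["ND"], out["NR"], atol=1e-12)
        assert ((out["NR"] >= -1e-12) & (out["NR"] <= out["FD"] + 1e-12)).all()
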