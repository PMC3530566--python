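import numpy as np
import pytest

from daytrace.predict import (
    entropy_predictability_correlation,
    fit_transition_model,
    long_range_curve,
    static_quality,
    transition_quality,
)

from conftest import make_matrix


def iid_matrix(rng, p=(0.4, 0.3, 0.2, 0.1), n_days=300, n_slots=24):
    labs = np.array(list("ABCD")[: len(p)], dtype=object)
    rows = labs[rng.choice(len(p), size=(n_days, n_slots), p=p)]
    return make_matrix(rows.tolist())


class TestStaticQuality:
    def test_deterministic_user(self):
        dm = make_matrix([["A"] * 12 + ["B"] * 12] * 6)
        for rule in ("matching", "mode"):
            assert static_quality(dm, rule=rule).day_average == pytest.approx(1.0)

    def test_two_locations_half(self):
        dm = make_matrix([["A"] * 24, ["B"] * 24])
        assert static_quality(dm, rule="matching").day_average == pytest.approx(0.5)
        assert static_quality(dm, rule="mode").day_average == pytest.approx(0.5)

    def test_unknown_rule(self, two_pattern_matrix):
        with pytest.raises(ValueError):
            static_quality(two_pattern_matrix, rule="bogus")

    def test_matching_equals_mc_guess_oracle(self, rng):
        p = np.array([0.5, 0.3, 0.2])
        dm = iid_matrix(rng, p=tuple(p), n_days=400)
        analytic = float((p**2).sum())
        # Monte-Carlo oracle: guess by sampling the *true* p, check success
        n_mc = 100_000
        guesses = rng.choice(3, size=n_mc, p=p)
        truths = rng.choice(3, size=n_mc, p=p)
        mc = float((guesses == truths).mean())
        est = static_quality(dm, rule="matching").day_average
        sigma_mc = np.sqrt(analytic * (1 - analytic) / n_mc)
        assert abs(mc - analytic) < 3 * sigma_mc + 1e-3
        assert est == pytest.approx(analytic, abs=0.02)

    def test_jensen_with_patterns_dominates(self, rng):
        # exact inequality on any complete-data fixture and any partition
        for trial in range(5):
            dm = iid_matrix(rng, n_days=30)
            labels = rng.integers(0, 3, size=30)
            q_with = static_quality(dm, labels, "matching").day_average
            q_without = static_quality(dm, None, "matching").day_average
            assert q_with >= q_without - 1e-12

    def test_mode_dominates_matching(self, rng):
        dm = iid_matrix(rng, n_days=50)
        q_mode = static_quality(dm, rule="mode").per_slot
        q_match = static_quality(dm, rule="matching").per_slot
        assert (q_mode >= q_match - 1e-12).all()

    def test_quality_bounds(self, rng):
        dm = iid_matrix(rng, n_days=40)
        q = static_quality(dm, rule="matching")
        assert 0.0 <= q.day_average <= 1.0
        assert q.day_average >= 1.0 / 4  # matching >= 1/|alphabet|


class TestTransitionModel:
    def test_deterministic_cycle_unit_rows(self):
        day = [f"L{j % 4}" for j in range(24)]
        dm = make_matrix([day] * 10)
        model = fit_transition_model(dm, 1)
        for j in range(24):
            row = model.row(j, model.alphabet.index(day[j]))
            assert row is not None
            assert row.max() == pytest.approx(1.0)

    def test_hand_counts_toy(self):
        # 3 days, 2 slots; transitions within days: A->A, A->B, B->A
        # plus midnight pairs day1->day2: A->A, day2->day3: B->B
        rows = [["A", "A"], ["A", "B"], ["B", "A"]]
        dm = make_matrix(rows)
        model = fit_transition_model(dm, 1)
        ia = model.alphabet.index("A")
        ib = model.alphabet.index("B")
        # slot 0 -> slot 1 counts: A->A 1, A->B 1, B->A 1
        assert model.counts[0, ia, ia] == 1
        assert model.counts[0, ia, ib] == 1
        assert model.counts[0, ib, ia] == 1
        # slot 1 -> next-day slot 0 counts: A->A 1, B->B 1
        assert model.counts[1, ia, ia] == 1
        assert model.counts[1, ib, ib] == 1

    def test_row_sums_one_where_defined(self, rng):
        dm = iid_matrix(rng, n_days=20)
        model = fit_transition_model(dm, 2)
        for j in range(24):
            for a in range(len(model.alphabet)):
                row = model.row(j, a)
                if row is not None:
                    assert row.sum() == pytest.approx(1.0)

    def test_bad_lag(self, two_pattern_matrix):
        with pytest.raises(ValueError):
            fit_transition_model(two_pattern_matrix, 0)


class TestTransitionQuality:
    def test_deterministic_cycle_q1_all_lags(self):
        day = [f"L{j % 4}" for j in range(24)]
        dm = make_matrix([day] * 8)
        for lag in (1, 3, 6):
            model = fit_transition_model(dm, lag)
            rep = transition_quality(model, dm, "mode")
            assert rep.overall == pytest.approx(1.0)

    def test_iid_identity_with_static(self, rng):
        p = (0.5, 0.3, 0.2)
        dm = iid_matrix(rng, p=p, n_days=400)
        stat = static_quality(dm, rule="matching").day_average
        model = fit_transition_model(dm, 1)
        trans = transition_quality(model, dm, "matching").overall
        analytic = sum(q**2 for q in p)
        assert trans == pytest.approx(analytic, abs=0.03)
        assert trans == pytest.approx(stat, abs=0.03)

    def test_disjoint_patterns_reach_q1_noiseless(self):
        # nowhere-overlapping constant templates: transitions deterministic
        rows = [["A"] * 24, ["B"] * 24] * 8
        dm = make_matrix(rows)
        model = fit_transition_model(dm, 1)
        assert transition_quality(model, dm, "mode").overall == pytest.approx(1.0)

    def test_patterns_never_hurt_at_lag1(self, two_pattern_matrix):
        labels = np.array([0, 1] * 5)
        q_with = transition_quality(
            fit_transition_model(two_pattern_matrix, 1, labels),
            two_pattern_matrix,
            "matching",
        ).overall
        q_without = transition_quality(
            fit_transition_model(two_pattern_matrix, 1),
            two_pattern_matrix,
            "matching",
        ).overall
        assert q_with >= q_without - 1e-9


class TestLongRange:
    def test_deterministic_flat_at_one(self):
        day = [f"L{j % 3}" for j in range(24)]
        dm = make_matrix([day] * 8)
        curve = long_range_curve(dm, max_lag=6, rule="mode")
        assert np.allclose(curve.quality, 1.0)
        assert curve.fit_slope == pytest.approx(0.0, abs=1e-9)
        assert curve.stays_above_static

    def test_iid_flat_at_sum_p_squared(self, rng):
        p = (0.6, 0.4)
        dm = iid_matrix(rng, p=p, n_days=400)
        curve = long_range_curve(dm, max_lag=6, rule="matching")
        analytic = sum(q**2 for q in p)
        assert np.allclose(curve.quality, analytic, atol=0.03)
        assert abs(curve.fit_slope) < 0.02

    def test_markov_quality_nonincreasing(self, rng):
        # sticky 2-state chain: predictability decays with the lag
        m = np.array([[0.9, 0.1], [0.1, 0.9]])
        labs = np.array(["A", "B"], dtype=object)
        state = 0
        rows = []
        for _ in range(200):
            row = []
            for _ in range(24):
                row.append(labs[state])
                state = rng.choice(2, p=m[state])
            rows.append(row)
        dm = make_matrix(rows)
        curve = long_range_curve(dm, max_lag=8, rule="matching")
        diffs = np.diff(curve.quality)
        assert (diffs < 0.02).all()  # non-increasing within MC tolerance


class TestCorrelation:
    def test_perfect_antimonotone(self):
        rho, _ = entropy_predictability_correlation([1.0, 2.0, 3.0], [0.9, 0.5, 0.1])
        assert rho == pytest.approx(-1.0)

    def test_degenerate_flagged(self):
        with pytest.raises(ValueError):
            entropy_predictability_correlation([1.0, 1.0, 1.0], [0.1, 0.2, 0.3])

    def test_too_few_users(self):
        with pytest.raises(ValueError):
            entropy_predictability_correlation([1.0, 2.0], [0.2, 0.1])
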