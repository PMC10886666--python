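"""Survival matrix construction, Cox partial-likelihood loss, concordance."""

import math

import numpy as np
import pytest

from wsimil.bags import InstanceBag
from wsimil.misl import (
    STATUS_EVENT,
    STATUS_LEFT_CENSORED,
    STATUS_RIGHT_CENSORED,
    MISLRiskRegressor,
    build_survival_matrix,
    concordance_index,
    cox_loss,
    matrix_to_training_samples,
    train_misl,
)


def _row_oracle(t: float, e: int, col_times: np.ndarray) -> list[int]:
    """Handwritten row-filling rule: before the observed time the patient is
    under observation; from it onward the terminal status repeats."""
    row = []
    for ct in col_times:
        if ct < t:
            row.append(STATUS_LEFT_CENSORED)
        else:
            row.append(STATUS_EVENT if e else STATUS_RIGHT_CENSORED)
    return row


class TestSurvivalMatrix:
    def test_dimensions(self):
        m = build_survival_matrix([30, 60, 90], [1, 0, 1], tstep=30)
        assert m.statuses.shape == (3, 3)
        assert m.tmax == 90
        np.testing.assert_array_equal(m.timesteps, [30, 60, 90])

    def test_rows_match_oracle_for_every_time_and_status(self):
        # every observed day in (0, 90], both statuses, against the oracle
        times = list(range(1, 91))
        for e in (0, 1):
            m = build_survival_matrix(times + [90], [e] * 90 + [0], tstep=30)
            col_times = m.timesteps
            for i, t in enumerate(times):
                assert list(m.statuses[i]) == _row_oracle(t, e, col_times), t

    def test_single_transition_per_row(self):
        rng = np.random.default_rng(3)
        times = rng.integers(1, 1827, size=40)
        events = rng.integers(0, 2, size=40)
        m = build_survival_matrix(times, events)
        assert m.statuses.shape[1] == math.ceil(times.max() / 30)
        for row in m.statuses:
            changes = np.count_nonzero(np.diff(row))
            assert changes <= 1

    def test_longest_follow_up_censored_row(self):
        m = build_survival_matrix([50, 90], [1, 0], tstep=30)
        assert m.statuses[1, -1] == STATUS_RIGHT_CENSORED
        assert list(m.statuses[1, :2]) == [STATUS_LEFT_CENSORED] * 2

    def test_nonpositive_time_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            build_survival_matrix([0, 5], [1, 1])


class TestTrainingSamples:
    def test_one_replicate_per_cell(self):
        rng = np.random.default_rng(0)
        times = rng.integers(1, 1827, size=10)
        m = build_survival_matrix(times, rng.integers(0, 2, size=10))
        reps = matrix_to_training_samples(m)
        assert len(reps) == 10 * m.statuses.shape[1]
        # every patient contributes the same number of replicates
        assert reps.groupby("patient_id").size().nunique() == 1

    def test_tstep_equal_tmax_degenerates_to_one_column(self):
        m = build_survival_matrix([10, 40], [1, 0], tstep=40)
        reps = matrix_to_training_samples(m)
        assert m.statuses.shape[1] == 1
        assert len(reps) == 2

    def test_misaligned_bags_rejected(self):
        m = build_survival_matrix([10, 40], [1, 0], patient_ids=["a", "b"])
        bags = [InstanceBag("b", np.zeros((1, 2))), InstanceBag("a", np.zeros((1, 2)))]
        with pytest.raises(RuntimeError, match="different patients"):
            matrix_to_training_samples(m, bags)


def _naive_breslow(risks, times, events):
    """Independent O(n^2) double-loop negative partial log-likelihood."""
    total = 0.0
    for i in range(len(risks)):
        if events[i] != 1:
            continue
        denom = 0.0
        for j in range(len(risks)):
            if times[j] >= times[i]:
                denom += math.exp(risks[j])
        total -= risks[i] - math.log(denom)
    return total


class TestCoxLoss:
    def test_two_patient_equal_risk_closed_form(self):
        assert cox_loss([0.7, 0.7], [1, 2], [1, 0]) == pytest.approx(math.log(2))

    def test_all_events_equal_risks_is_log_factorial(self):
        n = 7
        loss = cox_loss(np.zeros(n), np.arange(1, n + 1), np.ones(n))
        assert loss == pytest.approx(math.log(math.factorial(n)))

    def test_shift_invariance(self):
        rng = np.random.default_rng(1)
        r = rng.normal(size=12)
        t = rng.integers(1, 100, size=12)
        e = rng.integers(0, 2, size=12)
        e[0] = 1
        assert cox_loss(r + 5.0, t, e) == pytest.approx(cox_loss(r, t, e), abs=1e-8)

    def test_matches_naive_double_loop_on_random_cohorts(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            n = rng.integers(2, 50)
            r = rng.normal(size=n)
            t = rng.integers(1, 20, size=n).astype(float)  # heavy ties
            e = rng.integers(0, 2, size=n)
            if e.sum() == 0:
                e[rng.integers(n)] = 1
            assert cox_loss(r, t, e) == pytest.approx(
                _naive_breslow(r, t, e), abs=1e-6)

    def test_no_events_rejected(self):
        with pytest.raises(ValueError, match="at least one event"):
            cox_loss([0.1, 0.2], [1, 2], [0, 0])


def _naive_c_index(risks, times, events):
    """Brute-force enumeration over all comparable pairs."""
    num = den = 0.0
    n = len(risks)
    for i in range(n):
        for j in range(n):
            if i == j or events[i] != 1:
                continue
            if times[i] < times[j] or (times[i] == times[j] and events[j] == 0):
                den += 1
                if risks[i] > risks[j]:
                    num += 1
                elif risks[i] == risks[j]:
                    num += 0.5
    if den == 0:
        return float("nan")
    return num / den


class TestConcordance:
    def test_perfectly_anti_ordered_risks_score_one(self):
        t = np.array([5, 4, 3, 2, 1])
        assert concordance_index([1, 2, 3, 4, 5], t, np.ones(5)) == 1.0

    def test_negation_flips_concordance(self):
        rng = np.random.default_rng(5)
        r = rng.normal(size=30)
        t = rng.exponential(10, size=30)
        e = rng.integers(0, 2, size=30)
        e[0] = 1
        c = concordance_index(r, t, e)
        assert concordance_index(-r, t, e) == pytest.approx(1.0 - c)

    def test_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            n = rng.integers(3, 50)
            r = np.round(rng.normal(size=n), 1)  # risk ties
            t = rng.integers(1, 15, size=n).astype(float)  # time ties
            e = rng.integers(0, 2, size=n)
            if e.sum() == 0:
                e[rng.integers(n)] = 1
            expected = _naive_c_index(r, t, e)
            got = concordance_index(r, t, e)
            if math.isnan(expected):
                assert math.isnan(got)
            else:
                assert got == pytest.approx(expected, abs=1e-6)

    def test_undefined_without_comparable_pairs(self):
        with pytest.warns(UserWarning):
            assert math.isnan(concordance_index([1, 2], [5, 5], [0, 0]))


def _toy_bags(n=24, seed=0):
    rng = np.random.default_rng(seed)
    bags = []
    for i in range(n):
        risk = rng.normal()
        t = float(max(1, rng.exponential(300 * np.exp(-risk))))
        x = rng.normal(size=(6, 8)) + risk * np.r_[np.ones(4), np.zeros(4)]
        bags.append(InstanceBag(f"P{i}", x, ["C1", "C2", "C3"] * 2,
                                time_days=min(t, 900.0),
                                event=int(t < 900)))
    return bags


class TestMislTraining:
    def test_same_seed_reproduces_risks_exactly(self):
        bags = _toy_bags()
        kwargs = dict(max_epochs=6, patience=6, batch_cells=256)
        df1, _ = train_misl(bags, k=3, seed=3, **kwargs)
        df2, _ = train_misl(bags, k=3, seed=3, **kwargs)
        np.testing.assert_array_equal(df1["risk"], df2["risk"])
        assert set(df1["patient_id"]) == {b.patient_id for b in bags}
        assert df1["patient_id"].is_unique

    def test_missing_survival_rejected(self):
        bag = InstanceBag("P0", np.zeros((2, 4)), ["C1", "C2"])
        with pytest.raises(ValueError, match="survival"):
            MISLRiskRegressor(max_epochs=1).fit([bag])

    def test_risk_is_scalar_per_patient_and_centered_scale(self):
        bags = _toy_bags()
        model = MISLRiskRegressor(max_epochs=5, patience=5, batch_cells=256,
                                  val_fraction=0.0)
        model.fit(bags)
        risks = model.predict(bags)
        assert risks.shape == (len(bags),)
        # centering: training-cohort risks average near zero
        assert abs(np.mean(risks)) < 1.0
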