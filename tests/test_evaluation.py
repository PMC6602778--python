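import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as spstats
from statsmodels.stats.proportion import proportion_confint

from gutsound import (ContingencyTable, bootstrap_eval, diagnostic_metrics,
                      fisher_exact, kfold_battery, kfold_cv, loocv)
from gutsound.errors import DegenerateLabelsError, InvalidParameterError
from gutsound.evaluation import (DEFAULT_BOOTSTRAP_REPS,
                                 table_from_predictions, wilson_interval)


def _separated_cohort(n_pos=12, n_neg=14, seed=5):
    rng = np.random.default_rng(seed)
    y = np.concatenate([np.ones(n_pos, bool), np.zeros(n_neg, bool)])
    X = rng.normal(size=(len(y), 3))
    X[:, 0] += np.where(y, 3.0, -3.0)
    return X, y, ["a", "b", "c"]


class TestDiagnosticMetrics:
    def test_loocv_table_reproduces_reference_metrics(self):
        m = diagnostic_metrics(ContingencyTable(tp=28, fn=3, fp=3, tn=34))
        assert round(100 * m.sensitivity) == 90
        assert round(100 * m.specificity) == 92
        assert round(100 * m.accuracy) == 91
        assert round(m.lr_neg, 2) == 0.11

    def test_independent_table_reproduces_reference_metrics(self):
        m = diagnostic_metrics(ContingencyTable(tp=13, fn=2, fp=2, tn=13))
        assert round(100 * m.sensitivity) == 87
        assert round(100 * m.specificity) == 87

    def test_perfect_table(self):
        m = diagnostic_metrics(ContingencyTable(10, 0, 0, 10))
        assert (m.sensitivity, m.specificity, m.ppv, m.npv, m.accuracy) == \
            (1.0, 1.0, 1.0, 1.0, 1.0)
        assert m.lr_neg == 0.0
        assert math.isinf(m.lr_pos)
        assert m.ci["lr_pos"] is None

    def test_empty_class_rejected(self):
        with pytest.raises(InvalidParameterError):
            diagnostic_metrics(ContingencyTable(0, 0, 3, 4))

    def test_negative_count_rejected(self):
        with pytest.raises(InvalidParameterError):
            ContingencyTable(-1, 2, 3, 4)

    def test_wilson_matches_statsmodels(self):
        for k, n in [(28, 31), (34, 37), (13, 15), (1, 10), (0, 5), (5, 5)]:
            lo, hi = wilson_interval(k, n)
            slo, shi = proportion_confint(k, n, method="wilson")
            assert lo == pytest.approx(slo, abs=1e-10)
            assert hi == pytest.approx(shi, abs=1e-10)

    @pytest.mark.parametrize("tp,fn,fp,tn", [
        (28, 3, 3, 34), (13, 2, 2, 13), (7, 5, 3, 11), (1, 1, 1, 1)])
    def test_lr_identities(self, tp, fn, fp, tn):
        m = diagnostic_metrics(ContingencyTable(tp, fn, fp, tn))
        assert m.lr_pos * (1 - m.specificity) == pytest.approx(
            m.sensitivity, abs=1e-12)
        assert m.lr_neg * m.specificity == pytest.approx(
            1 - m.sensitivity, abs=1e-12)

    def test_sensitivity_monotone_in_correct_positives(self):
        base = diagnostic_metrics(ContingencyTable(10, 5, 2, 8)).sensitivity
        more = diagnostic_metrics(ContingencyTable(11, 5, 2, 8)).sensitivity
        assert more >= base

    def test_counts_sum_invariant(self):
        t = ContingencyTable(3, 4, 5, 6)
        assert t.n == 18
        assert t.n_positive == 7 and t.n_negative == 11


class TestLoocv:
    def test_separable_cohort_perfect_accuracy(self):
        X, y, names = _separated_cohort()
        table, idx = loocv(X, y, names)
        assert table.tp + table.tn == len(y)
        assert np.all((idx >= 0.5) == y)

    def test_equals_kfold_with_k_n(self):
        X, y, names = _separated_cohort(8, 9)
        t1, idx1 = loocv(X, y, names)
        t2, idx2 = kfold_cv(X, y, names, k=len(y), stratified=False, seed=3)
        np.testing.assert_allclose(idx1, idx2)
        assert (t1.tp, t1.fn, t1.fp, t1.tn) == (t2.tp, t2.fn, t2.fp, t2.tn)

    def test_table_counts_sum_to_n(self):
        X, y, names = _separated_cohort(7, 9)
        table, _ = loocv(X, y, names)
        assert table.n == len(y)
        assert table.n_positive == 7

    def test_permutation_null_oracle(self):
        rng = np.random.default_rng(17)
        n = 24
        X = rng.normal(size=(n, 3))
        accs = []
        for _ in range(100):
            y = np.zeros(n, bool)
            y[rng.choice(n, n // 2, replace=False)] = True
            table, _ = loocv(X, y, ["a", "b", "c"])
            accs.append((table.tp + table.tn) / n)
        accs = np.array(accs)
        assert abs(accs.mean() - 0.5) <= 3 * accs.std()

    def test_too_small_rejected(self):
        with pytest.raises(InvalidParameterError):
            loocv(np.zeros((2, 1)), np.array([True, False]), ["a"])

    def test_single_class_rejected(self):
        with pytest.raises(DegenerateLabelsError):
            loocv(np.zeros((5, 1)), np.ones(5, bool), ["a"])


class TestKfold:
    def test_partition_properties(self):
        from gutsound.evaluation import _kfold_indices
        y = np.arange(68) < 31
        for k in (2, 5, 10):
            for strat in (True, False):
                folds = _kfold_indices(68, k, y, strat, seed=1)
                sizes = [len(f) for f in folds]
                assert max(sizes) - min(sizes) <= 1
                assert sorted(np.concatenate(folds)) == list(range(68))

    def test_stratified_fold_class_shares(self):
        from gutsound.evaluation import _kfold_indices
        y = np.arange(68) < 31
        folds = _kfold_indices(68, 5, y, stratified=True, seed=2)
        for f in folds:
            n_ibs = int(np.sum(y[f]))
            expected = len(f) * 31 / 68
            assert abs(n_ibs - expected) <= 1.0

    def test_k_out_of_range_rejected(self):
        X, y, names = _separated_cohort(4, 4)
        with pytest.raises(InvalidParameterError):
            kfold_cv(X, y, names, k=1)
        with pytest.raises(InvalidParameterError):
            kfold_cv(X, y, names, k=9)

    def test_deterministic_given_seed(self):
        X, y, names = _separated_cohort(10, 10)
        t1, i1 = kfold_cv(X, y, names, 5, True, seed=4)
        t2, i2 = kfold_cv(X, y, names, 5, True, seed=4)
        np.testing.assert_array_equal(i1, i2)

    def test_battery_has_seven_schemes(self):
        X, y, names = _separated_cohort(10, 10)
        battery = kfold_battery(X, y, names, seed=0)
        assert len(battery) == 7
        assert "loocv" in battery


class TestBootstrap:
    def test_default_repetitions_is_300(self):
        assert DEFAULT_BOOTSTRAP_REPS == 300

    def test_deterministic_given_seed(self):
        X, y, names = _separated_cohort(8, 8)
        r1 = bootstrap_eval(X, y, names, B=20, seed=9)
        r2 = bootstrap_eval(X, y, names, B=20, seed=9)
        np.testing.assert_array_equal(r1.rep_accuracy, r2.rep_accuracy)
        assert r1.n_reps == 20

    def test_consistent_with_loocv_on_separated_cohort(self):
        X, y, names = _separated_cohort(12, 12, seed=8)
        table, _ = loocv(X, y, names)
        m = diagnostic_metrics(table)
        boot = bootstrap_eval(X, y, names, B=60, seed=1)
        lo, hi = m.ci["accuracy"]
        assert lo <= boot.metrics.accuracy <= hi

    def test_invalid_b_rejected(self):
        X, y, names = _separated_cohort(4, 4)
        with pytest.raises(InvalidParameterError):
            bootstrap_eval(X, y, names, B=0)


class TestFisherExact:
    def test_balanced_table(self):
        assert fisher_exact(((1, 1), (1, 1))) == pytest.approx(1.0)

    def test_diagonal_table_closed_form(self):
        # P = 2 / C(10, 5): only the two extreme tables qualify
        assert fisher_exact(((5, 0), (0, 5))) == pytest.approx(
            2 / math.comb(10, 5))

    def test_matches_scipy_and_brute_force(self, rng):
        for _ in range(25):
            a, b, c, d = rng.integers(0, 8, size=4)
            if (a + b) == 0 or (c + d) == 0 or (a + c) == 0 or (b + d) == 0:
                continue
            ours = fisher_exact(((a, b), (c, d)))
            _, scipy_p = spstats.fisher_exact([[a, b], [c, d]])
            assert ours == pytest.approx(scipy_p, abs=1e-10)
            # brute force over all tables with the observed margins
            total = 0.0
            p_obs = (math.comb(a + b, a) * math.comb(c + d, c)
                     / math.comb(a + b + c + d, a + c))
            for x in range(0, min(a + b, a + c) + 1):
                y2 = a + c - x
                if y2 < 0 or y2 > c + d:
                    continue
                p_x = (math.comb(a + b, x) * math.comb(c + d, y2)
                       / math.comb(a + b + c + d, a + c))
                if p_x <= p_obs * (1 + 1e-9):
                    total += p_x
            assert ours == pytest.approx(min(total, 1.0), abs=1e-10)

    def test_negative_counts_rejected(self):
        with pytest.raises(InvalidParameterError):
            fisher_exact(((-1, 2), (3, 4)))


class TestProperties:
    @given(tp=st.integers(1, 50), fn=st.integers(0, 50),
           fp=st.integers(0, 50), tn=st.integers(1, 50))
    @settings(max_examples=100, deadline=None)
    def test_lr_identities_hold_on_any_table(self, tp, fn, fp, tn):
        m = diagnostic_metrics(ContingencyTable(tp, fn, fp, tn))
        if math.isfinite(m.lr_pos):
            assert m.lr_pos * (1 - m.specificity) == pytest.approx(
                m.sensitivity, abs=1e-12)
        assert m.lr_neg * m.specificity == pytest.approx(
            1 - m.sensitivity, abs=1e-12)
        assert 0.0 <= m.accuracy <= 1.0

    @given(k=st.integers(0, 40), extra=st.integers(0, 40))
    @settings(max_examples=100, deadline=None)
    def test_wilson_interval_contains_point_estimate(self, k, extra):
        n = k + extra
        if n == 0:
            return
        lo, hi = wilson_interval(k, n)
        assert 0.0 <= lo <= k / n <= hi <= 1.0

    @given(a=st.integers(0, 12), b=st.integers(0, 12),
           c=st.integers(0, 12), d=st.integers(0, 12))
    @settings(max_examples=60, deadline=None)
    def test_fisher_exact_valid_and_transpose_invariant(self, a, b, c, d):
        p = fisher_exact(((a, b), (c, d)))
        assert 0.0 <= p <= 1.0
        assert p == pytest.approx(fisher_exact(((a, c), (b, d))), abs=1e-12)


class TestTableFromPredictions:
    def test_counts(self):
        y = np.array([True, True, False, False])
        pred = np.array([True, False, True, False])
        t = table_from_predictions(y, pred)
        assert (t.tp, t.fn, t.fp, t.tn) == (1, 1, 1, 1)
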