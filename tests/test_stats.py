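"""Clinical statistics: labels, ROC cutoff, predictive values, Wilson CI,
severity regression, nonparametric tests, concordance, event-set overlap."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import optimize
from scipy import stats as sct

import scalphfo as sh
from scalphfo.rates import RecordingSummary
from scalphfo.stats import DegenerateInputError


def _summary(stage="post", rate=1.0, non=0.5, sf=None, ilae=None):
    return RecordingSummary(
        patient_id="P", stage=stage, affected_rate=rate,
        nonaffected_rate=non, seizure_freq=sf, ilae=ilae,
    )


class TestLabelActivity:
    @pytest.mark.parametrize(
        "kwargs, expected",
        [
            (dict(stage="pre"), "active"),
            (dict(stage="post", ilae=1), "seizure_free"),
            (dict(stage="post", ilae=3), "active"),
            (dict(stage="post", sf=0.35), "active"),
            (dict(stage="post", sf=0.0), "seizure_free"),
        ],
    )
    def test_labelling_policy(self, kwargs, expected):
        assert sh.label_activity(_summary(**kwargs)) == expected

    def test_post_without_outcome_information(self):
        with pytest.raises(ValueError):
            sh.label_activity(_summary(stage="post"))


class TestClassifyPositive:
    def test_strictly_greater(self):
        assert sh.classify_positive(0.26, 0.25)
        assert not sh.classify_positive(0.25, 0.25)
        assert not sh.classify_positive(0.0, 0.25)


class TestRocThreshold:
    def test_perfectly_separated_toy(self):
        rates = [0.1, 0.2, 1.0, 2.0]
        labels = ["seizure_free", "seizure_free", "active", "active"]
        assert sh.optimal_threshold_roc(rates, labels) == 0.2

    def test_single_class_rejected(self):
        with pytest.raises(DegenerateInputError):
            sh.optimal_threshold_roc([1.0, 2.0], ["active", "active"])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.data())
    def test_accuracy_equals_exhaustive_sweep(self, data):
        n = data.draw(st.integers(4, 12))
        rates = data.draw(st.lists(
            st.floats(0, 5).map(lambda v: round(v, 2)), min_size=n, max_size=n))
        labels = data.draw(st.lists(
            st.sampled_from(["active", "seizure_free"]), min_size=n, max_size=n))
        if len(set(labels)) < 2:
            return
        t = sh.optimal_threshold_roc(rates, labels)
        r = np.asarray(rates)
        act = np.asarray(labels) == "active"
        accs = {c: ((r > c) == act).mean() for c in set(rates)}
        assert accs[t] == max(accs.values())


class TestConfusionAndPredictiveValues:
    def test_all_correct_toy(self):
        cm = sh.confusion_matrix([1.0, 0.1], ["active", "seizure_free"], 0.5)
        assert (cm.tp, cm.fp, cm.fn, cm.tn) == (1, 0, 0, 1)
        assert sh.predictive_values(cm) == (1.0, 1.0, 1.0)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            sh.confusion_matrix([1.0], ["active", "seizure_free"], 0.5)

    def test_random_matrices_match_formula(self, rng):
        for _ in range(20):
            tp, fp, fn, tn = rng.integers(1, 30, 4)
            cm = sh.ConfusionMatrix(int(tp), int(fp), int(fn), int(tn))
            ppv, npv, acc = sh.predictive_values(cm)
            assert ppv == pytest.approx(tp / (tp + fp))
            assert npv == pytest.approx(tn / (tn + fn))
            assert acc == pytest.approx((tp + tn) / (tp + fp + fn + tn))

    def test_zero_denominator_raises(self):
        with pytest.raises(ZeroDivisionError):
            sh.predictive_values(sh.ConfusionMatrix(0, 0, 1, 1))

    def test_order_invariance(self, rng):
        rates = rng.uniform(0, 2, 10)
        labels = np.where(rng.random(10) < 0.5, "active", "seizure_free")
        perm = rng.permutation(10)
        cm1 = sh.confusion_matrix(rates, labels, 0.5)
        cm2 = sh.confusion_matrix(rates[perm], labels[perm], 0.5)
        assert sh.predictive_values(cm1) == sh.predictive_values(cm2)


class TestWilsonInterval:
    def test_zero_successes_has_zero_lower_bound(self):
        iv = sh.wilson_interval(0, 10)
        assert iv.lower == 0.0

    def test_contains_point_estimate(self, rng):
        for _ in range(30):
            n = int(rng.integers(1, 50))
            k = int(rng.integers(0, n + 1))
            iv = sh.wilson_interval(k, n)
            assert iv.lower - 1e-12 <= k / n <= iv.upper + 1e-12

    def test_matches_score_test_inversion(self, rng):
        # endpoints solve |p_hat - p| = z*sqrt(p(1-p)/n)
        z = sct.norm.ppf(0.975)
        for _ in range(10):
            n = int(rng.integers(5, 40))
            k = int(rng.integers(1, n))
            ph = k / n

            def score(p):
                return (ph - p) ** 2 - z**2 * p * (1 - p) / n

            iv = sh.wilson_interval(k, n)
            lo = optimize.brentq(score, 0, ph)
            hi = optimize.brentq(score, ph, 1)
            assert iv.lower == pytest.approx(lo, abs=1e-8)
            assert iv.upper == pytest.approx(hi, abs=1e-8)

    def test_coverage_near_nominal(self, rng):
        # exact coverage at n=19, p=0.84 by binomial enumeration
        p, n = 0.84, 19
        cov = sum(
            sct.binom.pmf(k, n, p)
            for k in range(n + 1)
            if sh.wilson_interval(k, n).lower <= p <= sh.wilson_interval(k, n).upper
        )
        assert 0.93 <= cov <= 0.99

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            sh.wilson_interval(1, 0)


class TestSeverityRegression:
    def test_exact_power_law_is_r2_one(self):
        sfs = [0.5, 2.0, 10.0, 80.0, 400.0]
        summaries = [
            _summary(stage="pre", rate=0.6 * s**0.4, sf=s) for s in sfs
        ]
        fit = sh.severity_regression(summaries)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)
        assert fit.slope == pytest.approx(0.4)

    def test_r2_equals_squared_correlation_oracle(self, rng):
        summaries = [
            _summary(stage="pre", rate=float(r), sf=float(s))
            for r, s in zip(rng.uniform(0.1, 5, 15), rng.uniform(0.1, 300, 15))
        ]
        fit = sh.severity_regression(summaries)
        x = np.log10([s.seizure_freq for s in summaries])
        y = np.log10([s.affected_rate for s in summaries])
        assert fit.r_squared == pytest.approx(np.corrcoef(x, y)[0, 1] ** 2)

    def test_seizure_free_rows_enter_at_proxy(self):
        summaries = [
            _summary(stage="pre", rate=0.6 * s**0.4, sf=s) for s in (1.0, 10.0, 100.0)
        ] + [_summary(stage="post", rate=0.6 * 0.05**0.4, sf=0.0, ilae=1)]
        fit = sh.severity_regression(summaries)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_nonpositive_rate_rejected(self):
        bad = [_summary(stage="pre", rate=0.0, sf=1.0)] * 3
        with pytest.raises(ValueError):
            sh.severity_regression(bad)


def _exact_signed_rank_p(diffs):
    """Enumerate all 2^n sign assignments of the |diff| ranks."""
    ranks = sct.rankdata(np.abs(diffs))
    w_obs = ranks[diffs > 0].sum()
    n = len(diffs)
    stats_all = [
        sum(r for r, s in zip(ranks, signs) if s)
        for signs in itertools.product([False, True], repeat=n)
    ]
    mean_w = len(ranks) * (len(ranks) + 1) / 4
    dev = abs(w_obs - mean_w)
    return sum(1 for w in stats_all if abs(w - mean_w) >= dev - 1e-9) / len(stats_all)


class TestPairedHemisphereTest:
    def test_identical_vectors_give_p_one(self):
        assert sh.paired_hemisphere_test([1.0] * 6, [1.0] * 6) == 1.0

    def test_matches_exact_enumeration_at_n8(self, rng):
        a = rng.uniform(0, 4, 8)
        b = rng.uniform(0, 4, 8)
        assert sh.paired_hemisphere_test(a, b) == pytest.approx(
            _exact_signed_rank_p(a - b), abs=1e-9)

    def test_too_few_pairs(self):
        with pytest.raises(ValueError):
            sh.paired_hemisphere_test([1, 2], [3, 4])


class TestGroupRateTest:
    def test_identical_singletons_give_p_one(self):
        assert sh.group_rate_test([1.0], [1.0]) == 1.0

    def test_matches_permutation_oracle_for_small_groups(self, rng):
        a = rng.uniform(0, 3, 4)
        b = rng.uniform(0, 3, 5)
        pooled = np.concatenate([a, b])
        ranks = sct.rankdata(pooled)
        w_obs = ranks[:4].sum()
        mean_w = 4 * (len(pooled) + 1) / 2
        count = total = 0
        for idx in itertools.combinations(range(len(pooled)), 4):
            w = ranks[list(idx)].sum()
            if abs(w - mean_w) >= abs(w_obs - mean_w) - 1e-9:
                count += 1
            total += 1
        assert sh.group_rate_test(a, b) == pytest.approx(count / total, abs=1e-9)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            sh.group_rate_test([], [1.0])


class TestConcordanceChi2:
    def test_fully_concordant_diagonal_equals_sum(self):
        pairs = [(True, True)] * 7 + [(False, False)]
        chi2, p = sh.concordance_chi2(pairs)
        assert chi2 == pytest.approx(8.0)
        assert p == pytest.approx(sct.chi2.sf(8.0, 1))

    def test_single_cell_is_degenerate(self):
        with pytest.raises(DegenerateInputError):
            sh.concordance_chi2([(True, True)] * 8)

    def test_random_tables_match_textbook_formula(self, rng):
        for _ in range(15):
            a, b, c, d = (int(x) for x in rng.integers(1, 10, 4))
            pairs = ([(True, True)] * a + [(True, False)] * b
                     + [(False, True)] * c + [(False, False)] * d)
            chi2, _ = sh.concordance_chi2(pairs)
            n = a + b + c + d
            expect = n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
            assert chi2 == pytest.approx(expect)


class TestCompareEventSets:
    def _events(self, times, ch="C4"):
        return [sh.HfoEvent(ch, "ripple", s, s + 0.05, 120.0, 3.0) for s in times]

    def test_identical_sets_fully_shared(self):
        evs = self._events([1.0, 2.0, 3.0])
        n_a, n_b, n_shared, frac = sh.compare_event_sets(evs, list(evs))
        assert (n_a, n_b, n_shared, frac) == (3, 3, 3, 1.0)

    def test_disjoint_sets_share_nothing(self):
        a = self._events([1.0, 2.0])
        b = self._events([10.0, 20.0])
        assert sh.compare_event_sets(a, b)[3] == 0.0

    def test_matches_bruteforce_interval_intersection(self, rng):
        a = self._events(sorted(rng.uniform(0, 30, 15)))
        b = self._events(sorted(rng.uniform(0, 30, 12)))
        tol = 0.01
        _, _, n_shared, _ = sh.compare_event_sets(a, b, overlap_tol_s=tol)
        # greedy one-to-one matching oracle
        used = set()
        expect = 0
        for ev in a:
            for j, other in enumerate(b):
                if j in used:
                    continue
                if ev.start_s - tol < other.end_s and other.start_s < ev.end_s + tol:
                    used.add(j)
                    expect += 1
                    break
        assert n_shared == expect


class TestTable1Fixture:
    def test_nineteen_scalp_recordings(self, table1):
        assert len(table1) == 19
        stages = [s.stage for s in table1]
        assert stages.count("pre") == 8 and stages.count("post") == 11

    def test_activity_split(self, table1):
        labels = [sh.label_activity(s) for s in table1]
        assert labels.count("active") == 13
        assert labels.count("seizure_free") == 6

    def test_ecog_rows_present(self):
        df = sh.load_table1("ecog")
        assert len(df) == 8
        assert df.affected_rate.max() == pytest.approx(31.73)
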