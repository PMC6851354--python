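"""Clinical validation statistics for HFO rates.

Implements the recording-level classification of "shows HFO" against
epilepsy activity: activity labelling from surgical stage and ILAE
outcome, ROC selection of the rate cutoff, confusion-matrix predictive
values with Wilson score intervals, the log-log severity regression of
HFO rate on seizure frequency, paired and group Wilcoxon comparisons,
the pre/post concordance chi-squared, and amplifier event-set overlap.

Standard statistical machinery comes from scipy and statsmodels; the
clinically specific rules (strict-greater classification, the
accuracy-maximising threshold sweep, the seizure-freedom proxy) are
defined here.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import statsmodels.api as sm
from scipy import stats as sct
from statsmodels.stats.proportion import proportion_confint

from ._intervals import overlaps
from .detector import HfoEvent
from .rates import RecordingSummary

__all__ = [
    "ConfusionMatrix",
    "BinomialInterval",
    "RegressionFit",
    "ClassifierConfig",
    "label_activity",
    "classify_positive",
    "optimal_threshold_roc",
    "confusion_matrix",
    "predictive_values",
    "wilson_interval",
    "severity_regression",
    "paired_hemisphere_test",
    "group_rate_test",
    "concordance_chi2",
    "compare_event_sets",
]


class DegenerateInputError(ValueError):
    pass


@dataclass
class ConfusionMatrix:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("counts must be >= 0")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def n_positive(self) -> int:
        return self.tp + self.fp


@dataclass
class BinomialInterval:
    lower: float
    upper: float
    level: float = 0.95


@dataclass
class RegressionFit:
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n: int
    log_scale: bool = True


@dataclass
class ClassifierConfig:
    """Rate cutoff (HFO/min) and the seizures/month proxy for seizure freedom."""

    rate_threshold: float = 0.25
    freedom_proxy: float = 0.05

    def __post_init__(self) -> None:
        if self.rate_threshold < 0 or self.freedom_proxy <= 0:
            raise ValueError("threshold must be >= 0 and proxy > 0")


def label_activity(summary: RecordingSummary) -> str:
    """'active' or 'seizure_free' from stage, ILAE outcome, seizure frequency.

    All presurgical recordings are active.  Postsurgical recordings are
    seizure-free with ILAE 1 and active with ILAE > 1; when ILAE is
    unavailable, the recording is active iff seizures persist
    (seizure_freq > 0).
    """
    if summary.stage == "pre":
        return "active"
    if summary.ilae is not None:
        return "seizure_free" if summary.ilae == 1 else "active"
    if summary.seizure_freq is None:
        raise ValueError(
            f"postsurgical recording {summary.patient_id} has neither ILAE nor seizure frequency"
        )
    return "active" if summary.seizure_freq > 0 else "seizure_free"


def classify_positive(rate: float, threshold: float) -> bool:
    """Recording shows HFO iff its rate strictly exceeds the threshold."""
    if rate < 0:
        raise ValueError("rate must be >= 0")
    return rate > threshold


def optimal_threshold_roc(rates: Sequence[float], labels: Sequence[str]) -> float:
    """Accuracy-maximising rate cutoff from ROC analysis.

    Candidate thresholds are the observed rate values; a recording is
    positive when its rate strictly exceeds the candidate.  Among
    accuracy ties the largest candidate is returned — the most specific
    cutoff, so the reported threshold is the highest rate that active
    recordings must exceed.
    """
    rates = np.asarray(rates, dtype=float)
    labels = np.asarray(labels)
    if rates.shape != labels.shape:
        raise ValueError("rates and labels must align")
    active = labels == "active"
    if active.all() or (~active).all():
        raise DegenerateInputError("need both active and seizure_free labels")
    best_t, best_acc = None, -1.0
    for t in sorted(set(rates.tolist())):
        acc = float(((rates > t) == active).mean())
        if acc >= best_acc:  # ties resolved toward the larger threshold
            best_acc, best_t = acc, t
    return float(best_t)


def confusion_matrix(
    rates: Sequence[float], labels: Sequence[str], threshold: float
) -> ConfusionMatrix:
    rates = np.asarray(rates, dtype=float)
    labels = np.asarray(labels)
    if rates.shape != labels.shape:
        raise ValueError("rates and labels must align")
    pos = rates > threshold
    active = labels == "active"
    return ConfusionMatrix(
        tp=int((pos & active).sum()),
        fp=int((pos & ~active).sum()),
        fn=int((~pos & active).sum()),
        tn=int((~pos & ~active).sum()),
    )


def predictive_values(cm: ConfusionMatrix) -> tuple[float, float, float]:
    """(PPV, NPV, accuracy) as exact proportions.

    PPV = TP/(TP+FP), NPV = TN/(TN+FN), accuracy = (TP+TN)/N.  A zero
    denominator raises for the affected metric.
    """
    if cm.tp + cm.fp == 0:
        raise ZeroDivisionError("PPV undefined: no positive classifications")
    if cm.tn + cm.fn == 0:
        raise ZeroDivisionError("NPV undefined: no negative classifications")
    if cm.total == 0:
        raise ZeroDivisionError("accuracy undefined: empty matrix")
    return (
        cm.tp / (cm.tp + cm.fp),
        cm.tn / (cm.tn + cm.fn),
        (cm.tp + cm.tn) / cm.total,
    )


def wilson_interval(successes: int, n: int, level: float = 0.95) -> BinomialInterval:
    """Closed-form Wilson score interval for a binomial proportion."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= successes <= n:
        raise ValueError("successes must be in [0, n]")
    lo, hi = proportion_confint(successes, n, alpha=1 - level, method="wilson")
    return BinomialInterval(lower=float(lo), upper=float(hi), level=level)


def severity_regression(
    summaries: Iterable[RecordingSummary],
    config: ClassifierConfig | None = None,
    log_scale: bool = True,
) -> RegressionFit:
    """OLS regression of affected-hemisphere HFO rate on seizure frequency.

    Default is log10–log10 (the severity relation is a power law and the
    clinical axes are logarithmic); seizure-free recordings enter at the
    freedom proxy.  ``log_scale=False`` fits the raw scale as a
    sensitivity analysis.
    """
    if config is None:
        config = ClassifierConfig()
    summaries = list(summaries)
    if len(summaries) < 3:
        raise ValueError("need at least 3 recordings")
    rates = np.array([s.affected_rate for s in summaries], dtype=float)
    sf = np.array(
        [s.seizure_freq if s.seizure_freq else config.freedom_proxy for s in summaries],
        dtype=float,
    )
    if log_scale:
        if (rates <= 0).any():
            raise ValueError("log-scale regression requires positive rates")
        x, y = np.log10(sf), np.log10(rates)
    else:
        x, y = sf, rates
    model = sm.OLS(y, sm.add_constant(x)).fit()
    return RegressionFit(
        slope=float(model.params[1]), intercept=float(model.params[0]),
        r_squared=float(model.rsquared), p_value=float(model.f_pvalue),
        n=len(summaries), log_scale=log_scale,
    )


def paired_hemisphere_test(
    affected_rates: Sequence[float], nonaffected_rates: Sequence[float]
) -> float:
    """Two-sided Wilcoxon signed-rank p for paired hemisphere rates.

    Exact enumeration up to n = 12 pairs, normal approximation without
    continuity correction beyond.  All-zero differences (identical
    vectors) are the no-effect degenerate case and return p = 1.
    """
    a = np.asarray(affected_rates, dtype=float)
    b = np.asarray(nonaffected_rates, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired vectors must have equal length")
    if a.size < 5:
        raise ValueError("need at least 5 pairs")
    if np.all(a == b):
        return 1.0
    method = "exact" if a.size <= 12 else "approx"
    res = sct.wilcoxon(a, b, correction=False, method=method, alternative="two-sided")
    return float(res.pvalue)


def group_rate_test(
    active_rates: Sequence[float], free_rates: Sequence[float]
) -> float:
    """Two-sided rank-sum p comparing active vs seizure-free rates.

    Exact (Mann-Whitney enumeration) when the combined sample is at most
    12, otherwise the normal approximation without continuity
    correction.
    """
    a = np.asarray(active_rates, dtype=float)
    b = np.asarray(free_rates, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    if a.size == b.size == 1 and a[0] == b[0]:
        return 1.0
    if a.size + b.size <= 12:
        res = sct.mannwhitneyu(a, b, method="exact", alternative="two-sided")
        return float(res.pvalue)
    return float(sct.ranksums(a, b).pvalue)


def concordance_chi2(pre_post_pairs: Sequence[tuple[bool, bool]]) -> tuple[float, float]:
    """1-df chi-squared on the 2×2 table of pre→post direction of change.

    Each pair is (HFO rate decreased, seizure frequency decreased).  The
    statistic is the textbook N(ad-bc)²/(margin product), no continuity
    correction; for a fully concordant diagonal table [[a,0],[0,b]] it
    equals a + b.  A zero margin leaves the statistic undefined.
    """
    pairs = list(pre_post_pairs)
    if not pairs:
        raise ValueError("no pairs")
    a = sum(1 for h, s in pairs if h and s)
    b = sum(1 for h, s in pairs if h and not s)
    c = sum(1 for h, s in pairs if not h and s)
    d = sum(1 for h, s in pairs if not h and not s)
    n = a + b + c + d
    margins = [(a + b), (c + d), (a + c), (b + d)]
    if 0 in margins:
        raise DegenerateInputError("chi-squared undefined: zero row/column margin")
    chi2 = n * (a * d - b * c) ** 2 / (margins[0] * margins[1] * margins[2] * margins[3])
    return float(chi2), float(sct.chi2.sf(chi2, df=1))


def compare_event_sets(
    events_a: Sequence[HfoEvent],
    events_b: Sequence[HfoEvent],
    overlap_tol_s: float = 0.01,
) -> tuple[int, int, int, float]:
    """Match two detectors' event sets (e.g. low-noise vs commercial amplifier).

    Events match when on the same channel and time-overlapping after
    padding set A's intervals by ``overlap_tol_s``; matching is greedy
    one-to-one.  Returns (n_a, n_b, n_shared, n_shared/n_a).
    """
    used_b: set[int] = set()
    n_shared = 0
    for ev in events_a:
        for j, other in enumerate(events_b):
            if j in used_b or other.channel != ev.channel:
                continue
            if overlaps(ev.interval, other.interval, pad=overlap_tol_s):
                used_b.add(j)
                n_shared += 1
                break
    n_a = len(events_a)
    return n_a, len(events_b), n_shared, (n_shared / n_a if n_a else float("nan"))
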