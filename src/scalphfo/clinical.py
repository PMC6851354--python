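"""Packaged clinical table and the one-shot reproduction of its statistics.

The packaged fixture ``data/table1.csv`` holds the 19 scalp EEG
recordings (8 presurgical, 11 postsurgical) of an 11-patient pediatric
drug-resistant focal epilepsy cohort — affected- and non-affected-
hemisphere ripple rates (HFO/min), seizure frequency (per month) at the
time of each recording, and the ILAE outcome class for postsurgical
recordings — plus the intraoperative ECoG maximal fast-ripple rates of
the four patients with ECoG.  One patient's first postsurgical
recording doubled as the presurgical recording of a second surgery and
is counted once.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

from .rates import RecordingSummary
from .stats import (
    ClassifierConfig,
    confusion_matrix,
    group_rate_test,
    label_activity,
    optimal_threshold_roc,
    paired_hemisphere_test,
    predictive_values,
    severity_regression,
    wilson_interval,
)

__all__ = ["load_table1", "table1_summaries", "reproduce_table1_metrics"]


def load_table1(modality: str | None = "scalp") -> pd.DataFrame:
    """The packaged clinical table as a DataFrame (scalp rows by default)."""
    with resources.files("scalphfo.data").joinpath("table1.csv").open() as fh:
        df = pd.read_csv(fh)
    if modality is not None:
        df = df[df["modality"] == modality].reset_index(drop=True)
    return df


def table1_summaries() -> list[RecordingSummary]:
    """The 19 scalp recordings as :class:`RecordingSummary` rows."""
    out = []
    for _, row in load_table1("scalp").iterrows():
        out.append(RecordingSummary(
            patient_id=row["patient_id"],
            stage=row["stage"],
            modality="scalp",
            affected_rate=float(row["affected_rate"]),
            nonaffected_rate=float(row["nonaffected_rate"]),
            seizure_freq=None if pd.isna(row["seizure_freq"]) else float(row["seizure_freq"]),
            ilae=None if pd.isna(row["ilae"]) else int(row["ilae"]),
        ))
    return out


def reproduce_table1_metrics(config: ClassifierConfig | None = None) -> dict:
    """Recompute every clinical-table statistic from the packaged fixture.

    Returns a JSON-ready dict: the ROC rate threshold, positive count,
    confusion counts, PPV/NPV/accuracy (exact and percent-rounded) with
    the Wilson 95% CI on accuracy, the log-log and raw-scale severity
    regressions, and the two Wilcoxon p-values.
    """
    summaries = table1_summaries()
    labels = [label_activity(s) for s in summaries]
    rates = [s.affected_rate for s in summaries]
    threshold = optimal_threshold_roc(rates, labels)
    if config is None:
        config = ClassifierConfig(rate_threshold=threshold)
    cm = confusion_matrix(rates, labels, config.rate_threshold)
    ppv, npv, acc = predictive_values(cm)
    ci = wilson_interval(cm.tp + cm.tn, cm.total)
    fit_log = severity_regression(summaries, config, log_scale=True)
    fit_raw = severity_regression(summaries, config, log_scale=False)
    p_hemi = paired_hemisphere_test(
        [s.affected_rate for s in summaries],
        [s.nonaffected_rate for s in summaries],
    )
    active_rates = [r for r, l in zip(rates, labels) if l == "active"]
    free_rates = [r for r, l in zip(rates, labels) if l == "seizure_free"]
    p_group = group_rate_test(active_rates, free_rates)
    return {
        "n_recordings": cm.total,
        "rate_threshold": threshold,
        "n_positive": cm.n_positive,
        "confusion": {"tp": cm.tp, "fp": cm.fp, "fn": cm.fn, "tn": cm.tn},
        "ppv": ppv,
        "npv": npv,
        "accuracy": acc,
        "ppv_pct": round(100 * ppv),
        "npv_pct": round(100 * npv),
        "accuracy_pct": round(100 * acc),
        "accuracy_ci_pct": [round(100 * ci.lower), round(100 * ci.upper)],
        "regression_log10": {
            "slope": fit_log.slope, "intercept": fit_log.intercept,
            "r_squared": fit_log.r_squared, "p_value": fit_log.p_value,
        },
        "regression_raw": {
            "slope": fit_raw.slope, "intercept": fit_raw.intercept,
            "r_squared": fit_raw.r_squared, "p_value": fit_raw.p_value,
        },
        "p_hemisphere_wilcoxon": p_hemi,
        "p_group_ranksum": p_group,
        "n_active": len(active_rates),
        "n_seizure_free": len(free_rates),
    }
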