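"""Endpoint derivation and survival statistics for animal cohorts.

Endpoints are derived from per-animal event tables: time from induction to
MRI-confirmed tumor onset, time from onset (or enrollment) to death, or time
from birth/induction to death. Deaths from disease and euthanasia on
predefined termination criteria count as events; animals terminated for
unrelated reasons are excluded by default (the study's stated policy), with
an option to censor them instead. Curves and tests use the Kaplan-Meier
product-limit estimator and the Mantel-Cox log-rank test; pairwise group
location shifts use Mann-Whitney U.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from scipy import stats

__all__ = [
    "derive_endpoints",
    "km_median",
    "logrank_test",
    "mann_whitney",
    "volume_fold_change",
]

EVENT_CAUSES = ("disease", "termination_criteria")
ENDPOINTS = ("from_birth", "onset", "post_onset", "post_enrollment")


def derive_endpoints(
    events: pd.DataFrame,
    endpoint: str = "post_onset",
    unrelated: str = "exclude",
) -> pd.DataFrame:
    """Turn an animal event table into survival records.

    Parameters
    ----------
    events
        One row per animal: ``animal_id``, ``group``, ``arm``,
        ``induction_day``, ``onset_day`` (NaN if never observed),
        ``end_day``, ``end_cause``.
    endpoint
        ``onset``: time = onset - induction, event = onset observed;
        ``post_onset`` / ``post_enrollment``: time = end - onset, event per
        cause; ``from_birth``: time = end - induction.
    unrelated
        ``exclude`` drops animals with an unrelated end cause (default
        policy); ``censor`` keeps them as censored observations.

    Returns columns subject, group, arm, time, event. Subjects are
    conserved: len(output) + excluded = len(input).
    """
    if endpoint not in ENDPOINTS:
        raise ValueError(f"unknown endpoint {endpoint!r}")
    if unrelated not in ("exclude", "censor"):
        raise ValueError("unrelated must be 'exclude' or 'censor'")
    rows = []
    for r in events.itertuples(index=False):
        if endpoint == "onset":
            if pd.isna(r.onset_day):
                # never-onset animals are censored at end of follow-up
                t, e = r.end_day - r.induction_day, 0
            else:
                t, e = r.onset_day - r.induction_day, 1
        else:
            if r.end_cause == "unrelated":
                if unrelated == "exclude":
                    continue
                e = 0
            else:
                e = 1 if r.end_cause in EVENT_CAUSES else 0
            if endpoint == "from_birth":
                t = r.end_day - r.induction_day
            else:
                if pd.isna(r.onset_day):
                    continue  # no onset: post-onset time undefined
                if r.end_day < r.onset_day:
                    raise ValueError(
                        f"animal {r.animal_id}: end_day precedes onset_day"
                    )
                t = r.end_day - r.onset_day
        if t <= 0:
            t = 1e-9  # simultaneous onset and death: keep a positive time
        rows.append({"subject": r.animal_id, "group": r.group, "arm": r.arm,
                     "time": float(t), "event": int(e)})
    return pd.DataFrame(rows, columns=["subject", "group", "arm", "time", "event"])


@dataclass
class KMResult:
    curve: pd.DataFrame  # columns time, survival
    median: float  # NaN when S(t) never reaches 0.5
    median_defined: bool


def km_median(records: pd.DataFrame) -> KMResult:
    """Kaplan-Meier curve and median survival time.

    Median is the smallest observed time with S(t) <= 0.5, NaN (flagged via
    ``median_defined``) when the curve never drops that far — e.g. when all
    records are censored.
    """
    if not len(records):
        raise ValueError("no records")
    kmf = KaplanMeierFitter()
    kmf.fit(records["time"], records["event"])
    curve = kmf.survival_function_.reset_index()
    curve.columns = ["time", "survival"]
    med = float(kmf.median_survival_time_)
    defined = math.isfinite(med)
    return KMResult(curve=curve, median=med if defined else float("nan"),
                    median_defined=defined)


def logrank_test(records_a: pd.DataFrame, records_b: pd.DataFrame) -> tuple[float, float]:
    """Mantel-Cox log-rank chi-square statistic and p (1 df).

    Symmetric in the two groups; ties are handled by grouping simultaneous
    events (hypergeometric variance). Requires at least one event overall.
    """
    if not len(records_a) or not len(records_b):
        raise ValueError("both groups must be non-empty")
    if records_a["event"].sum() + records_b["event"].sum() == 0:
        raise ValueError("log-rank requires at least one event")
    res = _ll_logrank(
        records_a["time"], records_b["time"],
        event_observed_A=records_a["event"], event_observed_B=records_b["event"],
    )
    return float(res.test_statistic), float(res.p_value)


def mann_whitney(sample_a: Sequence[float], sample_b: Sequence[float]) -> tuple[float, float]:
    """Two-sided Mann-Whitney U (tie-corrected).

    Exact enumeration for small samples (both n <= 8, no ties), normal
    approximation with continuity correction otherwise. Returns the U of the
    first sample and the p value; identical samples give p = 1.
    """
    a, b = np.asarray(sample_a, float), np.asarray(sample_b, float)
    small = len(a) <= 8 and len(b) <= 8
    no_ties = len(np.unique(np.concatenate([a, b]))) == len(a) + len(b)
    method = "exact" if (small and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method,
                             use_continuity=True)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def volume_fold_change(
    volumes: pd.DataFrame, timepoints: Sequence[float] | None = None
) -> pd.DataFrame:
    """Per-animal tumor-volume fold change relative to baseline.

    ``volumes`` has columns animal_id, day, volume (mm^3); the baseline is
    each animal's earliest measurement. Animals with baseline volume 0 are
    excluded with a warning. Returns animal_id, day, volume, fold_change,
    optionally restricted to ``timepoints`` (days after baseline).
    """
    import warnings

    out = []
    for animal, sub in volumes.groupby("animal_id"):
        sub = sub.sort_values("day")
        v0 = float(sub["volume"].iloc[0])
        if v0 <= 0:
            warnings.warn(f"animal {animal}: baseline volume 0, excluded")
            continue
        day0 = float(sub["day"].iloc[0])
        for r in sub.itertuples(index=False):
            dt = float(r.day) - day0
            if timepoints is not None and dt not in timepoints:
                continue
            out.append({"animal_id": animal, "day": float(r.day),
                        "days_from_baseline": dt, "volume": float(r.volume),
                        "fold_change": float(r.volume) / v0})
    return pd.DataFrame(
        out, columns=["animal_id", "day", "days_from_baseline", "volume",
                      "fold_change"]
    )
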