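"""Kaplan-Meier estimation, the log-rank test, and predicted-group comparison.

Estimation and testing are delegated to lifelines (product-limit estimator
and the standard two-group log-rank chi-square with hypergeometric moments);
this module adapts them to the pipeline's containers and handles the
degenerate cases (no events, an empty predicted group). The event flag
defaults to 1 for every sample when absent, since the upstream clinical
pre-processing keeps only samples with a recorded overall survival.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test

from .datatypes import HIGH_OS, LOW_OS
from .pcpa import EvalReport

logger = logging.getLogger(__name__)


@dataclass
class KMCurve:
    """A right-continuous step function: survival probability over time."""

    times: np.ndarray  # step locations (event times), increasing
    survival: np.ndarray  # S(t) just after each step

    def at(self, t: float) -> float:
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


@dataclass
class SurvivalComparison:
    groups: pd.Series  # sample -> group label
    km_curves: dict  # group -> KMCurve
    logrank_chi2: float
    logrank_p: float
    median_os: dict  # group -> median observed os_days


def km_estimate(times, events=None) -> KMCurve:
    """Product-limit survival curve; censored times shrink the risk set only."""
    t = np.asarray(times, dtype=float)
    if t.size == 0:
        raise ValueError("km_estimate needs at least one observation")
    e = np.ones_like(t) if events is None else np.asarray(events, dtype=int)
    kmf = KaplanMeierFitter()
    kmf.fit(t, event_observed=e)
    sf = kmf.survival_function_
    steps = sf[sf.index > 0]
    return KMCurve(times=steps.index.to_numpy(dtype=float), survival=steps.iloc[:, 0].to_numpy())


def log_rank(times, events, groups) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi2, p).

    With no events at all the statistic is 0 with p = 1.
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    g = np.asarray(groups)
    levels = pd.unique(g)
    if len(levels) != 2:
        raise ValueError(f"log_rank needs exactly 2 groups, got {len(levels)}")
    if e.sum() == 0:
        return 0.0, 1.0
    mask = g == levels[0]
    res = logrank_test(t[mask], t[~mask], event_observed_A=e[mask], event_observed_B=e[~mask])
    chi2 = float(res.test_statistic)
    if not np.isfinite(chi2):  # identical groups can yield 0/0
        return 0.0, 1.0
    return chi2, float(res.p_value)


def compare_predicted_groups(report: EvalReport, clinical: pd.DataFrame) -> SurvivalComparison:
    """Survival comparison between predicted high-OS and low-OS samples.

    Median OS is the median of observed ``os_days`` per predicted group;
    KM curves and the log-rank test run over the predicted grouping. A
    degenerate prediction (one group empty) yields p = 1 with a logged note.
    """
    clin = clinical.drop_duplicates(subset="sample").set_index("sample")
    preds = report.predictions()
    shared = [s for s in preds.index if s in clin.index]
    if not shared:
        raise ValueError("no overlap between evaluated samples and clinical table")
    preds = preds.loc[shared]
    times = clin.loc[shared, "os_days"].to_numpy(dtype=float)
    events = (
        clin.loc[shared, "event"].to_numpy(dtype=int)
        if "event" in clin.columns
        else np.ones(len(shared), dtype=int)
    )

    km_curves, median_os = {}, {}
    for grp in (HIGH_OS, LOW_OS):
        mask = (preds == grp).to_numpy()
        if mask.any():
            km_curves[grp] = km_estimate(times[mask], events[mask])
            median_os[grp] = float(np.median(times[mask]))
        else:
            median_os[grp] = float("nan")
    if len(km_curves) < 2:
        logger.warning("a predicted group is empty; log-rank comparison degenerate")
        chi2, p = 0.0, 1.0
    else:
        chi2, p = log_rank(times, events, preds.to_numpy())
    return SurvivalComparison(
        groups=preds, km_curves=km_curves, logrank_chi2=chi2, logrank_p=p, median_os=median_os
    )


def km_median(curve: KMCurve) -> float:
    """First time the KM curve drops to 0.5 or below (nan if it never does)."""
    below = np.nonzero(curve.survival <= 0.5)[0]
    return float(curve.times[below[0]]) if below.size else float("nan")
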