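"""Prognosis-related differential expression between high-OS and low-OS groups.

Each feature is scored with a two-tailed Welch (unequal-variance) t-test and
a linear-scale fold change between the two prognosis groups. The omic-specific
gates are: miRNA passes at P < 0.05; lncRNA passes at P < 0.01 together with a
two-sided fold-change gate (FC >= 2 or FC <= 0.5, the absolute-fold-change
reading that also captures down-regulation). P-values are unadjusted by
default, with Benjamini-Hochberg available behind a flag. A factor-analysis
reduction is provided for small cohorts, keeping the strongest-loading
features of each Kaiser-retained factor.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import LNCRNA, MIRNA, CohortLabels, ExpressionMatrix, MarkerSet

logger = logging.getLogger(__name__)

FC_EPS = 1e-8

#: omic-specific gates: (p threshold, apply fold-change gate?)
_GATES = {MIRNA: (0.05, False), LNCRNA: (0.01, True)}


@dataclass
class DEResult:
    feature_id: str
    t_stat: float
    p_value: float
    fold_change: float
    passes: bool


def welch_t(group_a, group_b) -> tuple[float, float, float]:
    """Welch unequal-variance t-test; returns (t, Welch-Satterthwaite df, p).

    Degenerate inputs follow the limiting behaviour: zero variance in both
    groups gives t=0, p=1 for equal means and p=0 (logged) for unequal means.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 values")
    if a.var(ddof=1) == 0.0 and b.var(ddof=1) == 0.0:
        if a.mean() == b.mean():
            return 0.0, float(len(a) + len(b) - 2), 1.0
        logger.warning("welch_t: zero variance with unequal means; p -> 0 limit")
        sign = np.sign(a.mean() - b.mean())
        return float(sign * np.inf), float(len(a) + len(b) - 2), 0.0
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def fold_change(high, low) -> float:
    """Linear-scale fold change of group means for log2(x+1) inputs.

    Values are back-transformed (2^x - 1) before averaging; a small epsilon
    guards all-zero groups.
    """
    h = np.exp2(np.asarray(high, dtype=float)) - 1.0
    lo = np.exp2(np.asarray(low, dtype=float)) - 1.0
    if h.size == 0 or lo.size == 0:
        raise ValueError("groups must be nonempty")
    return float((h.mean() + FC_EPS) / (lo.mean() + FC_EPS))


def fc_passes(fc: np.ndarray | float) -> np.ndarray | bool:
    """Two-sided absolute fold-change gate: FC >= 2 or FC <= 0.5."""
    fc = np.asarray(fc, dtype=float)
    out = (fc >= 2.0) | (fc <= 0.5)
    return bool(out) if out.ndim == 0 else out


def benjamini_hochberg(p_values) -> np.ndarray:
    """BH-adjusted p-values (step-up, monotone)."""
    p = np.asarray(p_values, dtype=float)
    n = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.clip(adjusted, 0.0, 1.0)
    return out


def detect_de(
    matrix: ExpressionMatrix,
    labels: CohortLabels,
    omic: str | None = None,
    adjust: bool = False,
) -> tuple[list[DEResult], MarkerSet]:
    """Score every feature between the high-OS and low-OS groups.

    Returns the per-feature results (in matrix feature order) and the
    MarkerSet of features passing the omic-specific gate. ``adjust=True``
    applies Benjamini-Hochberg before thresholding.
    """
    omic = omic or matrix.omic
    if omic not in _GATES:
        raise ValueError(f"no DE gate defined for omic {omic!r}")
    p_thresh, use_fc = _GATES[omic]

    lab = labels.for_samples(matrix.sample_ids)
    high_ids = [s for s in matrix.sample_ids if lab[s] == "high-OS"]
    low_ids = [s for s in matrix.sample_ids if lab[s] == "low-OS"]
    for name, ids in (("high-OS", high_ids), ("low-OS", low_ids)):
        if len(ids) < 2:
            raise ValueError(f"class {name} has {len(ids)} samples; need at least 2")

    high = matrix.data[high_ids].to_numpy()
    low = matrix.data[low_ids].to_numpy()

    with np.errstate(invalid="ignore", divide="ignore"):
        res = stats.ttest_ind(high, low, axis=1, equal_var=False)
        t_stats = np.asarray(res.statistic, dtype=float)
        p_values = np.asarray(res.pvalue, dtype=float)
    # constant features: scipy yields nan; equal means -> no evidence
    degenerate = np.isnan(t_stats)
    if degenerate.any():
        equal = high.mean(axis=1) == low.mean(axis=1)
        t_stats[degenerate & equal] = 0.0
        p_values[degenerate & equal] = 1.0
        bad = degenerate & ~equal
        if bad.any():
            logger.warning("%d zero-variance features with unequal means; p -> 0", bad.sum())
            t_stats[bad] = np.sign(high.mean(axis=1) - low.mean(axis=1))[bad] * np.inf
            p_values[bad] = 0.0

    lin_high = np.exp2(high) - 1.0
    lin_low = np.exp2(low) - 1.0
    fc = (lin_high.mean(axis=1) + FC_EPS) / (lin_low.mean(axis=1) + FC_EPS)

    p_for_gate = benjamini_hochberg(p_values) if adjust else p_values
    passes = p_for_gate < p_thresh
    if use_fc:
        passes &= fc_passes(fc)

    results = [
        DEResult(f, float(t_stats[i]), float(p_values[i]), float(fc[i]), bool(passes[i]))
        for i, f in enumerate(matrix.feature_ids)
    ]
    markers = MarkerSet(cancer="", omic=omic, markers=[r.feature_id for r in results if r.passes])
    return results, markers


def kaiser_n_factors(matrix: ExpressionMatrix) -> int:
    """Number of factors by the Kaiser criterion on the correlation matrix.

    Eigenvalues > 1 of the feature correlation matrix, capped at
    n_samples - 1; degenerate (constant) features contribute nothing.
    """
    X = matrix.data.to_numpy().T  # samples x features
    sd = X.std(axis=0)
    keep = sd > 0
    if keep.sum() < 2:
        return 1
    corr = np.corrcoef(X[:, keep], rowvar=False)
    eigvals = np.linalg.eigvalsh(corr)
    k = int((eigvals > 1.0).sum())
    return max(1, min(k, matrix.n_samples - 1))


def factor_reduce(matrix: ExpressionMatrix, n_top: int = 10) -> list[str]:
    """Reduce a feature space via factor analysis.

    Fits a factor model on standardized features with the Kaiser-selected
    number of factors and returns the union, over factors, of the ``n_top``
    features with the largest absolute loading (in matrix feature order).
    Falls back to principal-component loadings if the fit degenerates.
    """
    if matrix.n_samples < 3:
        raise ValueError("factor_reduce needs at least 3 samples")
    if n_top >= matrix.n_features:
        return list(matrix.feature_ids)
    X = matrix.data.to_numpy().T
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    Xs = (X - X.mean(axis=0)) / sd
    k = kaiser_n_factors(matrix)
    try:
        from sklearn.decomposition import FactorAnalysis

        fa = FactorAnalysis(n_components=k, rotation="varimax" if k > 1 else None, random_state=0)
        fa.fit(Xs)
        loadings = fa.components_.T  # features x factors
        if not np.all(np.isfinite(loadings)):
            raise np.linalg.LinAlgError("non-finite loadings")
    except (np.linalg.LinAlgError, ValueError):
        logger.warning("factor analysis degenerate; using principal-component loadings")
        _, s, vt = np.linalg.svd(Xs, full_matrices=False)
        loadings = (vt[:k].T * s[:k]) / np.sqrt(max(Xs.shape[0] - 1, 1))
    selected: set[int] = set()
    for j in range(loadings.shape[1]):
        top = np.argsort(-np.abs(loadings[:, j]), kind="stable")[:n_top]
        selected.update(int(i) for i in top)
    return [f for i, f in enumerate(matrix.feature_ids) if i in selected]
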