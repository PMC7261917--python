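"""End-to-end per-cancer analysis and the pan-cancer study driver.

One cohort flows through: median-OS labeling -> omic-specific differential
expression -> merge of the detected markers over the shared samples ->
(optional factor reduction for small cohorts) -> spatially stratified 2/3
split -> Gaussian NB prognosis model -> held-out ROC/AUC and predicted-group
survival comparison -> marker-oriented counterfactual screen of the miRNA
markers on the held-out low-OS samples.
"""

from __future__ import annotations

from dataclasses import dataclass

from .datatypes import LNCRNA, MIRNA, CohortLabels, ExpressionMatrix, MarkerSet
from .de import detect_de, factor_reduce
from .ingest import label_by_median_os, merge_omics
from .mos import MOSReport, high_os_reference, mos_scan
from .pcpa import EvalReport, PCPAModel, fit_gaussian_nb, predict_proba, roc_auc
from .split import SplitAssignment, spatial_subset_split
from .survival import SurvivalComparison, compare_predicted_groups

#: training-set size below which the factor-analysis reduction kicks in
SMALL_COHORT_THRESHOLD = 50


@dataclass
class CohortResult:
    cancer: str
    labels: CohortLabels
    mirna_markers: MarkerSet
    lncrna_markers: MarkerSet
    split: SplitAssignment
    model: PCPAModel
    eval_report: EvalReport
    survival: SurvivalComparison
    mos: MOSReport


def analyze_cohort(
    cancer: str,
    mirna: ExpressionMatrix,
    lncrna: ExpressionMatrix,
    clinical,
    rng_seed: int = 0,
    train_fraction: float = 2.0 / 3.0,
    small_cohort_threshold: int = SMALL_COHORT_THRESHOLD,
    factor_n_top: int = 10,
) -> CohortResult:
    """Run the full single-cancer analysis and return every intermediate."""
    labels = label_by_median_os(clinical)

    de_mirna, mirna_markers = detect_de(mirna, labels, MIRNA)
    de_lncrna, lncrna_markers = detect_de(lncrna, labels, LNCRNA)
    mirna_markers = MarkerSet(cancer, MIRNA, mirna_markers.markers)
    lncrna_markers = MarkerSet(cancer, LNCRNA, lncrna_markers.markers)
    if len(mirna_markers) + len(lncrna_markers) == 0:
        raise ValueError(f"{cancer}: no DE markers detected; nothing to model")

    merged = merge_omics(
        mirna.subset_features(mirna_markers.markers) if len(mirna_markers) else _empty_like(mirna),
        lncrna.subset_features(lncrna_markers.markers) if len(lncrna_markers) else _empty_like(lncrna),
    )

    n_train_projected = round(train_fraction * merged.n_samples)
    if n_train_projected < small_cohort_threshold and merged.n_features > factor_n_top:
        kept = factor_reduce(merged, n_top=factor_n_top)
        merged = merged.subset_features(kept)

    split = spatial_subset_split(merged, labels, train_fraction, rng_seed)
    train = merged.subset_samples(split.train_ids)
    test = merged.subset_samples(split.test_ids)

    model = fit_gaussian_nb(train, labels)
    prob_high = predict_proba(model, test)
    truth = labels.for_samples(split.test_ids)
    report = roc_auc(prob_high, truth.to_numpy())
    surv = compare_predicted_groups(report, clinical)

    mirna_in_model = [m for m in mirna_markers.markers if m in set(merged.feature_ids)]
    references = high_os_reference(train, labels, mirna_in_model)
    low_test = [s for s in split.test_ids if labels.labels[s] == "low-OS"]
    mos_report = mos_scan(
        model, merged.subset_samples(low_test), mirna_in_model, references, cancer=cancer
    )

    return CohortResult(
        cancer=cancer,
        labels=labels,
        mirna_markers=mirna_markers,
        lncrna_markers=lncrna_markers,
        split=split,
        model=model,
        eval_report=report,
        survival=surv,
        mos=mos_report,
    )


def _empty_like(matrix: ExpressionMatrix) -> ExpressionMatrix:
    return ExpressionMatrix(matrix.data.iloc[:0], matrix.omic, matrix.scale)


def analyze_pan_cancer(dataset, rng_seed: int = 0) -> dict:
    """Run :func:`analyze_cohort` for every cancer of a simulated dataset."""
    results = {}
    for cancer, bundle in dataset.cohorts.items():
        results[cancer] = analyze_cohort(
            cancer, bundle.mirna, bundle.lncrna, bundle.clinical, rng_seed=rng_seed
        )
    return results
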