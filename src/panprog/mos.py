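"""Marker-Oriented Simulation: a counterfactual in-silico marker screen.

For each miRNA marker independently, every low-OS sample whose expression
of that marker lies below the high-OS reference level (the marker's mean in
high-OS training samples) is raised to the reference, all other features
untouched, and the cohort is re-scored with the fitted prognosis model.
Markers whose perturbation increases the mean predicted high-OS probability
are flagged *prognosis-alternative*: their up-regulation moves poor-prognosis
samples toward the good-prognosis class, so the genes they repress are
candidate drug targets. Per cancer category, the screen intersects the
pathway genes targeted by each member cancer's alternative markers to yield
common candidate genes, optionally annotated against a known drug-target
table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import CohortLabels, ExpressionMatrix
from .pcpa import PCPAModel, predict_proba
from .pathways import PathwayCollection, TargetMap

logger = logging.getLogger(__name__)


@dataclass
class MOSReport:
    cancer: str
    mean_delta: dict  # marker -> mean change in prob_high over perturbed samples
    n_perturbed: dict  # marker -> number of low-OS samples below reference
    alternative_markers: list
    epsilon: float


@dataclass
class CommonGeneReport:
    category: str
    common_genes: set
    supporting_markers: dict = field(default_factory=dict)  # gene -> {cancer: [markers]}
    known_target_annotations: dict = field(default_factory=dict)  # gene -> [drugs]


def high_os_reference(
    train: ExpressionMatrix, labels: CohortLabels, markers: list, statistic: str = "mean"
) -> dict:
    """Reference expression level per marker: its average in high-OS training samples.

    ``statistic="median"`` is exposed as an alternative point estimate.
    """
    high = [s for s in train.sample_ids if labels.labels.get(s) == "high-OS"]
    if len(high) < 2:
        raise ValueError("need at least 2 high-OS training samples for a reference")
    missing = [m for m in markers if m not in set(train.feature_ids)]
    if missing:
        raise ValueError(f"markers absent from training matrix: {missing[:5]}")
    sub = train.data.loc[list(markers), high]
    levels = sub.median(axis=1) if statistic == "median" else sub.mean(axis=1)
    return levels.to_dict()


def mos_scan(
    model: PCPAModel,
    low_os_samples: ExpressionMatrix,
    markers: list,
    references: dict,
    epsilon: float = 1e-6,
    cancer: str = "",
) -> MOSReport:
    """Screen markers by counterfactual up-regulation of low-OS samples.

    Each marker is perturbed alternately (one at a time): samples below the
    marker's reference are set to it, the model re-scores, and the marker's
    ``mean_delta`` is the mean probability change over the perturbed
    samples. A marker is flagged alternative iff it perturbed at least one
    sample and ``mean_delta > epsilon``. Input matrices are never modified.
    """
    if low_os_samples.n_samples == 0:
        raise ValueError("no low-OS samples to perturb")
    baseline = predict_proba(model, low_os_samples)
    mean_delta: dict[str, float] = {}
    n_perturbed: dict[str, int] = {}
    flagged = []
    for marker in markers:
        ref = references[marker]
        row = low_os_samples.data.loc[marker]
        below = row < ref
        n = int(below.sum())
        n_perturbed[marker] = n
        if n == 0:
            mean_delta[marker] = 0.0
            continue
        perturbed = ExpressionMatrix(
            low_os_samples.data.copy(), low_os_samples.omic, low_os_samples.scale
        )
        perturbed.data.loc[marker, below] = ref
        after = predict_proba(model, perturbed)
        delta = float((after[below] - baseline[below]).mean())
        mean_delta[marker] = delta
        if delta > epsilon:
            flagged.append(marker)
    return MOSReport(
        cancer=cancer,
        mean_delta=mean_delta,
        n_perturbed=n_perturbed,
        alternative_markers=flagged,
        epsilon=epsilon,
    )


def category_common_genes(
    alternative_markers_by_cancer: dict,
    targets: TargetMap,
    pathways: PathwayCollection,
    taxonomy: dict,
) -> dict:
    """Common candidate genes per cancer category.

    For every category, intersect over member cancers the sets of genes
    targeted by that cancer's alternative markers, restricted to the union
    of the (unrefined) pathway gene sets. A single-cancer category's
    intersection is that cancer's own gene set (logged).
    """
    pathway_union = pathways.union()
    by_category: dict[str, list[str]] = {}
    for cancer in alternative_markers_by_cancer:
        cat = taxonomy.get(cancer)
        if cat is None:
            logger.warning("cancer %s missing from taxonomy; skipped", cancer)
            continue
        by_category.setdefault(cat, []).append(cancer)

    reports = {}
    for category, cancers in by_category.items():
        gene_sets = {}
        support: dict[str, dict[str, list[str]]] = {}
        for cancer in cancers:
            genes: set = set()
            for marker in alternative_markers_by_cancer[cancer]:
                hits = targets.genes_for(marker) & pathway_union
                genes |= hits
                for g in hits:
                    support.setdefault(g, {}).setdefault(cancer, []).append(marker)
            gene_sets[cancer] = genes
        if len(cancers) == 1:
            logger.info("category %s has a single cancer; common genes = its own set", category)
        common = set.intersection(*gene_sets.values()) if gene_sets else set()
        reports[category] = CommonGeneReport(
            category=category,
            common_genes=common,
            supporting_markers={g: support[g] for g in common},
        )
    return reports


def annotate_known_targets(genes: set, drug_target_table: pd.DataFrame) -> dict:
    """Left-join genes against a known drug-target table.

    The table needs ``gene`` and ``drug`` columns; unannotated genes are
    retained with an empty drug list.
    """
    lookup: dict[str, list[str]] = {}
    for g, d in drug_target_table[["gene", "drug"]].itertuples(index=False):
        lookup.setdefault(str(g), []).append(str(d))
    return {g: sorted(set(lookup.get(g, []))) for g in genes}
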