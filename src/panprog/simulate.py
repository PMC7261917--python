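"""Synthetic pan-cancer data with the structure the pipeline assumes.

The generator plants prognostic ncRNA markers whose expression enters an
exponential survival model, reproducing the two regimes the analysis is
built around: miRNA markers shared identically across every cancer type,
and lncRNA markers private to a single cancer type. It also fabricates a
miRNA -> target-gene map and a chain of partially overlapping pathway gene
sets, so every downstream stage (differential expression, classification,
survival evaluation, marker-sharing statistics, pathway regulation
profiling and the marker-oriented counterfactual screen) can be exercised
end to end without any external download.

Generative model
----------------
Expression for feature *f* in sample *i* is drawn on the log2 scale as
``x_fi ~ Normal(mu_f, expr_noise_sd)`` with ``mu_f`` drawn once per feature
from Uniform(3, 9). Survival time is exponential (Weibull with shape 1)
with per-sample log hazard

    log h_i = log(baseline_hazard) + sum_m s_m * beta * z_mi

over the planted markers *m*, where ``z`` is the feature's z-scored
expression and ``s_m`` is −1 for protective markers (high expression, long
survival) and +1 for hazardous ones. An independent exponential censoring
time with rate ``baseline_hazard * rate/(1-rate)`` yields an observed time
and event flag with expected censored fraction close to ``censoring_rate``.

All randomness derives from ``SimConfig.seed``; per-cancer streams are
derived by stable hashing of ``(seed, cancer_id)`` so adding a cancer does
not perturb the others.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .datatypes import ExpressionMatrix, MIRNA, LNCRNA, clinical_table

PROTECTIVE = "protective"
HAZARDOUS = "hazardous"


class ConfigurationError(ValueError):
    """Raised when a SimConfig requests an impossible dataset."""


@dataclass
class SimConfig:
    """Parameters of the synthetic pan-cancer dataset.

    Defaults describe a moderate pan-cancer study: four cancer types of 400
    samples, three pan-cancer miRNA markers plus one private lncRNA marker
    per cancer, a per-marker log-hazard coefficient of 1.0, and log2
    expression noise of 2.2 — a regime in which a planted marker's expected
    between-class log2 shift is about 1.5, large enough for the
    omic-specific detection gates while keeping per-feature dispersion in a
    realistic range.
    """

    n_cancers: int = 4
    samples_per_cancer: int = 400
    n_mirna: int = 150
    n_lncrna: int = 200
    n_shared_mirna_markers: int = 3
    n_specific_lncrna_markers_per_cancer: int = 1
    effect_size_beta: float = 1.0
    baseline_hazard: float = 1.0 / 1000.0  # events/day
    censoring_rate: float = 0.0
    expr_noise_sd: float = 2.2
    n_genes: int = 300
    targets_per_mirna: int = 10
    n_pathways: int = 8
    pathway_size: int = 20
    pathway_overlap: int = 3  # genes shared between consecutive pathways
    seed: int = 0
    weibull_shape: float = 1.0
    emit_linear: bool = False

    def validate(self) -> None:
        counts = {
            "n_cancers": self.n_cancers,
            "samples_per_cancer": self.samples_per_cancer,
            "n_mirna": self.n_mirna,
            "n_lncrna": self.n_lncrna,
        }
        for name, value in counts.items():
            if value <= 0:
                raise ConfigurationError(f"{name} must be positive, got {value}")
        if self.n_shared_mirna_markers < 0 or self.n_specific_lncrna_markers_per_cancer < 0:
            raise ConfigurationError("marker counts must be >= 0")
        if self.n_shared_mirna_markers > self.n_mirna:
            raise ConfigurationError("n_shared_mirna_markers exceeds n_mirna")
        if self.n_cancers * self.n_specific_lncrna_markers_per_cancer > self.n_lncrna:
            raise ConfigurationError(
                "cannot allocate disjoint cancer-specific lncRNA markers: "
                f"{self.n_cancers} x {self.n_specific_lncrna_markers_per_cancer} > {self.n_lncrna}"
            )
        if not 0.0 <= self.censoring_rate <= 1.0:
            raise ConfigurationError("censoring_rate must lie in [0, 1]")
        if self.baseline_hazard <= 0 or self.expr_noise_sd <= 0:
            raise ConfigurationError("baseline_hazard and expr_noise_sd must be positive")
        if self.pathway_overlap >= self.pathway_size:
            raise ConfigurationError("pathway_overlap must be smaller than pathway_size")
        union = self.n_pathways * self.pathway_size - (self.n_pathways - 1) * self.pathway_overlap
        if self.n_genes < union:
            raise ConfigurationError(
                f"n_genes={self.n_genes} cannot host the pathway union of {union} genes"
            )

    def cancer_ids(self) -> list[str]:
        return [f"C{i:02d}" for i in range(1, self.n_cancers + 1)]


@dataclass
class GroundTruth:
    """What was planted: marker identities, directions, targets, pathways."""

    planted_markers: dict  # cancer -> {"miRNA": [...], "lncRNA": [...]}
    marker_direction: dict  # marker -> PROTECTIVE / HAZARDOUS
    target_map_truth: dict = field(default_factory=dict)  # miRNA -> set of genes
    pathway_truth: dict = field(default_factory=dict)  # pathway name -> set of genes

    def markers_for(self, cancer: str, omic: str) -> list[str]:
        return list(self.planted_markers[cancer][omic])

    def protective_mirnas(self, cancer: str) -> list[str]:
        return [
            m
            for m in self.planted_markers[cancer][MIRNA]
            if self.marker_direction[m] == PROTECTIVE
        ]


@dataclass
class CohortBundle:
    """One cancer's simulated data."""

    cancer: str
    mirna: ExpressionMatrix
    lncrna: ExpressionMatrix
    clinical: pd.DataFrame


def _stream(seed: int, tag: str) -> np.random.Generator:
    """Deterministic per-tag RNG stream derived from the root seed."""
    return np.random.default_rng(np.random.SeedSequence([seed, zlib.crc32(tag.encode())]))


def _feature_names(prefix: str, n: int) -> list[str]:
    return [f"{prefix}-{i:04d}" for i in range(1, n + 1)]


def planted_allocation(config: SimConfig) -> GroundTruth:
    """Assign marker identities and directions; a pure function of the config.

    Shared miRNA markers carry the same identity in every cancer; each
    cancer's lncRNA markers are disjoint from every other cancer's.
    Directions alternate protective/hazardous along the combined ordered
    marker list, so planted markers split as evenly as possible.
    """
    config.validate()
    rng = _stream(config.seed, "marker-allocation")
    mirnas = _feature_names("miR", config.n_mirna)
    lncrnas = _feature_names("lnc", config.n_lncrna)

    shared = sorted(str(m) for m in rng.choice(mirnas, size=config.n_shared_mirna_markers, replace=False))
    k = config.n_specific_lncrna_markers_per_cancer
    pool = [str(m) for m in rng.choice(lncrnas, size=config.n_cancers * k, replace=False)]

    planted = {}
    ordered: list[str] = list(shared)
    for j, cancer in enumerate(config.cancer_ids()):
        specific = sorted(pool[j * k : (j + 1) * k])
        planted[cancer] = {MIRNA: list(shared), LNCRNA: specific}
        ordered.extend(specific)
    direction = {m: (PROTECTIVE if i % 2 == 0 else HAZARDOUS) for i, m in enumerate(ordered)}
    return GroundTruth(planted_markers=planted, marker_direction=direction)


def simulate_cancer_cohort(
    config: SimConfig,
    cancer_id: str,
    rng: np.random.Generator | None = None,
    truth: GroundTruth | None = None,
) -> tuple[ExpressionMatrix, ExpressionMatrix, pd.DataFrame, GroundTruth]:
    """Simulate one cancer's expression matrices and clinical table.

    The marker allocation is a function of the config alone, so calling this
    per cancer or through :func:`simulate_pan_cancer` yields the same data.
    Returns the miRNA matrix, lncRNA matrix, clinical table, and the
    ground-truth slice for this cancer.
    """
    config.validate()
    if truth is None:
        truth = planted_allocation(config)
    if cancer_id not in truth.planted_markers:
        raise ConfigurationError(f"unknown cancer_id {cancer_id!r}")
    if rng is None:
        rng = _stream(config.seed, f"cohort:{cancer_id}")

    n = config.samples_per_cancer
    samples = [f"{cancer_id}-S{i:04d}" for i in range(1, n + 1)]
    matrices = {}
    zscores = {}
    for omic, prefix, n_feat in ((MIRNA, "miR", config.n_mirna), (LNCRNA, "lnc", config.n_lncrna)):
        features = _feature_names(prefix, n_feat)
        mu = rng.uniform(3.0, 9.0, size=n_feat)
        noise = rng.standard_normal((n_feat, n))
        values = mu[:, None] + config.expr_noise_sd * noise
        values = np.clip(values, 0.0, None)  # expression is nonnegative on the log2(x+1) scale
        df = pd.DataFrame(values, index=features, columns=samples)
        matrices[omic] = df
        # hazard uses the exact z-score of the generated values
        z = (values - values.mean(axis=1, keepdims=True)) / values.std(axis=1, keepdims=True)
        zscores[omic] = pd.DataFrame(z, index=features, columns=samples)

    log_hazard = np.full(n, np.log(config.baseline_hazard))
    for omic in (MIRNA, LNCRNA):
        for marker in truth.planted_markers[cancer_id][omic]:
            sign = -config.effect_size_beta if truth.marker_direction[marker] == PROTECTIVE else config.effect_size_beta
            log_hazard = log_hazard + sign * zscores[omic].loc[marker].to_numpy()

    hazard = np.exp(log_hazard)
    event_time = (rng.exponential(1.0, size=n) / hazard) ** (1.0 / config.weibull_shape)
    if config.censoring_rate > 0:
        if config.censoring_rate >= 1.0:
            censor_time = np.zeros(n)
        else:
            c_rate = config.baseline_hazard * config.censoring_rate / (1.0 - config.censoring_rate)
            censor_time = rng.exponential(1.0 / c_rate, size=n)
        observed = np.minimum(event_time, censor_time)
        event = (event_time <= censor_time).astype(int)
    else:
        observed, event = event_time, np.ones(n, dtype=int)
    observed = np.maximum(observed, 1e-6)  # os_days must stay positive

    clinical = clinical_table(samples, observed, event=event, sample_type_code=["01"] * n)

    scale = "log2p1"
    if config.emit_linear:
        for omic in matrices:
            matrices[omic] = np.exp2(matrices[omic]) - 1.0
        scale = "linear"
    mirna = ExpressionMatrix(matrices[MIRNA], MIRNA, scale)
    lncrna = ExpressionMatrix(matrices[LNCRNA], LNCRNA, scale)
    return mirna, lncrna, clinical, truth


def simulate_pathways_and_targets(
    config: SimConfig, rng: np.random.Generator | None = None
) -> tuple[dict, dict]:
    """Build the chain-overlap pathway collection and the miRNA target map.

    Consecutive pathways share exactly ``pathway_overlap`` genes; every
    planted miRNA marker's target set contains at least one gene unique to
    a single pathway, so refined regulation fractions are nonzero by
    construction. Returns ``(pathways, target_map)`` as plain dicts of
    name -> ordered gene list and miRNA -> ordered gene list.
    """
    config.validate()
    if rng is None:
        rng = _stream(config.seed, "pathways-targets")
    genes = _feature_names("GENE", config.n_genes)
    step = config.pathway_size - config.pathway_overlap
    pathways = {}
    for p in range(config.n_pathways):
        start = p * step
        pathways[f"PW{p + 1:02d}"] = genes[start : start + config.pathway_size]

    # genes belonging to exactly one pathway
    from collections import Counter

    multiplicity = Counter(g for gs in pathways.values() for g in gs)
    unique_pool = [g for gs in pathways.values() for g in gs if multiplicity[g] == 1]

    truth = planted_allocation(config)
    planted_mirnas = set()
    for cancer in config.cancer_ids():
        planted_mirnas.update(truth.planted_markers[cancer][MIRNA])

    target_map = {}
    for mirna in _feature_names("miR", config.n_mirna):
        picks = list(rng.choice(genes, size=config.targets_per_mirna, replace=False))
        if mirna in planted_mirnas and not any(g in unique_pool and multiplicity[g] == 1 for g in picks):
            picks[-1] = unique_pool[int(rng.integers(len(unique_pool)))]
        target_map[mirna] = sorted(set(picks))
    return pathways, target_map


@dataclass
class PanCancerDataset:
    cohorts: dict  # cancer -> CohortBundle
    truth: GroundTruth
    target_map: dict
    pathways: dict
    config: SimConfig


def simulate_pan_cancer(config: SimConfig) -> PanCancerDataset:
    """Simulate every cancer cohort plus the shared target map and pathways."""
    config.validate()
    truth = planted_allocation(config)
    pathways, target_map = simulate_pathways_and_targets(config)
    truth.pathway_truth = {name: set(gs) for name, gs in pathways.items()}
    truth.target_map_truth = {m: set(gs) for m, gs in target_map.items()}
    cohorts = {}
    for cancer in config.cancer_ids():
        mirna, lncrna, clinical, _ = simulate_cancer_cohort(config, cancer, truth=truth)
        cohorts[cancer] = CohortBundle(cancer, mirna, lncrna, clinical)
    return PanCancerDataset(cohorts, truth, target_map, pathways, config)


def write_pan_cancer(dataset: PanCancerDataset, outdir) -> None:
    """Serialize a dataset in the TSV/GMT/JSON dialects the readers consume."""
    import json
    from pathlib import Path

    from .ingest import write_expression_tsv
    from .pathways import write_gmt

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    for cancer, bundle in dataset.cohorts.items():
        write_expression_tsv(bundle.mirna, out / f"{cancer}_mirna.tsv")
        write_expression_tsv(bundle.lncrna, out / f"{cancer}_lncrna.tsv")
        bundle.clinical.to_csv(out / f"{cancer}_clinical.tsv", sep="\t", index=False)
    write_gmt(dataset.pathways, out / "pathways.gmt")
    edges = [(m, g) for m, gs in sorted(dataset.target_map.items()) for g in gs]
    pd.DataFrame(edges, columns=["mirna", "gene"]).to_csv(
        out / "targets.tsv", sep="\t", index=False
    )
    truth = {
        "planted_markers": dataset.truth.planted_markers,
        "marker_direction": dataset.truth.marker_direction,
        "target_map_truth": {m: sorted(gs) for m, gs in dataset.truth.target_map_truth.items()},
        "pathway_truth": {p: sorted(gs) for p, gs in dataset.truth.pathway_truth.items()},
        "config": asdict(dataset.config),
    }
    (out / "ground_truth.json").write_text(json.dumps(truth, indent=2, sort_keys=True))
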