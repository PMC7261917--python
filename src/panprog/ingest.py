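"""Reading and pre-processing of expression and clinical inputs.

Pre-processing follows the order used for the TCGA-style inputs this
pipeline targets: drop features with any missing value, then samples;
sum isoforms per mature strand and log-transform; average rows that
collapse to the same ID; intersect with clinical samples carrying an
overall-survival value; remove normal-tissue samples by TCGA barcode
sample-type code; and label each sample high-OS/low-OS against the
cohort's median overall survival (strictly greater than the median is
high-OS; ties fall to low-OS).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .datatypes import (
    HIGH_OS,
    LOW_OS,
    MERGED,
    CohortLabels,
    ExpressionMatrix,
    FormatError,
)

logger = logging.getLogger(__name__)

_NA_TOKENS = ["NA", "na", "NaN", "nan", ""]


def read_expression_tsv(
    path,
    omic: str = "miRNA",
    orientation: str = "features-in-rows",
    scale: str = "log2p1",
) -> ExpressionMatrix:
    """Read an expression TSV into canonical features x samples orientation.

    The first column holds feature IDs (Xena-style); ``orientation=
    "samples-in-rows"`` reads the transpose. ``scale="linear"`` applies
    log2(x+1) after reading. Tokens ``NA`` and empty cells become missing
    values; any other non-numeric cell is a format error.
    """
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
    if len(set(header)) != len(header):
        dup = sorted({h for h in header if header.count(h) > 1})
        raise FormatError(f"duplicate sample IDs in header: {dup[:5]}")
    raw = pd.read_csv(
        path, sep="\t", index_col=0, na_values=_NA_TOKENS, keep_default_na=False, dtype=str
    )
    try:
        df = raw.apply(pd.to_numeric)
    except (ValueError, TypeError) as exc:
        raise FormatError(f"non-numeric cell in {path}: {exc}") from exc
    if orientation == "samples-in-rows":
        df = df.T
    elif orientation != "features-in-rows":
        raise ValueError(f"unknown orientation {orientation!r}")
    df.index = df.index.astype(str).rename("feature")
    df.columns = df.columns.astype(str).rename(None)
    if scale == "linear":
        if (df < 0).any().any():
            raise FormatError("negative value in linear-scale input")
        df = np.log2(df + 1.0)
        scale = "log2p1"
    elif scale != "log2p1":
        raise ValueError(f"unknown scale {scale!r}")
    return ExpressionMatrix(df, omic=omic, scale=scale)


def write_expression_tsv(matrix: ExpressionMatrix, path) -> None:
    df = matrix.data.copy()
    df.index.name = "feature"
    df.to_csv(path, sep="\t", float_format="%.10g")


def read_clinical_tsv(path) -> pd.DataFrame:
    """Read a clinical TSV with columns sample, os_days[, event, sample_type_code]."""
    tab = pd.read_csv(path, sep="\t", na_values=_NA_TOKENS, keep_default_na=False,
                      dtype={"sample": str})
    if "sample" not in tab.columns or "os_days" not in tab.columns:
        raise FormatError("clinical table needs 'sample' and 'os_days' columns")
    tab["os_days"] = pd.to_numeric(tab["os_days"], errors="coerce")
    if "sample_type_code" in tab.columns:
        tab["sample_type_code"] = tab["sample_type_code"].astype(str).str.zfill(2)
    return tab


def filter_missing(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Drop features with any missing value, then samples with any remaining.

    Features go first, so a sample is only dropped for missing values in
    features that survived the first pass. Idempotent; emits a warning when
    everything is filtered away.
    """
    df = matrix.data
    df = df.loc[~df.isna().any(axis=1)]
    df = df.loc[:, ~df.isna().any(axis=0)]
    if df.shape[0] == 0 or df.shape[1] == 0:
        logger.warning("filter_missing removed every feature or sample")
    return ExpressionMatrix(df, matrix.omic, matrix.scale)


def aggregate_isoforms(isoform_matrix: ExpressionMatrix, isoform_to_mature: dict) -> ExpressionMatrix:
    """Sum linear-scale isoform rows per mature strand, then log2(x+1).

    Isoforms without a mapping are dropped with a logged warning.
    """
    if isoform_matrix.scale != "linear":
        raise ValueError("aggregate_isoforms expects a linear-scale matrix")
    df = isoform_matrix.data
    unmapped = [f for f in df.index if f not in isoform_to_mature]
    if unmapped:
        logger.warning("dropping %d unmapped isoforms (e.g. %s)", len(unmapped), unmapped[:3])
    mapped = df.loc[[f for f in df.index if f in isoform_to_mature]]
    grouped = mapped.groupby([isoform_to_mature[f] for f in mapped.index], sort=True).sum()
    grouped.index = grouped.index.astype(str)
    return ExpressionMatrix(np.log2(grouped + 1.0), isoform_matrix.omic, "log2p1")


def collapse_duplicate_ids(matrix: ExpressionMatrix, accession_to_id: dict) -> ExpressionMatrix:
    """Rename rows via the map and average rows sharing a final ID.

    Averaging happens on the stored (log) scale, per sample. Accessions
    absent from the map keep their original identifier.
    """
    new_ids = [accession_to_id.get(f, f) for f in matrix.data.index]
    collapsed = matrix.data.groupby(new_ids, sort=False).mean()
    collapsed.index = collapsed.index.astype(str)
    return ExpressionMatrix(collapsed, matrix.omic, matrix.scale)


def align_with_clinical(
    matrix: ExpressionMatrix, clinical: pd.DataFrame
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Restrict to tumor samples present in both inputs with a known OS.

    Clinical rows with a missing ``os_days`` are removed before the
    intersection; when a ``sample_type_code`` column is present, only TCGA
    tumor codes 01-09 are retained. Outputs share an identical sample order
    (the matrix's column order).
    """
    clin = clinical.loc[clinical["os_days"].notna()].copy()
    if "sample_type_code" in clin.columns:
        codes = clin["sample_type_code"].astype(str).str.zfill(2)
        clin = clin.loc[codes.isin([f"{i:02d}" for i in range(1, 10)])]
    clin = clin.drop_duplicates(subset="sample", keep="first").set_index("sample")
    kept = [s for s in matrix.sample_ids if s in clin.index]
    if not kept:
        raise ValueError("no samples shared between expression matrix and clinical table")
    out_clin = clin.loc[kept].reset_index()
    return matrix.subset_samples(kept), out_clin


def label_by_median_os(clinical: pd.DataFrame) -> CohortLabels:
    """Split samples at the cohort's median overall survival.

    high-OS iff ``os_days`` strictly exceeds the median (midpoint of the two
    central order statistics for even n); ties at the median are low-OS.
    """
    os_days = clinical["os_days"].astype(float)
    if len(os_days) < 2:
        raise ValueError("need at least 2 samples to label by median OS")
    median = float(np.median(os_days))
    labels = pd.Series(
        np.where(os_days > median, HIGH_OS, LOW_OS),
        index=pd.Index(clinical["sample"], name="sample"),
    )
    if (labels == LOW_OS).all():
        logger.warning("all samples labeled low-OS (no OS exceeds the median)")
    return CohortLabels(median_os=median, labels=labels)


def merge_omics(mirna: ExpressionMatrix, lncrna: ExpressionMatrix) -> ExpressionMatrix:
    """Row-concatenate the two omics over their sample intersection."""
    collisions = set(mirna.feature_ids) & set(lncrna.feature_ids)
    if collisions:
        raise ValueError(f"feature namespaces collide: {sorted(collisions)[:5]}")
    shared = [s for s in mirna.sample_ids if s in set(lncrna.sample_ids)]
    if not shared:
        raise ValueError("no samples shared between the two omics")
    merged = pd.concat([mirna.data[shared], lncrna.data[shared]], axis=0)
    return ExpressionMatrix(merged, MERGED, mirna.scale)
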