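"""Core in-memory containers shared across the pipeline.

Expression data lives in a pandas DataFrame in canonical features x samples
orientation; thin dataclasses carry the omic tag, scale, and validated
invariants alongside it. Clinical tables are plain DataFrames with the
columns ``sample``, ``os_days`` and optionally ``event`` /
``sample_type_code``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

HIGH_OS = "high-OS"
LOW_OS = "low-OS"

#: omic tags
MIRNA = "miRNA"
LNCRNA = "lncRNA"
MERGED = "merged"


class FormatError(ValueError):
    """Raised when an input file violates the expected dialect."""


@dataclass
class ExpressionMatrix:
    """A features x samples expression matrix for one omic.

    Parameters
    ----------
    data : DataFrame
        Rows are features, columns are samples. Values are log2(x+1)
        unless ``scale`` says otherwise.
    omic : str
        One of ``miRNA``, ``lncRNA`` or ``merged``.
    scale : str
        ``log2p1`` (default) or ``linear``.
    """

    data: pd.DataFrame
    omic: str = MIRNA
    scale: str = "log2p1"

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            dup = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise FormatError(f"duplicate feature IDs: {dup[:5]}")
        if self.data.columns.has_duplicates:
            dup = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise FormatError(f"duplicate sample IDs: {dup[:5]}")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_features(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def has_missing(self) -> bool:
        return bool(self.data.isna().any().any())

    def subset_features(self, features) -> "ExpressionMatrix":
        return ExpressionMatrix(self.data.loc[list(features)], self.omic, self.scale)

    def subset_samples(self, samples) -> "ExpressionMatrix":
        return ExpressionMatrix(self.data[list(samples)], self.omic, self.scale)


@dataclass
class CohortLabels:
    """Per-sample prognosis class from the cohort's median overall survival."""

    median_os: float
    labels: pd.Series  # sample id -> HIGH_OS / LOW_OS

    @property
    def high_samples(self) -> list[str]:
        return list(self.labels.index[self.labels == HIGH_OS])

    @property
    def low_samples(self) -> list[str]:
        return list(self.labels.index[self.labels == LOW_OS])

    def for_samples(self, samples) -> pd.Series:
        return self.labels.loc[list(samples)]


@dataclass
class MarkerSet:
    """Prognosis-related ncRNA markers detected for one cancer and omic."""

    cancer: str
    omic: str
    markers: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(set(self.markers)) != len(self.markers):
            raise ValueError("marker IDs must be unique")

    def __len__(self) -> int:
        return len(self.markers)

    def __iter__(self):
        return iter(self.markers)


def clinical_table(sample_ids, os_days, event=None, sample_type_code=None) -> pd.DataFrame:
    """Assemble a clinical DataFrame with the canonical column names."""
    tab = pd.DataFrame({"sample": list(sample_ids), "os_days": np.asarray(os_days, dtype=float)})
    if event is not None:
        tab["event"] = np.asarray(event, dtype=int)
    if sample_type_code is not None:
        tab["sample_type_code"] = list(sample_type_code)
    return tab
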