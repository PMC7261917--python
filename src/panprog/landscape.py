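"""Cross-cancer marker sharing: incidence, summary fractions, and ranking.

A marker is *shared* when it appears in at least two cancer types and
*cancer-specific* when it appears in exactly one. The analysis contrasts
the two omics: miRNA markers tend to recur across cancers while lncRNA
markers tend to be private to one.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .datatypes import MarkerSet


@dataclass
class IncidenceMatrix:
    """Binary marker x cancer membership with an omic tag per marker."""

    membership: pd.DataFrame  # markers x cancers, 0/1
    omic: pd.Series  # marker -> omic tag

    def row_sums(self) -> pd.Series:
        return self.membership.sum(axis=1)

    def for_omic(self, omic: str) -> pd.DataFrame:
        return self.membership.loc[self.omic[self.omic == omic].index]


def build_incidence(marker_sets: list[MarkerSet]) -> IncidenceMatrix:
    """Union all marker sets into a deduplicated incidence matrix.

    A cancer may contribute one set per omic (marker namespaces are
    disjoint); duplicate (cancer, omic) pairs are an error.
    """
    keys = [(ms.cancer, ms.omic) for ms in marker_sets]
    if len(set(keys)) != len(keys):
        raise ValueError("duplicate (cancer, omic) marker sets")
    cancers = list(dict.fromkeys(ms.cancer for ms in marker_sets))
    markers: dict[str, str] = {}
    for ms in marker_sets:
        for m in ms.markers:
            markers.setdefault(m, ms.omic)
    index = list(markers)
    membership = pd.DataFrame(0, index=index, columns=cancers, dtype=int)
    for ms in marker_sets:
        if ms.markers:
            membership.loc[list(ms.markers), ms.cancer] = 1
    return IncidenceMatrix(membership=membership, omic=pd.Series(markers, dtype=object))


def sharing_summary(incidence: IncidenceMatrix) -> dict:
    """Per-omic counts and fractions of shared vs cancer-specific markers."""
    if incidence.membership.empty:
        raise ValueError("incidence matrix is empty")
    out = {}
    sums = incidence.row_sums()
    for omic in incidence.omic.unique():
        rows = sums.loc[incidence.omic[incidence.omic == omic].index]
        n_total = int(len(rows))
        n_shared = int((rows >= 2).sum())
        n_specific = int((rows == 1).sum())
        out[omic] = {
            "n_total": n_total,
            "n_shared": n_shared,
            "shared_fraction": n_shared / n_total if n_total else 0.0,
            "n_specific": n_specific,
            "specific_fraction": n_specific / n_total if n_total else 0.0,
        }
    return out


def rank_markers(incidence: IncidenceMatrix, k: int = 20) -> dict:
    """Top-k markers per omic by the number of associated cancer types.

    Ties break lexicographically by marker ID. Returns, per omic, an
    ordered list of (marker, cancer count) pairs.
    """
    out = {}
    sums = incidence.row_sums()
    for omic in incidence.omic.unique():
        rows = sums.loc[incidence.omic[incidence.omic == omic].index]
        ranked = sorted(rows.items(), key=lambda kv: (-kv[1], kv[0]))
        out[omic] = [(m, int(c)) for m, c in ranked[:k]]
    return out


def category_sharing_summary(incidence: IncidenceMatrix, taxonomy: dict) -> dict:
    """Sharing fractions at the cancer-category level.

    A marker is category-shared when its cancers span >= 2 categories of
    the supplied cancer-type -> category taxonomy.
    """
    out = {}
    for omic in incidence.omic.unique():
        rows = incidence.for_omic(omic)
        n_total = len(rows)
        n_shared = 0
        for _, row in rows.iterrows():
            cats = {taxonomy[c] for c in row.index[row == 1] if c in taxonomy}
            if len(cats) >= 2:
                n_shared += 1
        out[omic] = {
            "n_total": int(n_total),
            "n_category_shared": int(n_shared),
            "category_shared_fraction": n_shared / n_total if n_total else 0.0,
        }
    return out
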