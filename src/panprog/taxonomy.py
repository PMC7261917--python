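"""Bundled reference tables: the cancer-type taxonomy and known drug targets.

The taxonomy maps the 19 TCGA solid-tumor cohort codes onto nine cancer
categories (urologic, gynecologic, core GI, developmental GI, thoracic,
CNS, head and neck, endocrine, melanocytic). The drug-target table lists
published gene -> approved-drug associations for the marquee targets the
pan-cancer screen surfaces (EGFR, VEGFA, BCL2, ...).
"""

from __future__ import annotations

from importlib import resources

import pandas as pd


def _data_path(name: str):
    return resources.files("panprog.data") / name


def load_cancer_categories() -> dict:
    """Cancer-type code -> category name for the 19 solid-tumor cohorts."""
    tab = pd.read_csv(_data_path("cancer_categories.tsv"), sep="\t")
    return dict(zip(tab["cancer_type"], tab["category"]))


def load_known_drug_targets() -> pd.DataFrame:
    """Known drug-target table with ``gene`` and ``drug`` columns."""
    return pd.read_csv(_data_path("known_drug_targets.tsv"), sep="\t")


def load_canonical_pathways():
    """The bundled eight-pathway GMT (synthetic gene membership).

    Pathway names follow the eight canonical cancer signaling pathways
    (PI3K, MAPK, cell cycle, Wnt, p53, Hippo, TGF-beta, Notch); the gene
    lists are a compact synthetic stand-in assembled from well-known
    member genes, not a KEGG export.
    """
    from .pathways import read_gmt

    return read_gmt(_data_path("canonical_pathways_synthetic.gmt"))
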