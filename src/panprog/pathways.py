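"""Pathway gene sets, their gene-specific refinement, and regulation profiles.

The refinement removes every gene occurring in two or more of the supplied
gene sets, leaving pairwise-disjoint, pathway-specific cores. Regulation is
then quantified as the fraction of a cancer's miRNA markers with at least
one annotated target inside a (refined) pathway, and per gene as the
fraction of markers targeting it, gated at a configurable threshold.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field

import pandas as pd

from .datatypes import FormatError, MarkerSet

logger = logging.getLogger(__name__)


@dataclass
class PathwayCollection:
    """Named gene sets; ``refined`` marks the pairwise-disjoint state."""

    sets: dict  # name -> set of gene symbols
    refined: bool = False

    def __post_init__(self) -> None:
        self.sets = {name: set(genes) for name, genes in self.sets.items()}
        if self.refined:
            self._check_disjoint()

    def _check_disjoint(self) -> None:
        counts = Counter(g for gs in self.sets.values() for g in gs)
        dup = [g for g, c in counts.items() if c > 1]
        if dup:
            raise ValueError(f"refined collection is not disjoint: {sorted(dup)[:5]}")

    def union(self) -> set:
        return set().union(*self.sets.values()) if self.sets else set()

    def __len__(self) -> int:
        return len(self.sets)


@dataclass
class TargetMap:
    """miRNA -> set of target gene symbols."""

    targets: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.targets = {m: set(gs) for m, gs in self.targets.items() if gs}

    def genes_for(self, mirna: str) -> set:
        return self.targets.get(mirna, set())

    def __len__(self) -> int:
        return len(self.targets)


def read_gmt(path) -> PathwayCollection:
    """Read a GMT file (name, description, genes per tab-separated line)."""
    sets = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line needs name, description, >=1 gene")
            name, genes = fields[0], [g for g in fields[2:] if g]
            if not genes:
                raise FormatError(f"{path}:{lineno}: empty gene list for {name}")
            sets[name] = set(genes)
    return PathwayCollection(sets=sets, refined=False)


def write_gmt(sets: dict, path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for name in sets:
            genes = sorted(sets[name])
            fh.write("\t".join([name, description, *genes]) + "\n")


def read_target_map(path) -> TargetMap:
    """Read a two-column TSV edge list (mirna<TAB>gene); edges are unioned."""
    tab = pd.read_csv(path, sep="\t")
    cols = list(tab.columns[:2])
    targets: dict[str, set] = {}
    for m, g in tab[cols].itertuples(index=False):
        targets.setdefault(str(m), set()).add(str(g))
    return TargetMap(targets=targets)


def refine_pathways(collection: PathwayCollection) -> PathwayCollection:
    """Remove every gene present in >= 2 sets, leaving disjoint cores.

    A set that becomes empty is retained (with a warning) so pathway names
    survive refinement.
    """
    if collection.refined:
        raise ValueError("collection is already refined")
    counts = Counter(g for gs in collection.sets.values() for g in gs)
    refined = {
        name: {g for g in genes if counts[g] == 1} for name, genes in collection.sets.items()
    }
    for name, genes in refined.items():
        if not genes:
            logger.warning("pathway %s is empty after refinement", name)
    return PathwayCollection(sets=refined, refined=True)


def marker_regulation_fraction(markers: MarkerSet, targets: TargetMap, pathway: set) -> float:
    """Fraction of the cancer's miRNA markers with >= 1 target in the pathway.

    Markers without any annotated target stay in the denominator and
    regulate nothing.
    """
    if len(markers) == 0:
        raise ValueError("marker set is empty")
    pathway = set(pathway)
    hits = sum(1 for m in markers if targets.genes_for(m) & pathway)
    return hits / len(markers)


def regulation_profile(
    marker_sets: list[MarkerSet], targets: TargetMap, refined: PathwayCollection
) -> pd.DataFrame:
    """Cancer x pathway table of marker regulation fractions."""
    if not refined.refined:
        raise ValueError("regulation profiles require a refined collection")
    rows = {}
    for ms in marker_sets:
        rows[ms.cancer] = {
            name: marker_regulation_fraction(ms, targets, genes)
            for name, genes in refined.sets.items()
        }
    return pd.DataFrame.from_dict(rows, orient="index")


def gene_regulation_profile(
    markers: MarkerSet, targets: TargetMap, pathway: set, min_fraction: float = 0.07
) -> dict:
    """Per-gene regulation fractions within one refined pathway.

    For each pathway gene, the fraction of the cancer's miRNA markers
    targeting it; only genes strictly above ``min_fraction`` are returned.
    """
    n = len(markers)
    if n == 0:
        return {}
    out = {}
    for gene in pathway:
        frac = sum(1 for m in markers if gene in targets.genes_for(m)) / n
        if frac > min_fraction:
            out[gene] = frac
    return out


def map_lncrna_symbols(markers: MarkerSet, mapping: dict) -> tuple[list[str], list[str]]:
    """Translate lncRNA marker IDs to gene symbols.

    Returns (deduplicated symbols in first-seen order, unmapped IDs) —
    unmapped markers are reported, never silently dropped.
    """
    symbols: list[str] = []
    unmapped: list[str] = []
    seen = set()
    for m in markers:
        if m in mapping:
            sym = mapping[m]
            if sym not in seen:
                seen.add(sym)
                symbols.append(sym)
        else:
            unmapped.append(m)
    return symbols, unmapped
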