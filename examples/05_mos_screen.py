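"""Counterfactual marker screen (MOS) and common candidate drug-target genes.

For each cancer, raises each miRNA marker's expression in held-out low-OS
samples to its high-OS training mean and re-scores the naive-Bayes model;
markers that increase the predicted high-OS probability are flagged
prognosis-alternative. Member cancers of a category are then intersected
for common pathway genes targeted by those markers, annotated against the
bundled known drug-target table.
"""

from panprog import (
    PathwayCollection,
    SimConfig,
    TargetMap,
    analyze_pan_cancer,
    annotate_known_targets,
    category_common_genes,
    load_known_drug_targets,
    simulate_pan_cancer,
)

dataset = simulate_pan_cancer(SimConfig(seed=9))
results = analyze_pan_cancer(dataset, rng_seed=9)

alternative = {}
for cancer, res in results.items():
    protective = set(dataset.truth.protective_mirnas(cancer))
    flagged = res.mos.alternative_markers
    alternative[cancer] = flagged
    print(f"{cancer}: {len(flagged)} prognosis-alternative miRNAs "
          f"(planted protective recovered: {len(protective & set(flagged))}/{len(protective)})")

# group the simulated cancers into two categories for the intersection step
taxonomy = {c: ("category-A" if i < 2 else "category-B")
            for i, c in enumerate(dataset.cohorts)}
reports = category_common_genes(
    alternative, TargetMap(dataset.target_map), PathwayCollection(dataset.pathways), taxonomy
)
drug_table = load_known_drug_targets()
for category, rep in reports.items():
    annotated = annotate_known_targets(rep.common_genes, drug_table)
    print(f"{category}: {len(rep.common_genes)} common pathway genes "
          f"targeted by alternative markers in all member cancers")

# Protective planted markers are flagged because their high-OS class mean
# exceeds the low-OS mean, so the counterfactual up-shift provably raises
# the NB posterior; hazardous and null markers are left unflagged.
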