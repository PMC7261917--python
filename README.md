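# panprog

Pan-cancer prognosis analysis of non-coding RNA expression.

`panprog` is a tested, reusable implementation of a pan-cancer prognosis
workflow for bulk miRNA/lncRNA expression with clinical overall survival
(OS). For each cancer type it:

1. **labels** every sample high-OS or low-OS against the cohort's median
   overall survival (high-OS iff OS strictly exceeds the median);
2. **detects prognosis-related markers** by two-tailed Welch *t*-tests
   between the OS classes with omic-specific gates — miRNA: *P* < 0.05;
   lncRNA: *P* < 0.01 together with a linear-scale fold change FC ≥ 2 or
   FC ≤ 0.5 — plus an optional factor-analysis reduction for small cohorts;
3. **splits** the cohort by *spatial subset sampling*: within each OS class,
   a greedy farthest-point ordering from a random seed sample sends the
   first two-thirds (the most dispersed subset) to training;
4. **classifies** prognosis with a Gaussian naive-Bayes model
   (logistic-regression, SVM and neural-network adapters are available),
   evaluated by held-out ROC/AUC;
5. **compares survival** of the predicted groups with Kaplan–Meier curves
   and the two-group log-rank test;
6. **contrasts marker sharing** across cancer types (markers in ≥ 2 types
   are *shared*, in exactly 1 *cancer-specific*) — the regime where miRNA
   markers recur across cancers while lncRNA markers stay private;
7. **profiles pathway regulation**: eight canonical cancer pathways are
   refined to disjoint pathway-specific gene cores, and each cancer's
   miRNA markers are scored by the fraction with ≥ 1 annotated target in
   each core, with per-gene profiles above a 7 % (or 5 %) gate;
8. **screens markers counterfactually** (the Marker-Oriented Simulation,
   MOS): each miRNA marker's expression in held-out low-OS samples is
   raised to its high-OS training mean and the model re-scored; markers
   that increase the predicted high-OS probability are flagged
   *prognosis-alternative*, and the pathway genes they target are
   intersected across the cancers of a category into common candidate
   drug targets.

A synthetic pan-cancer generator (`panprog.simulate`) plants markers whose
expression enters an exponential survival model — shared miRNA markers
identical across all cancers, lncRNA markers private to one — so the whole
pipeline is testable end to end without any external download.

## The model in brief

Expression is stored as log2(x+1). For feature *f* and sample *i* the
generator draws x_fi ~ N(μ_f, σ²) and couples survival to the planted
markers through an exponential time-to-event model with per-sample hazard

    log h_i = log h₀ + Σ_m s_m · β · z_mi ,

where z is the marker's z-scored expression and s_m = −1 for protective
markers (high expression → long survival), +1 for hazardous ones. The
prognosis classifier is Gaussian naive Bayes: class priors are training
frequencies, each feature has per-class mean/variance (floored at
1e-9 × the largest feature variance), and posteriors are computed in log
space. For an equal-variance marker with a higher high-OS mean, the NB
likelihood ratio is monotone in expression, so the MOS up-shift provably
raises the high-OS posterior — the property the counterfactual screen
relies on.

## Worked example

`examples/02_train_and_evaluate.py` simulates one 400-sample cohort,
detects markers, splits, trains and evaluates:

```
split: 266 training / 134 test samples
model features: 9 (6 miRNA + 3 lncRNA markers)
held-out AUC: 0.972
median OS, predicted high-OS group: 2488 days
median OS, predicted low-OS group:  114 days
log-rank: chi2 = 134.6, p = 4.01e-31
```

The split keeps two-thirds of each OS class for training. Nine detected
markers include the four planted ones plus nulls passing the unadjusted
gates at their nominal rate. The held-out AUC and the large gap in median
OS between predicted groups (with a decisive log-rank test) show the
planted expression–survival coupling is recovered from samples the model
never saw. The other scripts in `examples/` demonstrate marker detection,
the sharing contrast, pathway regulation profiling, and the MOS screen.

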