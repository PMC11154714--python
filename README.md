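# irsplit

Exon–intron split analysis of intron retention (IR) in bulk RNA-seq cohorts.

Many cancers — chronic lymphocytic leukemia prominently among them — show
broad dysregulation of the spliceosome, visible as introns retained in
mature transcripts. `irsplit` is for computational biologists who want to
quantify that signal from standard annotations and alignments and test it
between a disease and a control group: it splits each transcript's signal
into exonic (mature mRNA) and intronic (pre-mRNA / retained intron) TPM,
summarizes IR as the intron/exon ratio, and classifies transcripts into
directional IR sets with expression subsets under FDR control.

## The statistic

For transcript *t* and sample *s*, with TPM computed per feature class
(`TPM_f = 10⁶ (r_f/L_f) / Σ_g (r_g/L_g)`),

```
R_ts = (TPM_intron(t,s) + ε) / (TPM_exon(t,s) + ε),        ε = 0.01
effect_t = log2( median_case(R_t·) / median_control(R_t·) )
```

Two one-sided Wilcoxon rank-sum screens on intronic TPM (one per direction),
each Benjamini–Hochberg adjusted at 5%, define **set-I** (IR higher in
cases) and **set-II** (IR higher in controls). Whole-transcript TPM screens
then split each set into subsets **A** (over-expressed in cases), **B**
(under-expressed) and **C** (non-differential, two-sided p > 0.05). The
IR-vs-expression association is summarized by a 2×3 chi-square and a 2×2
Fisher exact test with odds ratio. Downstream products include top-N ranked
selections, Z-score heatmap matrices with fixed control → low-risk →
high-risk column blocks, volcano/quadrant tables, and local hypergeometric
over-representation analysis against GMT gene sets with Bonferroni
correction.

A planted-truth cohort simulator emulating a 97-case (41 high-risk + 56
low-risk) vs 9-control design makes every stage testable without any data
download.

## Worked example

Simulate a 1,000-transcript cohort with the default planted structure
(δ_ir = 4, δ_expr = 3, log-normal noise σ = 0.5), classify, and test the
association:

```python
from irsplit import (CohortConfig, generate_cohort, run_screens,
                     classify_sets, contingency)
from irsplit.simulate import label_accuracy

cohort = generate_cohort(CohortConfig(n_transcripts=1000, seed=42))
sr = run_screens(cohort.intronic.values, cohort.transcript.values,
                 cohort.groups, group_order=("CLL", "NBC"))
sa = classify_sets(sr)
print(sa.set_counts())
res = contingency(sa)
print("odds ratio =", round(res.odds_ratio, 1))
print(res.subset_percentages)
print("label recovery:", round(label_accuracy(sa, cohort.truth), 3))
```

prints

```
expr_subset    A    B   C  unassigned
ir_set
set-I        410    9  58           1
set-II         5  165  22           0
odds ratio = 1503.3
expr_subset   A   B   C
set-I        86   2  12
set-II        3  86  11
label recovery: 0.988
```

Reading: 478 transcripts were called high-IR in the case group (set-I), 192
in controls (set-II); within set-I, 86% are also over-expressed in cases
and only 2% under-expressed, while set-II mirrors that — the huge odds
ratio on the {A, B} columns says IR direction and expression direction are
strongly coupled, exactly the structure the simulator planted (98.8% of
planted six-set labels were recovered).

The same analysis runs from the shell:

```bash
irsplit simulate --out cohort/ --seed 42
irsplit run --fixture-dir cohort/ --out results/     # writes summary.json, TSVs
irsplit quantify --gtf genes.gtf --bam-dir bams/ --out tpm/   # from alignments
```

Every study threshold (60% expression-detection filter, α = 0.05, FDR 5%,
top-N 200, top fraction 25%, ε = 0.01) is a named config field with that
default.

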