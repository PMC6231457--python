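# seedcoex

Seed-gene co-expression analysis for tumor expression cohorts, with a fully
instrumented synthetic data generator for validating every step.

## The scientific problem

In tumors where a transcription factor is suspected to drive an
epithelial–mesenchymal transition (EMT)-like program — the motivating case
is Snail (*SNAI1*) and Slug (*SNAI2*) in ependymoma — a standard discovery
route is guilt by association on a bulk expression cohort:

1. Correlate every gene on the platform against each seed gene (Pearson r
   on pairwise-complete samples, p from the exact t transform).
2. Keep genes with |r| > 0.3 at p < 0.05, one probe per gene symbol
   (the most significant probe represents its gene).
3. Intersect the two seed modules: genes co-expressed with **both**
   factors are the co-regulated core.
4. Characterize the core by over-representation analysis (hypergeometric
   tail with Benjamini–Hochberg control per gene-set family) and preranked
   GSEA, then pick a candidate effector (e.g. the receptor *IL1R1*) whose
   expression also separates aggressive molecular subgroups.
5. Follow the candidate up: correlation against published EMT signatures,
   group comparisons (subgroup ANOVA, proliferation-class t-test), relative
   qPCR quantification by the comparative-Ct (2^−ΔΔCt) method, and
   median-dichotomized survival (Kaplan–Meier, log-rank, univariate Cox).

`seedcoex` implements this entire funnel as composable, deterministic
modules plus a one-command pipeline, and ships a synthetic cohort generator
whose planted structure (block correlations, enriched terms, signature
classes, hazard ratio) is known exactly — so sensitivity, specificity and
calibration of every stage can be measured rather than assumed.

## Worked example

```python
from seedcoex.synthetic import SyntheticConfig, generate_dataset
from seedcoex.coexpression import (seed_correlation_table, deduplicate_probes,
                                   filter_module, intersect_modules,
                                   reference_probe)
from seedcoex.survival import dichotomize_expression, cox_univariate

bundle = generate_dataset(SyntheticConfig(seed=7))
modules = {}
for seed in ("SNAI1", "SNAI2"):
    tab = deduplicate_probes(seed_correlation_table(bundle.matrix, seed))
    modules[seed] = filter_module(tab)          # |r| > 0.3 and p < 0.05
    m = modules[seed]
    print(f"{seed}: {m.size} genes pass "
          f"({len(m.positive)} positive, {len(m.negative)} negative)")
inter = intersect_modules(modules["SNAI1"], modules["SNAI2"])
print(f"common to both seeds: {inter.n_common} genes")
print("IL1R1 in common set:", "IL1R1" in inter.common)

md = bundle.metadata
expr = bundle.matrix.values.loc[
    reference_probe(bundle.matrix, "IL1R1"), md["sample_id"]]
split = dichotomize_expression(expr.astype(float))
grp = split.groups.loc[md["sample_id"]]
fit = cox_univariate(md["survival_time"], md["event"],
                     (grp == "high").to_numpy(float))
print(f"Cox HR (IL1R1-high vs low) = {fit.hr:.2f}, Wald p = {fit.p:.2e}")
```

Output:

```
SNAI1: 82 genes pass (64 positive, 18 negative)
SNAI2: 104 genes pass (82 positive, 22 negative)
common to both seeds: 32 genes
IL1R1 in common set: True
Cox HR (IL1R1-high vs low) = 2.94, Wald p = 5.40e-05
```

The generator plants 40 genes per seed at correlation 0.6, a 30-gene
overlap block (including IL1R1) correlated with both seeds, and a true
hazard ratio of 4.37 for the marker-high group — so the funnel above is
recovering real, known structure, with per-cohort sampling noise.

### Command line

```bash
seedcoex simulate --seed 7 --out-dir sim/
seedcoex run-all --expression sim/expression.tsv --metadata sim/metadata.tsv \
    --gene-sets sim/gene_sets.gmt --signatures sim/signatures.gmt \
    --qpcr sim/qpcr.tsv --calibrator-group SP --out-dir out/
```

`out/` then contains one TSV per stage (correlation tables, module lists,
common genes, enrichment, GSEA, signature summaries, fold changes, KM
curves, Cox fit) and a `manifest.txt` recording the module-size funnel and
a configuration hash. Reruns with the same config are byte-identical.

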