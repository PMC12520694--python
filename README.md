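# hypoxclass

Consensus hypoxia-state labeling and classification for single-cell RNA-seq.

Tumor cells and stromal cells (notably cancer-associated fibroblasts) shift
their transcriptional programs under oxygen deprivation, but single-cell data
give no direct oxygen readout: hypoxia must be inferred from expression.
`hypoxclass` implements a staged classifier for that inference:

1. **Score** every cell against a user-supplied panel of hypoxia gene sets
   (GMT format; typically K = 7 curated pathway sets) with a rank-based
   single-sample enrichment statistic (ssGSEA).  For a cell with N genes
   ranked by expression and a set G with rank weights r_g:

   `ES(G) = Σᵢ [P_in(i) − P_out(i)]`,
   `P_in(i) = Σ_{g∈G, pos(g)≤i} r_g^α / Σ_{g∈G} r_g^α`,
   `P_out(i) = |{g∉G : pos(g)≤i}| / (N − |G|)`  (α = 0.25).

2. **Label** cells by fitting a two-component univariate Gaussian mixture
   (EM) to each set's score distribution.  A cell assigned to the high
   component for *all* K sets is a high-confidence hypoxic cell; low in all
   K, high-confidence normoxic; anything else is low-confidence.

3. **Derive a hypoxia signature** with Wilcoxon rank-sum tests between the
   two high-confidence groups (raw p < 0.05, log₂FC > 0.25, protein-coding
   genes only, up in hypoxia).

4. **Benchmark** a panel of up to 10 classifiers (logistic regression,
   tree ensembles, boosting backends, SVM, naive Bayes, MLP) on two feature
   spaces — a dense cell embedding (external foundation-model export or a
   deterministic truncated-SVD fallback) versus the raw signature-gene
   expression — across stratified training fractions 10%…100%, with
   accuracy / AUROC / F1 on a fixed stratified holdout.  The model with the
   best mean rank across metrics is selected (the top-3-per-metric
   intersection is reported alongside).

5. **Classify** the low-confidence cells with the selected model.

A negative-binomial simulator with planted hypoxic / intermediate /
normoxic populations provides ground truth for every stage, so the whole
pipeline is testable offline.

## Worked example

```python
import numpy as np
import hypoxclass as hx

cm, truth, sets, ann = hx.simulate(hx.SimParams(seed=7))   # 2000 cells, 7 sets
counts, qc = hx.qc_filter(cm, ann)
norm = hx.log_normalize(counts)
scores = hx.ssgsea_score(norm, sets)
labels, fits = hx.label_cells(scores, seed=7)
print("planted:", truth.counts())
print("labels: ", labels.counts())

sig = hx.derive_signature(norm, labels, ann)
emb = hx.build_features(norm, hx.EmbeddingProviderSpec(kind="svd_fallback", dim=50), sig)
raw = hx.build_features(norm, hx.EmbeddingProviderSpec(kind="raw_signature"), sig)
hc = np.isin(labels.status, ["HC_HYPOXIC", "HC_NORMOXIC"])
ids = [c for c, m in zip(labels.cell_ids, hc) if m]
y = (labels.status[hc] == "HC_HYPOXIC").astype(int)
report = hx.run_benchmark({"embedding": emb.subset(ids), "raw_counts": raw.subset(ids)},
                          y, hx.BenchConfig(seed=7))
print("selected model:", report.selected_model)
```

prints

```
planted: {'HYPOXIC': 200, 'INTERMEDIATE': 400, 'NORMOXIC': 1400}
labels:  {'HC_HYPOXIC': 590, 'HC_NORMOXIC': 1153, 'LOW_CONF': 257}
selected model: decision_tree
```

All 200 planted hypoxic cells are recovered as high-confidence hypoxic and
no planted normoxic cell is mislabeled; the extra high-confidence hypoxic
calls are the intermediate cells, whose program is genuinely elevated in
every gene set.  The signature retains 350 genes.  At 10% training data the
embedding features outperform the raw signature-gene features by +0.07
accuracy, +0.06 AUROC and +0.11 F1 averaged over models
(`report.deltas.query("fraction == 0.1").mean()`), and the selected model's
holdout AUROC on embedding features is 1.00 — the planted effect
(multiplier 4) is strong by construction.

## Command line

Each stage is also a subcommand working on a run directory, and `run`
executes everything from a YAML config with digest-keyed caching and a
reproducibility manifest (`manifest.json`):

```bash
hypoxclass simulate --out run/ --seed 7
hypoxclass qc --out run/ --min-genes 500 --max-mito 0.2
hypoxclass score --out run/ --alpha 0.25
hypoxclass label --out run/ --seed 7
hypoxclass signature --out run/ --p 0.05 --lfc 0.25
hypoxclass embed --out run/ --provider svd --dim 50
hypoxclass bench --out run/ --fractions 0.1:1.0:0.1 --holdout 0.3
hypoxclass predict --out run/
```

Real data enter through an `inputs:` section in the config: a MatrixMarket
triplet (or dense table) of raw counts, a GMT of hypoxia sets, a gene
annotation table (biotype + mitochondrial flags), optional doublet flags
and an optional externally computed cell-embedding table.

## Acceptance script

`python scripts/acceptance.py --seed 1 --out results/acceptance.json`
re-runs the complete pipeline on the default synthetic cohort — simulation,
QC, scoring, mixture labeling, signature derivation, feature construction,
the full model benchmark and low-confidence prediction — and writes the
results file.  It takes ~1–2 minutes on one CPU.

See `docs/methods.md` for the statistical details, parameter defaults and
known limitations.
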