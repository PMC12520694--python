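# Methods

This note documents the statistical machinery of `hypoxclass`, the defaults
it ships with, the choices made where more than one reasonable design
existed, and what the synthetic tests do and do not establish.

## Quality control and normalization

Cells are removed when they have fewer than 500 detected genes (strict
`<`), when their mitochondrial count fraction exceeds 20% (strict `>`), or
when a supplied doublet flag is set.  Genes detected in fewer than 0.1% of
the retained cells are then dropped as high-dropout genes.  All three
thresholds are configurable (`--min-genes`, `--max-mito`,
`--min-cells-frac`).  Mitochondrial genes are identified by annotation
flags, with an `MT-` name-prefix fallback when no gene in the matrix
carries a flag.

The cell rules are evaluated on the input matrix and the gene rule on the
retained cells, in one pass.  This is not idempotent in the strict sense —
removing genes could in principle push a cell that sat exactly at the
detected-gene threshold below it on a second application — but with the
default permissive gene filter the fixed point is reached in one pass on
any realistic matrix, and the property suite asserts as much on the
synthetic cohort.

Normalization is library-size log1p: `v = ln(1 + c·s/total)` with scale
factor s = 10⁴.  Heavier variance-stabilizing transforms are deliberately
avoided: the enrichment scoring downstream is rank-based (invariant to any
strictly increasing within-cell transform) and the mixture labeling is
affine-invariant, so the choice of monotone normalization provably cannot
change labels.  Both invariances are asserted as tests.

## Per-cell gene-set scoring

Scores are the classical single-sample enrichment running-sum statistic
with weighting exponent α = 0.25, the canonical choice.  Two numerical
details matter on zero-inflated single-cell matrices, where most genes tie
at zero:

* tied expression values receive **average rank weights**, and
* the order of tied genes along the running sum is fixed by **ascending
  gene id**,

making the statistic fully deterministic.  Scores are not rescaled across
cells: the downstream mixture labeling is affine-invariant, so min–max
rescaling cannot change any label (asserted as a property test).  A set
must retain at least 3 genes after intersection with the matrix (coverage
fractions are reported), and a set covering the entire gene universe is
rejected as degenerate.

## Mixture labeling and consensus

Each set's score vector over all cells is fit with a two-component
univariate Gaussian mixture by EM: one deterministic initialization from a
30th/70th-percentile split plus four seeded random restarts, tolerance
1e-6, at most 500 iterations, variance floor 1e-6 × sample variance.  The
log-likelihood trajectory is retained and its monotonicity asserted on
every fit in the test suite.  The component with the larger mean is the
"high" (hypoxia-active) component, ties broken by weight.  A cell is
assigned HIGH for a set when its posterior for the high component exceeds
0.5 (configurable, `--posterior-cut`); the maximum-responsibility rule.

The consensus is strict: HIGH in **all** K sets → high-confidence hypoxic;
LOW in all K → high-confidence normoxic; otherwise low-confidence.  A
master seed expands to per-set seeds by set index, so results do not
depend on fit order and are reproducible run to run.

## Signature derivation

Genes detected in at least 10% of either high-confidence group are tested
with the two-sided Mann–Whitney U (rank-sum) test.  The scalar
`rank_sum_test` uses exact enumeration when the pooled sample is ≤ 12 and
tie-free, otherwise the normal approximation with tie and continuity
correction; the vectorized per-gene path uses the approximation, which is
the operative regime at realistic group sizes.  The fold change is
`log2((m_h + 1)/(m_n + 1))` with `m` the group mean of de-logged
(expm1) normalized expression — the dominant single-cell convention.  A
gene enters the signature when raw p < 0.05, log₂FC > 0.25 and it is
protein-coding; Benjamini–Hochberg adjusted p-values are reported for
transparency but intentionally not used in the filter, which follows a raw
p cutoff.  Only genes up in the hypoxic group can pass.

## Feature spaces

The classifier consumes one of three feature matrices:

* **external_file** — a dense cells × d table exported from a pretrained
  single-cell foundation model.  Nothing of the model itself is
  implemented here; the contract is purely the file.
* **svd_fallback** — deterministic truncated SVD (default d = 50) of the
  column-centered normalized matrix restricted to signature genes (or the
  2000 most variable genes when no signature exists).  Components are
  capped at the numerical rank with a logged warning, and each component's
  sign is fixed by making its largest-magnitude gene loading positive, so
  the output is bitwise reproducible and invariant to cell order.  It
  exists so the full benchmark is runnable offline; it is *not* a
  substitute for a pretrained embedding on real data.
* **raw_signature** — normalized expression of the passing signature
  genes, the "raw count" comparator arm of the benchmark.

A property test verifies the robustness claim that motivates embeddings:
deleting 20% of non-signature genes perturbs the SVD features less (mean
row-wise cosine distance) than deleting 20% of signature genes perturbs
the raw features.

## Benchmark design

One stratified holdout (30%) is drawn once per run and reused as the test
set for every training fraction, keeping learning curves comparable.  For
each fraction f ∈ {0.1, …, 1.0} a stratified sample of floor(f·pool)
cells is drawn independently (per-class floors, at least one cell per
class).  Every model × feature-mode pair is trained per fraction and
scored on the holdout and any extra validation sets: accuracy, AUROC (rank
formulation, ties 0.5) and F1 of the hypoxic class at a strict 0.5
probability threshold.

Models are ranked per metric within each (fraction, evaluation-set)
condition, ranks averaged over conditions, and the model minimizing the
mean rank across the three metrics is selected (ties: AUROC rank, then
name).  The intersection of the per-metric top-3 sets is computed and
reported as well, since both selection phrasings are in circulation; the
mean-rank minimum is the operative rule.  Hyperparameters are library
defaults, seeded; no class reweighting is applied by default.  CatBoost,
XGBoost and LightGBM are optional imports — an absent backend is skipped
with a warning, never an error — so the reproducible core panel is the
seven scikit-learn models.  The selected model is refit on the full
training pool and used to classify low-confidence cells; a predicted
probability of exactly 0.5 is called NORMOXIC (strict `>`).

## Synthetic cohort

The generator plants a hypoxia program into negative-binomial counts:
baseline gene rates p_g ~ log-normal (normalized to sum 1), library sizes
L_i ~ log-normal (median 10⁴, σ = 0.3 on the log scale), and mean
`μ_ig = L_i · p_g · θ^(e_i·m_g)` where m_g marks hypoxia-set genes and
e_i = 1 / 0.5 / 0 for hypoxic / intermediate / normoxic cells.  Counts are
NB with variance μ + φμ², φ = 0.3 — mid-range overdispersion for droplet
data.  Defaults: 2000 cells, 2000 genes, 7 disjoint sets of 50 genes, 10%
hypoxic, 20% intermediate, θ = 4.  Mitochondrial genes (2%) and
non-protein-coding genes (10%) are drawn outside the program so that QC
and the coding filter have work to do without interacting with the planted
effect.  An `overlap` mode shares a 10-gene core across sets, mimicking
how curated hypoxia sets overlap in practice.

What the generator does **not** emulate: batch effects, doublets, ambient
RNA, gene–gene correlation beyond the single planted program, or realistic
pathway redundancy.  A green end-to-end test therefore establishes that
the machinery recovers a strong planted signal exactly as specified — not
that it would resolve subtle hypoxia gradients in real tumors.

One empirical property of this world is worth stating plainly: with
mixing weight 0.5 and θ = 4, intermediate cells are elevated ≈2× in
*every* gene set, so the strict consensus labels them high-confidence
hypoxic rather than low-confidence; the low-confidence class is populated
mainly by borderline normoxic cells.  Intermediates only land in the
low-confidence class when their elevation is weak or inconsistent across
sets.  The quantitative recovery guarantees (≥ 90% of planted hypoxic
cells recovered, ≤ 1% of planted normoxic mislabeled) hold regardless and
are asserted in the acceptance suite.

## Reproducibility

Every stochastic step takes an explicit seed; the pipeline expands one
master seed into per-stage and per-gene-set seeds deterministically.  The
orchestrator caches stage outputs keyed by a digest of parameters and
input files, records everything in `manifest.json`, and two runs with the
same config produce byte-identical tabular outputs (asserted in the
acceptance suite).  Floating-point output is printed at 10 significant
digits.

## Known limitations

* The per-gene vectorized rank-sum path never switches to the exact small-
  sample mode; with ≥ 3 cells per group and heavy zero-ties the
  approximation is the appropriate regime, but p-values for pathological
  3-vs-3 comparisons are approximate.
* The SVD fallback is a linear stand-in for a nonlinear pretrained
  embedding; benchmark deltas between feature modes on synthetic data are
  qualitative, not estimates of the real-data gap.
* EM on a mixture whose two true components coincide converges to an
  arbitrary split; the labeling contract requires genuinely bimodal (or at
  least dispersed) score distributions, and all-identical scores are
  rejected.
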