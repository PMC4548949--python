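# Methods

This note records the statistical model behind each pipeline stage, the
defaults and why they were chosen, what the synthetic generator does and
does not emulate, and the numerical conventions that matter when
reproducing results.

## The design being analysed

The pipeline targets a three-condition ordered series — the archetype is a
salinity gradient (0, 8, 16 psu) profiled by bulk RNA-seq — with either one
pooled library per condition or a small number of replicates. All
thresholds are configuration keys with the conventional screening defaults:
fold-change gates 2 and 0.5, p and FDR gates 0.05, trend-correlation floor
0.85, co-expression |r| gate 0.999, GO-style enrichment gate p < 0.01 with
batch FDR < 0.05, pathway-style gate p < 0.05. Every inequality is strict.

## Differential screening

Counts are normalised to pseudocounted CPM,
`(count + c) / (library + c·G) × 1e6` with c = 0.5 by default (finite fold
changes for zero counts; G = gene count). Fold change is the ratio of mean
CPM between conditions. Multi-transcript genes are first collapsed to their
longest transcript (ties broken lexicographically by transcript id).

Two tests are provided, chosen automatically from the design:

* **Replicated (≥ 2 per condition): moderated pooled t.** A per-gene
  two-sample t on log2 CPM whose pooled variance is shrunk toward a common
  prior: the gene variances are modelled as s²_g ~ s₀²·F(d, d₀), with
  (d₀, s₀²) estimated by matching the mean and variance of log s²_g
  (digamma/trigamma moment equations; the trigamma inverse is solved by
  Newton iteration). The posterior variance (d₀s₀² + d s²_g)/(d₀ + d) is
  used with d₀ + d degrees of freedom. Rationale: with 3 replicates an
  unmoderated t-test has 2–4 df and a p-value floor around 10⁻³–10⁻⁴, so a
  BH-FDR < 0.05 gate is unreachable when true positives are a realistic few
  percent of genes — we measured 16-fold planted effects passing the FC and
  raw-p gates at 98% but the FDR gate at 27%. Moderation is the standard
  remedy; a plain Welch t remains available (`method="welch"`).
* **Unreplicated (1 vs 1): Audic–Claverie exact test.** Conditional on the
  two counts' sum, the second count is Binomial(x+y, N_B/(N_A+N_B)) under
  the null; the two-sided exact binomial p-value is used. With one library
  per condition there is no variance information, so this Poisson-flavoured
  test is the honest option; it is anti-conservative under biological
  overdispersion, which the fold-change gate partially absorbs.

BH adjustment runs over all genes within a comparison. The union of genes
selected in ≥ 1 of the three comparisons, with per-comparison provenance
flags, feeds every downstream stage.

## Trend clustering

Model profiles are all step-sign vectors in {−1,0,+1}^(C−1) except
all-zero; for C = 3 that is 8 profiles, indexed lexicographically with
−1 < 0 < +1 (index 0 = (−1,−1), 7 = (+1,+1)). Assignment correlates each
gene's mean log2 CPM per condition against the model vectors (0, s1,
s1+s2); the argmax profile is taken when r ≥ 0.85, ties to the lowest
index, zero-variance genes unassigned. Log scale was chosen to match the
fold-change-based screen; Pearson correlation makes the assignment
invariant to positive affine transforms of the gene vector, and negating a
vector maps each profile to its sign-flipped partner.

A geometric fact worth knowing: centered 3-condition vectors live on a
circle, and the 8 model directions leave a maximal angular gap of 60°, so
the *worst-case* best correlation of any non-constant vector is
cos 30° ≈ 0.866. The conventional 0.85 floor therefore only rejects genes
through noise in the per-condition summaries, not by geometry; a floor
above 0.866 is needed for the gate to bind on noiseless data.

Per-profile significance compares observed assignment counts with expected
counts obtained by permuting each gene's condition order (all 6
permutations averaged; a Monte-Carlo subset is configurable, and a uniform
1/8 prior is available as `mode="uniform"`). The permutation null is the
default because the model-vector set is not closed under coordinate
permutations, so a uniform prior misstates the null for skewed expression
summaries. Each profile is tested one-sided by Fisher's exact test on the
2×2 table (in-profile vs not) × (observed vs expected pool), expected
counts rounded to integers, then BH-adjusted across the 8 profiles.

The reversal profiles ((−1,+1), (+1,−1)) are reported with their category
but conventionally excluded from enrichment: such genes show no net change
between the outer conditions, so outer-pair fold changes carry no signal
for them.

## Enrichment

Per term: one-sided hypergeometric tail P(X ≥ k) (Fisher) and 1-df Pearson
χ² without continuity correction on the same table (k = list∩term, K =
background∩term, n = list size after dropping genes outside the background,
N = background size). Terms with a zero margin get χ² p = 1 so the batch
pairing stays total. The batch-level empirical FDR 1 − N_K/T (N_K = #terms
with Fisher p strictly below χ² p) is implemented literally and attached to
every term in the batch; it takes values on the grid {0, 1/T, …, 1}. Note
its behaviour: on mostly-null batches roughly a third of terms have
Fisher p < χ² p, so the batch FDR sits far above 0.05 and the GO-style
significance gate (p < 0.01 AND batch FDR < 0.05) rarely fires — this is a
property of the definition, not a bug; per-term BH values are reported
alongside as the defensible alternative, and the pathway-style gate
(p < 0.05) does not use the batch FDR.

## Networks

Gene-act: induced subgraph of the typed relation table on the DE genes
(isolated DE genes kept as nodes), edge kinds from the closed vocabulary,
indirect edges kept with a boolean flag, node attributes = up/down
regulation sign. Co-expression: edges where |r| > 0.999 (strict) and the
two-sided correlation t-test (n−2 df) gives p < 0.05; requires ≥ 3
expression columns, which the generator supplies as replicates — a pooled
one-library-per-condition design has no sample axis for correlation, and
this requirement is the package's documented resolution of that gap.
Degree centrality counts distinct neighbours (direction and edge
multiplicity ignored); core numbers come from classic iterative pruning
(networkx), with self-loops excluded; core factors rank genes by
|degree(A) − degree(B)| between two networks, descending, ties by gene id,
absent nodes counting as degree 0.

## qPCR

ΔCt = mean(target Ct) − mean(reference Ct) per (gene, condition),
arithmetic mean over replicates on the cycle scale; ΔΔCt differences
against the control condition; fold change 2^−ΔΔCt. The control condition
is exactly 1 by construction and plate-wide Ct shifts cancel. Concordance
with RNA-seq is Pearson r on log2 fold changes over shared
(gene, condition) pairs (≥ 3 required).

## Synthetic generator

`SimulationConfig` defaults define the study conditions used by the test
suite and the acceptance script:

| parameter | default | meaning |
|---|---|---|
| n_genes | 1000 | transcriptome size |
| profile_fractions | 1% per profile | 8% of genes carry a planted trend |
| step_log2fc (Δ) | 2.0 | one planted step, log2 units |
| nb_dispersion | 0.05 | NB overdispersion (0 → Poisson) |
| replicates_per_condition | 3 | sample columns per condition |
| baseline_log_mean / sd | 7.0 / 1.5 | per-gene log2 baseline (log-normal) |
| n_terms / planted | 50 / 5 | gene sets, planted at 80% stratum draw |
| ct_noise_sd | 0.2 cycles | qPCR replicate noise |

A gene with planted steps (s1, s2) has expected log2 means
(m, m+s1Δ, m+s1Δ+s2Δ); counts are negative-binomial around those means
(library-size scaling optional). The DE fraction of 8% mirrors the scale of
real gradient studies (a union of ~1–2 thousand genes out of ~20k). It is
deliberately *not* larger: planted shifts enter library totals, so a large
asymmetric DE fraction induces a composition bias under total-count CPM —
at 40% DE we measured a ~1 log2 global offset at the third condition, which
falsely selects a third of flat genes and corrupts trend assignment. This
is a real phenomenon of total-count normalisation, not a generator
artifact; analyses of transcriptome-wide shifts need a different
normaliser, which is out of scope here.

Gene sets draw `planting_enrichment` of each planted term's members from
the non-flat stratum and the rest uniformly; decoy terms draw uniformly.
Relations are uniform random typed edges. Ct tables are generated as
reference level + per-gene offset − planted log2FC + Gaussian noise, with a
constant reference gene — so noiseless tables invert exactly through
2^−ΔΔCt.

What the generator does *not* emulate: sequencing-depth heterogeneity and
GC/length biases, correlated gene modules beyond the shared planted
profiles, annotation incompleteness, isoform structure, batch effects, and
the mean–variance relationships of real libraries beyond a single global
dispersion. Passing tests therefore demonstrate the pipeline's correctness
and its recovery behaviour under the stated noise model, not performance on
real libraries.

Problem sizes used by the checks — 1000 genes × 9 samples for recovery,
5000 genes for the null screen, 200 genes at high depth (baseline 2^14,
dispersion 0) for co-expression, 2000 genes / 200 large terms for the
null-enrichment uniformity test — were chosen so each property is measured
with comfortable margins at interactive runtimes. The null-enrichment check
uses large terms (50–200 members) deliberately: exact hypergeometric
p-values on small terms are too discrete to resemble a uniform
distribution, and a KS uniformity test would reject on discreteness alone.

## Numerical conventions and edge cases

* All randomness flows through `numpy.random.default_rng` seeded per stage
  from the configured seed; identical seeds give bit-identical outputs
  (the pipeline writes a sha256 manifest to make this checkable).
* BH adjustment is the standard step-up with monotonicity enforcement and a
  final pointwise max against the input to guard float rounding.
* Fold changes and screening inequalities are strict, exactly as
  conventionally printed; FC = 0.5 or 2.0 is *not* selected.
* Zero-variance expression vectors are unassignable; zero-margin χ² tables
  raise (or are reported as p = 1 inside batch enrichment); rate
  computations with zero denominators raise rather than return NaN.
* QC percentages are reported rounded to one decimal, with unrounded values
  retained; per-library read counts must satisfy
  unique ≤ mapped ≤ filtered ≤ raw.

## Known limitations

* The moderated test assumes a common variance prior across genes; strong
  mean–variance trends would call for an intensity-dependent prior.
* The batch-level FDR is faithful to its printed definition but has weak
  frequentist guarantees; use the per-term BH column for calibrated
  control.
* Enrichment treats terms as flat sets (no ontology-graph propagation).
* The co-expression |r| > 0.999 gate is extremely strict; with noisy data
  it yields empty networks unless depth is high — this matches its
  intended use as a near-duplicate-profile detector, not a general
  module-discovery tool.
* Tendency significance is implemented for the 3-condition design;
  `enumerate_profiles` generalises, the significance machinery does not.
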