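# Methods

This note documents the statistical models, the defaults and the design
choices behind `sigrev`, in the order the pipeline runs them.

## Differential expression

Expression values are assumed normalized and on a log scale (log2
microarray intensities or log-CPM-like values), so a two-group Gaussian
model with a common within-group variance per gene is appropriate. For
gene g with `n₁` case and `n₂` control samples:

- `logFC_g = mean(case) − mean(control)` (log2 units),
- `s²_g` = pooled within-group variance on `d_g = n₁ + n₂ − 2` df.

Variances are moderated empirically: under the hierarchical model
`s²_g ~ s₀²·F(d_g, d₀)`, the prior `(d₀, s₀²)` is estimated by moment
matching on the log scale — the empirical variance of
`log s²_g − ψ(d_g/2) + log(d_g/2)` in excess of `ψ′(d_g/2)` identifies
`ψ′(d₀/2)` (inverted numerically), and the mean identifies `log s₀²`.
When the excess is non-positive there is no detectable variance
heterogeneity and `d₀ = ∞` (complete shrinkage, normal reference). This is
the classical Fisher-z estimator for a scaled-F sample; during development
it was checked to agree with the standard moderated-t implementations to
machine precision on random data. The posterior variance
`s̃²_g = (d₀s₀² + d_g s²_g)/(d₀ + d_g)` always lies between `s²_g` and
`s₀²`.

P-values are two-sided from `t(d₀ + d_g)` and are used **raw**: the DEG
threshold is a strict `p < α` with `α = 0.05` by default, because the
downstream conservation step is itself a strong filter and the screening
stage consumes ranked tags, not inference. A BH-FDR `q` column is emitted
for reference but not used by any default filter.

Degenerate inputs: a gene constant across all samples has `s²_g = 0` and
is flagged; its moderated t is still defined whenever `d₀ > 0`. A dataset
where *every* variance is zero (e.g. a noise-free simulation) cannot
support prior estimation and is rejected with instructions — callers that
deliberately work noise-free pass an explicit `ModerationParams`.

## Conservation

Symbols are compared case-insensitively throughout (mouse "Myc" vs human
"MYC"). Ortholog pairs that are not one-to-one are dropped by default and
counted; an optional "first-alphabetical" resolution exists for users who
prefer coverage over strictness. Concordance is judged on `sign(logFC)`
only — a gene 4-fold up in one species and 1.3-fold up in the other is
still conserved.

The overlap test is the one-sided hypergeometric tail `P(X ≥ k)` with
`X ~ Hypergeom(N, K, n)`, equivalent to the one-sided Fisher exact test on
the 2×2 table. The background `N` defaults to 20 000 (approximate human
protein-coding gene count) and is always an explicit, logged parameter:
the p-value is meaningless without knowing `N`, and reasonable choices
(measured genes vs genome) differ by a factor of ~2. Note `P(X ≥ k)` is
monotone *decreasing* in `N` at fixed list sizes — a larger universe makes
the same overlap more surprising.

## Connectivity screen

The query is built from the cDEG: each side ordered by ascending human
p-value (ties broken by symbol), truncated to 1000 tags per side. P-value
ranking (rather than fold change) is a documented choice; with a cDEG below
the cap the ordering is irrelevant.

Each reference instance is a full ranking of its gene universe (rank 1 =
most up-regulated by the perturbagen). Tags absent from an instance's
universe are dropped for that instance with the tag count recomputed;
an entirely absent side is an error. The signed KS statistic and the
combined score follow the original 2006 connectivity-map recipe, including
the rule that an instance scores 0 when both tag sets drift the same way.
The newer weighted-connectivity (WTCS) variant is out of scope. Two exact
properties hold and are tested: swapping the up/down tag sets negates the
raw score, and reversing an instance's ranking flips the sign of a
non-zero score. The flip is a sign property only — the rank-based maxima
carry a `1/t − 1/n` offset under reversal, and a tag set sitting exactly
at the list midpoint (tie `a = b`) can collapse to 0.

Scaling is per screen: positive raw scores are divided by the screen's
maximum positive score, negatives by |most negative|, so ES ∈ [−1, 1] and
each occupied sign attains ±1. Per-(perturbagen, cell line) summaries are
the mean instance ES with the instance count n. The permutation p-value —
the fraction of 10 000 random same-size instance groups from the same
screen with |mean ES| at least as extreme, with a +1 correction so
p ∈ (0, 1] — is this package's addition; the classical output carries only
n and ES, and the column is labeled `perm_p` to keep that distinction.

The default hit filter keeps negative mean ES, n ≥ 3, on cell line HL60 —
the screen's reversal logic: a *negative* ES means the drug pushes the
disease's up-genes down and down-genes up.

## Enrichment

Preranked GSEA uses the weighted-KS running sum (hit increments
`|r|^w / Σ_hits|r|^w` with `w = 1`, miss decrements `1/(N−t)`), with the ES
taken at the extremum of larger magnitude (ties resolve positive; a set
covering the whole ranking has ES = 1 by convention). Significance uses
gene-label permutations — random same-size sets — which is the only null
available for a preranked statistic; NES divides the ES by the sign-matched
mean of |permuted ES| and p uses the +1-corrected same-sign count. Default
10 000 permutations. The ranking is ordered by statistic with symbol
tie-breaks so results are reproducible bit-for-bit.

ORA reuses the same hypergeometric implementation as the conservation
overlap test (one shared code path) and corrects across sets with BH;
the default report flags sets at p < 0.001 and q < 0.001.

## Bibliometric triage and visualization

`score_m = log₁₀(c·p·i·w)` with `w = 2`. The logarithm base is a fixed
constant; only the ordering (base-invariant) is consumed downstream.
Molecules with `c·p = 0` receive a −∞ sentinel and are flagged
`unstudied`, ranking *first*: a pseudocount would silently interleave
never-studied molecules with barely-studied ones, which is exactly the
distinction the triage exists to make. Impact tiers `i` are taken as given
input; deriving tiers from raw journal impact factors is out of scope.

Bubbles: one horizontal band per cell line (blue HL60, yellow MCF7,
orange PC3 by default; unknown lines fall back to a fixed palette cycle),
y = |mean ES|, seeded uniform horizontal jitter, and radius mapped
inverse-linearly from the score into `[r_min, r_max]` (sentinel treated as
the minimum finite score; zero score range maps everything to the
midpoint). A tidy coordinate table accompanies the image so the plot is
testable without pixel comparison.

## Synthetic data generator

The generator defines the study conditions and emulates a two-species
case/control microarray comparison:

- Gaussian log-scale expression; per-gene baseline ~ N(7, 1), residual
  sd `noise_sd = 1.0` (typical log2 microarray residual spread), planted
  |logFC| = 2.0 — a strong but realistic disease effect.
- Default 13 cases vs 17 controls per species, mirroring a human
  leukemia-vs-healthy-T-cell cohort of that shape; 2000 genes by default
  (a down-scaled transcriptome that keeps runs fast while leaving hundreds
  of null genes for calibration).
- Planted gene statuses: 5% shared-concordant (the signal the pipeline
  must recover), 15% species-private, 2% deliberately discordant
  (DE in both species, opposite signs — must be excluded from the cDEG),
  rest null. Signs are random per gene; magnitudes are constant so
  noise-free runs reproduce the planted logFC exactly.
- Mouse symbols are case-variants of the human ones with a suffix
  ("GENE0007" ↔ "Gene0007m"), linked only through the emitted ortholog
  table — nothing can work by accidental string identity; 10% of genes are
  missing from the table by default.
- Perturbagen instances rank the human gene universe by
  `x = s·ρ·u + √(1−ρ²)·ε`, with `u` the standardized disease logFC
  vector, `ρ` the configured reversal strength (default 0.8), `s = −1`
  for reversers, `+1` for mimickers, and `ε` fresh standard-normal noise
  per instance (neutral drugs are pure noise). The noise share is tied to
  the correlation, so `ρ = 1` is exactly noise-free. Score ties are broken
  by gene order so every emitted ranking is a strict permutation.
- Cell lines: each perturbagen's instances share one line. Neutral drugs
  round-robin over HL60/MCF7/PC3 so every band of the visualization is
  populated; planted drugs are pinned to HL60 so the default screen filter
  (single cell line, n ≥ 3) can observe them at full instance count. A
  per-instance round-robin would cap every (perturbagen, line) group at
  n = 1 and make the n ≥ 3 filter unsatisfiable by construction.
- Bibliometric counts are Poisson (trials mean 2, publications mean 10)
  with uniform tiers; gene sets are a small GMT collection containing
  modules drawn from the planted up/down cores plus random filler sets.

All randomness derives from one root seed through named substreams, so
every stage re-run in isolation sees the stream it saw in a full run, and
fixing the seed fixes every emitted byte.

What the generator does **not** emulate: probe-level array structure,
batch and platform effects, correlated gene modules in the noise,
dose–response structure within perturbagens, and realistic gene-gene
correlation in reference rankings. Passing tests therefore demonstrate the
correctness and calibration of the algorithms under the stated model, not
performance on real GEO/CMAP data.

## Problem sizes and numerical choices

Tests and the acceptance script run at deliberately modest scales chosen
as representative: 400–2000 genes, 12–50 perturbagens, 100–10 000
permutations, 50 replicate screens for recovery rates. Tolerances: exact
(1e-9–1e-12) wherever an enumeration oracle exists; binomial/Kolmogorov
bands for calibration checks. Hypergeometric p-values are clipped into
(0, 1] at the floating-point tiny; permutation p-values use the +1
correction and cannot be 0. The trigamma inverse is solved by bisection on
[1e-8, 1e8], covering any realistic prior df.

## Known limitations

- Two-group designs only; no covariates, pairing or batch terms.
- One-to-many ortholog handling is deliberately lossy under the default
  policy.
- Gene-label permutation GSEA is less conservative than sample
  permutation for correlated genes; with the generator's independent noise
  this distinction vanishes, but on real data NES/p should be read with
  the usual preranked caveats.
- The overlap-test background is a user choice; reported p-values move by
  orders of magnitude with it.
- Reference rankings must be strict permutations; tied scores at the
  format level are rejected rather than resolved.
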