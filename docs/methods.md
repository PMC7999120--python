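# Methods

## Quantification model and assumptions

The pipeline treats peptide MS1 intensities as multiplicative signals:
on the log2 scale a peptide measurement decomposes into protein
abundance, a per-sample loading/acquisition factor, a peptide-specific
ionization efficiency, and technical noise. Three consequences shape the
design:

* **Normalization is by column.** Per-sample median scaling removes the
  loading factor. The common target `T` is set to the median of the
  per-sample medians; this is a reporting convention only — any positive
  constant yields identical ratios and log-scale test statistics, which
  the suite verifies as a rescaling-invariance property (per-sample
  rescaling changes the protein table by exactly one global factor and
  leaves every downstream quantity invariant to 1e-9 relative).
* **Missingness is left-censored (MNAR).** Low-abundance ions
  preferentially fall below the detection limit, so missing cells are
  filled with a per-sample noise floor (the 1st percentile of observed
  values) rather than a central value. Imputation runs after
  normalization and filtering and before aggregation, so imputed values
  participate in protein sums; the noise centile is therefore computed
  on normalized intensities. The stage order is fixed — reordering
  changes the result — and is part of the method definition.
* **Pairing is structural.** Each cell line contributes one control and
  one treatment sample sharing a line-level abundance offset. Testing
  within-line differences cancels that offset, which is why the paired
  *t*-test has power at n = 4 lines. The test runs on log2 intensities
  by default (`test_scale="linear"` is available for sensitivity
  analysis): the noise model is multiplicative, and log differences make
  the per-line differences approximately Gaussian.

"Quantified peptide" means a peptide that passed the
two-in-one-condition filter; the ≥ 2-peptide protein rule counts such
peptides once per leading protein regardless of condition. Grouping is
strictly by the leading razor protein string — no re-assignment of
shared peptides is attempted, since protein inference is the upstream
search engine's job.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `noise_centile` | 1 (%) | per-sample noise floor used for imputation |
| `min_values_per_condition` | 2 | observed values needed in one condition |
| `min_peptides_per_protein` | 2 | quantified peptides needed per protein |
| `include_classes` | unique, razor | peptide classes used for quantification |
| `alpha` | 0.05 | significance level on the paired-t p-value |
| `fc_threshold` | 1.2 (proteins), 1.5 (transcripts) | two-sided fold-change cutoff, strict |
| `weight` | 1 | exponent on \|score\| in the enrichment walk (0 gives the unweighted closed-form case) |
| `n_perm` | 1000 | gene-permutation null size |

Fold-change rules are two-sided (`max(r, 1/r) > threshold`) because both
directions of regulation are of interest; thresholds and alpha are
strict inequalities. The protein-level test uses raw p-values by
default (BH adjustment is available by flag and then replaces the raw p
in the significance rule); over-representation results are always
BH-adjusted across sets and selected at adjusted p < 0.01.

## Enrichment conventions

The preranked statistic walks the fold-change-ranked list; hits advance
the running sum by `|s_i|^w / Σ_hits |s_i|^w`, misses retreat by
`1/(N − K)`; the ES is the signed maximal deviation and the leading edge
collects hit members at or before the extremum (at or after it for
negative ES). The null permutes gene labels (random same-size sets),
because the pipeline receives a single ranked list rather than
per-sample expression for phenotype shuffling. The p-value uses the
add-one convention over same-sign nulls, `p = (1 + #extreme)/(1 +
#same-sign)`, so permutation p-values are never zero; when no null
shares the observed sign, p is reported at the `1/(1 + n_perm)` floor
with a flag. NES divides the ES by the mean |null ES| of the same sign.
Ties in the ranking are broken by stable sort on input order.

## Synthetic data: what it emulates and what it does not

`simulate_peptides` emulates the paired knockdown design the analysis
assumes: 4 cell lines × 2 conditions, ~2000 proteins with log2 baseline
N(23, 2), line effects N(0, 0.5) shared within a pair, peptide offsets
N(0, 1), technical noise N(0, 0.25), peptides per protein 1 + Poisson(2)
(mean ≈ 3), a 10% differential fraction with |log2FC| ~ U(0.5, 2) and
P(down) = 0.72, and logistic dropout with location 19 and slope 1 on the
log2 scale — chosen to give a realistic overall missingness near 10% at
the default abundance distribution. One master seed drives four spawned
`SeedSequence` streams (truth, structure, intensities, missingness), so
outputs are byte-reproducible and each stage can be regenerated
independently.

The generator does **not** model retention-time alignment,
match-between-runs, interference/chimeric spectra, shared-peptide
mis-assignment, or batch effects beyond the per-sample loading factor.
Passing tests therefore demonstrate the statistical chain's correctness
and calibration under its own assumptions, not robustness to every
artifact of real acquisitions.

The companion generators share identifiers with the proteomic truth:
`simulate_deg_table` copies a configurable fraction (default all) of the
differential proteins into the transcript layer with extra noise, which
is what makes the concordance analysis exercisable with a known answer;
`simulate_trace` builds flux traces from constant segment means plus
Gaussian noise; `simulate_counts` draws binomial staining counts.

## Numerical choices and degenerate inputs

* Percentiles use linear interpolation between order statistics
  (configurable), matching `numpy.percentile`'s default.
* A protein whose within-line differences are all identical has an
  undefined t statistic; its p is reported as missing with a
  `degenerate` flag, never as 0 or 1.
* Stored zero intensities are converted to missing on read; valid
  intensities are strictly positive, so ratios are always defined.
* Identifier harmonization for the concordance report is exact match
  after uppercasing and trimming, with an optional protein→gene map;
  unmatched features are counted and listed, never silently dropped.
  The overlap hypergeometric uses the intersection of *measured* (not
  called) features as its universe.
* Flux traces are segmented by strict time comparison against the
  injection annotations; each of the four segments must contain at least
  one measurement cycle. The post-FCCP summary is the segment mean by
  default (`max` available); post-rotenone (non-mitochondrial)
  subtraction is available but off by default. Per-cell metrics are
  reported per 10^4 cells for readable magnitudes, alongside raw
  per-well values.

## Problem sizes

The test suite and the acceptance script run entirely on synthetic data:
the chain-correctness checks use a ~500-peptide fixture compared
stage-by-stage against loop-based reimplementations; the paired-test
equivalence uses 1,000 random 4-pair matrices; calibration and recovery
use 2,000–2,600-protein simulations (seconds each); permutation nulls
use 100–1,000 permutations. These sizes give stable Monte-Carlo
estimates for every reported fraction while keeping a full run fast.

## Known limitations

* Aggregation by summed intensity weights abundant peptides heavily; no
  alternative summaries (median polish, top-n, MaxLFQ-style pairwise
  ratios) are provided.
* The noise-floor imputation is a single-value fill per sample; it
  understates imputation uncertainty, and proteins quantified mostly
  from imputed values inherit that optimism. The quantifiability filter
  is the guard against testing such proteins.
* No moderated (empirical-Bayes) variance estimation: with 4 pairs the
  per-protein variance is noisy, and the raw paired t is what the
  pipeline defines.
* Over-representation assumes a well-defined measured universe; results
  are sensitive to that choice, which is why the universe is an explicit
  argument.
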