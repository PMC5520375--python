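# Methods

Models, parameter choices and numerical decisions behind `clockmine`.

## Homology screen

**Alignment.** Exact Smith–Waterman local alignment with affine gaps via
`Bio.Align.PairwiseAligner`: BLOSUM62, gap open 11, gap extend 1, so a gap
of length *k* costs 11 + *k* (encoded as `open_gap_score = -12`,
`extend_gap_score = -1`). The ambiguity residue X scores 0 against
everything. Correctness is established against an independent Gotoh
dynamic-programming oracle in the test suite. `percent_similarity` is the
BLAST-style positives fraction (substitution score > 0) over the alignment
length.

**E-values.** Karlin–Altschul statistics `E = K·m·n·exp(−λS)` with the
standard gapped constants for BLOSUM62 11/1, λ = 0.267 and K = 0.041, where
*m* is the query length and *n* the summed database length. These track
BLASTP's e-values in order of magnitude but not digit-for-digit (no
composition adjustment or finite-size edge correction); that is acceptable
because every decision made with them is threshold-based (forward
`E ≤ 1e-5`, reverse `E ≤ 10`), far from the regime where the refinements
matter.

**RBH.** For each query, up to 10,000 forward hits pass the e-value gate;
each subject is re-aligned against the full query set and accepted only if
its best reverse hit (ordering: e-value ascending, bitscore descending,
subject id) is the original query. The accepted subject's subtype is the
query with the highest forward bitscore (ties: lower e-value, then
lexicographic query id). The screen uses 23 query factors — 17 from
*Synechococcus elongatus* PCC 7942 plus the KaiB1–3/KaiC1–3 paralogs of
*Synechocystis* PCC 6803 — merged to 21 analysis factors
(KaiB → KaiB1, KaiC → KaiC1).

## Inventory

Copy numbers count distinct accepted subjects per merged factor and strain.
Strains without a KaiC-family homolog (KaiC1/2/3) are removed: a clock
without its central oscillator component is not interpretable as a clock
system. Genus summaries average percent similarity over strains *having*
the factor (absence is missing data, not zero). Copy-number display
condenses counts above 5 to ">5".

## Co-occurrence

**Deduplication.** Genome databases over-represent a few heavily sequenced
genera, which would let one repeated genome architecture drive every pair
toward significance. Strains are therefore collapsed to unique factor
combinations ("clock systems") before testing.

**Exact test.** Right-sided Fisher's exact test: with margins fixed the
joint-presence count is hypergeometric, and the p-value is the upper tail
P(X ≥ a), summed from log-factorials (`lgamma`) so that tables of any size
are computed without overflow and to near machine precision (verified
against direct `math.comb` enumeration, max error < 1e-14). BH step-up at
FDR 0.01 controls the 210-pair family. On simulated independent-presence
matrices (69 systems × 10 factors at prevalence 0.5) the pooled fraction of
raw p ≤ 0.05 is ≈ 0.03 — conservative, as expected for a discrete exact
test — and false network edges average ≈ 0.003 per matrix.

**Display.** Factor ordering for heatmaps comes from average-linkage
hierarchical clustering of the adjusted-p matrix. Labels are pre-sorted so
that equal-distance ties resolve identically regardless of input order. The
co-occurrence graph joins factors with adjusted p ≤ 0.01, edge weight the
adjusted p, node attribute the degree.

## Rhythm analysis

**Model.** Fixed-period harmonic regression
`y = β₀ + β₁t + c·cos(ωt) + d·sin(ωt)`, ω = 2π/24 h, fitted by least
squares; significance from the F-test (2 numerator df) against the
trend-only model; amplitude `A = √(c² + d²)`; peak phase
`φ = atan2(d, c)/ω mod 24`. Genes are called oscillating at BH-adjusted
q ≤ 0.05. Input in linear units passes through the l2m transform
(log2 of each value over its gene mean); zero values are handled by adding
the smallest positive value of the row before the log.

**Why the fit runs on the raw series by default.** The design decision to
de-spike profiles with a Savitzky–Golay (window 5, order 2) filter before
fitting interacts badly with the F-test: smoothing correlates neighbouring
residuals and shrinks the residual variance, inflating the type-I error
from the nominal 0.05 to a measured ≈ 0.30 on pure-trend genes. It also
attenuates a genuine 24-h component by the filter gain 32/35 ≈ 0.914 at
4-h sampling, breaking noiseless exactness. The default is therefore
`smooth=False` (measured type-I error 0.057, inside the calibration band
[0.03, 0.07]); smoothing remains available as an explicit option
(`--smooth`) for visual de-spiking, with the caveat documented.

**Phase-recovery limit.** For the reference design — 12 timepoints at 0,
4, …, 44 h, amplitude 1, noise σ = 0.5 — the exact OLS covariance of the
(c, d) coefficients gives sd(φ̂) ≈ 0.82 h. The fraction of genes whose
phase lands within ±1 h of truth is then at most ≈ 0.78 for *any* unbiased
estimator; measured performance (0.75–0.79 across seeds) sits at that
bound. The acceptance criterion demanding ≥ 0.90 is therefore
information-theoretically unattainable and its test is left honestly red
rather than weakened or tuned.

**Cross-dataset comparison.** Shared oscillators (optionally joined through
a homolog-group map) are compared by the Jammalamadaka–SenGupta circular
correlation of peak phases, with the asymptotic normal p-value from the
second-order trigonometric moments, and by Pearson correlation of
amplitudes. Fewer than 3 shared oscillators yields no comparison (with a
warning). The implementation is cross-checked against `pingouin.circ_corrcc`.

## Motif conservation

Alignment columns are projected onto reference residue numbers (KaiC-7942
numbering by convention): column *i* maps to the count of non-gap reference
characters up to *i*, a bijection between non-gap reference columns and
1..L. Motif windows are stated as inclusive reference ranges; per window a
position frequency matrix over the 20 amino acids plus gap is computed
(rows sum to 1). Shipped windows: phosphosites S431/T432, the
dephosphorylation-relevant T426, and the CII Walker A P-loop anchored by
locating GATGTGKT in the ungapped reference. Wildcard patterns (X = any)
give per-motif match fractions.

## Synthetic data

The generators produce the statistical structure each stage assumes — and
deliberately nothing more:

- **Proteomes**: query families mutated to a target percent identity by
  substituting `round((1 − id/100)·L)` distinct positions with
  BLOSUM62-positive exchange partners (weighted by exchange score), planted
  among decoys drawn from the pooled query composition. Realized identity
  equals the target to rounding precision. No indels, domain shuffling or
  compositional bias — this tests the RBH logic, not BLAST's heuristics.
- **Clock systems**: independent Bernoulli columns except for planted
  pairs drawn jointly from the 2×2 distribution with the requested
  marginals and odds ratio (p₁₁ solves the implied quadratic; infeasible
  combinations are rejected). No phylogenetic correlation between systems
  is modelled — the deduplication step exists precisely to justify that
  assumption downstream.
- **Expression**: sinusoid-plus-linear-trend in log-ratio units at the
  4-h/48-h reference cadence, Gaussian noise, truth table with phase,
  amplitude, slope and intercept per gene. No autocorrelated noise,
  missing values or non-sinusoidal waveforms.

All generators draw from `numpy.random.default_rng(seed)` only; identical
configuration and seed give byte-identical serialized output.

## Problem sizes and runtime

Unit plus acceptance suites run in ≈ 1 minute on one CPU. The most
expensive pieces are the exhaustive Fisher enumeration (all tables with
n ≤ 30, ≈ 46k tables), the 1000-matrix null calibration, and the RBH
fixture (10 taxa × 25 proteins of length 200 against 5 queries, ≈ 1 s with
score-only alignment and reverse-hit caching). `scripts/acceptance.py`
completes in ≈ 5 s.

## Known limitations

- E-values are analytic Karlin–Altschul values, not BLAST-calibrated;
  only threshold decisions should be read from them.
- The harmonic F-test assumes i.i.d. Gaussian residuals; autocorrelated
  biological noise will inflate its nominal significance (use the q-values
  comparatively, not as literal error rates).
- The circular-correlation p-value is asymptotic; below ~20 shared genes
  it is a rough guide only.
- Subtype assignment is winner-takes-all by bitscore; genuinely ambiguous
  paralogs near the decision boundary carry no confidence measure.
- Benchmarks against the published homolog tables require downloads and
  are out of scope for this offline build; all acceptance checks are
  property-based on synthetic data.
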