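# clockmine

Comparative genomics and rhythm analysis of prokaryotic KaiABC-type
circadian clocks.

## The scientific problem

The cyanobacterial circadian clock is built around three proteins — KaiC, a
hexamer-forming autokinase/phosphatase; KaiA, which stimulates KaiC
phosphorylation; and KaiB, which antagonizes it — plus input/output factors
(CikA, SasA, RpaA, LdpA, Pex and others) that couple the oscillator to the
environment and to gene expression. Which prokaryotes carry which pieces of
this machinery, which pieces travel together, and whether the predicted
clocks actually drive rhythmic gene expression are comparative questions
that this package answers from sequence and expression data:

1. **Homology screen** — find homologs of the clock factors in annotated
   proteomes with a reciprocal best-hit (RBH) strategy: a subject protein is
   accepted only if its best alignment back against the query genome is the
   original query. Alignments are exact Smith–Waterman local alignments
   (BLOSUM62, affine gaps 11/1) with Karlin–Altschul e-values
   `E = K·m·n·exp(−λS)` (gapped constants λ = 0.267, K = 0.041); forward
   hits need `E ≤ 1e-5`, reverse confirmation uses `E ≤ 10`.
2. **Clock inventory** — per-strain factor copy numbers, KaiB/KaiC paralog
   subtype assignment (KaiB1–3, KaiC1–3), per-genus similarity summaries
   and protein-length distributions. Strains without a KaiC-family homolog
   are dropped.
3. **Co-occurrence** — strains with identical factor combinations collapse
   to unique "clock systems"; every factor pair is then tested for joint
   presence with a right-sided Fisher's exact test (hypergeometric upper
   tail computed via log-factorials), Benjamini–Hochberg corrected at
   FDR 0.01. Significant pairs form a co-occurrence network.
4. **Rhythm analysis** — harmonic regression of expression time series:
   `y(t) = β₀ + β₁t + A·cos(2π(t − φ)/24)` fitted by least squares, with
   oscillation significance from an F-test against the trend-only model and
   BH-adjusted q ≤ 0.05 calling oscillators. Datasets are compared by the
   Jammalamadaka–SenGupta circular correlation of peak phases.
5. **Motif conservation** — homolog alignments projected onto reference
   (KaiC-7942) residue numbering; position frequency matrices and
   wildcard-pattern match fractions for functional motifs such as the CII
   Walker A P-loop (GXXXXGKT; GATGTGKT in the reference) and the
   phosphosites S431/T432.
6. **Synthetic data** — seeded generators with ground-truth tables for all
   of the above (planted homolog families among decoys, presence matrices
   with planted odds ratios, sinusoid-plus-trend expression matrices), so
   every statistical claim is testable without downloads.

## Worked example

Plant one enriched factor pair (odds ratio 20) in 69 synthetic clock
systems and test every pair:

```python
from clockmine.simulate import simulate_clock_systems
from clockmine.cooccurrence import PresenceMatrix, pairwise_cooccurrence, results_table

sim = simulate_clock_systems(
    69, {f"factor_{i+1}": 0.5 for i in range(8)},
    enriched_pairs=[("factor_1", "factor_2", 20.0)], seed=0,
)
res = pairwise_cooccurrence(PresenceMatrix(sim.presence), fdr=0.01)
print(results_table(res).sort_values("p_adj").head(3).to_string(index=False))
```

```
factor_i factor_j  a  b  c  d        p_raw        p_adj  significant
factor_1 factor_2 31  3  5 30 3.722748e-11 1.042370e-09         True
factor_4 factor_8 17 12 11 29 9.276101e-03 1.298654e-01        False
factor_6 factor_7 18 11 17 23 8.651724e-02 6.124983e-01        False
```

Only the planted pair survives BH correction. Rhythm detection on a
synthetic diurnal time course (500 genes, 20% oscillating at amplitude 1,
noise σ = 0.3, sampled every 4 h over 48 h):

```python
from clockmine.simulate import simulate_expression
from clockmine.rhythm import analyze_matrix

sim = simulate_expression(500, frac_oscillating=0.2, noise_sd=0.3, seed=0)
res = analyze_matrix(sim.matrix, transform=False)   # already log-ratio units
print(res[res["oscillating"]].head(3)[["amplitude", "phase", "p", "q"]])
```

```
            amplitude      phase         p         q
gene_00001   0.844532  14.971249  0.001577  0.008481
gene_00002   1.060623   6.325183  0.000009  0.000319
gene_00003   1.097302   0.674077  0.000060  0.000816
```

All 100 planted oscillators are recovered (recall 1.0) with 6 false calls
among 106 — an empirical FDR of 5.7%, matching the nominal q ≤ 0.05.

The same stages are available on the command line (`clockmine --help`):
`simulate`, `rbh`, `inventory`, `lengths`, `cooccur`, `rhythm`, `compare`,
`motifs`, and `run`, which executes the full demo pipeline
(simulate → rbh → inventory → cooccur → rhythm) into a run directory with a
provenance manifest:

```sh
clockmine run --seed 3 --outdir runs/demo
```

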