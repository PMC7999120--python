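# pairedlfq

Label-free quantitative proteomics differential-abundance analysis for
**paired two-condition designs**, with downstream gene-set enrichment,
transcript–protein concordance scoring, and bench-assay metrics. The
motivating setting is an siRNA-knockdown experiment in patient-derived
cell lines (e.g. pulmonary-artery smooth muscle cells): each line is
measured under a scrambled control siRNA and a targeting siRNA, so
inference is on within-line differences, and protein abundances come
from MaxQuant-style `peptides.txt` intensity tables.

It is written for proteomics analysts who have peptide-level LFQ output
and a paired design, and for method developers who want a fully
seeded synthetic test bed with known ground truth.

## The method

Starting from peptide intensities `x_ij` (peptide *i*, sample *j*, linear
scale, zeros treated as missing), the pipeline applies, in order:

1. **Median normalization by column** — `x'_ij = x_ij · T / m_j`, where
   `m_j` is the median of sample *j*'s observed intensities and
   `T = median_j(m_j)`, so every sample's median becomes `T`.
2. **Quantifiability filter** — keep unique and razor peptides with at
   least two observed values in the control group *or* in the treatment
   group.
3. **Noise-floor imputation** — replace each remaining missing cell in
   sample *j* by the 1st percentile of sample *j*'s observed values.
   Missingness in label-free MS is left-censored (low-abundance ions fall
   under the detection limit), so the fill value is a per-sample noise
   floor rather than a central value.
4. **Razor aggregation** — sum peptide intensities per leading razor
   protein accession; keep proteins with ≥ 2 quantified peptides.
5. **Paired testing** — per protein, the effect is the ratio of group
   means `r = mean(treatment) / mean(control)` and the test is a paired
   two-sided Student's *t* on within-line log2 differences
   `d_k = log2(x_{treat,k}) − log2(x_{ctrl,k})`,
   `t = mean(d) / (sd(d)/√n)` with `n − 1` degrees of freedom.
   A protein is differential when `p < 0.05` and
   `max(r, 1/r) > 1.2` (both strict).

Downstream, the package provides a preranked enrichment score (weighted
running-sum walk over a fold-change-ranked list, gene-permutation null,
normalized enrichment score NES), hypergeometric over-representation
with Benjamini–Hochberg selection at adjusted `p < 0.01`, a
transcript–protein concordance report (transcript calls at
`|FC| > 1.5`, `FDR < 0.05`; direction-agreement quadrants; overlap
hypergeometric on the shared measured universe), and closed-form assay
metrics (staining index, ΔΔCt relative expression, and
oligomycin/FCCP/rotenone flux stress-test segmentation).

A synthetic-data generator (`pairedlfq.simulate`) produces all inputs
with known truth: log-normal protein abundance, cell-line random effects
shared within a pair, peptide ionization offsets, abundance-dependent
(MNAR) logistic dropout, and a 10% differential fraction with a
down-skewed sign distribution (72% down).

## Worked example

```bash
python analysis/01_simulate.py --seed 1
python analysis/02_lfq.py --seed 1
python analysis/03_differential.py --seed 1
python analysis/04_enrichment.py --seed 1
python analysis/05_integration.py --seed 1
python analysis/06_assay_metrics.py --seed 1
```

prints, at seed 1:

```
wrote 6182 peptides / 2000 proteins for 4 paired cell lines to results/data
spiked 197 differential proteins (139 down, 58 up); 9.1% of cells missing ...
       stage  peptides  proteins
       input      6182      2000
quantifiable      5763      1986
    proteins      5446      1669
176 differential proteins (124 down, 52 up) of 1669 tested
sensitivity 91.9% on 160 spiked proteins; false discoveries 29
TRUE_DOWN_SET    55 -0.936581 -2.286011 0.001271    0.026684
175 DEGs, 176 DEPs, 130 in common on a 1669-feature shared universe
130/130 common calls agree in direction (quadrants {'up_up': 34, 'down_down': 96, ...})
```

Reading: of 2000 simulated proteins, 1669 survive the two-peptide filter
(160 of the spiked effects among them); the paired test recovers 91.9%
of them at the 1.2-fold / p < 0.05 rule, with the expected down-skew
(124 down vs 52 up). The gene set loaded with truly downregulated
proteins ranks first with NES −2.29, and every transcript–protein
common call agrees in direction — the qualitative signature of a
knockdown that acts in the same direction at both levels.

The same run is available as one command (`pairedlfq --seed 1 run-all
--out-dir results`), which also writes a `manifest.json` recording
parameters, stage counts and the seed; rerunning with the same seed
reproduces every output byte for byte.

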