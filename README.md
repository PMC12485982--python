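# procap-atlas

Analysis stack for PRO-cap nascent-transcription atlases: classification
of transcriptional regulatory elements (TREs), library quality control,
quantification and normalization, tissue-specificity scoring, initiation
shape classification, single-molecule RNAPII pause-distance profiling,
and tissue-of-origin prediction for metastatic samples.

PRO-cap maps transcription initiation at base-pair resolution by
sequencing 5'-capped nascent RNA; each read also carries the 3' position
the polymerase had reached, so one library simultaneously measures where
transcription starts, how focused initiation is, and how far RNAPII
travels before promoter-proximal pausing. This package implements the
statistics built on those observables, for anyone analyzing PRO-cap /
PRO-seq-style strand-specific per-base signal:

- **Elements** — peaks on opposite strands within 300 bp (summit to
  summit) pair into *divergent* elements; lone peaks are *unidirectional*.
  Elements are *proximal* (within ±500 bp of an annotated gene TSS) or
  *distal*, and intragenic/intergenic by gene overlap.
- **QC** — the gene-body ratio: over the top 10% of genes by promoter
  signal, length-normalized gene-body read density divided by the sum of
  body and TSS (first 500 bp) densities. Samples at ≥ 0.025 fail.
- **Quantification** — 5'-end counts per element span; median-of-ratios
  size factors `s_j = median_e (c_ej / (Π_j c_ej)^{1/n})` over all-positive
  element rows, rescaled to geometric mean 1; values `log2(c/s + 1)`.
- **Specificity** — per element, tissue means q_t become probabilities
  `p_t = q_t / Σ q_t`; with entropy `H = −Σ p_t log2 p_t`, the score is
  `S = 1 − H / log2 N` (0 ubiquitous, 1 exclusive). Tissue-specific sets
  are the top 5% of elements per tissue by the t-statistic of a ±1-coded
  OLS membership regression on log-normalized expression.
- **Shape** — per strand, `SI = 2 + Σ_i p_i log2 p_i` over within-element
  read positions (≥ 50 reads/strand); `SI > −1.5` is peaked (P), else
  broad (B); divergent elements are P-P, P-B or B-B.
- **Pausing** — per molecule, distance from 5' to 3' end (strand
  oriented); element medians split into early/intermediate/late classes
  at empirical tertiles.
- **Origin** — average-linkage clustering under correlation distance;
  Pearson similarity in the PC space explaining 90% of variance; and a
  one-vs-rest linear SVC (C = 1) over tissue-specific element features
  that ranks candidate primary sites for metastatic queries with top-k
  output.

A bundled synthetic-data generator plants known ground truth (element
geometry, tissue activity, shape labels, pause offsets, size factors) so
every stage is tested by parameter recovery, without any external data.

## Worked example

```bash
python examples/01_simulate_and_classify.py
```

```
simulated 12 samples, 60 planted elements
called 64 elements: 38 divergent, 26 unidirectional; 18 proximal
first three calls:
  chr1:57301-57502: unidirectional, proximal, intragenic
  chr1:129737-130043: divergent, proximal, intragenic
  chr1:140250-140751: divergent, distal, intergenic
```

Twelve samples over four tissues are simulated, peaks are called on the
pooled 5' signal and paired into divergent/unidirectional elements; the
divergent distal calls are the candidate enhancers downstream stages
score. `examples/02_qc_and_quantify.py` shows the gene-body ratio
separating a clean library (0.0002, pass) from a half-contaminated copy
(0.074, fail) and size-factor recovery (planted 1.544 vs estimated 1.600
for the first sample); `examples/03_specificity_shape_pausing.py` scores
tissue specificity (a planted liver-only element reaches S ≈ 0.8),
initiation shape and pause classes; `examples/04_tissue_of_origin.py`
trains the origin classifier on 93 synthetic normals from 15 tissues and
predicts 23 metastatic-like queries (top-1 100% at default noise) and
reproduces the primary > metastatic > other similarity ordering in PC
space.

The pipeline also runs from the shell:

```bash
procap-atlas run --out results/demo --seed 0     # full pipeline + manifest
procap-atlas simulate --out results/data --seed 0
```

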