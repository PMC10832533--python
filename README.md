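# plasmidtx

Analysis toolkit for the transcriptional landscape of bacterial plasmids:
how strongly each plasmid gene is transcribed, where its transcripts start
and stop, which promoter and terminator architectures drive those levels,
how the plasmid's codon usage relates to the tRNAs it carries, and what
plasmid carriage does to the host chromosome's expression. It is aimed at
microbial genomics researchers who have strand-specific RNA-seq coverage
and gene-level counts for a plasmid/host system and want a reproducible,
tested version of this analysis chain — together with a synthetic-data
generator that plants every feature with known ground truth, so each stage
can be validated by recovery rather than by eye.

## What it computes

* **Expression tiers** — RPKM per gene,
  `RPKM = numReads / ((geneLength/10³) · (totalNumReads/10⁶))`, an
  expression floor of 1.5 RPKM below which genes are called silent, and
  low/medium/high tiers split at the quartiles Q1/Q3 of expressed-gene
  RPKM. TPM (`10⁶ · (count/length) / Σ(count/length)`) for cross-sample
  work.
* **Transcript boundaries** — TSS/TTS called where windowed median
  coverage steps up/down against the local flank; adjacent co-covered
  genes merged into transcriptional units; 5′/3′ UTR lengths, with the TSS
  re-anchored 7 nt downstream of the −10 box when a promoter is placed
  (RNA-seq 5′ ends systematically miss ~20 nt).
* **Promoters** — a bipartite −35/spacer/−10 PWM model with variable
  15–19 nt spacer, fitted by hard-assignment EM seeded from the canonical
  consensus TTGACA·n₁₇·TATAAT; log-odds scanning, per-tier spacer
  histograms, and sequence-logo information content
  `IC_j = 2 + Σ_b f_bj log₂ f_bj`.
* **Terminators** — perfect GC-rich inverted repeats (stem 5–15 nt, loop
  3–10 nt, scored G:C = 3 / A:T = 2), classified rho-independent when a
  ≥4 T tract follows the stem, stem-loop without it, or convergent when
  opposite-strand units terminate head-on within 100 nt.
* **Regulon motif** — IUPAC scanning (W/Y/N semantics) of a 34 bp
  consensus over 60 bp windows upstream of start codons.
* **Codon usage** — RSCU, Sharp–Li CAI, Bennetzen–Hall CBI, third-position
  composition (A3/T3/C3/G3/GC3), Kyte–Doolittle gravy and aromaticity,
  rare codons (<10% within-family usage), anticodon→codon decoding, a
  chi-squared comparison of codon-count profiles, and mean-RSCU
  compatibility of gene sets with a tRNA pool.
* **Differential expression** — TPM matrix, k-means with SSE-elbow
  selection of k, per-gene tests with empirical-Bayes variance moderation
  and adaptive fold-change shrinkage, Benjamini–Hochberg FDR, and calls at
  fc ≥ 2, p < 0.05, FDR < 0.1; Mann–Whitney functional-class-scoring
  enrichment over the log₂ fold changes.

## Worked example

The numbered scripts under `analysis/` run the whole study on synthetic
data; each writes its tables under `results/` and prints what it found:

```sh
python analysis/01_simulate.py --seed 1
python analysis/03_boundaries.py
python analysis/04_regulatory_elements.py
python analysis/06_differential_expression.py
```

prints, among other lines:

```
TSS recovery within 5 nt: 12/12; TTS within 10 nt: 12/12
promoter consensus: -35 TTGACA / -10 TATAAT, modal spacer 17 nt (2 EM iterations)
terminator classes: {'stem_loop': 4, 'rho_independent': 6, 'convergent': 2}
regulon motif: 2 hits across 2 genes (planted in 2; recovered 2)
k-means: optimal k = 2 (SSE by k: {1: 10990, 2: 8865, 3: 7687, ...})
calls: 122 up, 28 down (planted 127 up, 30 down)
sensitivity 0.936, empirical FDR 0.020
```

Every planted start site was re-found within 5 nt from coverage alone, the
EM recovered the exact planted promoter consensus and the 17 nt modal
spacer, all three termination strategies were classified correctly, and
the differential-expression stage recovered 94% of the planted 157
up/down genes with 2% false discoveries at the fc ≥ 2 / p < 0.05 /
FDR < 0.1 thresholds. `analysis/07_full_pipeline.py` runs the same chain
as one deterministic command (same seed ⇒ byte-identical outputs).

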