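# Methods

This note documents the models behind each stage, the defaults and why
they were chosen, what the synthetic generator does and does not emulate,
and the numerical conventions. Internally all coordinates are 0-based
half-open on the forward strand; GFF3 and printed feature spans are
1-based inclusive (a feature printed as 120,876–121,272 spans 397 nt).

## Synthetic data generator

The generator (`plasmidtx.synthetic`) builds a high-GC plasmid genome in
which every regulatory feature is planted explicitly and recorded in a
`TruthSet`, so downstream stages are evaluated by recovery against known
truth rather than against curated annotations.

**Genome layout.** Background sequence is i.i.d. with GC fraction 0.60
(bifidobacteria and their plasmids are high-GC; the exact value is a
modelling choice). Default 12–16 genes of 100–300 codons are placed in
transcriptional units separated by random gaps; an optional
`operon_sizes` list groups several genes into one unit sharing a promoter
and terminator. Tiers {high, medium, low, silent} are assigned by the
`tier_proportions` fractions (default ¼ each).

**Promoters.** Each non-silent unit carries −35/−10 hexamers derived from
the canonical consensus TTGACA/TATAAT with at most 1 (high tier), 2
(medium) or 3 (low) substitutions, a spacer drawn per tier — high-tier
spacers are 17 nt with 80% probability, medium/low tiers peak at 16 nt
with a ±1 spread — and a TSS exactly 7 nt downstream of the −10 3′ end.
5′ UTRs are drawn 32–60 nt for high-tier and 20–45 nt for other units, so
highly transcribed units have longer 5′ UTRs by construction; this is a
planted property the boundary stage must *recover*, not discover.

**Terminators.** Rho-independent and stem-loop units get a perfect
8 bp inverted repeat (≥6 of 8 stem pairs G:C) with a 4 nt loop planted
just downstream of the annotated TTS, followed by an 8 T tract
(rho-independent) or an explicitly T-free tail (stem-loop). Convergent
units are planted as opposite-strand pairs whose 3′ ends fall within
50 nt and carry no hairpin. Default class mix: 50/30/20%.

**Regulon motif.** `motif_count` copies of the 34 bp IUPAC consensus
(W/Y resolved at random) overwrite the region [TSS−20, TSS+14) of
distinct highly expressed genes, so the motif's internal TATACT box
replaces the planted −10 hexamer exactly as the motif is defined to
overlap it.

**Coverage.** Each transcript is covered by `depth` independent
full-length copies (tier defaults 200/100/50/0×); each copy is cut into
consecutive `frag_len` = 50 nt fragments at a random phase. Fragment
boundaries are therefore uniform over the transcript while per-base depth
equals the tier target exactly, with sharp steps at the TSS and TTS — the
situation the coverage-step detector is designed for. A Poisson(0.2)
per-base background on both strands exercises the thresholding logic.
Total signal depth equals fragments × length minus logged end-truncation.

**Counts.** The two-condition chromosome experiment draws baselines from
log-normal(log 50, 1) and counts from a negative binomial with dispersion
0.1 at 3 replicates per condition; 127 up- and 30 down-regulated genes
are planted at |log₂fc| = 2. These defaults mirror the scale of a
plasmid-carriage comparison with 157 differentially expressed genes.

**Not emulated:** read-level errors, mappability, rRNA contamination,
fragment GC bias, operonic read-through variation, codon bias within
CDSs (codons are GC-weighted random, so no within-family codon is rare —
the rare-codon rule is exercised by unit tests on constructed profiles),
and any correlation between tier and GC3. Passing recovery tests
therefore shows the inference machinery is correct under idealised noise,
not that it is robust to every artefact of real libraries.

## Quantification and tiering

RPKM uses the gene-level fragment count, gene length and per-sample
mapped total. The expression floor (default 1.5 RPKM) marks genes silent;
quartiles are computed on expressed genes only with linear-interpolation
(type-7) quantiles — the most common convention, fixed for
reproducibility. Boundaries: low ≤ Q1 < medium ≤ Q3 < high, a partition
whose choice only matters at ties. Tiers are assigned on the mean RPKM
across replicates so each gene carries one tier. Note that the absolute
floor presumes realistically deep libraries; on shallow synthetic
fixtures (tens of thousands of fragments) RPKM values are inflated and
the quartile split, not the floor, separates the silent genes.

## Boundary detection

A TSS is any position whose windowed median depth (window 5 nt) is at
least max(10, 3 × median of the upstream 50 nt flank); chained candidates
closer than the window merge to the position with the largest single-base
rise (leftmost on ties). TTS detection is the exact mirror, implemented
by running the same detector on the reversed track, which also gives the
strand-symmetry invariant for free. Flanks are edge-padded, not
zero-padded, so a contig edge is never itself a step. The paper-style
description ("first/last base where coverage rises/drops") gives no
thresholds; min-depth 10, ratio 3 and the windows are package defaults
exposed in `StepParams`.

Units are assembled by joining consecutive same-strand genes when the
inter-gene depth never falls below 0.25 × the smaller flanking gene mean
and no TSS lies between them (0.25 is conservative and configurable);
each unit takes the nearest upstream TSS and downstream TTS within
300 nt. When a promoter is subsequently placed, the TSS is re-anchored
7 nt downstream of the −10 3′ end (the prokaryotic norm is 6–8 nt; 7 is
fixed for determinism), recovering the ~20 nt the RNA-seq 5′ end tends to
miss; a refinement that would cross the start codon is rejected and
flagged.

## Promoter model

The model is two 4×6 PWMs (−35, −10), a spacer prior over 15–19 nt and a
background base distribution estimated from the input windows. Fitting is
hard-assignment EM: the E-step picks the placement maximising
Σ log₂(pwm/background) + log₂ spacer-prior (leftmost placement, then
shortest spacer, on ties); the M-step rebuilds PWMs with pseudocount 0.5
per cell — also applied to the spacer counts to keep the prior strictly
positive — stopping when no PWM entry moves by 1e-4 or after 100
iterations. Seeding from the literature consensus makes this a
constrained refinement, not de-novo discovery: that is deliberate, since
the biology anchors on a known consensus. The scan threshold (4 bits) and
the 62 nt window width are package defaults. Models whose mean column
information content is below 0.5 bits in both PWMs are flagged
low-information.

## Terminator calling

Hairpins are perfect Watson–Crick inverted repeats (no G:U, no bulges in
this version — an extension point), stem 5–15 nt, loop 3–10 nt, scored
3 per G:C and 2 per A:T pair; overlapping candidates are pruned to the
best score. Classification looks in [TTS−20, TTS+150], ignores hairpins
scoring below 18 (chance perfect 5-mers are common in 60% GC sequence;
the threshold corresponds to a strong 6–8 bp stem), and takes the
qualifying hairpin *nearest the TTS* — the terminator acting on a
transcript is the one at its 3′ end, and a neighbouring unit's terminator
can easily sit within 150 nt. Precedence: GC fraction ≥ 0.5 plus ≥4 T in
the 8 nt after the stem → rho-independent; any other qualifying hairpin →
stem-loop; otherwise an opposite-strand unit terminating within 100 nt →
convergent; else none. Thermodynamic folding (nearest-neighbour ΔG) is
out of scope.

## Codon usage

RSCU is observed/expected frequency within each synonymous family; CAI is
the Sharp–Li geometric mean of relative adaptiveness w = RSCU/max-RSCU
(absent codons floored at w = 0.01), excluding ATG, TGG and stops; CBI is
Bennetzen–Hall (N_opt − N_rand)/(N_tot − N_rand) over multi-codon
families. These conventions are stated explicitly because published
analyses often cite CodonW without printing formulas. GC3 is computed
over the third positions of all sense codons (the plain reading of
"G+C content in the third position"); synonymous-only variants can be
derived from the same counts. Hydropathy and aromaticity come from the
Kyte–Doolittle scale and the F/Y/W fraction via Biopython. Anticodon
decoding is strict reverse-complement (no wobble) in this version. The
profile comparison chi-squared runs on raw codon counts, not RSCU values
— RSCU ratios violate the count assumptions of the test — pooling
columns whose expected count falls below 1.

## Differential expression

TPM normalisation, per-gene tests on log₂(TPM+1), BH FDR, and calls at
|log₂fc| ≥ 1 with p < 0.05 and q < 0.1 after a mean-TPM ≥ 1 pre-filter.
Three estimator choices matter at n = 3 replicates and are the package's
own design:

1. **Variance moderation.** Per-gene pooled variances are squeezed toward
   a scaled-inverse-chi-square prior whose log-scale centre follows a
   quadratic trend in mean expression, with prior df estimated by moments
   (the limma/limma-trend idea, implemented directly). Unmoderated Welch
   tests at n = 3 are so underpowered that BH yields no q < 0.1 calls at
   all on the default design; `gene_test` (plain Welch with a 1e-3
   variance floor) remains available and `call_degs(moderate=False)` uses
   it.
2. **Median recentring.** TPM is compositional: an asymmetric set of true
   changes (127 up vs 30 down) shifts every null gene's log-ratio by
   ~−0.3, which a naive test converts into genome-wide spurious "down"
   calls. The median log-ratio across tested genes estimates the shift
   (the median-of-ratios normalisation assumption: most genes unchanged)
   and is subtracted before testing and thresholding.
3. **Fold-change shrinkage.** Reported log₂fc is the posterior mean under
   a two-component prior fitted by EM — a spike (true effect 0) and a
   normal slab of real effects — so chance 2-fold changes of null genes
   (≈2.6σ events at this design, frequent among ~1700 nulls) are damped
   below the fc threshold while genuine 4-fold effects pass nearly
   unshrunk. Raw estimates are kept in `log2fc_raw`. On the default
   planted design this yields sensitivity ≈ 0.89–0.95 and empirical FDR
   ≤ 0.04 across seeds.

Cluster number is chosen by k-means (k-means++, 10 restarts, fixed seed
20240111) over row-z-scored log₂(TPM+1), maximising the second difference
of the SSE curve over k = 1..8 (smaller k on ties; identical rows give
k = 1). Enrichment is a two-sided Mann–Whitney test of a gene set's log₂
fold changes against the complement, exact by enumeration when |set| ≤ 8
and background ≤ 25, otherwise the tie-corrected normal approximation.

## Problem sizes and determinism

The bundled analyses use a 16-gene, 26 kb plasmid at 50–200× coverage and
a 1,864-gene count matrix — sizes at which every planted feature is
recovered in seconds while keeping the full suite comfortably fast. All
stages are pure functions of (parameters, seed); the pipeline embeds the
seed and a config hash in every output header and reruns byte-identically.

## Known limitations

Perfect-stem hairpins only; strict Watson–Crick anticodon decoding; no
condition-specific TSS switching or antisense unit discovery; the
chi-squared comparison treats pooled codon counts as independent
observations; enrichment uses ranks only (no gene-length or GC
covariates); and the synthetic generator's idealisations listed above
bound what recovery tests can certify about real libraries.
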