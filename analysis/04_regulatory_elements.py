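#!/usr/bin/env python
"""Characterise promoters, terminators and the 34 bp regulon motif.

Fits the -35/spacer/-10 promoter model by constrained EM on 62 bp windows
upstream of detected TSSs, tabulates spacer lengths by tier, classifies
termination strategies, and scans 60 bp windows upstream of start codons
for the regulon consensus.
"""

import argparse
from collections import Counter

import pandas as pd

from plasmidtx.boundaries import assemble_tus, detect_tss, detect_tts, refine_utrs
from plasmidtx.coverage import CoverageTrack, read_bedgraph
from plasmidtx.genome import GenomeBundle
from plasmidtx.regulatory import (
    IupacMotif, call_promoter_for_tu, classify_terminator, extract_upstream,
    fit_promoter_model, logo_matrix, scan_iupac_motif, spacer_stats,
)
from plasmidtx.synthetic import TruthSet


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--simdir", default="results/sim")
    ap.add_argument("--outdir", default="results")
    ap.add_argument("--max-mm", type=int, default=3)
    args = ap.parse_args()

    bundle = GenomeBundle.read(f"{args.simdir}/genome.fasta", f"{args.simdir}/genes.gff3")
    truth = TruthSet.from_json(f"{args.simdir}/truth.json")
    L = len(bundle)
    cov = CoverageTrack(
        plus=read_bedgraph(f"{args.simdir}/coverage.plus.bedgraph", L),
        minus=read_bedgraph(f"{args.simdir}/coverage.minus.bedgraph", L),
    )
    tiers = {g.gene_id: g.tier for g in truth.genes.values()}
    tus = assemble_tus(
        bundle.genes,
        {s: detect_tss(cov, s) for s in "+-"},
        {s: detect_tts(cov, s) for s in "+-"},
        cov, gene_tiers=tiers,
    )

    with_tss = [t for t in tus if t.tss is not None]
    windows = [extract_upstream(bundle, t.tss, 62, t.strand)[0] for t in with_tss]
    model = fit_promoter_model(windows)
    print(f"promoter consensus: -35 {model.consensus()[0]} / -10 {model.consensus()[1]}, "
          f"modal spacer {model.spacer_mode()} nt "
          f"({len(model.objective_trace)} EM iterations)")

    calls, by_tier = [], {}
    for tu in with_tss:
        call = call_promoter_for_tu(bundle, tu, model)
        if call:
            calls.append(call)
            refine_utrs(tu, call)
            if tu.tier:
                by_tier.setdefault(tu.tier, []).append(call)
    pd.DataFrame(
        [{"tu_id": c.tu_id, "minus35": c.minus35, "spacer": c.spacer_len,
          "minus10": c.minus10, "score_bits": round(c.score, 2)} for c in calls]
    ).to_csv(f"{args.outdir}/promoters.tsv", sep="\t", index=False)
    for tier, st in sorted(spacer_stats(by_tier).items()):
        print(f"  spacer histogram ({tier}): {st['hist']} -> mode {st['mode']}")

    ic, _ = logo_matrix([w[-33:] for w in windows])
    pd.DataFrame({"position": range(-33, 0), "ic_bits": ic.round(4)}).to_csv(
        f"{args.outdir}/logo.tsv", sep="\t", index=False
    )

    terms = [classify_terminator(tu, bundle, tus) for tu in tus]
    klasses = Counter(t.klass for t in terms)
    pd.DataFrame(
        [{"tu_id": t.tu_id, "class": t.klass, "stem_len": t.stem_len,
          "gc_frac": t.stem_gc_frac, "poly_t": t.poly_t, "score": t.score}
         for t in terms]
    ).to_csv(f"{args.outdir}/terminators.tsv", sep="\t", index=False)
    print(f"terminator classes: {dict(klasses)}")

    hits = scan_iupac_motif(bundle, IupacMotif(max_mismatches=args.max_mm))
    pd.DataFrame(
        [{"gene_id": h.gene_id, "start": h.genome_start, "strand": h.strand,
          "mismatches": h.mismatches} for h in hits]
    ).to_csv(f"{args.outdir}/motif_hits.tsv", sep="\t", index=False)
    planted = {g.gene_id for g in truth.genes.values() if g.motif_start is not None}
    found = {h.gene_id for h in hits}
    print(f"regulon motif: {len(hits)} hits across {len(found)} genes "
          f"(planted in {len(planted)}; recovered {len(planted & found)})")


if __name__ == "__main__":
    main()
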