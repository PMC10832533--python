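#!/usr/bin/env python
"""Map transcript boundaries from coverage and assemble transcriptional units.

Detects TSS/TTS as coverage steps, groups co-covered adjacent genes into
TUs, measures recovery against the planted truth, and compares 5' UTR
lengths between expression tiers.
"""

import argparse

import numpy as np
import pandas as pd

from plasmidtx.boundaries import assemble_tus, detect_tss, detect_tts
from plasmidtx.coverage import CoverageTrack, read_bedgraph
from plasmidtx.genome import GenomeBundle
from plasmidtx.synthetic import TruthSet


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--simdir", default="results/sim")
    ap.add_argument("--out", default="results/tus.tsv")
    args = ap.parse_args()

    bundle = GenomeBundle.read(f"{args.simdir}/genome.fasta", f"{args.simdir}/genes.gff3")
    truth = TruthSet.from_json(f"{args.simdir}/truth.json")
    L = len(bundle)
    cov = CoverageTrack(
        plus=read_bedgraph(f"{args.simdir}/coverage.plus.bedgraph", L),
        minus=read_bedgraph(f"{args.simdir}/coverage.minus.bedgraph", L),
    )
    tss = {s: detect_tss(cov, s) for s in "+-"}
    tts = {s: detect_tts(cov, s) for s in "+-"}
    tiers = {g.gene_id: g.tier for g in truth.genes.values()}
    tus = assemble_tus(bundle.genes, tss, tts, cov, gene_tiers=tiers)

    rows = [
        {"tu_id": t.tu_id, "strand": t.strand, "genes": ",".join(t.gene_ids),
         "tss": t.tss, "tts": t.tts, "utr5": t.utr5_len, "utr3": t.utr3_len,
         "tier": t.tier, "flags": ";".join(t.flags)}
        for t in tus
    ]
    pd.DataFrame(rows).to_csv(args.out, sep="\t", index=False)

    hit5 = hit10 = total = 0
    for g in truth.genes.values():
        if g.tss is None:
            continue
        total += 1
        hit5 += np.abs(tss[g.strand] - g.tss).min() <= 5
        hit10 += np.abs(tts[g.strand] - g.tts).min() <= 10
    print(f"{len(tus)} TUs -> {args.out}")
    print(f"TSS recovery within 5 nt: {hit5}/{total}; TTS within 10 nt: {hit10}/{total}")
    utr = {}
    for t in tus:
        if t.tier and t.utr5_len is not None:
            utr.setdefault(t.tier, []).append(t.utr5_len)
    for tier in ("high", "medium", "low"):
        if tier in utr:
            print(f"mean 5'UTR ({tier}): {np.mean(utr[tier]):.1f} nt")


if __name__ == "__main__":
    main()
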