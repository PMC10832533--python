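#!/usr/bin/env python
"""Codon-usage profile of the plasmid by transcription tier.

Pools codon counts of high- vs low/silent-tier genes, contrasts GC3 and
CAI/CBI, tests the codon-count profiles with a chi-squared comparison,
lists rare codons (<10% within-family usage), and scores RSCU
compatibility with a plasmid-carried tRNA set.
"""

import argparse
from collections import Counter

import pandas as pd

from plasmidtx import codon as cu
from plasmidtx.genome import GenomeBundle
from plasmidtx.synthetic import TruthSet

#: anticodons decoding codons rare in a typical high-GC host
ANTICODONS = ("UCU", "CCU", "CCC", "UCC", "AAG", "UGG", "UGA")


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--simdir", default="results/sim")
    ap.add_argument("--outdir", default="results")
    args = ap.parse_args()

    bundle = GenomeBundle.read(f"{args.simdir}/genome.fasta", f"{args.simdir}/genes.gff3")
    truth = TruthSet.from_json(f"{args.simdir}/truth.json")

    pooled: dict[str, Counter] = {"high": Counter(), "low": Counter()}
    rows = []
    for g in bundle.genes:
        tier = truth.genes[g.gene_id].tier
        cds = g.cds(bundle.seq)
        counts = cu.codon_counts(cds)
        comp = cu.base_composition(cds)
        gravy, aromo = cu.gravy_aromo(cu.translate(cds))
        rows.append({"gene_id": g.gene_id, "tier": tier, "gc3": round(comp["gc3"], 4),
                     "gc": round(comp["gc"], 4), "gravy": round(gravy, 3),
                     "aromo": round(aromo, 4)})
        key = "high" if tier == "high" else ("low" if tier in ("low", "silent") else None)
        if key:
            pooled[key].update(counts)
    pd.DataFrame(rows).to_csv(f"{args.outdir}/codon_profile.tsv", sep="\t", index=False)

    weights = cu.reference_weights(pooled["high"])
    for key, counts in pooled.items():
        gc3 = sum(v for c, v in counts.items() if c[2] in "GC") / sum(counts.values())
        print(f"{key}-tier pool: {sum(counts.values())} codons, GC3 {gc3:.3f}, "
              f"CAI {cu.cai(counts, weights):.3f}, "
              f"CBI {cu.cbi(counts, cu.optimal_codons(weights)):.3f}")

    chi2, df, p = cu.rscu_chisq(pooled["high"], pooled["low"])
    print(f"high vs low codon profile: chi2={chi2:.1f}, df={df}, p={p:.3g}")

    genome_counts = pooled["high"] + pooled["low"]
    rare = sorted(cu.rare_codons(genome_counts))
    print(f"rare codons (<10% within family): {rare}")

    trna = cu.trna_to_codons(ANTICODONS)
    profiles = {k: cu.rscu(v) for k, v in pooled.items()}
    compat = cu.trna_compatibility(profiles, trna)
    for k, v in sorted(compat.items()):
        print(f"mean RSCU over tRNA-decoded codons ({k}): {v['mean']:.3f}")

    rscu_rows = []
    for k, prof in profiles.items():
        for c, v in sorted(prof.items()):
            rscu_rows.append({"set": k, "codon": c, "rscu": round(v, 4)})
    pd.DataFrame(rscu_rows).to_csv(f"{args.outdir}/rscu_matrix.tsv", sep="\t", index=False)


if __name__ == "__main__":
    main()
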