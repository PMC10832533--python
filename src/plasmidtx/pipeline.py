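"""End-to-end pipeline orchestration over synthetic or provided inputs.

Runs simulate -> quantify -> boundaries -> promoters/terminators/motif scan
-> codon usage -> differential expression, writes every intermediate as a
TSV/flat file with a provenance header, and assembles a summary report.
Deterministic: the same (config, seed) yields byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import os
from collections import Counter
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import __version__
from .genome import GenomeBundle
from .coverage import CoverageTrack, read_bedgraph, write_bedgraph
from .synthetic import (
    CountDesign, GenParams, TruthSet, generate_plasmid, simulate_counts,
    simulate_coverage, write_fixture,
)
from .quantify import expression_table
from .boundaries import StepParams, assemble_tus, detect_tss, detect_tts, refine_utrs
from .regulatory import (
    IupacMotif, call_promoter_for_tu, classify_terminator, extract_upstream,
    fit_promoter_model, logo_matrix, scan_iupac_motif, spacer_stats,
)
from . import codon as cu
from .dge import DgeThresholds, call_degs

#: anticodons (RNA 5'->3') decoding codons that are rare in a typical
#: high-GC host; used for the tRNA-pool compatibility summary
DEFAULT_ANTICODONS = ("UCU", "CCU", "CCC", "UCC", "AAG", "UGG", "UGA")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    seed: int = 0
    gen: GenParams = field(default_factory=GenParams)
    design: CountDesign = field(default_factory=CountDesign)
    step: StepParams = field(default_factory=StepParams)
    depth_per_tier: dict | None = None
    frag_len: int = 50
    noise_rate: float = 0.2
    rpkm_floor: float = 1.5
    promoter_window: int = 62
    promoter_threshold: float = 4.0
    motif_max_mismatches: int = 3
    motif_window: int = 60
    anticodons: tuple = DEFAULT_ANTICODONS
    dge: DgeThresholds = field(default_factory=DgeThresholds)
    circular: bool = False

    def config_hash(self) -> str:
        payload = json.dumps(_to_jsonable(asdict(self)), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _to_jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj


def _header(config: PipelineConfig) -> str:
    return f"# plasmidtx {__version__} seed={config.seed} config={config.config_hash()}\n"


def _write_tsv(df: pd.DataFrame, path, config: PipelineConfig) -> None:
    with open(path, "w") as fh:
        fh.write(_header(config))
        df.to_csv(fh, sep="\t")


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Run the full synthetic-demo pipeline; returns the report as a dict."""
    os.makedirs(outdir, exist_ok=True)
    report: dict = {"seed": config.seed, "config_hash": config.config_hash()}

    # ------------------------------------------------ simulate
    try:
        config.gen.seed = config.seed
        config.design.seed = config.seed + 1
        bundle, truth = generate_plasmid(config.gen)
        cov, _ = simulate_coverage(
            bundle, truth, depth_per_tier=config.depth_per_tier,
            frag_len=config.frag_len, noise_rate=config.noise_rate,
            seed=config.seed + 2,
        )
        counts, deg_truth = simulate_counts(config.design)
        write_fixture(outdir, bundle, truth, cov=cov, counts=counts)
    except Exception as e:  # pragma: no cover - defensive
        raise PipelineError("simulate", e) from e

    # ------------------------------------------------ quantify
    try:
        cov_counts = pd.DataFrame(
            {
                "cov": [
                    int(round(cov.strand(g.strand)[g.start : g.end].sum() / config.frag_len))
                    for g in bundle.genes
                ]
            },
            index=pd.Index([g.gene_id for g in bundle.genes], name="gene_id"),
        )
        lengths = pd.Series(
            {g.gene_id: g.length for g in bundle.genes}, name="length"
        )
        expr = expression_table(cov_counts, lengths, floor=config.rpkm_floor)
        _write_tsv(expr, os.path.join(outdir, "expression.tsv"), config)
        tier_counts = Counter(expr["tier"])
        report["tier_counts"] = {t: int(tier_counts.get(t, 0)) for t in
                                 ("high", "medium", "low", "silent")}
    except Exception as e:
        raise PipelineError("quantify", e) from e

    # ------------------------------------------------ boundaries
    try:
        tss = {s: detect_tss(cov, s, config.step) for s in "+-"}
        tts = {s: detect_tts(cov, s, config.step) for s in "+-"}
        gene_tiers = expr["tier"].to_dict()
        tus = assemble_tus(bundle.genes, tss, tts, cov, gene_tiers, config.step)
    except Exception as e:
        raise PipelineError("boundaries", e) from e

    # ------------------------------------------------ promoters
    try:
        windows = []
        with_tss = [tu for tu in tus if tu.tss is not None]
        for tu in with_tss:
            w, _ = extract_upstream(bundle, tu.tss, config.promoter_window, tu.strand)
            windows.append(w)
        model = fit_promoter_model(windows) if len(windows) >= 10 else None
        calls, by_tier = [], {}
        if model is not None:
            for tu in with_tss:
                call = call_promoter_for_tu(
                    bundle, tu, model,
                    width=config.promoter_window,
                    threshold=config.promoter_threshold,
                )
                if call is not None:
                    calls.append(call)
                    refine_utrs(tu, call)
                    if tu.tier:
                        by_tier.setdefault(tu.tier, []).append(call)
            report["spacer_mode_by_tier"] = {
                t: st["mode"] for t, st in spacer_stats(by_tier).items()
            }
            ic, _ = logo_matrix([w[-33:] for w in windows])
            pd.DataFrame({"ic_bits": ic}).to_csv(
                os.path.join(outdir, "logo.tsv"), sep="\t"
            )
        prom_df = pd.DataFrame(
            [
                {
                    "tu_id": c.tu_id, "minus35": c.minus35,
                    "spacer": c.spacer_len, "minus10": c.minus10,
                    "score": round(c.score, 3),
                }
                for c in calls
            ]
        )
        _write_tsv(prom_df, os.path.join(outdir, "promoters.tsv"), config)
        utr_by_tier: dict[str, list] = {}
        for tu in tus:
            if tu.tier and tu.utr5_len is not None:
                utr_by_tier.setdefault(tu.tier, []).append(tu.utr5_len)
        report["mean_utr5_by_tier"] = {
            t: round(float(np.mean(v)), 2) for t, v in sorted(utr_by_tier.items())
        }
    except Exception as e:
        raise PipelineError("promoters", e) from e

    # ------------------------------------------------ terminators
    try:
        term_calls = [classify_terminator(tu, bundle, tus) for tu in tus]
        klasses = Counter(t.klass for t in term_calls)
        total = max(sum(klasses.values()), 1)
        report["terminator_proportions"] = {
            k: round(klasses.get(k, 0) / total, 3)
            for k in ("rho_independent", "stem_loop", "convergent", "none")
        }
        term_df = pd.DataFrame(
            [{"tu_id": t.tu_id, "class": t.klass, "score": t.score,
              "poly_t": t.poly_t} for t in term_calls]
        )
        _write_tsv(term_df, os.path.join(outdir, "terminators.tsv"), config)
    except Exception as e:
        raise PipelineError("terminators", e) from e

    # ------------------------------------------------ motif scan
    try:
        motif = IupacMotif(max_mismatches=config.motif_max_mismatches)
        scan_hits = scan_iupac_motif(bundle, motif, window=config.motif_window)
        report["regulon_gene_tally"] = len({h.gene_id for h in scan_hits})
        hits_df = pd.DataFrame(
            [{"gene_id": h.gene_id, "start": h.genome_start, "strand": h.strand,
              "mismatches": h.mismatches} for h in scan_hits]
        )
        _write_tsv(hits_df, os.path.join(outdir, "motif_hits.tsv"), config)
    except Exception as e:
        raise PipelineError("motifscan", e) from e

    # ------------------------------------------------ codon usage
    try:
        tier_counts_pool: dict[str, Counter] = {}
        for g in bundle.genes:
            tier = expr.loc[g.gene_id, "tier"]
            key = "high" if tier == "high" else ("low" if tier in ("low", "silent") else "medium")
            tier_counts_pool.setdefault(key, Counter()).update(cu.codon_counts(g.cds(bundle.seq)))
        profiles = {k: cu.rscu(v) for k, v in tier_counts_pool.items()}
        if {"high", "low"} <= set(tier_counts_pool):
            chi2, df_, p = cu.rscu_chisq(tier_counts_pool["high"], tier_counts_pool["low"])
            report["codon_chisq_p_high_vs_low"] = float(p)
        trna = cu.trna_to_codons(config.anticodons)
        compat = cu.trna_compatibility(profiles, trna)
        report["trna_compat_mean_rscu"] = {
            k: round(v["mean"], 3) for k, v in sorted(compat.items())
        }
    except Exception as e:
        raise PipelineError("codon", e) from e

    # ------------------------------------------------ differential expression
    try:
        chrom_lengths = pd.Series(1000.0, index=counts.index)
        a_cols = [c for c in counts.columns if c.startswith("ctrl")]
        b_cols = [c for c in counts.columns if c.startswith("plasmid")]
        res = call_degs(counts, chrom_lengths, a_cols, b_cols,
                        thresholds=config.dge, cluster_seed=config.seed + 3)
        _write_tsv(res.table, os.path.join(outdir, "dge.tsv"), config)
        report["deg_counts"] = {"up": res.n_up, "down": res.n_down}
        report["kmeans_k"] = res.clusters.k
    except Exception as e:
        raise PipelineError("dge", e) from e

    rows = [{"key": k, "value": json.dumps(_to_jsonable(v), sort_keys=True)}
            for k, v in sorted(report.items())]
    _write_tsv(pd.DataFrame(rows).set_index("key"),
               os.path.join(outdir, "report.tsv"), config)
    return report


# --------------------------------------------------------------------------
# input validation


def validate_io(files: dict) -> list[str]:
    """Check FASTA/GFF3/bedGraph/counts files for format violations.

    `files` maps kinds ('fasta', 'gff3', 'bedgraph', 'counts') to paths;
    returns a list of human-readable violations (empty when clean).
    """
    problems: list[str] = []
    genome_len = None
    if "fasta" in files:
        try:
            from Bio import SeqIO

            recs = list(SeqIO.parse(files["fasta"], "fasta"))
            if not recs:
                problems.append("fasta: no records")
            else:
                genome_len = len(recs[0].seq)
                bad = set(str(recs[0].seq).upper()) - set("ACGTN")
                if bad:
                    problems.append(f"fasta: invalid characters {sorted(bad)}")
        except Exception as e:
            problems.append(f"fasta: unparseable ({e})")
    if "gff3" in files:
        with open(files["gff3"]) as fh:
            for ln, line in enumerate(fh, 1):
                if line.startswith("#") or not line.strip():
                    continue
                parts = line.rstrip("\n").split("\t")
                if len(parts) != 9:
                    problems.append(f"gff3 line {ln}: expected 9 columns")
                    continue
                try:
                    start, end = int(parts[3]), int(parts[4])
                except ValueError:
                    problems.append(f"gff3 line {ln}: non-integer coordinates")
                    continue
                if end < start:
                    problems.append(f"gff3 line {ln}: end {end} < start {start}")
                if start < 1:
                    problems.append(f"gff3 line {ln}: start < 1")
                if genome_len is not None and end > genome_len:
                    problems.append(f"gff3 line {ln}: end {end} beyond genome")
                if parts[6] not in "+-.":
                    problems.append(f"gff3 line {ln}: bad strand {parts[6]!r}")
    for key in ("bedgraph", "bedgraph_plus", "bedgraph_minus"):
        if key not in files:
            continue
        prev_end = None
        with open(files[key]) as fh:
            for ln, line in enumerate(fh, 1):
                if not line.strip() or line.startswith(("#", "track")):
                    continue
                parts = line.rstrip("\n").split("\t")
                if len(parts) != 4:
                    problems.append(f"{key} line {ln}: expected 4 columns")
                    continue
                s, e = int(parts[1]), int(parts[2])
                if e <= s:
                    problems.append(f"{key} line {ln}: empty/negative interval")
                if prev_end is not None and s < prev_end:
                    problems.append(f"{key} line {ln}: overlapping intervals")
                prev_end = e
    if "counts" in files:
        try:
            df = pd.read_csv(files["counts"], sep="\t", index_col=0, comment="#")
            if (df.select_dtypes(include=[np.number]) < 0).any().any():
                problems.append("counts: negative values")
            if df.select_dtypes(include=[np.number]).shape[1] != df.shape[1]:
                problems.append("counts: non-numeric sample columns")
        except Exception as e:
            problems.append(f"counts: unparseable ({e})")
    return problems
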