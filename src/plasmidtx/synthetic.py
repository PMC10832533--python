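"""Synthetic plasmid/chromosome fixtures with known regulatory ground truth.

The generator emulates the structure of a high-GC plasmid transcriptome:
tiered gene expression, canonical TTGACA-n17-TATAAT promoters whose
degeneracy and spacer jitter depend on expression tier, GC-rich hairpin
terminators with or without a poly-T tail, convergent gene pairs, an
embedded 34 bp IUPAC regulon motif overlapping -10 elements, and a
two-condition negative-binomial count matrix with planted up/down
differentially expressed genes.  Every planted feature is recorded in a
:class:`TruthSet` so downstream recovery can be measured exactly.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .genome import Gene, GenomeBundle, revcomp
from .coverage import CoverageTrack

logger = logging.getLogger(__name__)

TIERS = ("high", "medium", "low", "silent")
CONSENSUS_35 = "TTGACA"
CONSENSUS_10 = "TATAAT"
SPACER_RANGE = (15, 19)

#: 34 bp regulon consensus; W={A,T}, Y={C,T}; the -10 box (TATACT) spans
#: positions 9-14 (1-based) of the pattern.
REGULON_MOTIF = "AWAYATGYTATACTGAATATGTCCACATAAAAWA"

STOP_CODONS = ("TAA", "TAG", "TGA")


class SizingError(ValueError):
    """Requested features do not fit in the requested genome length."""


# --------------------------------------------------------------------------
# parameter containers


def _default_spacer_dist() -> dict:
    # 17 bp dominates in highly expressed genes; 16 bp is modal with a
    # +/-1 deviation for medium/low tiers.
    return {
        "high": {15: 0.02, 16: 0.08, 17: 0.80, 18: 0.08, 19: 0.02},
        "medium": {15: 0.05, 16: 0.40, 17: 0.25, 18: 0.20, 19: 0.10},
        "low": {15: 0.05, 16: 0.40, 17: 0.25, 18: 0.20, 19: 0.10},
    }


@dataclass
class GenParams:
    """Parameters for plasmid genome generation."""

    genome_length: int = 20000
    gc_content: float = 0.60
    n_genes: int = 12
    tier_proportions: dict = field(
        default_factory=lambda: {"high": 0.25, "medium": 0.25, "low": 0.25, "silent": 0.25}
    )
    promoter_fidelity: dict = field(
        default_factory=lambda: {"high": 1, "medium": 2, "low": 3}
    )
    spacer_dist: dict = field(default_factory=_default_spacer_dist)
    terminator_mix: dict = field(
        default_factory=lambda: {"rho_independent": 0.5, "stem_loop": 0.3, "convergent": 0.2}
    )
    motif_count: int = 2
    operon_sizes: list | None = None  # TU sizes; default all singletons
    seed: int = 0

    def validate(self) -> None:
        if abs(sum(self.tier_proportions.values()) - 1.0) > 1e-9:
            raise ValueError("tier_proportions must sum to 1")
        for tier, dist in self.spacer_dist.items():
            if abs(sum(dist.values()) - 1.0) > 1e-9:
                raise ValueError(f"spacer_dist[{tier}] must sum to 1")
            if any(not SPACER_RANGE[0] <= s <= SPACER_RANGE[1] for s in dist):
                raise ValueError("spacer lengths must lie in 15-19")
        if abs(sum(self.terminator_mix.values()) - 1.0) > 1e-9:
            raise ValueError("terminator_mix must sum to 1")
        if self.operon_sizes is not None and sum(self.operon_sizes) != self.n_genes:
            raise ValueError("operon_sizes must sum to n_genes")
        if not 0.0 < self.gc_content < 1.0:
            raise ValueError("gc_content must be a fraction in (0,1)")


@dataclass
class CountDesign:
    """Two-condition, replicated negative-binomial count design.

    Defaults mirror a chromosome-scale experiment with three biological
    replicates per condition and 127 up- / 30 down-regulated genes planted
    at a two-fold-change-squared effect (log2fc = 2).
    """

    n_genes: int = 1864
    replicates: int = 3
    nb_dispersion: float = 0.1
    n_up: int = 127
    n_down: int = 30
    effect_log2fc: float = 2.0
    baseline_log_mean: float = math.log(50.0)
    baseline_log_sigma: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_up + self.n_down > self.n_genes:
            raise ValueError("n_up + n_down exceeds n_genes")
        if self.replicates < 2:
            raise ValueError("need >= 2 replicates per condition")
        if self.nb_dispersion < 0:
            raise ValueError("dispersion must be >= 0")


# --------------------------------------------------------------------------
# truth bookkeeping


@dataclass
class GeneTruth:
    gene_id: str
    tier: str
    strand: str
    start: int
    end: int
    tu_id: str
    tss: int | None = None
    tts: int | None = None
    minus35: str | None = None
    spacer_len: int | None = None
    minus10: str | None = None
    pos35: int | None = None  # forward-strand leftmost coordinate of hexamer
    pos10: int | None = None
    terminator_class: str | None = None
    motif_start: int | None = None  # forward-strand leftmost coord of 34-mer


@dataclass
class TruthSet:
    """Ground truth for every planted feature, keyed by gene id."""

    genes: dict = field(default_factory=dict)  # gene_id -> GeneTruth
    deg: dict = field(default_factory=dict)  # gene_id -> {log2fc, direction}

    def tier_of(self, gene_id: str) -> str:
        return self.genes[gene_id].tier

    def tus(self) -> dict:
        """Group gene truths by transcriptional unit id (ordered)."""
        out: dict[str, list[GeneTruth]] = {}
        for gt in self.genes.values():
            out.setdefault(gt.tu_id, []).append(gt)
        return out

    def to_json(self, path) -> None:
        payload = {
            "genes": {k: asdict(v) for k, v in self.genes.items()},
            "deg": self.deg,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "TruthSet":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            genes={k: GeneTruth(**v) for k, v in payload["genes"].items()},
            deg=payload.get("deg", {}),
        )


# --------------------------------------------------------------------------
# sequence helpers


def _random_dna(rng: np.random.Generator, n: int, gc: float) -> str:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=n, p=p))


def _random_sense_codon(rng: np.random.Generator, gc: float) -> str:
    while True:
        c = _random_dna(rng, 3, gc)
        if c not in STOP_CODONS:
            return c


def _mutate(rng: np.random.Generator, seq: str, n_mismatches: int) -> str:
    """Introduce exactly `n_mismatches` substitutions at distinct positions."""
    seq = list(seq)
    pos = rng.choice(len(seq), size=n_mismatches, replace=False)
    for i in pos:
        alternatives = [b for b in "ACGT" if b != seq[i]]
        seq[i] = alternatives[rng.integers(0, 3)]
    return "".join(seq)


def resolve_iupac(rng: np.random.Generator, pattern: str) -> str:
    """Resolve IUPAC ambiguity codes to a concrete DNA string."""
    from .regulatory import IUPAC_SETS  # local import to avoid a cycle

    out = []
    for ch in pattern:
        choices = sorted(IUPAC_SETS[ch])
        out.append(choices[rng.integers(0, len(choices))])
    return "".join(out)


# --------------------------------------------------------------------------
# plasmid generation


def _assign_tiers(rng: np.random.Generator, params: GenParams, n_tus: int) -> list[str]:
    """Integer-rounded tier assignment over TUs, shuffled deterministically."""
    raw = {t: params.tier_proportions.get(t, 0.0) * n_tus for t in TIERS}
    counts = {t: int(math.floor(v)) for t, v in raw.items()}
    # distribute remainders to the largest fractional parts
    rem = n_tus - sum(counts.values())
    order = sorted(TIERS, key=lambda t: raw[t] - counts[t], reverse=True)
    for t in order[:rem]:
        counts[t] += 1
    tiers = [t for t in TIERS for _ in range(counts[t])]
    rng.shuffle(tiers)
    return tiers


def _assign_terminators(
    rng: np.random.Generator, params: GenParams, tu_tiers: list[str]
) -> list[str | None]:
    classes, probs = zip(*sorted(params.terminator_mix.items()))
    out: list[str | None] = []
    for tier in tu_tiers:
        if tier == "silent":
            out.append(None)
        else:
            out.append(str(rng.choice(classes, p=probs)))
    # convergent terminators need a partner: force the follower of every
    # convergent TU to be convergent on the opposite strand
    i = 0
    while i < len(out):
        if out[i] == "convergent":
            j = i + 1
            if j < len(out) and out[j] is not None:
                out[j] = "convergent"
                i = j + 1
                continue
            # no non-silent follower available: fall back to stem_loop
            out[i] = "stem_loop"
        i += 1
    return out


def _build_tu_block(
    rng: np.random.Generator,
    params: GenParams,
    tier: str,
    term_class: str | None,
    n_members: int,
    plant_motif: bool,
    tight_3prime: bool,
):
    """Build one transcriptional unit block in local forward coordinates.

    Returns (sequence string, dict of local features).
    """
    gc = params.gc_content
    chars: list[str] = []
    feats: dict = {"genes": [], "tier": tier}

    def emit(s: str) -> int:
        start = len(chars)
        chars.extend(s)
        return start

    emit(_random_dna(rng, int(rng.integers(15, 31)), gc))

    if tier != "silent":
        fidelity = params.promoter_fidelity.get(tier, 2)
        k35 = int(rng.integers(0, fidelity + 1))
        k10 = int(rng.integers(0, fidelity + 1))
        m35 = _mutate(rng, CONSENSUS_35, k35)
        m10 = _mutate(rng, CONSENSUS_10, k10)
        spacers, sp = zip(*sorted(params.spacer_dist[tier].items()))
        spacer_len = int(rng.choice(spacers, p=np.asarray(sp)))
        pos35 = emit(m35)
        emit(_random_dna(rng, spacer_len, gc))
        pos10 = emit(m10)
        emit(_random_dna(rng, 6, gc))  # -10 3' end to TSS-1
        if tier == "high":
            utr5 = int(rng.integers(32, 61)) if not plant_motif else int(rng.integers(32, 41))
        else:
            utr5 = int(rng.integers(20, 46))
        tss = len(chars)  # first transcribed base
        emit(_random_dna(rng, utr5, gc))
        feats.update(
            tss=tss, pos35=pos35, pos10=pos10,
            minus35=m35, minus10=m10, spacer_len=spacer_len,
        )
        if plant_motif:
            # overwrite [tss-20, tss+14) with a resolved copy of the 34 bp
            # consensus so its -10 box (pattern positions 9-14) replaces the
            # planted -10 hexamer exactly
            resolved = resolve_iupac(rng, REGULON_MOTIF)
            m0 = tss - 20
            chars[m0 : m0 + 34] = list(resolved)
            feats["motif_start"] = m0
            feats["minus10"] = "".join(chars[pos10 : pos10 + 6])
            feats["minus35"] = "".join(chars[pos35 : pos35 + 6])
    else:
        feats.update(tss=None)

    # coding sequences (an operon concatenates members with short linkers)
    for m in range(n_members):
        n_codons = int(rng.integers(100, 301))
        gene_start = emit("ATG")
        for _ in range(n_codons):
            emit(_random_sense_codon(rng, gc))
        emit("TAA")
        gene_end = len(chars)
        feats["genes"].append((gene_start, gene_end))
        if m < n_members - 1:
            emit(_random_dna(rng, int(rng.integers(12, 31)), gc))

    if tier != "silent":
        d = int(rng.integers(10, 61))
        emit(_random_dna(rng, d, gc))
        feats["tts"] = len(chars) - 1  # last transcribed base
        if term_class in ("rho_independent", "stem_loop"):
            emit(_random_dna(rng, 3, gc))
            while True:  # GC-rich stem: at least 6 of 8 pairs G:C
                stem = "".join(
                    rng.choice(list("GCAT"), size=8, p=[0.4, 0.4, 0.1, 0.1])
                )
                if sum(b in "GC" for b in stem) >= 6:
                    break
            loop = _random_dna(rng, 4, gc)
            emit(stem + loop + revcomp(stem))
            if term_class == "rho_independent":
                emit("TTTTTTTT")
            else:
                # explicitly T-free tail so the poly-T rule stays negative
                emit("".join(rng.choice(list("GCA"), size=8, p=[0.45, 0.45, 0.1])))
        feats["terminator_class"] = term_class
    else:
        feats["tts"] = None
        feats["terminator_class"] = None

    pad = 3 if tight_3prime else int(rng.integers(10, 26))
    emit(_random_dna(rng, pad, gc))
    return "".join(chars), feats


def _flip_point(p: int | None, block_len: int) -> int | None:
    return None if p is None else block_len - 1 - p


def _flip_interval(a: int, block_len: int, width: int) -> int:
    """Leftmost coordinate of a width-nt feature after reverse complement."""
    return block_len - (a + width)


def generate_plasmid(params: GenParams) -> tuple[GenomeBundle, TruthSet]:
    """Generate a plasmid genome with planted promoters, terminators and motifs."""
    params.validate()
    rng = np.random.default_rng(params.seed)
    gc = params.gc_content

    operon_sizes = params.operon_sizes or [1] * params.n_genes
    n_tus = len(operon_sizes)
    tu_tiers = _assign_tiers(rng, params, n_tus)
    tu_terms = _assign_terminators(rng, params, tu_tiers)

    # choose motif-bearing TUs among the most highly expressed, distinct TUs
    candidates = [i for i, t in enumerate(tu_tiers) if t == "high"]
    candidates += [i for i, t in enumerate(tu_tiers) if t == "medium"]
    if params.motif_count > len(candidates):
        raise SizingError("motif_count exceeds number of non-silent candidate TUs")
    motif_tus = set(candidates[: params.motif_count])

    # strands: convergent pairs are (+, -); everything else random
    strands: list[str] = [""] * n_tus
    i = 0
    while i < n_tus:
        if tu_terms[i] == "convergent":
            strands[i], strands[i + 1] = "+", "-"
            i += 2
        else:
            strands[i] = "+" if rng.random() < 0.6 else "-"
            i += 1

    pieces: list[str] = []
    offset = 0
    truth = TruthSet()
    genes: list[Gene] = []
    gene_no = 0

    def gap(n_lo: int, n_hi: int) -> None:
        nonlocal offset
        g = _random_dna(rng, int(rng.integers(n_lo, n_hi)), gc)
        pieces.append(g)
        offset += len(g)

    gap(30, 81)
    for ti in range(n_tus):
        tier, term, strand = tu_tiers[ti], tu_terms[ti], strands[ti]
        convergent_left = term == "convergent" and strand == "+"
        convergent_right = term == "convergent" and strand == "-"
        block, feats = _build_tu_block(
            rng, params, tier, term,
            n_members=operon_sizes[ti],
            plant_motif=ti in motif_tus,
            tight_3prime=convergent_left or convergent_right,
        )
        B = len(block)
        tu_id = f"TU{ti + 1:03d}"
        if strand == "-":
            block = revcomp(block)
            tss = None if feats["tss"] is None else offset + _flip_point(feats["tss"], B)
            tts = None if feats["tts"] is None else offset + _flip_point(feats["tts"], B)
            member_coords = [
                (offset + _flip_interval(a, B, b - a), offset + _flip_interval(a, B, b - a) + (b - a))
                for a, b in feats["genes"]
            ]
            member_coords.reverse()  # keep transcription order
            pos35 = feats.get("pos35")
            pos10 = feats.get("pos10")
            pos35 = None if pos35 is None else offset + _flip_interval(pos35, B, 6)
            pos10 = None if pos10 is None else offset + _flip_interval(pos10, B, 6)
            motif_start = feats.get("motif_start")
            if motif_start is not None:
                motif_start = offset + _flip_interval(motif_start, B, 34)
        else:
            tss = None if feats["tss"] is None else offset + feats["tss"]
            tts = None if feats["tts"] is None else offset + feats["tts"]
            member_coords = [(offset + a, offset + b) for a, b in feats["genes"]]
            pos35 = feats.get("pos35")
            pos10 = feats.get("pos10")
            pos35 = None if pos35 is None else offset + pos35
            pos10 = None if pos10 is None else offset + pos10
            motif_start = feats.get("motif_start")
            if motif_start is not None:
                motif_start = offset + motif_start

        pieces.append(block)
        offset += B

        for mi, (a, b) in enumerate(member_coords):
            gene_no += 1
            gid = f"P{gene_no:04d}"
            genes.append(Gene(gene_id=gid, start=a, end=b, strand=strand))
            truth.genes[gid] = GeneTruth(
                gene_id=gid, tier=tier, strand=strand, start=a, end=b, tu_id=tu_id,
                tss=tss, tts=tts,
                minus35=feats.get("minus35"), minus10=feats.get("minus10"),
                spacer_len=feats.get("spacer_len"),
                pos35=pos35, pos10=pos10,
                terminator_class=feats.get("terminator_class"),
                motif_start=motif_start if mi == 0 else None,
            )

        if convergent_left:
            gap(10, 31)  # keeps opposite 3' ends within 50 nt
        else:
            gap(30, 81)

    if offset > params.genome_length:
        raise SizingError(
            f"placed features need {offset} nt > genome_length {params.genome_length}"
        )
    pieces.append(_random_dna(rng, params.genome_length - offset, gc))
    seq = "".join(pieces)
    bundle = GenomeBundle(seq=seq, genes=sorted(genes, key=lambda g: g.start), name="plasmid")
    return bundle, truth


# --------------------------------------------------------------------------
# coverage simulation


DEFAULT_DEPTH = {"high": 200, "medium": 100, "low": 50, "silent": 0}


@dataclass
class CoverageStats:
    n_fragments: int = 0
    truncated_nt: int = 0


def simulate_coverage(
    bundle: GenomeBundle,
    truth: TruthSet,
    depth_per_tier: dict | None = None,
    frag_len: int = 50,
    noise_rate: float = 0.2,
    seed: int = 0,
) -> tuple[CoverageTrack, CoverageStats]:
    """Simulate strand-specific per-base coverage from planted transcripts.

    Each transcript is covered by `depth` independent full-length copies,
    each cut into consecutive fragments of `frag_len` at a random phase, so
    fragment boundaries are uniform over the transcript while per-base depth
    equals the tier target exactly, with sharp steps at the TSS and TTS.
    A Poisson background (`noise_rate` per base, both strands) is added.
    """
    depth_per_tier = dict(DEFAULT_DEPTH if depth_per_tier is None else depth_per_tier)
    d = [depth_per_tier[t] for t in ("high", "medium", "low")]
    if not (d[0] > d[1] > d[2]):
        raise ValueError("depth_per_tier must be strictly decreasing high->low")
    if frag_len < 20 and frag_len != 1:
        # frag_len 1 is allowed for calibration checks
        raise ValueError("frag_len must be >= 20")
    rng = np.random.default_rng(seed)
    L = len(bundle)
    plus = np.zeros(L)
    minus = np.zeros(L)
    stats = CoverageStats()

    for tu_id, members in truth.tus().items():
        gt = members[0]
        if gt.tss is None or gt.tts is None:
            continue
        depth = int(depth_per_tier[gt.tier])
        if depth <= 0:
            continue
        lo, hi = min(gt.tss, gt.tts), max(gt.tss, gt.tts)
        tlen = hi - lo + 1
        if tlen < frag_len:
            logger.warning(
                "transcript %s (%d nt) shorter than frag_len %d; fragments truncated",
                tu_id, tlen, frag_len,
            )
        track = plus if gt.strand == "+" else minus
        track[lo : hi + 1] += depth
        for _ in range(depth):
            phase = int(rng.integers(0, frag_len))
            covered = tlen
            nf = (1 if phase > 0 else 0) + math.ceil(max(tlen - phase, 0) / frag_len)
            stats.n_fragments += nf
            stats.truncated_nt += nf * frag_len - covered

    if noise_rate > 0:
        plus += rng.poisson(noise_rate, L)
        minus += rng.poisson(noise_rate, L)
    return CoverageTrack(plus=plus, minus=minus), stats


# --------------------------------------------------------------------------
# count simulation


def simulate_counts(design: CountDesign) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a two-condition count matrix with planted DEGs.

    Returns (counts, deg_truth): counts is genes x samples with columns
    ``ctrl_1..R, plasmid_1..R``; deg_truth has per-gene planted ``log2fc``
    and ``direction`` in {up, down, null}.
    """
    design.validate()
    rng = np.random.default_rng(design.seed)
    n, r = design.n_genes, design.replicates
    gene_ids = [f"G{i + 1:04d}" for i in range(n)]

    baselines = rng.lognormal(design.baseline_log_mean, design.baseline_log_sigma, n)
    lfc = np.zeros(n)
    idx = rng.permutation(n)
    up_idx = idx[: design.n_up]
    down_idx = idx[design.n_up : design.n_up + design.n_down]
    lfc[up_idx] = design.effect_log2fc
    lfc[down_idx] = -design.effect_log2fc

    def nb(mean: np.ndarray) -> np.ndarray:
        if design.nb_dispersion == 0:
            return rng.poisson(mean)
        size = 1.0 / design.nb_dispersion
        p = size / (size + mean)
        return rng.negative_binomial(size, p)

    data = {}
    for j in range(r):
        data[f"ctrl_{j + 1}"] = nb(baselines)
    mu2 = baselines * np.power(2.0, lfc)
    for j in range(r):
        data[f"plasmid_{j + 1}"] = nb(mu2)

    counts = pd.DataFrame(data, index=pd.Index(gene_ids, name="gene_id"))
    direction = np.full(n, "null", dtype=object)
    direction[up_idx] = "up"
    direction[down_idx] = "down"
    deg_truth = pd.DataFrame(
        {"log2fc": np.where(direction == "null", 0.0, lfc), "direction": direction},
        index=counts.index,
    )
    return counts, deg_truth


# --------------------------------------------------------------------------
# writers


def write_fixture(outdir, bundle: GenomeBundle, truth: TruthSet,
                  cov: CoverageTrack | None = None,
                  counts: pd.DataFrame | None = None) -> None:
    """Write the standard fixture file set into `outdir`."""
    import os

    os.makedirs(outdir, exist_ok=True)
    bundle.write_fasta(os.path.join(outdir, "genome.fasta"))
    bundle.write_gff3(os.path.join(outdir, "genes.gff3"))
    truth.to_json(os.path.join(outdir, "truth.json"))
    if cov is not None:
        from .coverage import write_bedgraph

        write_bedgraph(cov.plus, os.path.join(outdir, "coverage.plus.bedgraph"), bundle.name)
        write_bedgraph(cov.minus, os.path.join(outdir, "coverage.minus.bedgraph"), bundle.name)
    if counts is not None:
        counts.to_csv(os.path.join(outdir, "counts.tsv"), sep="\t")
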