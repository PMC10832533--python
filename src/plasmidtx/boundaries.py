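"""Transcript boundary detection from strand-specific coverage.

A transcriptional start site (TSS) is called where windowed median depth
jumps relative to the upstream flank; a termination site (TTS) is the
mirrored drop.  Consecutive co-covered same-strand genes are assembled into
transcriptional units (TUs), and 5'/3' UTR lengths are refined against a
placed promoter (the RNA-seq 5' end systematically misses ~20 nt, so when a
promoter is called the TSS is re-anchored 7 nt downstream of the -10 box).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .coverage import CoverageTrack
from .genome import Gene
from .quantify import TIER_ORDER


@dataclass
class StepParams:
    min_depth: float = 10.0
    ratio: float = 3.0
    window: int = 5
    flank: int = 50
    join_ratio: float = 0.25  # operon joining: min inter-gene depth fraction
    max_utr_search: int = 300  # how far up/downstream a boundary may sit

    def __post_init__(self) -> None:
        if self.ratio <= 1:
            raise ValueError("ratio must be > 1")
        if self.window < 1:
            raise ValueError("window must be >= 1")


@dataclass
class TranscriptionalUnit:
    tu_id: str
    strand: str
    gene_ids: list
    tss: int | None
    tts: int | None
    utr5_len: int | None
    utr3_len: int | None
    tier: str | None = None
    flags: list = field(default_factory=list)
    first_start: int | None = None  # start codon anchor (forward coord)
    last_end: int | None = None


def _sliding_median(x: np.ndarray, width: int) -> np.ndarray:
    """median over [i, i+width), edge-padded by repeating the last value."""
    pad = np.concatenate([x, np.full(width - 1, x[-1] if len(x) else 0.0)])
    win = np.lib.stride_tricks.sliding_window_view(pad, width)
    return np.median(win, axis=1)


def _flank_median(x: np.ndarray, flank: int) -> np.ndarray:
    """median over [i-flank, i), edge-padded before the origin.

    Repeating the first value (rather than padding zeros) avoids
    fabricating a coverage step at the contig edge.
    """
    pad = np.concatenate([np.full(flank, x[0] if len(x) else 0.0), x])
    win = np.lib.stride_tricks.sliding_window_view(pad, flank)[: len(x)]
    return np.median(win, axis=1)


def _detect_step_up(depth: np.ndarray, p: StepParams) -> np.ndarray:
    """Positions where depth steps up (forward orientation)."""
    if len(depth) == 0:
        return np.array([], dtype=int)
    win_med = _sliding_median(depth, p.window)
    fl_med = _flank_median(depth, p.flank)
    cond = win_med >= np.maximum(p.min_depth, p.ratio * fl_med)
    cand = np.flatnonzero(cond)
    if len(cand) == 0:
        return cand
    rise = depth - np.concatenate([[0.0], depth[:-1]])
    out = []
    group = [cand[0]]
    for c in cand[1:]:
        if c - group[-1] < p.window:
            group.append(c)
        else:
            out.append(_best_of_group(group, rise))
            group = [c]
    out.append(_best_of_group(group, rise))
    return np.array(sorted(set(out)), dtype=int)


def _best_of_group(group: list, rise: np.ndarray) -> int:
    g = np.asarray(group)
    return int(g[np.argmax(rise[g])])  # argmax keeps the leftmost on ties


def detect_tss(cov: CoverageTrack, strand: str, p: StepParams | None = None) -> np.ndarray:
    """Transcription start sites on `strand` (coordinate of first transcribed base)."""
    p = p or StepParams()
    track = cov.strand(strand)
    if strand == "+":
        return _detect_step_up(track, p)
    pos = _detect_step_up(track[::-1], p)
    return np.sort(len(track) - 1 - pos)


def detect_tts(cov: CoverageTrack, strand: str, p: StepParams | None = None) -> np.ndarray:
    """Transcription termination sites on `strand` (last transcribed base)."""
    p = p or StepParams()
    track = cov.strand(strand)
    if strand == "+":
        pos = _detect_step_up(track[::-1], p)
        return np.sort(len(track) - 1 - pos)
    return _detect_step_up(track, p)


def assemble_tus(
    genes: list[Gene],
    tss_by_strand: dict,
    tts_by_strand: dict,
    cov: CoverageTrack,
    gene_tiers: dict | None = None,
    p: StepParams | None = None,
) -> list[TranscriptionalUnit]:
    """Join co-covered adjacent same-strand genes into TUs and assign boundaries."""
    p = p or StepParams()
    tus: list[TranscriptionalUnit] = []
    counter = 0
    for strand in ("+", "-"):
        track = cov.strand(strand)
        sg = sorted((g for g in genes if g.strand == strand), key=lambda g: g.start)
        if not sg:
            continue
        chains: list[list[Gene]] = [[sg[0]]]
        for g in sg[1:]:
            prev = chains[-1][-1]
            if _should_join(prev, g, track, tss_by_strand.get(strand, []), strand, p):
                chains[-1].append(g)
            else:
                chains.append([g])
        for chain in chains:
            body = np.concatenate([track[g.start : g.end] for g in chain])
            if body.mean() < p.min_depth:
                continue  # not expressed on this strand
            counter += 1
            tus.append(
                _make_tu(
                    f"TU{counter:03d}", strand, chain,
                    np.asarray(tss_by_strand.get(strand, []), dtype=int),
                    np.asarray(tts_by_strand.get(strand, []), dtype=int),
                    gene_tiers, p,
                )
            )
    return tus


def _should_join(
    g1: Gene, g2: Gene, track: np.ndarray, tss_list, strand: str, p: StepParams
) -> bool:
    lo, hi = g1.end, g2.start
    if hi <= lo:
        return True  # overlapping/adjacent genes
    inter = track[lo:hi]
    m1 = track[g1.start : g1.end].mean()
    m2 = track[g2.start : g2.end].mean()
    if m1 <= 0 or m2 <= 0:
        return False
    if inter.min() < p.join_ratio * min(m1, m2):
        return False
    tss_arr = np.asarray(tss_list, dtype=int)
    if np.any((tss_arr >= lo) & (tss_arr < hi)):
        return False
    return True


def _make_tu(tu_id, strand, chain, tss_arr, tts_arr, gene_tiers, p) -> TranscriptionalUnit:
    fs = chain[0].start
    le = chain[-1].end
    flags: list[str] = []
    if strand == "+":
        up = tss_arr[(tss_arr < fs) & (tss_arr >= fs - p.max_utr_search)]
        tss = int(up.max()) if len(up) else None
        down = tts_arr[(tts_arr >= le - 1) & (tts_arr <= le - 1 + p.max_utr_search)]
        tts = int(down.min()) if len(down) else None
        utr5 = None if tss is None else fs - tss
        utr3 = None if tts is None else tts - (le - 1)
        anchor5, anchor3 = fs, le
    else:
        up = tss_arr[(tss_arr > le - 1) & (tss_arr <= le - 1 + p.max_utr_search)]
        tss = int(up.min()) if len(up) else None
        down = tts_arr[(tts_arr <= fs) & (tts_arr >= fs - p.max_utr_search)]
        tts = int(down.max()) if len(down) else None
        utr5 = None if tss is None else tss - (le - 1)
        utr3 = None if tts is None else fs - tts
        anchor5, anchor3 = le, fs
    if tss is None:
        flags.append("no_tss")
    if tts is None:
        flags.append("no_tts")
    tier = None
    if gene_tiers:
        members = [gene_tiers.get(g.gene_id) for g in chain]
        members = [t for t in members if t]
        if members:
            tier = max(members, key=lambda t: TIER_ORDER[t])
    return TranscriptionalUnit(
        tu_id=tu_id, strand=strand, gene_ids=[g.gene_id for g in chain],
        tss=tss, tts=tts, utr5_len=utr5, utr3_len=utr3, tier=tier, flags=flags,
        first_start=fs, last_end=le,
    )


def refine_utrs(tu: TranscriptionalUnit, promoter_call, terminator_call=None) -> TranscriptionalUnit:
    """Re-anchor the TSS 7 nt downstream of a placed promoter's -10 box.

    `promoter_call` must expose `pos10_genome` (forward-strand leftmost
    coordinate of the -10 hexamer) or be None, in which case the TU is
    returned unchanged.  A refinement that would land at or beyond the
    start codon is rejected and flagged.
    """
    if promoter_call is None or getattr(promoter_call, "pos10_genome", None) is None:
        return tu
    p10 = promoter_call.pos10_genome
    if tu.strand == "+":
        new_tss = p10 + 5 + 7
        ok = tu.first_start is not None and new_tss < tu.first_start
        utr5 = None if tu.first_start is None else tu.first_start - new_tss
    else:
        new_tss = p10 - 7
        ok = tu.last_end is not None and new_tss > tu.last_end - 1
        utr5 = None if tu.last_end is None else new_tss - (tu.last_end - 1)
    if not ok:
        tu.flags.append("refine_failed")
        return tu
    tu.tss = new_tss
    tu.utr5_len = utr5
    return tu
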