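"""Promoter, regulon-motif and terminator characterisation.

The promoter model is a bipartite -35/spacer/-10 position-weight-matrix
model with a variable 15-19 nt spacer, fitted by hard-assignment EM seeded
from the canonical bacterial consensus (TTGACA / TATAAT).  Terminators are
classified from perfect GC-rich hairpins with or without a downstream
poly-T tract, or by head-on convergence of opposite-strand units.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .genome import GenomeBundle, revcomp
from .synthetic import CONSENSUS_35, CONSENSUS_10, REGULON_MOTIF, SPACER_RANGE

BASES = "ACGT"
BASE_IDX = {b: i for i, b in enumerate(BASES)}

IUPAC_SETS = {
    "A": {"A"}, "C": {"C"}, "G": {"G"}, "T": {"T"},
    "W": {"A", "T"}, "Y": {"C", "T"}, "N": {"A", "C", "G", "T"},
}

SPACERS = tuple(range(SPACER_RANGE[0], SPACER_RANGE[1] + 1))
HEX = 6
MIN_LAYOUT = 2 * HEX + SPACERS[0]  # shortest possible -35..-10 placement


# --------------------------------------------------------------------------
# upstream window extraction


def extract_upstream(
    bundle: GenomeBundle, anchor: int, width: int, strand: str
) -> tuple[str, bool]:
    """Strand-aware window of `width` nt ending 1 nt before `anchor`.

    Returns (sequence in transcription orientation, truncated flag).  On a
    circular replicon the window wraps the origin instead of truncating.
    """
    if width <= 0:
        raise ValueError("width must be > 0")
    L = len(bundle)
    if not 0 <= anchor < L:
        raise ValueError(f"anchor {anchor} outside genome of length {L}")
    if strand == "+":
        lo, hi = anchor - width, anchor
    elif strand == "-":
        lo, hi = anchor + 1, anchor + 1 + width
    else:
        raise ValueError(f"bad strand {strand!r}")
    truncated = False
    if bundle.circular:
        seq = "".join(bundle.seq[i % L] for i in range(lo, hi))
    else:
        clo, chi = max(lo, 0), min(hi, L)
        truncated = clo != lo or chi != hi
        seq = bundle.seq[clo:chi]
    if strand == "-":
        seq = revcomp(seq)
    return seq, truncated


# --------------------------------------------------------------------------
# promoter model


@dataclass
class PromoterModel:
    pwm35: np.ndarray  # 4 x 6 column-stochastic
    pwm10: np.ndarray
    spacer_prior: np.ndarray  # probabilities over 15..19
    background: np.ndarray  # base frequencies (ACGT)
    converged: bool = True
    low_information: bool = False
    objective_trace: list = field(default_factory=list)

    def consensus(self) -> tuple[str, str]:
        c35 = "".join(BASES[i] for i in np.argmax(self.pwm35, axis=0))
        c10 = "".join(BASES[i] for i in np.argmax(self.pwm10, axis=0))
        return c35, c10

    def spacer_mode(self) -> int:
        return SPACERS[int(np.argmax(self.spacer_prior))]


@dataclass
class PromoterCall:
    tu_id: str | None
    minus35: str
    pos35: int  # leftmost index within the searched window
    spacer_len: int
    minus10: str
    pos10: int
    score: float  # log-odds, bits
    pos10_genome: int | None = None  # forward-strand leftmost coordinate


def _encode(seq: str) -> np.ndarray:
    return np.array([BASE_IDX.get(b, 0) for b in seq], dtype=int)


def _hexamer_scores(enc: np.ndarray, log_odds: np.ndarray) -> np.ndarray:
    """Score of the hexamer starting at each position (log2 pwm/background)."""
    n = len(enc) - HEX + 1
    if n <= 0:
        return np.full(0, -np.inf)
    out = np.zeros(n)
    for j in range(HEX):
        out += log_odds[enc[j : j + n], j]
    return out


def _best_placement(enc: np.ndarray, model: PromoterModel):
    """Maximum log-odds placement (pos35, spacer).  Leftmost wins ties."""
    with np.errstate(divide="ignore"):
        lo35 = np.log2(model.pwm35 / model.background[:, None])
        lo10 = np.log2(model.pwm10 / model.background[:, None])
        lsp = np.log2(model.spacer_prior)
    s35 = _hexamer_scores(enc, lo35)
    s10 = _hexamer_scores(enc, lo10)
    best = (-np.inf, None)
    for si, s in enumerate(SPACERS):
        off = HEX + s
        n = len(enc) - (2 * HEX + s) + 1
        if n <= 0:
            continue
        tot = s35[:n] + s10[off : off + n] + lsp[si]
        i = int(np.argmax(tot))
        if tot[i] > best[0] + 1e-12:
            best = (float(tot[i]), (i, s))
        elif best[1] is not None and abs(tot[i] - best[0]) <= 1e-12:
            if i < best[1][0]:  # leftmost placement wins ties
                best = (float(tot[i]), (i, s))
    return best


def _pwm_from_consensus(consensus: str, weight: float = 0.7) -> np.ndarray:
    pwm = np.full((4, HEX), (1 - weight) / 3)
    for j, b in enumerate(consensus):
        pwm[BASE_IDX[b], j] = weight
    return pwm


def mean_column_ic(pwm: np.ndarray) -> float:
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(pwm > 0, pwm * np.log2(pwm), 0.0)
    return float(np.mean(2.0 + term.sum(axis=0)))


def fit_promoter_model(
    seqs: list[str],
    init_consensus: tuple[str, str] = (CONSENSUS_35, CONSENSUS_10),
    pseudocount: float = 0.5,
    tol: float = 1e-4,
    max_iter: int = 100,
) -> PromoterModel:
    """Fit the bipartite promoter model by hard-assignment EM.

    E-step: best-scoring (pos35, spacer) placement per sequence under the
    current model.  M-step: rebuild PWMs (pseudocount 0.5) and the spacer
    prior from the placements.  Deterministic given the inputs.
    """
    if len(seqs) < 10:
        raise ValueError("need >= 10 sequences to fit the promoter model")
    if any(len(s) < MIN_LAYOUT for s in seqs):
        raise ValueError(f"every sequence must be >= {MIN_LAYOUT} nt")
    encs = [_encode(s) for s in seqs]
    counts = np.zeros(4)
    for e in encs:
        counts += np.bincount(e, minlength=4)
    background = counts / counts.sum()

    model = PromoterModel(
        pwm35=_pwm_from_consensus(init_consensus[0]),
        pwm10=_pwm_from_consensus(init_consensus[1]),
        spacer_prior=np.full(len(SPACERS), 1.0 / len(SPACERS)),
        background=background,
    )
    converged = False
    for _ in range(max_iter):
        placements = []
        objective = 0.0
        for e in encs:
            score, plc = _best_placement(e, model)
            placements.append(plc)
            objective += score
        model.objective_trace.append(objective)

        c35 = np.full((4, HEX), pseudocount)
        c10 = np.full((4, HEX), pseudocount)
        csp = np.full(len(SPACERS), pseudocount)
        for e, plc in zip(encs, placements):
            i, s = plc
            for j in range(HEX):
                c35[e[i + j], j] += 1
                c10[e[i + HEX + s + j], j] += 1
            csp[SPACERS.index(s)] += 1
        new35 = c35 / c35.sum(axis=0)
        new10 = c10 / c10.sum(axis=0)
        delta = max(
            np.abs(new35 - model.pwm35).max(), np.abs(new10 - model.pwm10).max()
        )
        model.pwm35, model.pwm10 = new35, new10
        model.spacer_prior = csp / csp.sum()
        if delta < tol:
            converged = True
            break
    model.converged = converged
    model.low_information = (
        mean_column_ic(model.pwm35) < 0.5 and mean_column_ic(model.pwm10) < 0.5
    )
    return model


def scan_promoter(
    seq: str, model: PromoterModel, threshold: float = 4.0, tu_id: str | None = None
) -> PromoterCall | None:
    """Best promoter placement in `seq`, or None below `threshold` bits."""
    if len(seq) < MIN_LAYOUT:
        return None
    score, plc = _best_placement(_encode(seq), model)
    if plc is None or score < threshold:
        return None
    i, s = plc
    return PromoterCall(
        tu_id=tu_id,
        minus35=seq[i : i + HEX], pos35=i,
        spacer_len=s,
        minus10=seq[i + HEX + s : i + 2 * HEX + s], pos10=i + HEX + s,
        score=score,
    )


def call_promoter_for_tu(
    bundle: GenomeBundle, tu, model: PromoterModel,
    width: int = 62, threshold: float = 4.0,
) -> PromoterCall | None:
    """Scan the upstream window of a TU's TSS and attach genome coordinates."""
    if tu.tss is None:
        return None
    window, _ = extract_upstream(bundle, tu.tss, width, tu.strand)
    call = scan_promoter(window, model, threshold=threshold, tu_id=tu.tu_id)
    if call is None:
        return None
    if tu.strand == "+":
        call.pos10_genome = tu.tss - width + call.pos10
    else:
        call.pos10_genome = tu.tss + width - call.pos10 - 5
    return call


def spacer_stats(calls_by_tier: dict) -> dict:
    """Spacer-length histogram and mode per expression tier."""
    out = {}
    for tier, calls in calls_by_tier.items():
        if not calls:
            raise ValueError(f"no promoter calls in tier {tier!r}")
        hist = Counter(c.spacer_len for c in calls)
        counts = {s: hist.get(s, 0) for s in SPACERS}
        mode = max(counts, key=lambda s: (counts[s], -s))
        out[tier] = {"hist": counts, "mode": mode}
    return out


def logo_matrix(seqs: list[str]) -> tuple[np.ndarray, np.ndarray]:
    """Per-column information content (bits) and base frequencies.

    IC_j = 2 + sum_b f_bj log2 f_bj, with 0 log 0 := 0 and no small-sample
    correction.
    """
    if len({len(s) for s in seqs}) != 1:
        raise ValueError("sequences must be equal length")
    n, width = len(seqs), len(seqs[0])
    freq = np.zeros((4, width))
    for s in seqs:
        for j, b in enumerate(s):
            freq[BASE_IDX[b], j] += 1
    freq /= n
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(freq > 0, freq * np.log2(freq), 0.0)
    ic = 2.0 + term.sum(axis=0)
    return ic, freq


# --------------------------------------------------------------------------
# IUPAC motif scanning


@dataclass
class IupacMotif:
    pattern: str = REGULON_MOTIF
    max_mismatches: int = 0

    def __post_init__(self) -> None:
        bad = set(self.pattern) - set(IUPAC_SETS)
        if bad:
            raise ValueError(f"invalid IUPAC codes {sorted(bad)}")


@dataclass
class MotifHit:
    gene_id: str
    strand: str
    genome_start: int  # forward-strand leftmost coordinate of the match
    window_offset: int
    mismatches: int
    matched_seq: str


def iupac_mismatches(pattern: str, subject: str) -> int:
    """Number of positions where `subject` is outside the pattern's IUPAC set."""
    if len(pattern) != len(subject):
        raise ValueError("length mismatch")
    return sum(s not in IUPAC_SETS[p] for p, s in zip(pattern, subject))


def scan_iupac_motif(
    bundle: GenomeBundle, motif: IupacMotif, window: int = 60
) -> list[MotifHit]:
    """Scan `window` nt upstream of every start codon (gene strand) for the motif."""
    m = len(motif.pattern)
    hits: list[MotifHit] = []
    for gene in bundle.genes:
        anchor = gene.start if gene.strand == "+" else gene.end - 1
        seq, _ = extract_upstream(bundle, anchor, window, gene.strand)
        for w in range(len(seq) - m + 1):
            mm = iupac_mismatches(motif.pattern, seq[w : w + m])
            if mm <= motif.max_mismatches:
                if gene.strand == "+":
                    gstart = gene.start - len(seq) + w
                else:
                    gstart = gene.end + len(seq) - w - m
                hits.append(
                    MotifHit(
                        gene_id=gene.gene_id, strand=gene.strand,
                        genome_start=gstart, window_offset=w,
                        mismatches=mm, matched_seq=seq[w : w + m],
                    )
                )
    return hits


# --------------------------------------------------------------------------
# hairpins and terminators


@dataclass
class Hairpin:
    start: int  # within the searched region
    stem_len: int
    loop_len: int
    gc_frac: float
    score: int

    @property
    def end(self) -> int:
        return self.start + 2 * self.stem_len + self.loop_len

    @property
    def stem2_end(self) -> int:
        return self.end


def find_hairpins(
    seq: str,
    stem_range: tuple[int, int] = (5, 15),
    loop_range: tuple[int, int] = (3, 10),
) -> list[Hairpin]:
    """Perfect Watson-Crick inverted repeats within the size bounds.

    Each candidate is scored G:C=3 / A:T=2 per stem pair; overlapping
    candidates are pruned to the best score (leftmost on ties).
    """
    n = len(seq)
    cands: list[Hairpin] = []
    for i in range(n):
        for stem in range(stem_range[0], stem_range[1] + 1):
            for loop in range(loop_range[0], loop_range[1] + 1):
                end = i + 2 * stem + loop
                if end > n:
                    break
                s1 = seq[i : i + stem]
                s2 = seq[i + stem + loop : end]
                if revcomp(s1) != s2:
                    continue
                score = sum(3 if a in "GC" else 2 for a in s1)
                gc = sum(1 for a in s1 if a in "GC") / stem
                cands.append(Hairpin(i, stem, loop, gc, score))
    cands.sort(key=lambda h: (-h.score, h.start, h.loop_len))
    kept: list[Hairpin] = []
    for h in cands:
        if all(h.end <= k.start or h.start >= k.end for k in kept):
            kept.append(h)
    kept.sort(key=lambda h: h.start)
    return kept


@dataclass
class TerminatorCall:
    tu_id: str | None
    klass: str  # rho_independent | stem_loop | convergent | none
    stem_start_genome: int | None = None
    stem_len: int | None = None
    loop_len: int | None = None
    stem_gc_frac: float | None = None
    poly_t: bool = False
    score: int | None = None


def classify_terminator(
    tu,
    bundle: GenomeBundle,
    all_tus: list,
    min_score: int = 18,
    upstream: int = 20,
    downstream: int = 150,
) -> TerminatorCall:
    """Classify the termination strategy of a TU.

    Precedence: (1) qualifying hairpin (score >= `min_score`) with stem GC
    fraction >= 0.5 and >= 4 T within 8 nt downstream of the stem ->
    rho_independent; (2) any other qualifying hairpin -> stem_loop; (3) no
    hairpin but an opposite-strand TU terminating within 100 nt or
    overlapping -> convergent; otherwise none.
    """
    if tu.tts is None:
        return TerminatorCall(tu_id=tu.tu_id, klass="none")
    L = len(bundle)
    if tu.strand == "+":
        lo, hi = max(0, tu.tts - upstream), min(L, tu.tts + downstream + 1)
        region = bundle.seq[lo:hi]
    else:
        lo, hi = max(0, tu.tts - downstream), min(L, tu.tts + upstream + 1)
        region = revcomp(bundle.seq[lo:hi])
    hairpins = [h for h in find_hairpins(region) if h.score >= min_score]
    if hairpins:
        # the terminator acting on this transcript is the hairpin closest to
        # its 3' end, not the strongest one anywhere in the window
        h = min(hairpins, key=lambda x: (abs(x.start - upstream), -x.score))
        tail = region[h.stem2_end : h.stem2_end + 8]
        poly_t = tail.count("T") >= 4
        if tu.strand == "+":
            stem_start = lo + h.start
        else:
            stem_start = hi - h.end  # leftmost forward coordinate
        klass = "rho_independent" if (poly_t and h.gc_frac >= 0.5) else "stem_loop"
        return TerminatorCall(
            tu_id=tu.tu_id, klass=klass,
            stem_start_genome=stem_start, stem_len=h.stem_len,
            loop_len=h.loop_len, stem_gc_frac=h.gc_frac,
            poly_t=poly_t, score=h.score,
        )
    for other in all_tus:
        if other is tu or other.strand == tu.strand or other.tts is None:
            continue
        if abs(other.tts - tu.tts) <= 100:
            return TerminatorCall(tu_id=tu.tu_id, klass="convergent")
    return TerminatorCall(tu_id=tu.tu_id, klass="none")
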