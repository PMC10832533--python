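"""Codon-usage indices and tRNA-pool compatibility.

Implements RSCU (relative synonymous codon usage), the Sharp-Li codon
adaptation index (CAI), the Bennetzen-Hall codon bias index (CBI),
third-position base composition, Kyte-Doolittle hydropathy and
aromaticity, rare-codon identification and anticodon decoding.  Stop
codons and the single-codon families (Met/ATG, Trp/TGG) are excluded from
RSCU-derived indices.
"""

from __future__ import annotations

from collections import Counter

import numpy as np
from scipy import stats
from Bio.Data import CodonTable
from Bio.Seq import Seq
from Bio.SeqUtils.ProtParam import ProteinAnalysis

from .genome import revcomp

_TABLE = CodonTable.unambiguous_dna_by_id[1]
SENSE_CODONS = tuple(sorted(_TABLE.forward_table))  # 61 codons
STOP_CODONS = tuple(sorted(_TABLE.stop_codons))
AA_OF = dict(_TABLE.forward_table)

#: amino acid -> tuple of synonymous codons
FAMILIES: dict[str, tuple[str, ...]] = {}
for _c in SENSE_CODONS:
    FAMILIES.setdefault(AA_OF[_c], ())
FAMILIES = {
    aa: tuple(sorted(c for c in SENSE_CODONS if AA_OF[c] == aa)) for aa in FAMILIES
}

SINGLE_CODON = {c for f in FAMILIES.values() if len(f) == 1 for c in f}  # ATG, TGG

START_CODONS = ("ATG", "GTG", "TTG")
WEIGHT_FLOOR = 0.01


def codon_counts(cds: str, starts: tuple[str, ...] = START_CODONS) -> Counter:
    """Counts over the 61 sense codons of an in-frame CDS.

    The terminal stop is excluded; an out-of-frame length, bad start codon
    or internal stop raises with the offending position.
    """
    cds = cds.upper()
    if len(cds) % 3 != 0:
        raise ValueError(f"CDS length {len(cds)} not divisible by 3")
    codons = [cds[i : i + 3] for i in range(0, len(cds), 3)]
    if codons and codons[-1] in STOP_CODONS:
        codons = codons[:-1]
    if not codons:
        raise ValueError("empty CDS")
    if codons[0] not in starts:
        raise ValueError(f"CDS starts with {codons[0]}, expected one of {starts}")
    counts: Counter = Counter()
    for i, c in enumerate(codons):
        if c in STOP_CODONS:
            raise ValueError(f"internal stop codon {c} at codon position {i}")
        if c not in AA_OF:
            raise ValueError(f"invalid codon {c!r} at codon position {i}")
        counts[c] += 1
    return counts


def rscu(counts) -> dict[str, float]:
    """Relative synonymous codon usage per codon.

    rscu_c = count_c / (family_total / family_size).  Families with zero
    total are absent from the result.
    """
    out: dict[str, float] = {}
    for fam in FAMILIES.values():
        total = sum(counts.get(c, 0) for c in fam)
        if total == 0:
            continue
        expected = total / len(fam)
        for c in fam:
            out[c] = counts.get(c, 0) / expected
    return out


def reference_weights(ref_counts) -> dict[str, float]:
    """Sharp-Li relative adaptiveness w_c = rscu_c / max family rscu.

    Computed on pooled reference counts; absent codons get the 0.01 floor.
    """
    r = rscu(ref_counts)
    w: dict[str, float] = {}
    for fam in FAMILIES.values():
        fam_vals = [r.get(c, 0.0) for c in fam]
        m = max(fam_vals) if fam_vals else 0.0
        for c in fam:
            if m == 0:
                w[c] = WEIGHT_FLOOR
            else:
                w[c] = max(r.get(c, 0.0) / m, WEIGHT_FLOOR)
    return w


def cai(cds_or_counts, weights: dict[str, float]) -> float:
    """Codon adaptation index: geometric mean of w over informative codons.

    ATG, TGG and stop codons are excluded (single-codon families carry no
    usage information).
    """
    counts = _as_counts(cds_or_counts)
    log_sum, n = 0.0, 0
    for c, k in counts.items():
        if c in SINGLE_CODON:
            continue
        log_sum += k * np.log(weights[c])
        n += k
    if n == 0:
        raise ValueError("no informative codons for CAI")
    return float(np.exp(log_sum / n))


def optimal_codons(weights: dict[str, float]) -> set[str]:
    """The argmax-w codon of each multi-codon family."""
    out = set()
    for fam in FAMILIES.values():
        if len(fam) == 1:
            continue
        out.add(max(fam, key=lambda c: (weights[c], c)))
    return out


def cbi(cds_or_counts, optimal: set[str]) -> float:
    """Bennetzen-Hall codon bias index over multi-codon families.

    (N_opt - N_rand) / (N_tot - N_rand), N_rand = sum over families of
    n_family / family_size.
    """
    counts = _as_counts(cds_or_counts)
    n_opt = n_tot = n_rand = 0.0
    for fam in FAMILIES.values():
        if len(fam) == 1:
            continue
        fam_total = sum(counts.get(c, 0) for c in fam)
        if fam_total == 0:
            continue
        n_tot += fam_total
        n_rand += fam_total / len(fam)
        n_opt += sum(counts.get(c, 0) for c in fam if c in optimal)
    if n_tot == n_rand:
        raise ValueError("CBI undefined: no synonymous choice available")
    return (n_opt - n_rand) / (n_tot - n_rand)


def base_composition(cds: str) -> dict[str, float]:
    """Third-position base fractions (a3/t3/c3/g3/gc3) and overall GC."""
    counts = codon_counts(cds)
    thirds = Counter()
    for c, k in counts.items():
        thirds[c[2]] += k
    n3 = sum(thirds.values())
    comp = {f"{b.lower()}3": thirds.get(b, 0) / n3 for b in "ATCG"}
    comp["gc3"] = comp["c3"] + comp["g3"]
    seq = cds.upper()
    comp["gc"] = (seq.count("G") + seq.count("C")) / len(seq)
    return comp


def gravy_aromo(protein: str) -> tuple[float, float]:
    """Grand average of hydropathy (Kyte-Doolittle) and aromatic fraction."""
    if not protein:
        raise ValueError("empty protein")
    pa = ProteinAnalysis(protein)
    return pa.gravy(), pa.aromaticity()


def translate(cds: str) -> str:
    aa = str(Seq(cds).translate(table=1))
    return aa[:-1] if aa.endswith("*") else aa


def trna_to_codons(anticodons) -> set[str]:
    """Decode 5'->3' RNA anticodons to the DNA codons they read.

    Strict Watson-Crick: codon = reverse complement of the anticodon.
    """
    out = set()
    for ac in anticodons:
        ac = ac.upper().replace("U", "T")
        if len(ac) != 3 or set(ac) - set("ACGT"):
            raise ValueError(f"invalid anticodon {ac!r}")
        out.add(revcomp(ac))
    return out


def rare_codons(counts, threshold: float = 0.10) -> set[str]:
    """Codons used at < `threshold` within-family frequency."""
    out = set()
    for fam in FAMILIES.values():
        total = sum(counts.get(c, 0) for c in fam)
        if total == 0:
            continue
        for c in fam:
            if counts.get(c, 0) / total < threshold:
                out.add(c)
    return out


def rscu_chisq(counts_a, counts_b) -> tuple[float, int, float]:
    """Two-sample chi-squared comparison of codon-count profiles.

    Raw counts (not RSCU values) form a 2 x k table over codons present in
    either profile; columns whose expected count falls below 1 are pooled
    before the test.  Returns (chi2, df, p).
    """
    codons = [c for c in SENSE_CODONS if counts_a.get(c, 0) + counts_b.get(c, 0) > 0]
    a = np.array([counts_a.get(c, 0) for c in codons], dtype=float)
    b = np.array([counts_b.get(c, 0) for c in codons], dtype=float)
    table = np.vstack([a, b])
    table = _pool_small_expected(table)
    if table.shape[1] < 2:
        raise ValueError("fewer than 2 codon classes after pooling")
    chi2, p, df, _ = stats.chi2_contingency(table, correction=False)
    return float(chi2), int(df), float(p)


def _pool_small_expected(table: np.ndarray) -> np.ndarray:
    row = table.sum(axis=1, keepdims=True)
    col = table.sum(axis=0, keepdims=True)
    expected = row @ col / table.sum()
    small = (expected < 1).any(axis=0)
    if small.sum() <= 1:
        return table
    pooled = table[:, small].sum(axis=1, keepdims=True)
    return np.hstack([table[:, ~small], pooled])


def trna_compatibility(profiles: dict[str, dict[str, float]], trna_codons: set[str]):
    """Mean RSCU over tRNA-decoded codons, per gene-set RSCU profile."""
    if not trna_codons:
        raise ValueError("empty tRNA codon set")
    out = {}
    for name, prof in profiles.items():
        vals = [prof.get(c, 0.0) for c in sorted(trna_codons)]
        out[name] = {"per_codon": dict(zip(sorted(trna_codons), vals)),
                     "mean": float(np.mean(vals))}
    return out


def _as_counts(cds_or_counts):
    if isinstance(cds_or_counts, str):
        return codon_counts(cds_or_counts)
    return cds_or_counts
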