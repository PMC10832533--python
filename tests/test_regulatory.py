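"""Promoter model fitting/scanning, motif scanning, hairpins and terminators."""

import re

import numpy as np
import pytest

from plasmidtx.boundaries import TranscriptionalUnit
from plasmidtx.genome import Gene, GenomeBundle, revcomp
from plasmidtx.regulatory import (
    REGULON_MOTIF,
    IupacMotif,
    classify_terminator,
    extract_upstream,
    find_hairpins,
    fit_promoter_model,
    iupac_mismatches,
    logo_matrix,
    mean_column_ic,
    scan_iupac_motif,
    scan_promoter,
)
from plasmidtx.synthetic import GenParams, generate_plasmid, resolve_iupac


# ------------------------------------------------------------- windows


def test_extract_upstream_plus_strand(default_fixture):
    _, bundle, _ = default_fixture
    seq, trunc = extract_upstream(bundle, 100, 62, "+")
    assert seq == bundle.seq[38:100]
    assert not trunc


def test_extract_upstream_minus_strand(default_fixture):
    _, bundle, _ = default_fixture
    seq, _ = extract_upstream(bundle, 100, 62, "-")
    assert seq == revcomp(bundle.seq[101:163])


def test_extract_upstream_truncates_at_edge(default_fixture):
    _, bundle, _ = default_fixture
    seq, trunc = extract_upstream(bundle, 10, 62, "+")
    assert trunc and seq == bundle.seq[:10]


def test_extract_upstream_circular_wraps(default_fixture):
    _, bundle, _ = default_fixture
    circ = GenomeBundle(seq=bundle.seq, genes=[], circular=True)
    seq, trunc = extract_upstream(circ, 10, 62, "+")
    assert not trunc
    assert seq == bundle.seq[-52:] + bundle.seq[:10]


def test_extract_upstream_errors(default_fixture):
    _, bundle, _ = default_fixture
    with pytest.raises(ValueError):
        extract_upstream(bundle, len(bundle), 62, "+")
    with pytest.raises(ValueError):
        extract_upstream(bundle, 100, 0, "+")


# ------------------------------------------------------------- promoter EM


@pytest.fixture(scope="module")
def planted_30():
    """30 high-tier promoters, each <=1 mismatch from TTGACA-n17-TATAAT."""
    params = GenParams(
        seed=11, n_genes=30, genome_length=48000,
        tier_proportions={"high": 1.0, "medium": 0, "low": 0, "silent": 0},
        motif_count=0,
    )
    bundle, truth = generate_plasmid(params)
    windows = []
    for g in truth.genes.values():
        w, _ = extract_upstream(bundle, g.tss, 62, g.strand)
        windows.append(w)
    return bundle, truth, windows


def test_em_recovers_planted_consensus_and_spacer(planted_30):
    _, truth, windows = planted_30
    model = fit_promoter_model(windows)
    assert model.consensus() == ("TTGACA", "TATAAT")
    assert model.spacer_mode() == 17
    assert not model.low_information


def test_em_minus10_placement_within_1nt(planted_30):
    # in a 62 nt window anchored at the true TSS the -10 box starts at 50
    _, truth, windows = planted_30
    model = fit_promoter_model(windows)
    good = sum(
        1
        for w in windows
        if (c := scan_promoter(w, model)) is not None and abs(c.pos10 - 50) <= 1
    )
    assert good / len(windows) >= 0.90


def test_em_objective_nondecreasing(planted_30):
    _, _, windows = planted_30
    model = fit_promoter_model(windows)
    obj = model.objective_trace
    assert all(b >= a - 1e-9 for a, b in zip(obj, obj[1:]))


def test_em_identical_sequences_give_point_masses():
    seq = "A" * 20 + "TTGACA" + "G" * 17 + "TATAAT" + "C" * 13
    model = fit_promoter_model([seq] * 40)
    # with pseudocount 0.5 over 40 identical placements: 40.5/42 per column
    assert model.pwm35.max(axis=0).min() > 0.95
    assert model.spacer_prior.max() > 0.95


def test_em_random_sequences_flagged_low_information(rng):
    seqs = ["".join(rng.choice(list("ACGT"), 62)) for _ in range(30)]
    model = fit_promoter_model(seqs)
    assert mean_column_ic(model.pwm35) < 0.5 or model.low_information


def test_scan_exact_consensus_and_tie_rule(planted_30):
    _, _, windows = planted_30
    model = fit_promoter_model(windows)
    seq = "G" * 23 + "TTGACA" + "C" * 17 + "TATAAT" + "G" * 10
    call = scan_promoter(seq, model)
    assert call is not None
    assert call.spacer_len == 17
    assert call.minus35 == "TTGACA" and call.minus10 == "TATAAT"
    # duplicated identical placement: leftmost is reported
    block = "TTGACA" + "C" * 17 + "TATAAT"
    two = "A" * 5 + block + "A" * 5 + block + "A" * 5
    call2 = scan_promoter(two, model)
    assert call2.pos35 == 5


def test_scan_short_sequence_returns_none(planted_30):
    _, _, windows = planted_30
    model = fit_promoter_model(windows)
    assert scan_promoter("TTGACA", model) is None


def test_degenerate_promoter_recovery():
    """2-mismatch planted promoters are still placed within +/-1 nt >=80%."""
    params = GenParams(
        seed=13, n_genes=30, genome_length=48000,
        tier_proportions={"medium": 1.0, "high": 0, "low": 0, "silent": 0},
        promoter_fidelity={"high": 1, "medium": 2, "low": 3},
        motif_count=0,
    )
    bundle, truth = generate_plasmid(params)
    windows = [
        extract_upstream(bundle, g.tss, 62, g.strand)[0]
        for g in truth.genes.values()
    ]
    model = fit_promoter_model(windows)
    good = sum(
        1
        for w in windows
        if (c := scan_promoter(w, model, threshold=-100)) is not None
        and abs(c.pos10 - 50) <= 1
    )
    assert good / len(windows) >= 0.80


def test_spacer_stats_modes(planted_30):
    from plasmidtx.regulatory import spacer_stats

    _, truth, windows = planted_30
    model = fit_promoter_model(windows)
    calls = [scan_promoter(w, model) for w in windows]
    stats = spacer_stats({"high": [c for c in calls if c]})
    assert stats["high"]["mode"] == 17
    with pytest.raises(ValueError):
        spacer_stats({"empty": []})


# ------------------------------------------------------------- logo


def test_logo_information_content_endpoints():
    ic, freq = logo_matrix(["AC", "AG", "AT", "AA"])
    assert ic[0] == pytest.approx(2.0)  # all-A column
    assert ic[1] == pytest.approx(0.0)  # uniform column
    ic2, _ = logo_matrix(["A", "A", "C", "C"])
    assert ic2[0] == pytest.approx(1.0)  # f = (0.5, 0.5, 0, 0)


def test_logo_requires_equal_lengths():
    with pytest.raises(ValueError):
        logo_matrix(["AA", "A"])


# ------------------------------------------------------------- IUPAC motif


def test_iupac_semantics():
    assert iupac_mismatches("AWA", "ATA") == 0
    assert iupac_mismatches("AWA", "AGA") == 1
    assert iupac_mismatches("NYN", "GTC") == 0


def test_invalid_iupac_code_rejected():
    with pytest.raises(ValueError):
        IupacMotif(pattern="AXZ")


def test_regulon_motif_constant():
    assert len(REGULON_MOTIF) == 34
    assert set(REGULON_MOTIF) <= set("ACGTWYN")
    # the -10 box of the pattern sits at positions 9-14 (1-based)
    assert REGULON_MOTIF[8:14] == "TATACT"


def test_planted_motifs_found_exactly_no_extras(default_fixture):
    params, bundle, truth = default_fixture
    hits = scan_iupac_motif(bundle, IupacMotif(max_mismatches=0))
    planted = {
        (g.gene_id, g.motif_start)
        for g in truth.genes.values()
        if g.motif_start is not None
    }
    assert {(h.gene_id, h.genome_start) for h in hits} == planted
    assert len(planted) == params.motif_count


def test_scan_matches_regex_oracle(default_fixture):
    """Window-by-window comparison against an independent regex matcher."""
    _, bundle, _ = default_fixture
    motif = IupacMotif(max_mismatches=0)
    rx = re.compile(
        "(?=("
        + "".join({"W": "[AT]", "Y": "[CT]", "N": "."}.get(c, c) for c in motif.pattern)
        + "))"
    )
    expected = set()
    for gene in bundle.genes:
        anchor = gene.start if gene.strand == "+" else gene.end - 1
        window, _ = extract_upstream(bundle, anchor, 60, gene.strand)
        for m in rx.finditer(window):
            expected.add((gene.gene_id, m.start()))
    got = {(h.gene_id, h.window_offset) for h in scan_iupac_motif(bundle, motif)}
    assert got == expected


def test_resolved_motif_matches_pattern(rng):
    for _ in range(10):
        assert iupac_mismatches(REGULON_MOTIF, resolve_iupac(rng, REGULON_MOTIF)) == 0


# ------------------------------------------------------------- hairpins


def test_constructed_palindrome_hairpin():
    hp = find_hairpins("GGGGGGTTTTCCCCCC")
    assert len(hp) == 1
    h = hp[0]
    assert (h.stem_len, h.loop_len, h.gc_frac, h.score) == (6, 4, 1.0, 18)


def test_poly_a_has_no_hairpins():
    assert find_hairpins("A" * 60) == []


def _nussinov_max_pairs(seq: str, min_loop: int = 3) -> int:
    """Independent Nussinov dynamic program: maximum Watson-Crick pairs."""
    pair = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}
    n = len(seq)
    N = [[0] * n for _ in range(n)]
    for span in range(min_loop + 1, n):
        for i in range(n - span):
            j = i + span
            best = N[i + 1][j]
            for k in range(i + min_loop + 1, j + 1):
                if (seq[i], seq[k]) in pair:
                    left = N[i + 1][k - 1] if k - 1 > i else 0
                    right = N[k + 1][j] if k + 1 <= j else 0
                    best = max(best, 1 + left + right)
            N[i][j] = best
    return N[0][n - 1]


def test_hairpin_stem_equals_nussinov_maximum(rng):
    """On single-hairpin sequences the best stem equals the Nussinov optimum."""
    for _ in range(10):
        stem_len = int(rng.integers(5, 11))
        loop_len = int(rng.integers(3, 8))
        stem = "".join(rng.choice(list("GC"), stem_len))
        loop = "A" * loop_len
        seq = "A" * 8 + stem + loop + revcomp(stem) + "A" * 8
        hits = find_hairpins(seq)
        assert hits
        assert max(h.stem_len for h in hits) == _nussinov_max_pairs(seq)


# ------------------------------------------------------------- terminators


def _tu(tu_id, strand, tss, tts):
    return TranscriptionalUnit(
        tu_id=tu_id, strand=strand, gene_ids=[tu_id], tss=tss, tts=tts,
        utr5_len=None, utr3_len=None,
    )


def _bundle_with(seq_parts: list[str]) -> GenomeBundle:
    return GenomeBundle(seq="".join(seq_parts), genes=[])


def test_hairpin_with_polyt_is_rho_independent():
    stem = "GGCGGCGG"
    # 'C' before the stem cannot pair with the 'T' after it, so the stem
    # cannot extend into the poly-T tract
    seq = "A" * 219 + "C" + stem + "AAAA" + revcomp(stem) + "TTTTTT" + "A" * 100
    tu = _tu("t1", "+", 10, 200)
    call = classify_terminator(tu, _bundle_with([seq]), [tu])
    assert call.klass == "rho_independent"
    assert call.poly_t and call.stem_gc_frac >= 0.5


def test_hairpin_without_polyt_is_stem_loop():
    stem = "GGCGGCGG"
    seq = "A" * 220 + stem + "AAAA" + revcomp(stem) + "ACACACAC" + "A" * 100
    tu = _tu("t1", "+", 10, 200)
    call = classify_terminator(tu, _bundle_with([seq]), [tu])
    assert call.klass == "stem_loop"
    assert not call.poly_t


def test_opposed_tus_without_hairpin_are_convergent():
    seq = "A" * 300 + "C" * 300
    plus = _tu("p", "+", 10, 290)
    minus = _tu("m", "-", 580, 310)
    tus = [plus, minus]
    b = _bundle_with([seq])
    assert classify_terminator(plus, b, tus).klass == "convergent"
    assert classify_terminator(minus, b, tus).klass == "convergent"


def test_no_signal_is_none():
    tu = _tu("t", "+", 10, 200)
    assert classify_terminator(tu, _bundle_with(["A" * 400]), [tu]).klass == "none"


def test_planted_terminator_classes_recovered(covered_fixture):
    """Every planted class (rho/stem-loop/convergent) is called correctly."""
    from plasmidtx.boundaries import assemble_tus, detect_tss, detect_tts

    bundle, truth, cov, _ = covered_fixture
    tus = assemble_tus(
        bundle.genes,
        {s: detect_tss(cov, s) for s in "+-"},
        {s: detect_tts(cov, s) for s in "+-"},
        cov,
    )
    seen = set()
    for tu in tus:
        expected = truth.genes[tu.gene_ids[0]].terminator_class
        call = classify_terminator(tu, bundle, tus)
        assert call.klass == expected
        seen.add(expected)
    assert {"rho_independent", "stem_loop", "convergent"} <= seen


def test_classification_is_total(covered_fixture):
    from plasmidtx.boundaries import assemble_tus, detect_tss, detect_tts

    bundle, truth, cov, _ = covered_fixture
    tus = assemble_tus(
        bundle.genes,
        {s: detect_tss(cov, s) for s in "+-"},
        {s: detect_tts(cov, s) for s in "+-"},
        cov,
    )
    for tu in tus:
        assert classify_terminator(tu, bundle, tus).klass in {
            "rho_independent", "stem_loop", "convergent", "none",
        }
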