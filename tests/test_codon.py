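"""Codon-usage indices, anticodon decoding and the codon chi-squared test."""

from collections import Counter

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from plasmidtx.codon import (
    FAMILIES,
    base_composition,
    cai,
    cbi,
    codon_counts,
    gravy_aromo,
    optimal_codons,
    rare_codons,
    reference_weights,
    rscu,
    rscu_chisq,
    translate,
    trna_compatibility,
    trna_to_codons,
)


def _random_cds(rng, n_codons=120):
    codons = [c for fam in FAMILIES.values() for c in fam if c != "ATG"]
    body = "".join(rng.choice(codons, n_codons))
    return "ATG" + body + "TAA"


# ------------------------------------------------------------- counting


def test_codon_counts_basic():
    assert codon_counts("ATGGCCTAA") == Counter({"ATG": 1, "GCC": 1})


def test_codon_counts_frame_and_stop_errors():
    with pytest.raises(ValueError):
        codon_counts("ATGGCCT")  # length 7
    with pytest.raises(ValueError, match="internal stop"):
        codon_counts("ATGTAAGCCTAA")
    with pytest.raises(ValueError):
        codon_counts("CCCGCCTAA")  # bad start


def test_codon_counts_concatenation_additivity(rng):
    a, b = _random_cds(rng, 50), _random_cds(rng, 70)
    joined = a[:-3] + b[3:]  # in-frame concatenation without internal stop
    assert codon_counts(a) + codon_counts(b) == codon_counts(joined) + Counter({"ATG": 1})


# ------------------------------------------------------------- RSCU


def test_rscu_endpoint_single_codon_of_four_family():
    # alanine encoded exclusively by GCC: 4 / (4/4) family members
    counts = Counter({"GCC": 8})
    assert rscu(counts)["GCC"] == pytest.approx(4.0)
    assert rscu(counts)["GCT"] == pytest.approx(0.0)


def test_rscu_uniform_family_is_one():
    counts = Counter({"GCT": 3, "GCC": 3, "GCA": 3, "GCG": 3})
    vals = rscu(counts)
    for c in ("GCT", "GCC", "GCA", "GCG"):
        assert vals[c] == pytest.approx(1.0)


def test_rscu_six_codon_family():
    counts = Counter({"CTG": 12})  # leucine family of six
    assert rscu(counts)["CTG"] == pytest.approx(6.0)


def test_rscu_family_sums_equal_family_size(rng):
    counts = codon_counts(_random_cds(rng, 400))
    vals = rscu(counts)
    for fam in FAMILIES.values():
        if any(counts.get(c, 0) for c in fam):
            assert sum(vals[c] for c in fam) == pytest.approx(len(fam))


# ------------------------------------------------------------- CAI / CBI


def test_reference_weights_max_and_floor():
    counts = Counter({"GCC": 6, "GCT": 3})
    w = reference_weights(counts)
    assert w["GCC"] == pytest.approx(1.0)
    assert w["GCT"] == pytest.approx(0.5)
    assert w["GCA"] == pytest.approx(0.01)  # absent codon floored
    tie = reference_weights(Counter({"GAA": 2, "GAG": 2}))
    assert tie["GAA"] == tie["GAG"] == pytest.approx(1.0)


def test_cai_all_optimal_gene_is_one(rng):
    ref = codon_counts(_random_cds(rng, 500))
    w = reference_weights(ref)
    opt = optimal_codons(w)
    gene = Counter({c: 3 for c in opt})
    assert cai(gene, w) == pytest.approx(1.0)


def test_cai_geometric_mean_identities():
    w = {c: 0.5 for fam in FAMILIES.values() for c in fam}
    assert cai(Counter({"GCC": 10, "CTG": 5}), w) == pytest.approx(0.5)
    w2 = dict(w)
    w2["GCC"], w2["CTG"] = 1.0, 0.25
    assert cai(Counter({"GCC": 1, "CTG": 1}), w2) == pytest.approx(0.5)


def test_cai_excludes_met_trp():
    w = {c: 0.01 for fam in FAMILIES.values() for c in fam}
    w["GCC"] = 1.0
    # ATG and TGG carry no information; only GCC counts
    assert cai(Counter({"ATG": 5, "TGG": 5, "GCC": 2}), w) == pytest.approx(1.0)


def test_cai_bounded_and_length_invariant(rng):
    ref = codon_counts(_random_cds(rng, 300))
    w = reference_weights(ref)
    for _ in range(20):
        g = codon_counts(_random_cds(rng, 150))
        v = cai(g, w)
        assert 0.0 <= v <= 1.0
        doubled = Counter({c: 2 * k for c, k in g.items()})
        assert cai(doubled, w) == pytest.approx(v)


def test_cbi_endpoints(rng):
    ref = codon_counts(_random_cds(rng, 500))
    w = reference_weights(ref)
    opt = optimal_codons(w)
    assert cbi(Counter({c: 2 for c in opt}), opt) == pytest.approx(1.0)
    uniform = Counter({c: 4 for fam in FAMILIES.values() for c in fam})
    assert cbi(uniform, opt) == pytest.approx(0.0)
    # half-optimal usage of a two-codon family: N_opt == N_rand
    half = Counter({"GAA": 5, "GAG": 5})
    opt2 = {"GAA"}
    assert cbi(half, opt2) == pytest.approx(0.0)


# ------------------------------------------------------------- composition


def test_base_composition_small_cases():
    comp = base_composition("ATGGCCTAA")  # codons ATG, GCC
    assert comp["gc3"] == pytest.approx(1.0)  # thirds are G and C
    poly_att = "ATG" + "ATT" * 30 + "TAA"
    assert base_composition(poly_att)["gc3"] == pytest.approx(1 / 31)


def test_base_composition_matches_direct_tally(rng):
    cds = _random_cds(rng, 200)
    comp = base_composition(cds)
    body = cds[:-3]
    thirds = body[2::3]
    for b in "ATCG":
        assert comp[f"{b.lower()}3"] == pytest.approx(thirds.count(b) / len(thirds))
    assert comp["gc3"] == pytest.approx(comp["c3"] + comp["g3"])
    assert comp["gc"] == pytest.approx(
        (cds.count("G") + cds.count("C")) / len(cds)
    )


def test_gravy_aromo_values():
    gravy, _ = gravy_aromo("A")
    assert gravy == pytest.approx(1.8)  # Kyte-Doolittle alanine
    _, aromo = gravy_aromo("FYW")
    assert aromo == pytest.approx(1.0)
    with pytest.raises(ValueError):
        gravy_aromo("")


def test_translate_strips_terminal_stop():
    assert translate("ATGGCCTAA") == "MA"


# ------------------------------------------------------------- tRNA decoding


@pytest.mark.parametrize(
    "anticodon, codon", [("UGC", "GCA"), ("CAU", "ATG"), ("GAA", "TTC")]
)
def test_anticodon_decoding(anticodon, codon):
    assert trna_to_codons([anticodon]) == {codon}


def test_anticodon_duplicates_collapse():
    assert trna_to_codons(["UGC", "UGC"]) == {"GCA"}


def test_invalid_anticodon_rejected():
    with pytest.raises(ValueError):
        trna_to_codons(["UG"])


def test_rare_codons_threshold():
    counts = Counter({"GAA": 19, "GAG": 1})  # 5% usage of GAG
    assert "GAG" in rare_codons(counts)
    assert "GAA" not in rare_codons(counts)
    uniform = Counter({"GCT": 5, "GCC": 5, "GCA": 5, "GCG": 5})
    assert rare_codons(uniform) == set()
    assert rare_codons(counts, threshold=0.0) == set()


# ------------------------------------------------------------- chi-squared


def test_chisq_identical_profiles():
    counts = Counter({"GCC": 30, "GCT": 10, "CTG": 25})
    chi2, df, p = rscu_chisq(counts, counts)
    assert chi2 == pytest.approx(0.0)
    assert p == pytest.approx(1.0)


def test_chisq_two_by_two_hand_value():
    a, b = Counter({"GCC": 10, "GCT": 0}), Counter({"GCC": 0, "GCT": 10})
    chi2, df, p = rscu_chisq(a, b)
    assert chi2 == pytest.approx(20.0)
    assert df == 1


def _chisq_direct(table: np.ndarray) -> float:
    row = table.sum(axis=1, keepdims=True)
    col = table.sum(axis=0, keepdims=True)
    e = row * col / table.sum()
    return float(((table - e) ** 2 / e).sum())


def test_chisq_matches_direct_formula_on_random_tables(rng):
    from plasmidtx.codon import SENSE_CODONS

    for _ in range(100):
        k = int(rng.integers(3, 15))
        codons = list(rng.choice(SENSE_CODONS, size=k, replace=False))
        a = Counter({c: int(v) for c, v in zip(codons, rng.integers(5, 80, k))})
        b = Counter({c: int(v) for c, v in zip(codons, rng.integers(5, 80, k))})
        chi2, df, p = rscu_chisq(a, b)
        table = np.array(
            [[a.get(c, 0) for c in codons], [b.get(c, 0) for c in codons]], float
        )
        assert chi2 == pytest.approx(_chisq_direct(table))
        assert df == k - 1


# ------------------------------------------------------------- compatibility


def test_trna_compatibility_mean():
    profiles = {"set": {"GCA": 2.0, "GGA": 1.0}}
    out = trna_compatibility(profiles, {"GCA", "GGA"})
    assert out["set"]["mean"] == pytest.approx(1.5)
    with pytest.raises(ValueError):
        trna_compatibility(profiles, set())


def test_enriched_gene_set_scores_higher():
    rich = Counter({"GCA": 30, "GCC": 2, "GGA": 30, "GGC": 2})
    poor = Counter({"GCA": 2, "GCC": 30, "GGA": 2, "GGC": 30})
    profiles = {"rich": rscu(rich), "poor": rscu(poor)}
    out = trna_compatibility(profiles, {"GCA", "GGA"})
    assert out["rich"]["mean"] > out["poor"]["mean"]


@given(st.integers(min_value=0, max_value=2**31 - 1))
@settings(max_examples=20, deadline=None)
def test_gc3_identity_property(seed):
    rng = np.random.default_rng(seed)
    comp = base_composition(_random_cds(rng, 60))
    assert comp["gc3"] == pytest.approx(comp["c3"] + comp["g3"])
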