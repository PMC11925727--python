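"""RGR cassette design: stem rule, arrays, arms, spacer enumeration."""

import random

import pytest
from hypothesis import given
from hypothesis import strategies as st

import rgrkit as rk
from rgrkit.design import DEFAULT_SPACER_LEN, PAM_GEOMETRY
from rgrkit.errors import CloningError, DesignError
from rgrkit.seqcore import IUPAC_DNA, revcomp_str

PAIRS = {"A": "T", "T": "A", "C": "G", "G": "C"}


# -- design_stem -----------------------------------------------------------

@pytest.mark.parametrize("six,expected", [
    ("GAAACC", "GGTTTC"),
    ("ATGCAT", "ATGCAT"),  # palindromic hexamer maps to itself
])
def test_design_stem_examples(six, expected):
    assert rk.design_stem(six) == expected


def test_design_stem_watson_crick_pairing():
    rng = random.Random(2)
    for _ in range(100):
        hexamer = "".join(rng.choice("ACGT") for _ in range(6))
        stem = rk.design_stem(hexamer)
        for i in range(6):
            assert stem[i] == PAIRS[hexamer[5 - i]]


@pytest.mark.parametrize("bad", ["GAAAC", "GAAACCA", ""])
def test_design_stem_wrong_length(bad):
    with pytest.raises(DesignError):
        rk.design_stem(bad)


def test_design_stem_ambiguity_rejected():
    with pytest.raises(Exception):
        rk.design_stem("GANACC")


# -- build_rgr -------------------------------------------------------------

def test_cas9_stem_pairs_with_spacer(registry):
    sp = rk.Spacer("GACCTTACGGAGCTTAGCAT", "spcas9", "g1")
    cassette = rk.build_rgr(sp, registry)
    assert cassette.full_sequence[:6] == revcomp_str(sp.sequence[:6])
    assert cassette.guide_body.startswith(sp.sequence)


def test_cas12a_stem_pairs_with_direct_repeat_not_spacer(registry):
    repeat = registry.get_part("cas12a_direct_repeat").sequence
    a = rk.build_rgr(rk.Spacer("GACCTTACGGAGCTTAGCATCCC", "lbcas12a", "a"), registry)
    b = rk.build_rgr(rk.Spacer("TTTTTTTTTTTTTTTTTTTTTTT", "lbcas12a", "b"), registry)
    assert a.full_sequence[:6] == revcomp_str(repeat[:6])
    assert a.stem == b.stem  # repeat-first crRNA: stem independent of spacer
    assert a.guide_body.startswith(repeat)


def test_cassette_length_additivity(registry, rng):
    hh_template = registry.get_part("hh_template")
    hdv = registry.get_part("hdv")
    for _ in range(50):
        cas = rng.choice(["spcas9", "lbcas12a"])
        n = DEFAULT_SPACER_LEN[cas]
        sp = rk.Spacer("".join(rng.choice("ACGT") for _ in range(n)), cas, "x")
        c = rk.build_rgr(sp, registry)
        assert len(c.full_sequence) == (len(hh_template.sequence)
                                        + len(c.guide_body) + len(hdv.sequence))
        a, b, end = c.boundaries
        assert c.full_sequence[a:b] == c.guide_body
        assert end == len(c.full_sequence)


def test_build_rgr_records_domestication_warning(registry):
    # spacer carrying a BbsI site: warned, not fatal
    sp = rk.Spacer("AAGAAGACAAACGTACGTAA", "spcas9", "warned")
    cassette = rk.build_rgr(sp, registry)
    assert any("BbsI" in w for w in cassette.warnings)


# -- build_array -----------------------------------------------------------

def test_two_cassette_array_preserves_order(registry):
    lb = rk.Spacer("GACCTTACGGAGCTTAGCATCCC", "lbcas12a", "pdgfb_like")
    sp = rk.Spacer("GTACCGGTTAGCACTAGGCA", "spcas9", "bmp2_like")
    arr = rk.build_array([lb, sp], registry)
    assert [c.label for c in arr.cassettes] == ["pdgfb_like", "bmp2_like"]
    assert arr.full_sequence == (arr.cassettes[0].full_sequence
                                 + arr.cassettes[1].full_sequence)


def test_single_spacer_array_equals_cassette(registry):
    sp = rk.Spacer("GTACCGGTTAGCACTAGGCA", "spcas9", "solo")
    arr = rk.build_array([sp], registry)
    assert arr.full_sequence == arr.cassettes[0].full_sequence


def test_array_length_is_sum_of_cassettes(registry, rng):
    spacers = [
        rk.Spacer("".join(rng.choice("ACGT") for _ in range(20)), "spcas9", f"s{i}")
        for i in range(5)
    ]
    arr = rk.build_array(spacers, registry)
    assert len(arr.full_sequence) == sum(len(c.full_sequence) for c in arr.cassettes)


def test_array_with_linker_length(registry):
    spacers = [rk.Spacer("GTACCGGTTAGCACTAGGCA", "spcas9", "a"),
               rk.Spacer("GTACCGGTTAGCACTAGGCC", "spcas9", "b")]
    arr = rk.build_array(spacers, registry, linker="AATT")
    assert len(arr.full_sequence) == sum(
        len(c.full_sequence) for c in arr.cassettes) + 4


def test_array_rejects_duplicates_and_empty(registry):
    sp = rk.Spacer("GTACCGGTTAGCACTAGGCA", "spcas9", "dup")
    with pytest.raises(DesignError, match="duplicate"):
        rk.build_array([sp, sp], registry)
    with pytest.raises(DesignError):
        rk.build_array([], registry)


# -- add_cloning_arms ------------------------------------------------------

@pytest.mark.parametrize("enzyme_name,pair", [
    ("SapI", ("AAT", "GCA")),
    ("BbsI", ("CACC", "AAAC")),
])
def test_arms_digest_releases_designed_insert(registry, two_rgr_array,
                                              enzyme_name, pair):
    enz = registry.get_enzyme(enzyme_name)
    frag = rk.add_cloning_arms(two_rgr_array, enz, pair)
    pieces = rk.digest(frag.to_ds(), enz)
    assert len(pieces) == 3
    insert = pieces[1]
    assert insert.left_overhang == pair[0]
    assert insert.right_overhang_plus == pair[1]
    assert len(insert.left_overhang) == enz.overhang_len
    assert insert.duplex_interior == two_rgr_array.full_sequence
    assert rk.find_sites(insert.span, enz.recognition, "both") == []


def test_arms_reject_internal_recognition_site(registry):
    # plant a SapI site inside the spacer -> fatal at arm-adding time
    sp = rk.Spacer("AAGCTCTTCAACGTACGTAA", "spcas9", "planted")
    arr = rk.build_array([sp], registry)
    enz = registry.get_enzyme("SapI")
    with pytest.raises(CloningError, match=r"\[\d+, \d+\)"):
        rk.add_cloning_arms(arr, enz, ("AAT", "GCA"))


def test_arms_reject_bad_overhangs(registry, two_rgr_array):
    enz = registry.get_enzyme("SapI")
    with pytest.raises(DesignError, match="length"):
        rk.add_cloning_arms(two_rgr_array, enz, ("AATC", "GCA"))
    with pytest.raises(DesignError, match="directionality"):
        rk.add_cloning_arms(two_rgr_array, enz, ("AAT", "AAT"))
    with pytest.raises(DesignError, match="flipped"):
        rk.add_cloning_arms(two_rgr_array, enz, ("AAT", "ATT"))


# -- domesticate_check -----------------------------------------------------

def test_domesticate_check_planted_sites(registry):
    seq = list("A" * 120)
    seq[10:16] = "GAAGAC"
    seq[100:106] = "GTCTTC"  # reverse complement of the BbsI site
    seq = "".join(seq)
    bbsi = registry.get_enzyme("BbsI")
    hits = rk.domesticate_check(seq, [bbsi])
    assert [(n, h.start, h.strand) for n, h in hits] == [
        ("BbsI", 10, "plus"), ("BbsI", 100, "minus")]


def test_domesticate_check_clean_random_500mer(registry, rng):
    enzymes = list(registry.enzymes.values())
    rng = random.Random(3)
    while True:  # rejection-sample a site-free 500-mer
        seq = "".join(rng.choice("ACGT") for _ in range(500))
        if not rk.domesticate_check(seq, enzymes):
            break
    assert rk.domesticate_check(seq, enzymes) == []


def test_domesticate_check_agrees_with_find_sites(registry, rng):
    enzymes = list(registry.enzymes.values())
    for _ in range(20):
        seq = "".join(rng.choice("ACGT") for _ in range(300))
        hits = rk.domesticate_check(seq, enzymes)
        expected = []
        for enz in enzymes:
            for h in rk.find_sites(seq, enz.recognition, "both"):
                expected.append((enz.name, h))
        expected.sort(key=lambda t: (t[1].start, t[0]))
        assert hits == expected


# -- find_candidate_spacers ------------------------------------------------

def naive_candidates(seq, tss, cas, min_up=75, max_up=300, spacer_len=None):
    """Exhaustive position x strand oracle for the promoter scan."""
    if spacer_len is None:
        spacer_len = DEFAULT_SPACER_LEN[cas]
    pam_pattern, pam_side = PAM_GEOMETRY[cas]
    k = len(pam_pattern)
    lo, hi = tss - max_up, tss - min_up

    def pam_ok(sub):
        return len(sub) == k and all(c in IUPAC_DNA[p] for c, p in zip(sub, pam_pattern))

    out = []
    for start in range(len(seq) - spacer_len + 1):
        end = start + spacer_len
        if start < lo or end - 1 > hi:
            continue
        for strand in ("plus", "minus"):
            if strand == "plus":
                pam = (seq[end:end + k] if pam_side == "three_prime"
                       else seq[max(start - k, 0):start] if start >= k else "")
            else:
                pam_plus = (seq[max(start - k, 0):start] if start >= k and pam_side == "three_prime"
                            else seq[end:end + k] if pam_side == "five_prime" else "")
                pam = revcomp_str(pam_plus) if pam_plus else ""
            if pam_ok(pam):
                out.append((start, end, strand))
    return out


def make_promoter_with_hit(dist_proximal, spacer_len=20, tss=350, length=400):
    """Alternating A/C background (PAM-free) with one planted AGG."""
    base = list("AC" * (length // 2))
    proximal = tss - dist_proximal
    for i, ch in enumerate("AGG"):
        base[proximal + 1 + i] = ch
    return "".join(base)


@pytest.mark.parametrize("dist,expected_n", [(75, 1), (74, 0)])
def test_window_proximal_boundary(dist, expected_n):
    seq = make_promoter_with_hit(dist)
    hits = rk.find_candidate_spacers(seq, 350, "spcas9")
    assert len(hits) == expected_n
    if expected_n:
        assert hits[0].dist_to_tss == 75


@pytest.mark.parametrize("dist_start,expected_n", [(300, 1), (301, 0)])
def test_window_distal_boundary(dist_start, expected_n):
    tss, length = 350, 400
    base = list("AC" * (length // 2))
    start = tss - dist_start
    for i, ch in enumerate("AGG"):
        base[start + 20 + i] = ch
    hits = rk.find_candidate_spacers("".join(base), tss, "spcas9")
    assert len(hits) == expected_n


def test_poly_a_promoter_has_no_candidates():
    seq = "A" * 400
    for cas in ("spcas9", "lbcas12a"):
        assert rk.find_candidate_spacers(seq, 350, cas) == []


def test_tss_out_of_range_errors():
    with pytest.raises(DesignError):
        rk.find_candidate_spacers("ACGT" * 100, 1000, "spcas9")


def test_window_without_room_warns_and_returns_empty():
    assert rk.find_candidate_spacers("ACGT" * 25, 50, "spcas9") == []


@pytest.mark.parametrize("cas", ["spcas9", "lbcas12a"])
def test_candidates_match_bruteforce_oracle(bundle, cas):
    hits = rk.find_candidate_spacers(bundle.promoter, bundle.promoter_tss, cas)
    got = [(h.start, h.end, h.strand) for h in hits]
    assert got == naive_candidates(bundle.promoter, bundle.promoter_tss, cas)
    # guide-sense spacer sequence and PAM consistency
    for h in hits:
        proto = bundle.promoter[h.start:h.end]
        assert h.spacer.sequence == (proto if h.strand == "plus"
                                     else revcomp_str(proto))


def test_candidates_random_promoters_match_oracle(rng):
    for _ in range(5):
        seq = "".join(rng.choice("ACGT") for _ in range(600))
        tss = 550
        for cas in ("spcas9", "lbcas12a"):
            got = [(h.start, h.end, h.strand)
                   for h in rk.find_candidate_spacers(seq, tss, cas)]
            assert got == naive_candidates(seq, tss, cas)


def test_planted_fixture_pams_are_recovered(bundle):
    for planted in bundle.planted_pams:
        hits = rk.find_candidate_spacers(bundle.promoter, bundle.promoter_tss,
                                         planted["cas"])
        assert any(h.start == planted["start"] and h.end == planted["end"]
                   and h.strand == planted["strand"] for h in hits)
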