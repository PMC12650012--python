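"""Motif grammar: scanning, decomposition and feature classifiers."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from g4strat import (
    ConfigError,
    GrammarParams,
    InputError,
    classify_permutation,
    classify_telomeric_variant,
    find_all_pqs,
    find_bulged_pqs,
    find_canonical_pqs,
    loop_class,
    match_flank_motif,
    reverse_complement,
)

from bruteforce import normalise_motif, oracle_scan

PLUS_ONLY = GrammarParams(both_strands=False)


# --------------------------------------------------------------------------
# canonical scanning
# --------------------------------------------------------------------------

def test_minimal_canonical_motif_decomposition():
    motifs = find_canonical_pqs("GGGTGGGTGGGTGGG", PLUS_ONLY)
    assert len(motifs) == 1
    m = motifs[0]
    assert (m.start, m.end, m.strand) == (0, 15, "+")
    assert m.n_tetrads == 3
    assert m.loop_set.lengths == (1, 1, 1)
    assert m.loop_set.sequences == ("T", "T", "T")
    assert loop_class(m) == "all_1nt"
    assert not m.is_bulged


def test_no_g_tract_means_no_motif():
    assert find_canonical_pqs("ACGTACGTACGT") == []


def test_telomeric_repeat_decomposition():
    motifs = find_canonical_pqs("GGGTTAGGGTTAGGGTTAGGG", PLUS_ONLY)
    assert len(motifs) == 1
    m = motifs[0]
    assert m.n_tetrads == 3
    assert m.loop_set.lengths == (3, 3, 3)
    assert m.loop_set.sequences == ("TTA", "TTA", "TTA")
    assert classify_telomeric_variant(m) == "WT"


def test_flanks_are_reported_and_exclude_motif_bases():
    seq = "ACGTA" + "GGGTGGGTGGGTGGG" + "TACCA"
    (m,) = find_canonical_pqs(seq, PLUS_ONLY)
    assert (m.start, m.end) == (5, 20)
    assert m.flank5 == "ACGTA"
    assert m.flank3 == "TACCA"
    assert m.end - m.start == len(m.sequence)


def test_minus_strand_motif_in_plus_coordinates():
    plus_motif = "AACCA" + "GGGTTAGGGTTAGGGTTAGGG" + "CATTC"
    seq = reverse_complement(plus_motif)
    (m,) = find_canonical_pqs(seq)
    assert m.strand == "-"
    assert (m.start, m.end) == (5, 26)
    # decomposition is on the G-rich (motif) strand
    assert m.loop_set.sequences == ("TTA", "TTA", "TTA")
    assert m.flank5 == "AACCA"
    assert m.flank3 == "CATTC"


def test_surplus_terminal_guanines_stay_in_the_flank():
    # the run of four trailing Gs is trimmed to three (equal tetrad count,
    # shorter span), so a 3'-GAANN flank is observable as such
    seq = "GGGTGGGTGGGTGGG" + "GAACC"
    (m,) = find_canonical_pqs(seq, PLUS_ONLY)
    assert m.end == 15
    assert tuple(t.g_count for t in m.tracts) == (3, 3, 3, 3)
    assert m.flank3 == "GAACC"
    assert match_flank_motif(m, "3p", "GAANN")


def test_longer_tracts_win_over_shorter_span():
    (m,) = find_canonical_pqs("GGGGAGGGGAGGGGAGGGG", PLUS_ONLY)
    assert m.n_tetrads == 4
    assert tuple(t.g_count for t in m.tracts) == (4, 4, 4, 4)


def test_n_bases_terminate_motifs():
    assert find_canonical_pqs("GGGTGGGNGGGTGGG", PLUS_ONLY) == []


def test_invalid_alphabet_rejected():
    with pytest.raises(InputError):
        find_canonical_pqs("GGGTGGGTGGXTGGG")


def test_bad_loop_bounds_rejected():
    with pytest.raises(ConfigError):
        GrammarParams(loop_min=5, loop_max=2)
    with pytest.raises(ConfigError):
        GrammarParams(bulge_min=4, bulge_max=2)


# --------------------------------------------------------------------------
# bulged scanning
# --------------------------------------------------------------------------

def test_single_base_bulge_decomposition():
    motifs = find_bulged_pqs("GGAGTGGGTGGGTGGG", PLUS_ONLY)
    assert len(motifs) == 1
    m = motifs[0]
    assert m.n_tetrads == 3
    assert m.loop_set.lengths == (1, 1, 1)
    b = m.bulge
    assert (b.tract_index, b.size, b.sequence) == (0, 1, "A")
    assert b.offset_in_tract == 2


def test_canonical_locus_never_reported_as_bulged():
    assert find_bulged_pqs("GGGTGGGTGGGTGGG", PLUS_ONLY) == []


def test_multibase_bulge_matches_bruteforce_decomposition():
    # expected decomposition computed by the substring-enumeration oracle:
    # the only parse under the G-free-bulge grammar is a 4 nt bulge "ACTA"
    seq = "GGACTAGTGGGTGGGTGGG"
    canonical, bulged = oracle_scan(seq)
    assert canonical == []
    assert len(bulged) == 1
    _, _, g_counts, loops, bulge = bulged[0]
    assert bulge == (0, 2, "ACTA")

    (m,) = find_bulged_pqs(seq, PLUS_ONLY)
    assert normalise_motif(m) == bulged[0]
    assert m.bulge.size == 4
    assert m.loop_set.lengths == (1, 1, 1)


def test_bulge_counts_guanines_not_span():
    (m,) = find_bulged_pqs("GGAGTGGGTGGGTGGG", PLUS_ONLY)
    bulged_tract = m.tracts[0]
    assert bulged_tract.g_count == 3
    assert bulged_tract.span == 4
    assert m.n_tetrads == 3


# --------------------------------------------------------------------------
# oracle equivalence on random sequence
# --------------------------------------------------------------------------

def _random_seq(rng, length, p_g=0.35):
    other = (1 - p_g) / 3
    return "".join(
        rng.choice(["A", "C", "G", "T"], size=length,
                   p=[other, other, p_g, other])
    )


def test_scanner_equals_bruteforce_on_random_sequences(rng):
    params = GrammarParams(both_strands=False)
    for _ in range(30):
        seq = _random_seq(rng, 400)
        canonical, bulged = find_all_pqs(seq, params)
        oc, ob = oracle_scan(seq)
        assert [normalise_motif(m) for m in canonical] == oc
        assert [normalise_motif(m) for m in bulged] == ob


@given(st.text(alphabet="GGGACT", min_size=0, max_size=80))
def test_scanner_equals_bruteforce_property(seq):
    canonical, bulged = find_all_pqs(seq, PLUS_ONLY)
    oc, ob = oracle_scan(seq)
    assert [normalise_motif(m) for m in canonical] == oc
    assert [normalise_motif(m) for m in bulged] == ob


@given(st.text(alphabet="GGGACT", min_size=0, max_size=80))
def test_strand_symmetry(seq):
    params = GrammarParams()
    forward = find_canonical_pqs(seq, params) + find_bulged_pqs(seq, params)
    mirrored = find_canonical_pqs(reverse_complement(seq), params) \
        + find_bulged_pqs(reverse_complement(seq), params)
    n = len(seq)

    def norm(motifs, mirror):
        out = []
        for m in motifs:
            start, end = (n - m.end, n - m.start) if mirror else (m.start, m.end)
            strand = {"+": "-", "-": "+"}[m.strand] if mirror else m.strand
            out.append((start, end, strand,
                        tuple(t.g_count for t in m.tracts),
                        m.loop_set.sequences))
        return sorted(out)

    assert norm(forward, False) == norm(mirrored, True)


@given(st.text(alphabet="GGGGACT", min_size=0, max_size=80))
def test_decomposition_invariants_and_rescan_roundtrip(seq):
    canonical, bulged = find_all_pqs(seq, PLUS_ONLY)
    for m in canonical + bulged:
        assert len(m.tracts) == 4
        assert m.n_tetrads == min(t.g_count for t in m.tracts)
        assert m.loop_set.total_length == sum(m.loop_set.lengths)
        assert m.end - m.start == len(m.sequence)
        # re-scanning the motif's own sequence reproduces the decomposition
        rc_canonical, rc_bulged = find_all_pqs(m.sequence, PLUS_ONLY)
        again = (rc_canonical + rc_bulged)
        assert len(again) == 1
        a = again[0]
        assert (a.start, a.end) == (0, len(m.sequence))
        assert tuple(t.g_count for t in a.tracts) == \
            tuple(t.g_count for t in m.tracts)
        assert a.loop_set.sequences == m.loop_set.sequences
        assert (a.bulge is None) == (m.bulge is None)


def test_motifs_non_overlapping_per_strand(rng):
    for _ in range(10):
        seq = _random_seq(rng, 600, p_g=0.45)
        canonical, bulged = find_all_pqs(seq, PLUS_ONLY)
        spans = sorted((m.start, m.end) for m in canonical + bulged)
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            assert e1 <= s2


# --------------------------------------------------------------------------
# classifiers
# --------------------------------------------------------------------------

@pytest.mark.parametrize(
    "lengths, shape, label",
    [
        ((1, 3, 2), "x!=y!=z", "s-l-m"),
        ((3, 1, 2), "x!=y!=z", "l-s-m"),
        ((2, 3, 1), "x!=y!=z", "m-l-s"),
        ((2, 2, 1), "x=y>z", "x-x-z"),
        ((1, 2, 2), "x=y>z", "x-y-y"),
        ((5, 2, 2), "x=y<z", "x-y-y"),
        ((1, 1, 4), "x=y<z", "x-x-z"),
        ((3, 1, 3), "x=y>z", "x-y-x"),
        ((1, 4, 1), "x=y<z", "x-y-x"),
        ((1, 1, 1), "all_equal", "x-x-x"),
    ],
)
def test_permutation_classes(lengths, shape, label):
    cls = classify_permutation(lengths)
    assert cls.shape == shape
    assert cls.label == label


@pytest.mark.parametrize(
    "lengths, expected",
    [((1, 1, 1), "all_1nt"), ((2, 1, 2), "max_2nt"), ((1, 2, 1), "max_2nt"),
     ((1, 6, 1), "long"), ((3, 3, 3), "long"), ((1, 3, 1), "long")],
)
def test_loop_length_classes(lengths, expected):
    assert loop_class(lengths) == expected


@pytest.mark.parametrize(
    "seq, expected",
    [
        ("GGGTTAGGGTTAGGGTTAGGG", "WT"),
        ("GGGTTTGGGTTAGGGTTAGGG", "A_to_T_variant"),
        ("GGGTTTGGGTTTGGGTTTGGG", "A_to_T_variant"),
        ("GGGTGGGTGGGTGGG", "not_telomeric"),
        ("GGGTCAGGGTTAGGGTTAGGG", "not_telomeric"),
    ],
)
def test_telomeric_variant_classification(seq, expected):
    (m,) = find_canonical_pqs(seq, PLUS_ONLY)
    assert classify_telomeric_variant(m) == expected


def test_four_layer_telomeric_like_is_not_telomeric():
    (m,) = find_canonical_pqs("GGGGTTAGGGGTTAGGGGTTAGGGG", PLUS_ONLY)
    assert classify_telomeric_variant(m) == "not_telomeric"


@pytest.mark.parametrize(
    "flank5, pattern, expected",
    [("ACGTT", "NNNTT", True), ("CATGA", "NNTGA", True),
     ("ACGTA", "NNNTT", False), ("AATT", "NNNTT", False)],
)
def test_flank_matching_5p(flank5, pattern, expected):
    seq = flank5 + "GGGTGGGTGGGTGGG" + "AACCA"
    (m,) = find_canonical_pqs(seq, PLUS_ONLY)
    assert m.flank5 == flank5
    assert match_flank_motif(m, "5p", pattern) is expected


def test_flank_matching_3p_is_left_anchored():
    seq = "AACCA" + "GGGTGGGTGGGTGGG" + "TTACA"
    (m,) = find_canonical_pqs(seq, PLUS_ONLY)
    assert match_flank_motif(m, "3p", "TTNNN")
    assert not match_flank_motif(m, "3p", "GAANN")


def test_flank_matching_rejects_bad_inputs():
    (m,) = find_canonical_pqs("GGGTGGGTGGGTGGG", PLUS_ONLY)
    with pytest.raises(ConfigError):
        match_flank_motif(m, "left", "NNNTT")
    with pytest.raises(ConfigError):
        match_flank_motif(m, "5p", "NNQTT")
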