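import logging

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from eulertigs import canonical_spectrum, canonicalize, kmer_sequence, reverse_complement
from eulertigs.dna import DNA, AlphabetError, ComplementMap, clean_fragments, split_into_fragments

dna_text = st.text(alphabet="ACGT", max_size=60)


@pytest.mark.parametrize(
    "s,expected",
    [("GAATG", "CATTC"), ("AT", "AT"), ("", ""), ("ACGT", "ACGT"), ("AAA", "TTT")],
)
def test_reverse_complement_examples(s, expected):
    assert reverse_complement(s) == expected


@settings(max_examples=200, derandomize=True)
@given(dna_text)
def test_reverse_complement_is_involution(s):
    assert reverse_complement(reverse_complement(s)) == s


def test_reverse_complement_rejects_foreign_characters():
    with pytest.raises(AlphabetError, match=r"'N' at position 2"):
        reverse_complement("ACNGT")


def test_complement_map_must_be_involution():
    with pytest.raises(ValueError, match="involution"):
        ComplementMap({"A": "C", "C": "G", "G": "A", "T": "T"})


def test_complement_map_is_configurable():
    # a binary alphabet with 0<->1 complement behaves like DNA on {A,T}
    m = ComplementMap({"0": "1", "1": "0"})
    assert m.rc("0011") == "0011"
    assert m.rc("001") == "011"


@pytest.mark.parametrize(
    "kmer,canonical,reversed_,selfc",
    [
        ("CTG", "CAG", True, False),
        ("AT", "AT", False, True),
        ("ATC", "ATC", False, False),
        ("ACGT", "ACGT", False, True),
    ],
)
def test_canonicalize_examples(kmer, canonical, reversed_, selfc):
    ck = canonicalize(kmer)
    assert (ck.text, ck.was_reversed, ck.self_complemental) == (
        canonical,
        reversed_,
        selfc,
    )


@settings(max_examples=200, derandomize=True)
@given(st.text(alphabet="ACGT", min_size=1, max_size=12))
def test_canonicalize_agrees_between_strands(kmer):
    a = canonicalize(kmer)
    b = canonicalize(reverse_complement(kmer))
    assert a.text == b.text
    assert a.text <= reverse_complement(a.text)
    if a.self_complemental:
        assert not a.was_reversed and not b.was_reversed
    else:
        assert a.was_reversed != b.was_reversed


def test_spectrum_of_worked_example():
    spec = canonical_spectrum(["GAATG", "ATCTGCT"], 3)
    assert spec.kmers == {"GAA", "AAT", "ATG", "ATC", "AGA", "CAG", "GCA", "AGC"}


def test_spectrum_collapses_repeats_and_counts_distinct():
    assert canonical_spectrum(["AAAA"], 3).kmers == {"AAA"}
    assert len(canonical_spectrum(["AGGTGCCGTGGGAT"], 4)) == 11


@settings(max_examples=150, derandomize=True)
@given(st.lists(st.text(alphabet="ACGT", min_size=3, max_size=30), max_size=3))
def test_spectrum_is_strand_invariant_and_bounded(strings):
    k = 3
    fwd = canonical_spectrum(strings, k)
    rev = canonical_spectrum([reverse_complement(s) for s in strings], k)
    assert fwd == rev
    for s in strings:
        assert len(canonical_spectrum([s], k)) <= len(s) - k + 1


def test_kmer_sequence_examples():
    assert kmer_sequence("GAATG", 3) == ["GAA", "AAT", "ATG"]
    assert kmer_sequence("ATCT", 4) == ["ATCT"]
    seq = kmer_sequence("AGGTGCCGTGGGAT", 4)
    assert len(seq) == 11 and seq[:3] == ["AGGT", "GGTG", "GTGC"]
    with pytest.raises(ValueError):
        kmer_sequence("AT", 3)


def test_fragment_splitting_and_case_folding(caplog):
    assert split_into_fragments("acgtNNggT") == ["ACGT", "GGT"]
    assert split_into_fragments("NNN") == []
    with caplog.at_level(logging.WARNING):
        frags = clean_fragments(["ACGTNAG", "cc"], k=3)
    assert frags == ["ACGT"]
    assert "dropping fragment" in caplog.text


def test_spectrum_requires_k_at_least_two():
    with pytest.raises(ValueError):
        canonical_spectrum(["ACGT"], 1)
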