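"""C-terminal ER-retrieval motif matching and consensus profiling."""

import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from secrepy.errors import ConfigurationError, ValidationError
from secrepy.motif import (
    XXEL_POSITION_CLASS,
    MotifPattern,
    derive_consensus,
    match_xxel,
)

CLASS22 = set(XXEL_POSITION_CLASS)


def brute_force_xxel(tetra: str) -> bool:
    """Independent checker: positions 3-4 are E,L and positions 1-2 are in
    the 22-letter class."""
    return (
        len(tetra) == 4
        and tetra[2] == "E"
        and tetra[3] == "L"
        and tetra[0] in CLASS22
        and tetra[1] in CLASS22
    )


@pytest.mark.parametrize(
    "sequence, expected",
    [
        ("MKTAYIAKQRKDEL", "KDEL"),  # canonical ER-retrieval signal
        ("MKTAYIAKQRHDEL", "HDEL"),  # yeast-style variant
        ("AAAABZEL", "BZEL"),  # ambiguity codes allowed at positions 1-2
        ("MKTAYIAKQRKDELA", None),  # EL not terminal: anchored match only
        ("EL", None),  # shorter than the four-residue window
        ("AAAUXEL", None),  # U excluded from the position-1/2 class
        ("AAAXKEL", None),  # X excluded from the position-1/2 class
        ("kdel", "KDEL"),  # lower-case input is normalised
        ("AAAAKDE", None),  # tail is not EL
    ],
)
def test_match_xxel_examples(sequence, expected):
    match = match_xxel(sequence)
    if expected is None:
        assert match is None
    else:
        assert match is not None
        assert match.tetrapeptide == expected
        assert match.start == len(sequence) - 3


def test_match_position_reported():
    match = match_xxel("A" * 96 + "KDEL")
    assert match.start == 97


def test_invalid_residue_names_offender():
    with pytest.raises(ValidationError, match=r"'1' at position 3"):
        match_xxel("AB1KDEL")


@settings(derandomize=True, max_examples=300)
@given(st.text(alphabet="ABCDEFGHIJKLMNOPQRSTUVWXYZ", min_size=4, max_size=30))
def test_match_agrees_with_bruteforce_on_random_sequences(sequence):
    assert (match_xxel(sequence) is not None) == brute_force_xxel(sequence[-4:])


def test_appending_residue_destroys_match():
    """Anchoring: any single-residue extension that does not re-create a
    terminal EL kills the match."""
    rng = random.Random(42)
    for _ in range(50):
        seq = "".join(rng.choices("ACDEFGHIKLMNPQRSTVWY", k=10)) + "KDEL"
        assert match_xxel(seq) is not None
        extra = rng.choice("ACDEFGHIKMNPQRSTVWY")  # anything; tail becomes DEL+x
        assert match_xxel(seq + extra) is None


def test_pattern_from_character_class_roundtrip():
    pattern = MotifPattern.from_character_class("[ARNDCQEGHILKMFPSTWYVBZ]{2}EL")
    assert pattern == MotifPattern.default()
    narrow = MotifPattern.from_character_class("[K]{2}EL")
    assert narrow.matches("KKEL") and not narrow.matches("KDEL")


def test_pattern_from_character_class_rejects_garbage():
    with pytest.raises(ConfigurationError):
        MotifPattern.from_character_class("KDEL motif")


def test_pattern_allow_list():
    pattern = MotifPattern.from_allow_list(["KDEL", "HDEL"])
    assert match_xxel("AAAKDEL", pattern) is not None
    assert match_xxel("AAASNEL", pattern) is None
    with pytest.raises(ConfigurationError):
        MotifPattern.from_allow_list(["KDELX"])


class TestDeriveConsensus:
    def test_shared_tail_only(self):
        profile = derive_consensus(["AAAKDEL", "CCCHTEL", "DDDSNEL"], k=4)
        assert profile.consensus == "XXEL"
        assert profile.tetrapeptide_counts == {"HTEL": 1, "KDEL": 1, "SNEL": 1}
        assert all(sum(c.values()) == 3 for c in profile.counts)

    def test_single_sequence_dominates(self):
        profile = derive_consensus(["MSPAQKDEL"])
        assert profile.consensus == "KDEL"

    def test_unanimous_set_returns_exact_kmer_and_perturbation_flips_to_x(self):
        seqs = ["AA" + "HDEL" for _ in range(5)]
        assert derive_consensus(seqs).consensus == "HDEL"
        seqs[0] = "AA" + "KDEL"  # break unanimity at window position 1
        assert derive_consensus(seqs).consensus == "XDEL"

    def test_dominance_below_unanimity(self):
        seqs = ["AKDEL"] * 3 + ["AHDEL"]
        assert derive_consensus(seqs, dominance=1.0).consensus == "XDEL"
        assert derive_consensus(seqs, dominance=0.75).consensus == "KDEL"

    def test_tetrapeptide_ordering_count_then_lexicographic(self):
        seqs = ["AHDEL"] * 2 + ["AKDEL"] * 2 + ["ASNEL"] * 3
        profile = derive_consensus(seqs)
        assert list(profile.tetrapeptide_counts) == ["SNEL", "HDEL", "KDEL"]

    def test_match_implies_el_consensus(self):
        rng = random.Random(7)
        for _ in range(20):
            seq = "".join(rng.choices("ACDEFGHIKLMNPQRSTVWY", k=12)) + rng.choice(
                ["KDEL", "HTEL", "RSEL"]
            )
            assert match_xxel(seq) is not None
            assert derive_consensus([seq]).consensus.endswith("EL")

    @pytest.mark.parametrize(
        "sequences, k, dominance, message",
        [
            ([], 4, 1.0, "empty"),
            (["KD"], 4, 1.0, "shorter than the window"),
            (["AKDEL"], 4, 0.3, "dominance"),
            (["AKDEL"], 0, 1.0, "window length"),
        ],
    )
    def test_validation_errors(self, sequences, k, dominance, message):
        with pytest.raises(ValidationError, match=message):
            derive_consensus(sequences, k=k, dominance=dominance)
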