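"""Complementarity scoring rules and exhaustiveness of the site scanner."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from duplex_oracle import enumerate_accepted, enumerate_accepted_noprune
from pipeline_utils import random_scan_instance

from srnadig.duplex import (
    Bulge,
    DuplexAlignment,
    PairState,
    ScoringConfig,
    build_alignment,
    find_candidate_sites,
    pair_state,
    score_alignment,
)
from srnadig.errors import InputError
from srnadig.seqio import Transcript, reverse_complement

CFG = ScoringConfig()
_STATE = {"W": PairState.WC, "G": PairState.GU, "M": PairState.MM,
          "B": PairState.BULGE_SRNA}


def _aln(states: str, bulges: tuple[Bulge, ...] = ()) -> DuplexAlignment:
    """Hand-built alignment from a per-position state string (W/G/M/B)."""
    return DuplexAlignment(
        srna_sequence="A" * len(states),
        target_id="t",
        target_start=1,
        target_end=len(states),
        pair_states=tuple(_STATE[c] for c in states),
        bulges=bulges,
        penalty=0.0,
        position_map=tuple(
            None if c == "B" else len(states) - i for i, c in enumerate(states)
        ),
    )


@pytest.mark.parametrize(
    "s,t,expected",
    [
        ("G", "C", PairState.WC),
        ("A", "T", PairState.WC),
        ("G", "T", PairState.GU),
        ("T", "G", PairState.GU),
        ("A", "C", PairState.MM),
        ("A", "G", PairState.MM),
    ],
)
def test_pair_state_classification(s, t, expected):
    assert pair_state(s, t) is expected


def test_pair_state_rejects_undetermined_bases():
    with pytest.raises(InputError):
        pair_state("N", "A")


@pytest.mark.parametrize(
    "states,bulges,expected",
    [
        # perfect 21-nt duplex carries no penalty
        ("W" * 21, (), 0.0),
        # one G:U wobble costs 0.5 wherever it sits
        ("W" * 4 + "G" + "W" * 16, (), 0.5),
        ("W" * 20 + "G", (), 0.5),
        # seed mismatch costs 1.0, non-seed mismatch 0.5
        ("W" * 2 + "M" + "W" * 18, (), 1.0),
        ("M" + "W" * 20, (), 0.5),
        ("W" * 14 + "M" + "W" * 6, (), 0.5),
        # two seed mismatches allowed, G:U never counts toward the cap
        ("W" + "MM" + "G" * 4 + "W" * 14, (), 4.0),
        # 1-nt bulge costs 2.0; each extra bulged nucleotide adds 0.5
        ("W" * 21, (Bulge(5, 1, "target"),), 2.0),
        ("W" * 21, (Bulge(5, 2, "target"),), 2.5),
        ("W" * 21, (Bulge(5, 3, "target"),), 3.0),
        # 2-nt target bulge plus one G:U: 2.0 + 0.5 + 0.5
        ("W" * 4 + "G" + "W" * 16, (Bulge(7, 2, "target"),), 3.0),
        # two 1-nt bulges on opposite strands
        ("W" * 5 + "B" + "W" * 15, (Bulge(5, 1, "srna"), Bulge(9, 1, "target")), 4.0),
        # exactly at the acceptance cap: 2 seed MM + 6 non-seed MM
        ("MWMM" + "W" * 9 + "M" * 5 + "W" * 3, (), 5.0),
    ],
)
def test_penalty_arithmetic(states, bulges, expected):
    assert score_alignment(_aln(states, bulges), CFG) == pytest.approx(expected)


@pytest.mark.parametrize(
    "states,bulges",
    [
        # mismatches forbidden at slicer positions 10 and 11
        ("W" * 9 + "M" + "W" * 11, ()),
        ("W" * 10 + "M" + "W" * 10, ()),
        # more than two seed mismatches
        ("W" * 2 + "M" + "W" * 2 + "M" + "W" * 2 + "M" + "W" * 12, ()),
        # more than two bulges
        ("W" * 21, (Bulge(3, 1, "target"), Bulge(7, 1, "target"),
                    Bulge(11, 1, "target"))),
        # total penalty above the cap
        ("M" * 10 + "W" * 10 + "M", ()),
        ("G" * 11 + "W" * 10, ()),
    ],
)
def test_hard_rules_reject(states, bulges):
    assert score_alignment(_aln(states, bulges), CFG) is None


def test_gu_does_not_count_toward_seed_mismatch_cap():
    # 2 seed MM plus 3 seed G:U stays legal (penalty 3.5)
    states = "W" + "MM" + "GGG" + "W" * 15
    assert score_alignment(_aln(states), CFG) == pytest.approx(3.5)


def _embed(srna: str, flank5: int = 100, flank3: int = 100, seed: int = 0):
    rng = np.random.default_rng(seed)
    left = "".join("ACGT"[i] for i in rng.integers(0, 4, flank5))
    right = "".join("ACGT"[i] for i in rng.integers(0, 4, flank3))
    return Transcript("t", left + reverse_complement(srna) + right)


def test_planted_perfect_site_found_at_exact_coordinates():
    srna = "TGACAGAAGAGAGTGAGCACA"
    tr = _embed(srna)
    hits = find_candidate_sites(srna, tr)
    perfect = [a for a in hits if a.penalty == 0.0]
    assert len(perfect) == 1
    aln = perfect[0]
    assert aln is hits[0]  # results are penalty-sorted
    assert (aln.target_start, aln.target_end) == (101, 121)
    assert aln.n_bulges == 0
    # antiparallel position map: sRNA 5' end pairs the window's 3' end
    assert aln.position_map[0] == 121 and aln.position_map[20] == 101


def test_planted_site_with_nonseed_mismatch_scores_half_point():
    srna = "TGACAGAAGAGAGTGAGCACA"
    tr = _embed(srna)
    mutated = srna[:17] + ("C" if srna[17] != "C" else "G") + srna[18:]
    hits = [a for a in find_candidate_sites(mutated, tr) if a.target_start == 101]
    assert hits and hits[0].penalty == pytest.approx(0.5)


def test_window_containing_n_is_never_returned():
    srna = "TGACAGAAGAGAGTGAGCACA"
    tr = _embed(srna)
    broken = Transcript("t", tr.sequence[:110] + "N" + tr.sequence[111:])
    assert all(
        not (a.target_start <= 110 + 1 <= a.target_end)
        for a in find_candidate_sites(srna, broken)
    )


def test_scanner_input_validation():
    tr = _embed("TGACAGAAGAGAGTGAGCACA")
    with pytest.raises(InputError):
        find_candidate_sites("ACGTACGTACGT", tr)  # shorter than the seed
    with pytest.raises(InputError):
        find_candidate_sites("TGACAGAAGAGAGTGAGCACN", tr)


def _contract(alignments):
    return {(a.target_start, a.penalty, a.n_bulges, a.n_mismatches)
            for a in alignments}


@pytest.mark.parametrize("transcript_len", [40, 120])
def test_scanner_equals_bruteforce_on_random_instances(transcript_len):
    """Both scanner code paths (DFS for short targets, vectorized above)
    must reproduce the brute-force enumerator exactly."""
    rng = np.random.default_rng(transcript_len)
    for _ in range(25):
        srna, tseq = random_scan_instance(rng, transcript_len)
        got = _contract(find_candidate_sites(srna, Transcript("t", tseq)))
        assert got == enumerate_accepted(srna, tseq, CFG)


def test_recursive_oracle_matches_flat_enumeration():
    """Validates the pruned oracle itself against shape-by-shape scoring."""
    rng = np.random.default_rng(99)
    for _ in range(3):
        srna, tseq = random_scan_instance(rng, 30)
        assert enumerate_accepted(srna, tseq, CFG) == enumerate_accepted_noprune(
            srna, tseq, CFG
        )


def test_lowering_max_score_yields_subset():
    rng = np.random.default_rng(5)
    tight_cfg = ScoringConfig(max_score=3.0)
    for _ in range(10):
        srna, tseq = random_scan_instance(rng, 150)
        tr = Transcript("t", tseq)
        wide = _contract(find_candidate_sites(srna, tr, CFG))
        tight = _contract(find_candidate_sites(srna, tr, tight_cfg))
        assert tight <= wide
        assert all(pen <= 3.0 for _, pen, _, _ in tight)


def test_perfect_sites_are_strand_symmetric():
    """A full-complement site is recovered at mirrored coordinates when both
    query and transcript are reverse-complemented."""
    srna = "TGACAGAAGAGAGTGAGCACA"
    tr = _embed(srna)
    (fwd,) = [a for a in find_candidate_sites(srna, tr) if a.penalty == 0.0]
    rc_tr = Transcript("t_rc", reverse_complement(tr.sequence))
    hits = [
        a
        for a in find_candidate_sites(reverse_complement(srna), rc_tr)
        if a.penalty == 0.0
    ]
    T = len(tr.sequence)
    assert {(T - a.target_end + 1, T - a.target_start + 1) for a in hits} == {
        (fwd.target_start, fwd.target_end)
    }


def test_build_alignment_penalty_agrees_with_scalar_scorer():
    srna = "TGACAGAAGAGAGTGAGCACA"
    tr = _embed(srna)
    for aln in find_candidate_sites(srna, tr):
        rebuilt = build_alignment(
            srna, tr, aln.target_end,
            tuple((b.position, b.side, b.length) for b in aln.bulges),
        )
        assert rebuilt is not None
        assert rebuilt.penalty == score_alignment(rebuilt, CFG)


@given(st.integers(min_value=0, max_value=10_000))
def test_render_marks_every_srna_position(seed):
    rng = np.random.default_rng(seed)
    srna, tseq = random_scan_instance(rng, 80)
    for aln in find_candidate_sites(srna, Transcript("t", tseq)):
        rendered = aln.render()
        bulged_target = sum(b.length for b in aln.bulges if b.side == "target")
        assert len(rendered) == len(srna) + bulged_target
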