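"""Complementarity penalty scoring and candidate binding-site scanning.

A plant sRNA binds its target nearly perfectly, antiparallel: sRNA position
``i`` (1-based from the 5' end) pairs the target base at ``target_end-i+1``
in a gap-free duplex.  Deviations from Watson–Crick pairing are penalised:

* G:U wobble — 0.5 points each, anywhere;
* mismatch inside the seed (sRNA positions 2–13) — 1.0 point each, at most
  two allowed (G:U pairs do not count toward that cap);
* mismatch outside the seed — 0.5 points each;
* a bulge (insertion/deletion on either strand) — 2.0 points, plus 0.5 per
  additional bulged nucleotide; at most two bulges;
* mismatches at sRNA positions 10 and 11 (the slicer site) are forbidden.

A duplex is accepted when none of the hard rules is violated and the total
penalty does not exceed ``max_score`` (default 5.0).  All of these knobs
live in :class:`ScoringConfig`.

The scanner :func:`find_candidate_sites` enumerates every alignment of the
sRNA against every transcript window with up to two bulges.  It is exact:
alignments are organised by *shape* (bulge sides/positions/lengths) and each
shape family is scored for all anchor positions at once with per-offset
diagonal prefix-sum arrays; a cheap penalty-only prefilter keeps survivors,
which are then rebuilt and re-scored position by position.  Transcript
windows containing ``N`` cannot be scored and are never returned.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from enum import Enum
from typing import Iterator, Optional, Union

import numpy as np

from .errors import InputError
from .seqio import AbundantRead, Transcript

#: sentinel per-position cost marking an unscorable cell (N base or a cell
#: outside the transcript); large but exactly representable so prefix-sum
#: differences remain exact in float64.
BIG = float(2 ** 24)


class PairState(str, Enum):
    WC = "WC"
    GU = "GU"
    MM = "MM"
    BULGE_SRNA = "BULGE_SRNA"
    BULGE_TARGET = "BULGE_TARGET"


_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


def pair_state(srna_base: str, target_base: str) -> PairState:
    """Classify one sRNA/target base pair (target read on the mRNA sense strand)."""
    if srna_base not in _COMPLEMENT or target_base not in _COMPLEMENT:
        raise InputError(
            f"cannot pair undetermined bases {srna_base!r}/{target_base!r}"
        )
    if _COMPLEMENT[srna_base] == target_base:
        return PairState.WC
    if (srna_base == "G" and target_base == "T") or (
        srna_base == "T" and target_base == "G"
    ):
        return PairState.GU
    return PairState.MM


@dataclass(frozen=True)
class ScoringConfig:
    """Penalty weights and hard limits of the complementarity rules."""

    gu_penalty: float = 0.5
    mm_penalty_seed: float = 1.0
    mm_penalty_nonseed: float = 0.5
    bulge_penalty: float = 2.0
    bulge_extra_nt_penalty: float = 0.5
    max_seed_mismatches: int = 2
    seed_start: int = 2
    seed_end: int = 13
    forbidden_mm_positions: tuple[int, ...] = (10, 11)
    max_bulges: int = 2
    max_score: float = 5.0

    def bulge_cost(self, length: int) -> float:
        return self.bulge_penalty + self.bulge_extra_nt_penalty * (length - 1)


@dataclass(frozen=True, order=True)
class Bulge:
    """A bulge run between sRNA positions ``position`` and ``position+1``.

    ``side == "srna"``: sRNA positions ``position+1 .. position+length`` are
    unpaired.  ``side == "target"``: ``length`` target bases are unpaired
    between the bases pairing sRNA positions ``position`` and ``position+1``.
    """

    position: int
    length: int
    side: str  # "srna" | "target"


_RENDER = {PairState.WC: "|", PairState.GU: "o", PairState.MM: ".",
           PairState.BULGE_SRNA: "-"}


@dataclass(frozen=True)
class DuplexAlignment:
    """An accepted sRNA/target pairing.

    ``pair_states`` has one entry per sRNA position (1..L from the 5' end);
    unpaired sRNA positions carry ``BULGE_SRNA``.  ``position_map`` gives the
    1-based target coordinate paired with each sRNA position (``None`` where
    bulged).  ``target_start``/``target_end`` are 1-based inclusive.
    """

    srna_sequence: str
    target_id: str
    target_start: int
    target_end: int
    pair_states: tuple[PairState, ...]
    bulges: tuple[Bulge, ...]
    penalty: float
    position_map: tuple[Optional[int], ...]

    @property
    def n_bulges(self) -> int:
        return len(self.bulges)

    @property
    def n_mismatches(self) -> int:
        return sum(1 for s in self.pair_states if s is PairState.MM)

    def shifted(self, offset: int) -> "DuplexAlignment":
        """Translate target coordinates by *offset* (used to lift bait-local
        alignments back onto the full transcript)."""
        return replace(
            self,
            target_start=self.target_start + offset,
            target_end=self.target_end + offset,
            position_map=tuple(
                None if p is None else p + offset for p in self.position_map
            ),
        )

    def render(self) -> str:
        """One-line duplex string, 5'->3' along the sRNA: ``|`` WC, ``o`` G:U,
        ``.`` mismatch, ``-`` bulged sRNA base, ``^`` bulged target base(s)."""
        target_bulge_after = {
            b.position: b.length for b in self.bulges if b.side == "target"
        }
        parts = []
        for pos, state in enumerate(self.pair_states, start=1):
            parts.append(_RENDER[state])
            if pos in target_bulge_after:
                parts.append("^" * target_bulge_after[pos])
        return "".join(parts)


def score_alignment(
    alignment: DuplexAlignment, config: ScoringConfig = ScoringConfig()
) -> Optional[float]:
    """Total penalty of an alignment, or ``None`` if a hard rule rejects it.

    Hard rules: mismatch at a forbidden position (10/11), more than
    ``max_seed_mismatches`` mismatches in the seed, more than ``max_bulges``
    bulges, or total penalty above ``max_score``.
    """
    penalty = 0.0
    seed_mm = 0
    for pos, state in enumerate(alignment.pair_states, start=1):
        if state is PairState.MM:
            if pos in config.forbidden_mm_positions:
                return None
            if config.seed_start <= pos <= config.seed_end:
                seed_mm += 1
                penalty += config.mm_penalty_seed
            else:
                penalty += config.mm_penalty_nonseed
        elif state is PairState.GU:
            penalty += config.gu_penalty
    if seed_mm > config.max_seed_mismatches:
        return None
    if len(alignment.bulges) > config.max_bulges:
        return None
    for b in alignment.bulges:
        penalty += config.bulge_cost(b.length)
    if penalty > config.max_score:
        return None
    return penalty


# ---------------------------------------------------------------------------
# scanning

_ENC = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}
# WC partner codes: A-T, C-G, G-C, T-A
_WC_PARTNER = {0: 3, 1: 2, 2: 1, 3: 0}


def _encode(seq: str) -> np.ndarray:
    return np.fromiter((_ENC[c] for c in seq), dtype=np.int8, count=len(seq))


def _cost_matrix(s_codes: np.ndarray, t_codes: np.ndarray,
                 config: ScoringConfig) -> np.ndarray:
    """Per (sRNA position, target position) pairing cost; BIG where target is N."""
    state = np.full((5, 5), 2, dtype=np.int8)  # 2 = MM
    for a, b in _WC_PARTNER.items():
        state[a, b] = 0  # WC
    state[2, 3] = 1  # sRNA G : target T
    state[3, 2] = 1  # sRNA T : target G
    state[4, :] = 3
    state[:, 4] = 3  # undetermined
    st = state[s_codes[:, None], t_codes[None, :]]  # (L, T)
    L = len(s_codes)
    pos = np.arange(1, L + 1)
    mm_cost = np.where(
        (pos >= config.seed_start) & (pos <= config.seed_end),
        config.mm_penalty_seed,
        config.mm_penalty_nonseed,
    )[:, None]
    cost = np.zeros(st.shape)
    cost += (st == 1) * config.gu_penalty
    cost = np.where(st == 2, mm_cost, cost)
    cost = np.where(st == 3, BIG, cost)
    return cost


def _diag_prefix(cost: np.ndarray, offset: int) -> np.ndarray:
    """Prefix sums along anchored diagonals.

    ``P[k, e0]`` is the summed cost of pairing sRNA rows ``0..k-1`` when the
    alignment is anchored at 0-based target-end ``e0`` and the segment runs
    at ``offset`` (row ``i`` pairs target column ``e0 - i + offset``); cells
    outside the transcript cost BIG.
    """
    L, T = cost.shape
    diag = np.full((L, T), BIG)
    for i in range(L):
        shift = i - offset  # target column = e0 - shift
        lo = max(0, shift)
        hi = min(T, T + shift)
        if lo < hi:
            diag[i, lo:hi] = cost[i, lo - shift:hi - shift]
    out = np.zeros((L + 1, T))
    np.cumsum(diag, axis=0, out=out[1:])
    return out


def _max_bulge_len(config: ScoringConfig) -> int:
    max_len = 1
    while config.bulge_cost(max_len + 1) <= config.max_score:
        max_len += 1
    return max_len


_GROUP_CACHE: dict[tuple, tuple] = {}


def _shape_groups(L: int, config: ScoringConfig) -> tuple:
    """Precomputed shape-family metadata for one (sRNA length, config) pair."""
    key = (L, config)
    if key in _GROUP_CACHE:
        return _GROUP_CACHE[key]
    budget = config.max_score
    max_len = _max_bulge_len(config)
    one: list[tuple] = []
    two: list[tuple] = []
    if config.max_bulges >= 1:
        for side in ("srna", "target"):
            for b in range(1, max_len + 1):
                bc = config.bulge_cost(b)
                if bc > budget:
                    break
                o = b if side == "srna" else -b
                p_hi = (L - 1 - b) if side == "srna" else (L - 1)
                p_arr = np.arange(1, p_hi + 1)
                if p_arr.size:
                    one.append((side, b, o, bc, p_arr))
    if config.max_bulges >= 2:
        for s1 in ("srna", "target"):
            for b1 in range(1, max_len + 1):
                for s2 in ("srna", "target"):
                    for b2 in range(1, max_len + 1):
                        bc = config.bulge_cost(b1) + config.bulge_cost(b2)
                        if bc > budget:
                            continue
                        o1 = b1 if s1 == "srna" else -b1
                        o2 = o1 + (b2 if s2 == "srna" else -b2)
                        d1 = b1 if s1 == "srna" else 0
                        d2 = b2 if s2 == "srna" else 0
                        p1_hi = (L - 1 - b1) if s1 == "srna" else (L - 1)
                        p2_hi = (L - 1 - b2) if s2 == "srna" else (L - 1)
                        p1_arr = np.arange(1, p1_hi + 1)
                        p2_arr = np.arange(2, p2_hi + 1)
                        if p1_arr.size == 0 or p2_arr.size == 0:
                            continue
                        # >= 1 paired position between the two bulge runs
                        valid = p2_arr[None, :] >= (p1_arr + d1 + 1)[:, None]
                        if not valid.any():
                            continue
                        two.append((s1, b1, s2, b2, o1, o2, d1, d2, bc,
                                    p1_arr, p2_arr, valid))
    _GROUP_CACHE[key] = (one, two)
    return _GROUP_CACHE[key]


def _shape_candidates(cost: np.ndarray, L: int,
                      config: ScoringConfig) -> Iterator[tuple[int, tuple]]:
    """Yield (e0, bulge-descriptor tuple) for every alignment shape whose
    pairing-cost total is within ``max_score``.  Bulge descriptors are
    (position, side, length) with 1-based sRNA positions.

    This is a penalty-only prefilter: seed-mismatch caps and forbidden
    positions are enforced later by the scalar scorer.
    """
    budget = config.max_score
    one, two = _shape_groups(L, config)
    prefixes: dict[int, np.ndarray] = {}

    def prefix(offset: int) -> np.ndarray:
        if offset not in prefixes:
            prefixes[offset] = _diag_prefix(cost, offset)
        return prefixes[offset]

    # gap-free
    p0 = prefix(0)
    for e0 in np.nonzero(p0[L] <= budget)[0]:
        yield int(e0), ()

    # one bulge
    for side, b, o, bc, p_arr in one:
        po = prefix(o)
        if side == "srna":
            pen = p0[p_arr] + (po[L] - po[p_arr + b]) + bc
        else:
            pen = p0[p_arr] + (po[L] - po[p_arr]) + bc
        for pi, e0 in np.argwhere(pen <= budget):
            yield int(e0), ((int(p_arr[pi]), side, b),)

    # two bulges; each costs >= bulge_penalty so lengths are tightly bounded
    for s1, b1, s2, b2, o1, o2, d1, d2, bc, p1_arr, p2_arr, valid in two:
        po1, po2 = prefix(o1), prefix(o2)
        # pen(p1,p2,e) = A[p1,e] + B[p2,e] + const[e] + bc
        A = p0[p1_arr] - po1[p1_arr + d1]
        B = po1[p2_arr] - po2[p2_arr + d2]
        rest = budget - bc - po2[L]  # per-anchor leftover
        feasible = np.nonzero(A.min(axis=0) + B.min(axis=0) <= rest)[0]
        if feasible.size == 0:
            continue
        pen3 = A[:, None, feasible] + B[None, :, feasible] - rest[feasible]
        hits = np.argwhere((pen3 <= 0.0) & valid[:, :, None])
        for i1, i2, fe in hits:
            yield int(feasible[fe]), (
                (int(p1_arr[i1]), s1, b1),
                (int(p2_arr[i2]), s2, b2),
            )


#: below this target length the numpy machinery costs more than it saves;
#: a pure-Python exhaustive search over the same shape space is used instead.
SMALL_TARGET_LEN = 64


def _shape_candidates_dfs(cost: np.ndarray, L: int,
                          config: ScoringConfig) -> Iterator[tuple[int, tuple]]:
    """Exhaustive depth-first search over the same shape space as
    :func:`_shape_candidates`, for short targets (e.g. 30-nt bait regions).

    Prunes only on conditions that are monotone under extension (penalty
    above ``max_score``; N/out-of-window cells cost BIG), so the yielded
    candidate set is identical to the vectorized enumeration's.
    """
    T = cost.shape[1]
    rows = cost.tolist()
    budget = config.max_score
    max_len = _max_bulge_len(config)
    max_bulges = config.max_bulges
    bulge_costs = [0.0] + [config.bulge_cost(b) for b in range(1, max_len + 1)]
    out: list[tuple[int, tuple]] = []

    def rec(i: int, t: int, pen: float, shape: tuple, e0: int) -> None:
        # pair sRNA position i (1-based) with target position t, then extend
        if not (1 <= t <= T):
            return
        pen += rows[i - 1][t - 1]
        if pen > budget:
            return
        if i == L:
            out.append((e0, shape))
            return
        rec(i + 1, t - 1, pen, shape, e0)
        if len(shape) < max_bulges:
            for b in range(1, max_len + 1):
                bpen = pen + bulge_costs[b]
                if bpen > budget:
                    break
                if i + b <= L - 1:  # sRNA bulge: positions i+1..i+b unpaired
                    rec(i + b + 1, t - 1, bpen, shape + ((i, "srna", b),), e0)
                rec(i + 1, t - 1 - b, bpen, shape + ((i, "target", b),), e0)

    for e in range(1, T + 1):
        rec(1, e, 0.0, (), e - 1)
    return iter(out)


def build_alignment(
    srna_sequence: str,
    transcript: Transcript,
    target_end: int,
    bulges: tuple[tuple[int, str, int], ...],
    config: ScoringConfig = ScoringConfig(),
) -> Optional[DuplexAlignment]:
    """Materialise the alignment of a given shape and score it.

    ``bulges`` are (position, side, length) descriptors ordered by position;
    ``target_end`` is the 1-based target base pairing sRNA position 1.
    Returns ``None`` if the shape leaves the transcript, meets an ``N``, or
    is rejected by :func:`score_alignment`.
    """
    L = len(srna_sequence)
    tseq = transcript.sequence
    T = len(tseq)
    bulge_after = {p: (side, ln) for p, side, ln in bulges}
    states: list[PairState] = [PairState.WC] * L
    pmap: list[Optional[int]] = [None] * L
    i = 1
    t = target_end
    while i <= L:
        if not (1 <= t <= T):
            return None
        tb = tseq[t - 1]
        sb = srna_sequence[i - 1]
        if tb == "N" or sb == "N":
            return None
        states[i - 1] = pair_state(sb, tb)
        pmap[i - 1] = t
        t -= 1
        if i in bulge_after:
            side, ln = bulge_after[i]
            if side == "srna":
                for k in range(i + 1, i + ln + 1):
                    states[k - 1] = PairState.BULGE_SRNA
                    pmap[k - 1] = None
                i += ln
            else:
                t -= ln
        i += 1
    if "N" in tseq[t:target_end]:  # windows containing N cannot be scored,
        return None                # even where the N would sit in a bulge
    aln = DuplexAlignment(
        srna_sequence=srna_sequence,
        target_id=transcript.id,
        target_start=t + 1,  # t sits one below the last paired base
        target_end=target_end,
        pair_states=tuple(states),
        bulges=tuple(Bulge(p, ln, side) for p, side, ln in bulges),
        penalty=0.0,
        position_map=tuple(pmap),
    )
    penalty = score_alignment(aln, config)
    if penalty is None:
        return None
    return replace(aln, penalty=penalty)


def find_candidate_sites(
    srna: Union[AbundantRead, str],
    transcript: Transcript,
    config: ScoringConfig = ScoringConfig(),
) -> list[DuplexAlignment]:
    """All accepted binding sites of one sRNA on one transcript.

    Exhaustive over every anchor and every bulge placement (up to
    ``max_bulges``).  Overlapping solutions are reduced to the best
    alignment per target start position — minimum penalty, ties broken by
    fewer bulges, then fewer mismatches, then leftmost (smallest target
    end).  The result is sorted by penalty ascending, then target start.
    """
    seq = srna.sequence if isinstance(srna, AbundantRead) else srna
    L = len(seq)
    if L < config.seed_end:
        raise InputError(
            f"sRNA of length {L} is shorter than the seed region end "
            f"({config.seed_end})"
        )
    if "N" in seq:
        raise InputError("sRNA contains undetermined bases (N)")
    if config.max_bulges > 2:
        raise InputError("the scanner supports at most 2 bulges")
    T = len(transcript.sequence)
    if T == 0:
        return []
    cost = _cost_matrix(_encode(seq), _encode(transcript.sequence), config)
    candidates = (
        _shape_candidates_dfs(cost, L, config)
        if T <= SMALL_TARGET_LEN
        else _shape_candidates(cost, L, config)
    )

    best: dict[int, tuple[tuple, DuplexAlignment]] = {}
    for e0, shape in candidates:
        aln = build_alignment(seq, transcript, e0 + 1, shape, config)
        if aln is None:
            continue
        key = (aln.penalty, aln.n_bulges, aln.n_mismatches, aln.target_end,
               aln.bulges)
        prev = best.get(aln.target_start)
        if prev is None or key < prev[0]:
            best[aln.target_start] = (key, aln)
    out = [aln for _, aln in best.values()]
    out.sort(key=lambda a: (a.penalty, a.target_start))
    return out
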