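"""The two mining pipelines: forward (sRNA -> validated targets) and reverse
(cleavage site -> all co-regulating sRNAs), plus multi-tissue aggregation.

Forward mining screens a query sRNA against every transcript for accepted
duplexes, intersects each binding site with the *specific* degradome
cleavage sites falling in the middle of the site (the target base paired to
sRNA position 10, the canonical AGO slicer position), and then
cross-validates each surviving site in reverse: a 30-nt bait centred on the
cleavage position (15 nt upstream, 14 nt downstream) is used to pull every
qualifying sRNA out of the sRNA HTS dataset.  Candidates expressed below
1/10 of the best-expressed candidate are dropped; the pair is confirmed only
when the query itself survives that expression filter.  Co-regulators
without a known annotation receive stable novel ids (``sRNA_<tag>_<n>``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Optional

from .degradome import (
    DEFAULT_MIN_ABS_SIGNAL,
    DEFAULT_MIN_RATIO,
    CleavageSite,
    DegradomeIndex,
    call_sites,
)
from .duplex import DuplexAlignment, ScoringConfig, find_candidate_sites
from .errors import InputError
from .seqio import AbundantRead, KnownAnnotation, Transcript

log = logging.getLogger(__name__)

#: sRNA position whose paired target base marks the slicer cleavage product's
#: 5' end ("the middle of the binding site").
CLEAVAGE_SRNA_POSITION = 10
BAIT_UPSTREAM = 15
BAIT_DOWNSTREAM = 14
EXPRESSION_FRACTION = 0.1  # candidates below max/10 are dropped


class NovelNamer:
    """Assigns stable ``sRNA_<tag>_<n>`` ids to unannotated sRNA sequences.

    Ids are handed out on first sight, so within one run the numbering is
    fully determined by the order in which sequences are encountered (itself
    deterministic: candidates are processed in sorted output order).
    """

    def __init__(self, species_tag: str = "XX"):
        self.species_tag = species_tag
        self._ids: dict[str, str] = {}

    def name_for(self, sequence: str) -> str:
        if sequence not in self._ids:
            self._ids[sequence] = f"sRNA_{self.species_tag}_{len(self._ids) + 1}"
        return self._ids[sequence]


@dataclass
class CoRegulator:
    """An sRNA recovered by reverse mining at one bait."""

    srna: AbundantRead
    names: list[str]
    alignment: DuplexAlignment
    retained: bool
    is_query: bool = False
    novel_id: Optional[str] = None

    @property
    def display_name(self) -> str:
        return ";".join(self.names) if self.names else (self.novel_id or "novel")


@dataclass
class TargetPair:
    """A candidate sRNA-target interaction with its cleavage evidence."""

    query_srna: AbundantRead
    target_id: str
    alignment: DuplexAlignment
    site: CleavageSite
    co_regulators: list[CoRegulator]
    confirmed: bool
    source_label: str = ""
    rejection_reason: Optional[str] = None


@dataclass(frozen=True)
class Bait:
    """The up-to-30-nt candidate binding region around a cleavage site."""

    target_id: str
    center: int
    sequence: str
    window_start: int
    window_end: int


@dataclass
class AggregatedPair:
    """One sRNA-target interaction united across tissues/datasets."""

    query_sequence: str
    target_id: str
    target_start: int
    confirmed: bool
    evidence: dict[str, TargetPair] = field(default_factory=dict)


def expected_cleavage_window(
    alignment: DuplexAlignment, tolerance: int = 0
) -> set[int]:
    """Target positions where slicer cleavage is expected for this duplex.

    The centre is the target base paired with sRNA position 10; bulges are
    accounted for through the alignment's position map.  If position 10 is
    itself bulged the centre is extrapolated from the nearest paired
    position (pairing runs antiparallel, so the target coordinate decreases
    as the sRNA position increases).
    """
    if len(alignment.pair_states) < CLEAVAGE_SRNA_POSITION:
        raise InputError("alignment spans fewer than 10 sRNA positions")
    center = alignment.position_map[CLEAVAGE_SRNA_POSITION - 1]
    if center is None:
        for i in range(CLEAVAGE_SRNA_POSITION - 1, 0, -1):
            t = alignment.position_map[i - 1]
            if t is not None:
                center = t - (CLEAVAGE_SRNA_POSITION - i)
                break
        else:
            for i in range(CLEAVAGE_SRNA_POSITION + 1, len(alignment.position_map) + 1):
                t = alignment.position_map[i - 1]
                if t is not None:
                    center = t + (i - CLEAVAGE_SRNA_POSITION)
                    break
    if center is None:
        raise InputError("alignment has no paired positions")
    return {p for p in range(center - tolerance, center + tolerance + 1) if p >= 1}


def extract_bait(transcript: Transcript, position: int) -> Bait:
    """The candidate binding region: cleavage position +/- 15/14 nt, clipped."""
    if not (1 <= position <= len(transcript)):
        raise InputError(
            f"position {position} outside transcript {transcript.id} "
            f"(length {len(transcript)})"
        )
    start = max(1, position - BAIT_UPSTREAM)
    end = min(len(transcript), position + BAIT_DOWNSTREAM)
    return Bait(
        target_id=transcript.id,
        center=position,
        sequence=transcript.sequence[start - 1:end],
        window_start=start,
        window_end=end,
    )


def reverse_dig(
    bait: Bait,
    srna_reads: list[AbundantRead],
    known: Optional[KnownAnnotation] = None,
    config: ScoringConfig = ScoringConfig(),
    tolerance: int = 0,
    namer: Optional[NovelNamer] = None,
    expression_fraction: float = EXPRESSION_FRACTION,
) -> list[CoRegulator]:
    """All sRNAs qualifying to cleave at the bait centre, best-expressed first.

    A read qualifies when its duplex with the bait region passes the
    complementarity rules *and* its expected cleavage window covers the bait
    centre.  The retained flag implements the expression filter: retained
    iff RPM >= (highest candidate RPM) / 10.
    """
    if namer is None:
        namer = NovelNamer()
    pseudo = Transcript(id=f"{bait.target_id}|bait@{bait.center}", sequence=bait.sequence)
    offset = bait.window_start - 1
    candidates: list[tuple[AbundantRead, DuplexAlignment]] = []
    for read in srna_reads:
        if "N" in read.sequence or len(read.sequence) < config.seed_end:
            continue
        for aln in find_candidate_sites(read.sequence, pseudo, config):
            lifted = replace(aln, target_id=bait.target_id).shifted(offset)
            if bait.center in expected_cleavage_window(lifted, tolerance):
                candidates.append((read, lifted))
                break  # alignments come penalty-sorted; keep the best match
    if not candidates:
        return []
    candidates.sort(key=lambda c: (-c[0].rpm, c[0].sequence))
    max_rpm = candidates[0][0].rpm
    cutoff = max_rpm * expression_fraction
    out = []
    for read, aln in candidates:
        names = known.names_for(read.sequence) if known is not None else []
        out.append(
            CoRegulator(
                srna=read,
                names=names,
                alignment=aln,
                retained=read.rpm >= cutoff,
                novel_id=None if names else namer.name_for(read.sequence),
            )
        )
    return out


def forward_dig(
    query_srna: AbundantRead,
    transcripts: list[Transcript],
    degradome_index: DegradomeIndex,
    srna_reads: list[AbundantRead],
    known: Optional[KnownAnnotation] = None,
    config: ScoringConfig = ScoringConfig(),
    tolerance: int = 0,
    min_ratio: float = DEFAULT_MIN_RATIO,
    min_abs_signal: float = DEFAULT_MIN_ABS_SIGNAL,
    source_label: str = "",
    namer: Optional[NovelNamer] = None,
) -> list[TargetPair]:
    """Mine and cross-validate every target of one query sRNA.

    Returns every candidate pair whose binding site has a specific cleavage
    signal in its middle; ``confirmed`` is True only when the query was also
    recovered and retained by reverse mining at the site.  Unconfirmed pairs
    carry a ``rejection_reason`` so they can be audited rather than silently
    dropped.
    """
    if "N" in query_srna.sequence:
        raise InputError("query sRNA contains undetermined bases (N)")
    if namer is None:
        namer = NovelNamer()
    pairs: list[TargetPair] = []
    for tr in transcripts:
        alignments = find_candidate_sites(query_srna.sequence, tr, config)
        if not alignments:
            continue
        sites = [
            s for s in call_sites(degradome_index, tr.id, min_ratio, min_abs_signal)
            if s.specific
        ]
        if not sites:
            continue
        # one pair per cleavage site: alignments come penalty-sorted, so the
        # first alignment whose expected window covers a site is the best one
        windows = [(aln, expected_cleavage_window(aln, tolerance))
                   for aln in alignments]
        for site in sites:
            for aln, window in windows:
                if site.position not in window:
                    continue
                bait = extract_bait(tr, site.position)
                co_regs = reverse_dig(
                    bait, srna_reads, known, config, tolerance, namer
                )
                query_co = next(
                    (c for c in co_regs if c.srna.sequence == query_srna.sequence),
                    None,
                )
                if query_co is not None:
                    query_co.is_query = True
                if query_co is None:
                    confirmed, reason = False, "query_not_recovered_by_reverse_mining"
                elif not query_co.retained:
                    confirmed, reason = False, "query_below_expression_cutoff"
                else:
                    confirmed, reason = True, None
                pairs.append(
                    TargetPair(
                        query_srna=query_srna,
                        target_id=tr.id,
                        alignment=aln,
                        site=site,
                        co_regulators=co_regs,
                        confirmed=confirmed,
                        source_label=source_label,
                        rejection_reason=reason,
                    )
                )
                break  # this site is claimed by its best alignment
    log.info(
        "forward: query %s -> %d candidate pairs, %d confirmed [%s]",
        query_srna.sequence,
        len(pairs),
        sum(p.confirmed for p in pairs),
        source_label or "-",
    )
    return pairs


def aggregate_tissues(
    per_dataset_pairs: dict[str, list[TargetPair]]
) -> list[AggregatedPair]:
    """Union pairs across datasets; confirmed overall iff confirmed anywhere.

    Keyed by (query sequence, target id, binding-site start); per-dataset
    evidence is preserved.  A tissue-specific interaction therefore counts
    as true as soon as a single tissue confirms it.
    """
    merged: dict[tuple[str, str, int], AggregatedPair] = {}
    for label, pairs in per_dataset_pairs.items():
        for pair in pairs:
            key = (pair.query_srna.sequence, pair.target_id,
                   pair.alignment.target_start)
            agg = merged.get(key)
            if agg is None:
                agg = AggregatedPair(
                    query_sequence=key[0],
                    target_id=key[1],
                    target_start=key[2],
                    confirmed=False,
                )
                merged[key] = agg
            agg.evidence[label] = pair
            agg.confirmed = agg.confirmed or pair.confirmed
    out = list(merged.values())
    out.sort(key=lambda a: (a.target_id, a.target_start, a.query_sequence))
    return out
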