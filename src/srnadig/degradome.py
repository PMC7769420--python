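"""Degradome read mapping, cleavage-signal intensities and site calling.

Degradome (PARE) reads are the uncapped 5' ends of cleaved transcripts: each
read's 5' end marks a putative cleavage position.  Reads are mapped to
transcripts by exact, full-length substring matching through a hash table of
read sequences; every 5'-end position of every exact occurrence is recorded.

At a candidate position the two intensities are

* site intensity — mean normalized count (RPM) over the distinct read
  sequences whose 5' end lies exactly at the position;
* background intensity — mean RPM over the distinct read sequences mapped
  elsewhere on the same transcript (excluding the site's own sequences).

A position is called a *specific* cleavage site when site/background >= 5
(the default ratio threshold).  With an empty background the ratio is
undefined; the site is then called specific when its intensity reaches an
absolute floor (``min_abs_signal``), which prevents single-spurious-read
calls on sparsely covered transcripts.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

from .errors import UndefinedSiteError
from .seqio import AbundantRead, Transcript

DEFAULT_MIN_RATIO = 5.0
DEFAULT_MIN_ABS_SIGNAL = 1.0


@dataclass
class DegradomeIndex:
    """Exact 5'-anchored occurrences of degradome reads on transcripts.

    ``hits[target_id][position]`` lists the reads whose full sequence matches
    the transcript starting at that 1-based position.  One read may occur at
    several positions and on several transcripts; every occurrence is kept.
    """

    hits: dict[str, dict[int, list[AbundantRead]]] = field(default_factory=dict)
    transcript_ids: list[str] = field(default_factory=list)

    def positions(self, target_id: str) -> list[int]:
        return sorted(self.hits.get(target_id, ()))


@dataclass
class CleavageSite:
    target_id: str
    position: int
    site_intensity: float
    background_intensity: float
    ratio: float
    specific: bool


def build_index(
    reads: list[AbundantRead], transcripts: list[Transcript]
) -> DegradomeIndex:
    """Map every read to every exact occurrence in every transcript.

    Equivalent to a naive substring search; implemented by hashing read
    sequences and probing each transcript window of each read length.
    """
    by_seq: dict[str, AbundantRead] = {}
    for r in reads:
        by_seq[r.sequence] = r
    lengths = sorted({len(s) for s in by_seq})
    index = DegradomeIndex(transcript_ids=[t.id for t in transcripts])
    for tr in transcripts:
        seq = tr.sequence
        per_pos: dict[int, list[AbundantRead]] = {}
        for ln in lengths:
            for start in range(len(seq) - ln + 1):
                read = by_seq.get(seq[start:start + ln])
                if read is not None:
                    per_pos.setdefault(start + 1, []).append(read)
        if per_pos:
            index.hits[tr.id] = per_pos
    return index


def site_intensity(index: DegradomeIndex, target_id: str, position: int) -> float:
    """Mean RPM over the distinct read sequences with 5' end at *position*."""
    reads = index.hits.get(target_id, {}).get(position)
    if not reads:
        raise UndefinedSiteError(
            f"no degradome reads at {target_id}:{position}"
        )
    return sum(r.rpm for r in reads) / len(reads)


def background_intensity(
    index: DegradomeIndex,
    target_id: str,
    position: int,
    include_site_in_denominator: bool = False,
) -> float:
    """Mean RPM of the distinct reads mapped elsewhere on the transcript.

    Sequences occurring at *position* are excluded from the numerator; with
    ``include_site_in_denominator`` they still count in the denominator (an
    alternative reading of the background definition).  Returns 0.0 when no
    other reads map.
    """
    per_pos = index.hits.get(target_id, {})
    site_seqs = {r.sequence for r in per_pos.get(position, [])}
    others: dict[str, float] = {}
    for pos, reads in per_pos.items():
        if pos == position:
            continue
        for r in reads:
            if r.sequence not in site_seqs:
                others[r.sequence] = r.rpm
    denom = len(others) + (len(site_seqs) if include_site_in_denominator else 0)
    if denom == 0:
        return 0.0
    return sum(others.values()) / denom


def call_sites(
    index: DegradomeIndex,
    target_id: str,
    min_ratio: float = DEFAULT_MIN_RATIO,
    min_abs_signal: float = DEFAULT_MIN_ABS_SIGNAL,
    include_site_in_denominator: bool = False,
) -> list[CleavageSite]:
    """Evaluate every mapped position on a transcript, sorted by position.

    Specific iff site/background >= ``min_ratio``; with zero background the
    site is specific iff its intensity >= ``min_abs_signal``.
    """
    sites = []
    for pos in index.positions(target_id):
        si = site_intensity(index, target_id, pos)
        bg = background_intensity(
            index, target_id, pos,
            include_site_in_denominator=include_site_in_denominator,
        )
        if bg > 0:
            ratio = si / bg
            specific = ratio >= min_ratio
        else:
            ratio = float("inf")
            specific = si >= min_abs_signal
        sites.append(
            CleavageSite(
                target_id=target_id,
                position=pos,
                site_intensity=si,
                background_intensity=bg,
                ratio=ratio,
                specific=specific,
            )
        )
    return sites


def tplot_data(
    index: DegradomeIndex, target_id: str, include_zeros: bool = False,
    transcript_length: int | None = None,
) -> list[tuple[int, float]]:
    """Per-position degradation signal: summed RPM of reads starting there.

    The data behind a t-plot.  With ``include_zeros`` every transcript
    position appears (requires ``transcript_length``).
    """
    if target_id not in index.transcript_ids:
        raise KeyError(f"unknown transcript {target_id!r}")
    per_pos = index.hits.get(target_id, {})
    table = {pos: sum(r.rpm for r in reads) for pos, reads in per_pos.items()}
    if include_zeros:
        if transcript_length is None:
            raise ValueError("include_zeros requires transcript_length")
        return [(p, table.get(p, 0.0)) for p in range(1, transcript_length + 1)]
    return sorted(table.items())


def write_tplot_csv(
    index: DegradomeIndex, target_id: str, path: str | Path
) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["position", "signal"])
        for pos, signal in tplot_data(index, target_id):
            writer.writerow([pos, f"{signal:.4f}"])
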