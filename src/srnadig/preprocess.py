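"""Read filtering and reads-per-million (RPM) normalization.

sRNA libraries keep reads of 18–30 nt (the biologically active length range);
degradome libraries are not length-filtered by default.  Reads containing an
undetermined base (``N``) and reads with a raw count of zero are always
removed.  RPM is computed over the reads that survive filtering:

    rpm = raw_count / total_raw_count_of_dataset * 10^6
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import NormalizationError
from .seqio import AbundantRead

import logging

log = logging.getLogger(__name__)

SRNA_MIN_LEN = 18
SRNA_MAX_LEN = 30


@dataclass
class DatasetStats:
    total_raw_count: int
    n_sequences: int
    length_histogram: dict[int, int] = field(default_factory=dict)


def dataset_stats(reads: list[AbundantRead]) -> DatasetStats:
    hist: dict[int, int] = {}
    total = 0
    for r in reads:
        hist[len(r.sequence)] = hist.get(len(r.sequence), 0) + r.raw_count
        total += r.raw_count
    return DatasetStats(total_raw_count=total, n_sequences=len(reads), length_histogram=hist)


def filter_reads(
    reads: list[AbundantRead],
    min_len: int = SRNA_MIN_LEN,
    max_len: int = SRNA_MAX_LEN,
    length_filter: bool = True,
) -> list[AbundantRead]:
    """Drop N-containing, zero-count and (optionally) out-of-length reads.

    Order of the surviving reads is preserved.  The N rule applies to every
    read regardless of length.  Pass ``length_filter=False`` for degradome
    datasets, which have no length bounds.
    """
    if min_len > max_len:
        raise ValueError(f"min_len {min_len} > max_len {max_len}")
    out = []
    for r in reads:
        if "N" in r.sequence:
            continue
        if r.raw_count == 0:
            continue
        if length_filter and not (min_len <= len(r.sequence) <= max_len):
            continue
        out.append(r)
    if reads and not out:
        log.warning("all %d reads removed by filtering", len(reads))
    return out


def normalize_rpm(reads: list[AbundantRead]) -> list[AbundantRead]:
    """Set each read's RPM from the dataset total; returns new read objects.

    The total is the sum of raw counts over the reads given (i.e. those that
    survived filtering).  Idempotent: rpm is recomputed from raw counts.
    """
    total = sum(r.raw_count for r in reads)
    if total <= 0:
        raise NormalizationError("cannot normalize: dataset total raw count is 0")
    return [
        AbundantRead(
            sequence=r.sequence,
            raw_count=r.raw_count,
            rpm=r.raw_count / total * 1e6,
            source_label=r.source_label,
        )
        for r in reads
    ]


def preprocess_srna(reads: list[AbundantRead], min_len: int = SRNA_MIN_LEN,
                    max_len: int = SRNA_MAX_LEN) -> list[AbundantRead]:
    """Standard sRNA pipeline stage: filter with length bounds, then normalize."""
    return normalize_rpm(filter_reads(reads, min_len, max_len, length_filter=True))


def preprocess_degradome(reads: list[AbundantRead]) -> list[AbundantRead]:
    """Standard degradome pipeline stage: filter without length bounds, then normalize."""
    return normalize_rpm(filter_reads(reads, length_filter=False))
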