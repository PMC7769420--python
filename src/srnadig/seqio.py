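"""Readers and writers for all external formats.

All nucleotide sequences are normalised to the DNA alphabet at ingest: ``U``
becomes ``T`` and lower-case is upper-cased, so RNA-space inputs (mature
miRNA annotations, sRNA reads) can be compared directly against DNA-space
transcripts and degradome fragments.  Transcript coordinates are 1-based
inclusive throughout the package.

Collapsed sRNA/degradome FASTA files carry an abundance per unique sequence.
Three header dialects are supported (there is no single community standard):

``x_suffix``
    header ends in ``_xN`` or ``_N`` (e.g. ``>read1_x42``) — the default.
``space_count``
    header is ``id N`` with the count as the second whitespace token.
``plain``
    ordinary FASTA; counts arise by collapsing duplicate sequences.

Duplicate sequences within one file are merged by summing their counts in
every dialect, so a loaded dataset always holds unique sequences.
"""

from __future__ import annotations

import csv
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from Bio import SeqIO

from .errors import FormatError

log = logging.getLogger(__name__)

DIALECTS = ("x_suffix", "space_count", "plain")
_VALID_BASES = frozenset("ACGTN")
_X_SUFFIX_RE = re.compile(r"_x?(\d+)$")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def normalize_sequence(raw: str) -> str:
    """Upper-case and rewrite U->T; reject characters outside {A,C,G,T,N}."""
    seq = raw.upper().replace("U", "T")
    if not set(seq) <= _VALID_BASES:
        bad = sorted(set(seq) - _VALID_BASES)
        raise FormatError(f"sequence contains invalid characters {bad}")
    return seq


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Transcript:
    """A cDNA/transcript sequence; coordinates on it are 1-based inclusive."""

    id: str
    sequence: str

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class AbundantRead:
    """A collapsed sequencing read (sRNA or degradome fragment).

    ``rpm`` is 0.0 until :func:`srnadig.preprocess.normalize_rpm` has run.
    """

    sequence: str
    raw_count: int
    rpm: float = 0.0
    source_label: str = ""

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class KnownAnnotation:
    """Exact-sequence lookup from sRNA sequence to known mature sRNA names.

    An empty name list means "novel / unannotated".
    """

    species_prefix: str = ""
    by_sequence: dict[str, list[str]] = field(default_factory=dict)

    def names_for(self, sequence: str) -> list[str]:
        return list(self.by_sequence.get(sequence, ()))

    def __len__(self) -> int:
        return len(self.by_sequence)


# ---------------------------------------------------------------------------
# readers


def read_fasta(path: str | Path) -> list[Transcript]:
    """Read transcripts from FASTA, normalising sequences; ids must be unique."""
    transcripts: list[Transcript] = []
    seen: set[str] = set()
    for i, rec in enumerate(SeqIO.parse(str(path), "fasta"), start=1):
        if not rec.id:
            raise FormatError(f"{path}: record {i} has an empty header")
        if not str(rec.seq):
            raise FormatError(f"{path}: record '{rec.id}' has an empty sequence")
        try:
            seq = normalize_sequence(str(rec.seq))
        except FormatError as exc:
            raise FormatError(f"{path}: record '{rec.id}': {exc}") from exc
        if rec.id in seen:
            raise FormatError(f"{path}: duplicate record id '{rec.id}'")
        seen.add(rec.id)
        transcripts.append(Transcript(id=rec.id, sequence=seq))
    return transcripts


def read_collapsed_reads(
    path: str | Path,
    dialect: str = "x_suffix",
    source_label: str = "",
) -> list[AbundantRead]:
    """Read a collapsed sRNA/degradome FASTA into unique (sequence, count) reads."""
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")
    counts: dict[str, int] = {}
    order: list[str] = []
    for i, rec in enumerate(SeqIO.parse(str(path), "fasta"), start=1):
        if not str(rec.seq):
            raise FormatError(f"{path}: record {i} ('{rec.id}') has an empty sequence")
        try:
            seq = normalize_sequence(str(rec.seq))
        except FormatError as exc:
            raise FormatError(f"{path}: record {i} ('{rec.id}'): {exc}") from exc
        if dialect == "plain":
            count = 1
        elif dialect == "x_suffix":
            m = _X_SUFFIX_RE.search(rec.id)
            if m is None:
                raise FormatError(
                    f"{path}: record {i} ('{rec.id}'): header does not end in _xN or _N"
                )
            count = int(m.group(1))
        else:  # space_count
            tokens = rec.description.split()
            if len(tokens) < 2 or not tokens[1].isdigit():
                raise FormatError(
                    f"{path}: record {i} ('{rec.id}'): expected 'id N' header"
                )
            count = int(tokens[1])
        if seq not in counts:
            counts[seq] = 0
            order.append(seq)
        counts[seq] += count
    return [
        AbundantRead(sequence=s, raw_count=counts[s], source_label=source_label)
        for s in order
    ]


def read_known_annotations(path: str | Path, species_prefix: str) -> KnownAnnotation:
    """Load a mature-sRNA annotation FASTA, keeping only one species' entries.

    Headers are expected to start with names like ``ath-miR156a-5p``; only
    names starting with *species_prefix* are retained.  Several names may
    share one sequence (paralogous mature sRNAs).
    """
    by_seq: dict[str, list[str]] = {}
    n_total = 0
    for rec in SeqIO.parse(str(path), "fasta"):
        n_total += 1
        name = rec.id
        if not name.startswith(species_prefix):
            continue
        seq = normalize_sequence(str(rec.seq))
        by_seq.setdefault(seq, []).append(name)
    if n_total and not by_seq:
        log.warning(
            "no annotation records match species prefix %r in %s; "
            "running in novel-only mode",
            species_prefix,
            path,
        )
    return KnownAnnotation(species_prefix=species_prefix, by_sequence=by_seq)


# ---------------------------------------------------------------------------
# writers


def write_fasta(transcripts: Iterable[Transcript], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for t in transcripts:
            fh.write(f">{t.id}\n{t.sequence}\n")


def write_collapsed_reads(
    reads: Iterable[AbundantRead],
    path: str | Path,
    dialect: str = "x_suffix",
) -> None:
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")
    with open(path, "w", encoding="utf-8") as fh:
        for i, r in enumerate(reads, start=1):
            if dialect == "x_suffix":
                fh.write(f">r{i}_x{r.raw_count}\n{r.sequence}\n")
            elif dialect == "space_count":
                fh.write(f">r{i} {r.raw_count}\n{r.sequence}\n")
            else:  # plain: one record per raw read
                for j in range(r.raw_count):
                    fh.write(f">r{i}.{j + 1}\n{r.sequence}\n")


PAIR_TSV_COLUMNS = [
    "transcript_id",
    "site_position",
    "srna_name_or_novel_id",
    "srna_sequence",
    "raw_count",
    "rpm",
    "penalty_score",
    "alignment_string",
    "site_intensity",
    "background_intensity",
    "ratio",
    "retained_flag",
    "source_label",
]


def write_pairs_tsv(pairs, path: str | Path, include_reason: bool = False) -> None:
    """Write one TSV row per (sRNA-target pair, co-regulator).

    Rows are ordered by transcript id ascending, then sRNA RPM descending,
    ties broken by sRNA sequence; this is the result ordering contract of the
    whole tool, so downstream consumers can rely on it.
    """
    columns = PAIR_TSV_COLUMNS + (["rejection_reason"] if include_reason else [])
    rows = []
    for pair in pairs:
        for co in pair.co_regulators:
            row = {
                "transcript_id": pair.target_id,
                "site_position": pair.site.position,
                "srna_name_or_novel_id": co.display_name,
                "srna_sequence": co.srna.sequence,
                "raw_count": co.srna.raw_count,
                "rpm": f"{co.srna.rpm:.4f}",
                "penalty_score": f"{co.alignment.penalty:g}",
                "alignment_string": co.alignment.render(),
                "site_intensity": f"{pair.site.site_intensity:.4f}",
                "background_intensity": f"{pair.site.background_intensity:.4f}",
                "ratio": "inf" if pair.site.ratio == float("inf") else f"{pair.site.ratio:.4f}",
                "retained_flag": int(co.retained),
                "source_label": pair.source_label,
            }
            if include_reason:
                row["rejection_reason"] = pair.rejection_reason or ""
            rows.append((pair.target_id, -co.srna.rpm, co.srna.sequence, row))
    rows.sort(key=lambda r: (r[0], r[1], r[2]))
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=columns, delimiter="\t")
        writer.writeheader()
        for _, _, _, row in rows:
            writer.writerow(row)
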