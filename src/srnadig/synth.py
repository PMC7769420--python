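"""Deterministic synthetic fixtures: transcripts with planted sRNA binding
sites, abundance-weighted sRNA datasets, and degradome datasets with a
dominant cleavage peak over a uniform low background — plus a truth table
stating, for every planted interaction, whether the full pipeline should
confirm it.

Every planted interaction consists of

* a transcript carrying the binding site,
* a query sRNA engineered to a chosen duplex penalty (deviations are placed
  at non-seed positions first, then as seed mismatches, never at the
  forbidden slicer positions 10/11),
* optionally one better/equally-expressed co-regulator sRNA (one G:U or
  seed deviation, penalty 0.5–1.0) binding the same site,
* a degradome peak read whose 5' end sits at the expected cleavage position
  (the target base paired to sRNA position 10), optionally displaced, with a
  configurable peak-to-background count ratio, and
* uniform background degradome reads on every transcript.

Expected confirmation is computed analytically from the planted parameters
and the pipeline thresholds alone, so end-to-end tests can assert exact
agreement.  All randomness flows from a single seed through per-dataset
child generators, so regenerating any dataset is stable; colliding draws
(duplicate sequences or positions) are re-drawn deterministically from the
same generator stream.
"""

from __future__ import annotations

import csv
import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np

from .duplex import ScoringConfig
from .seqio import (
    AbundantRead,
    Transcript,
    reverse_complement,
    write_collapsed_reads,
    write_fasta,
)

_BASES = "ACGT"
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


@dataclass(frozen=True)
class SynthConfig:
    """Study conditions of the simulated experiment (defaults are the ones
    every test and the acceptance run use unless a threshold is being probed)."""

    seed: int = 0
    n_transcripts: int = 12
    transcript_len: int = 300
    n_planted: int = 10
    n_decoy_srnas: int = 50
    srna_length: int = 21
    fragment_length: int = 20  # degradome read length (typical PARE signature)
    n_background_per_transcript: int = 6
    background_count: int = 10
    peak_to_background: float = 20.0
    peak_displacement: int = 0
    planted_penalty: float = 0.0
    plant_coregulator: bool = True
    base_query_count: int = 500
    query_expression_fraction: float | dict[str, float] = 1.0
    tissues: tuple[str, ...] = ("tissue1",)
    min_ratio: float = 5.0
    expression_fraction_cutoff: float = 0.1

    def fraction_for(self, tissue: str) -> float:
        if isinstance(self.query_expression_fraction, dict):
            return self.query_expression_fraction.get(tissue, 1.0)
        return self.query_expression_fraction


@dataclass
class PlantedInteraction:
    """Ground truth for one planted sRNA-target pair."""

    srna_sequence: str
    coreg_sequence: str | None
    target_id: str
    target_start: int
    penalty: float
    expected_cleavage_position: int
    peak_position: int
    peak_count: int
    background_count: int
    query_raw_count_by_tissue: dict[str, int]
    coreg_raw_count: int
    expected_confirmed_by_tissue: dict[str, bool]

    @property
    def expected_confirmed(self) -> bool:
        return any(self.expected_confirmed_by_tissue.values())


@dataclass
class SynthResult:
    config: SynthConfig
    transcripts: list[Transcript]
    srna_datasets: dict[str, list[AbundantRead]]
    degradome_datasets: dict[str, list[AbundantRead]]
    truth: list[PlantedInteraction]


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASES[i] for i in rng.integers(0, 4, size=length))


def _mismatch_base(target_base: str) -> str:
    """First base (alphabetically) that makes a true mismatch (not WC, not G:U)
    with *target_base*."""
    for b in _BASES:
        if _COMPLEMENT[b] == target_base:
            continue
        if (b == "G" and target_base == "T") or (b == "T" and target_base == "G"):
            continue
        return b
    raise AssertionError("unreachable")


# deviation sites used by the penalty builder; chosen so query and
# co-regulator never deviate at the same position
_QUERY_SEED_MM_POSITIONS = (5, 6)
_COREG_GU_POSITIONS = (3, 7, 8, 9, 12, 13, 2)
_COREG_FALLBACK_MM_POSITION = 3


def engineer_query(site_sequence: str, penalty: float,
                   config: ScoringConfig = ScoringConfig()) -> str:
    """Build a query sRNA with an exactly known duplex penalty vs *site_sequence*.

    The perfect query is the reverse complement of the binding site; the
    requested penalty (a multiple of 0.5) is reached with non-seed
    mismatches (0.5 each; positions L..14 then 1) and, beyond what those can
    carry, seed mismatches (1.0 each, at positions 5 then 6).  Values above
    ``max_score`` are allowed — they produce sRNAs the scanner must reject.
    """
    L = len(site_sequence)
    srna = list(reverse_complement(site_sequence))
    n_half = round(penalty / 0.5)
    if n_half * 0.5 != penalty or penalty < 0:
        raise ValueError(f"penalty must be a non-negative multiple of 0.5: {penalty}")
    nonseed = [p for p in range(L, config.seed_end, -1)] + [1]
    n_seed_mm = 0
    while n_half > len(nonseed):
        n_seed_mm += 1
        n_half -= 2
    if n_seed_mm > config.max_seed_mismatches:
        raise ValueError(f"penalty {penalty} not representable under the seed cap")
    positions = list(_QUERY_SEED_MM_POSITIONS[:n_seed_mm]) + nonseed[:n_half]
    for pos in positions:
        # sRNA position pos pairs the target base at site index L - pos
        target_base = site_sequence[L - pos]
        srna[pos - 1] = _mismatch_base(target_base)
    return "".join(srna)


def engineer_coregulator(site_sequence: str) -> str:
    """A co-regulator for the same site: one seed G:U (penalty 0.5) where the
    target offers a T or G, else one seed mismatch (penalty 1.0)."""
    L = len(site_sequence)
    srna = list(reverse_complement(site_sequence))
    for pos in _COREG_GU_POSITIONS:
        tb = site_sequence[L - pos]
        if tb == "T":
            srna[pos - 1] = "G"
            return "".join(srna)
        if tb == "G":
            srna[pos - 1] = "T"
            return "".join(srna)
    pos = _COREG_FALLBACK_MM_POSITION
    srna[pos - 1] = _mismatch_base(site_sequence[L - pos])
    return "".join(srna)


def _peak_window_clear(query: str, transcript: Transcript, peak_position: int,
                       config: ScoringConfig) -> bool:
    """True when no accepted alignment of *query* on *transcript* expects
    cleavage at *peak_position*.

    Needed because an sRNA engineered to fail (penalty above the cap, or a
    displaced peak) can occasionally be "rescued": a bulged variant
    alignment may score within the cap and still cover the peak.  Such
    plants would make the analytic truth table wrong, so they are re-drawn.
    """
    from .digger import expected_cleavage_window
    from .duplex import find_candidate_sites

    return all(
        peak_position not in expected_cleavage_window(a)
        for a in find_candidate_sites(query, transcript, config)
    )


def generate(config: SynthConfig) -> SynthResult:
    """Generate transcripts, sRNA and degradome datasets, and the truth table."""
    if config.n_planted > config.n_transcripts:
        raise ValueError("need at least one transcript per planted interaction")
    scoring = ScoringConfig()
    ss = np.random.SeedSequence(config.seed)
    child = ss.spawn(3 + 2 * len(config.tissues))
    rng_tx = np.random.default_rng(child[0])
    rng_plant = np.random.default_rng(child[1])
    rng_decoy = np.random.default_rng(child[2])

    L = config.srna_length
    T = config.transcript_len
    margin = 40  # room for the bait window and degradome fragments
    if T < 2 * margin + L:
        raise ValueError("transcript_len too small for planted sites")

    transcripts = [
        Transcript(id=f"SYNT{i + 1:04d}", sequence=_random_seq(rng_tx, T))
        for i in range(config.n_transcripts)
    ]

    # --- plant interactions -------------------------------------------------
    truth: list[PlantedInteraction] = []
    srna_sequences: set[str] = set()
    peak_count = round(config.background_count * config.peak_to_background)
    realized_ratio = peak_count / config.background_count
    penalty_accepted = (
        config.planted_penalty <= scoring.max_score
    )
    for k in range(config.n_planted):
        tr = transcripts[k]
        # deterministic re-draw rule: keep sampling start positions from the
        # planting stream until the plant is collision-free and (for plants
        # expected to fail) provably un-rescuable
        for _ in range(64):
            start = int(rng_plant.integers(margin, T - margin - L + 1))
            site = tr.sequence[start - 1:start - 1 + L]
            query = engineer_query(site, config.planted_penalty, scoring)
            coreg = engineer_coregulator(site) if config.plant_coregulator else None
            if query in srna_sequences or (
                coreg is not None and coreg in srna_sequences
            ):
                continue
            cleavage = start + L - CLEAVAGE_POSITION
            peak_position = cleavage + config.peak_displacement
            if (not penalty_accepted or config.peak_displacement != 0) and (
                not _peak_window_clear(query, tr, peak_position, scoring)
            ):
                continue
            break
        else:
            raise RuntimeError(
                f"could not place interaction {k}; change the seed"
            )
        srna_sequences.add(query)
        if coreg is not None:
            srna_sequences.add(coreg)
        query_counts = {
            t: round(config.base_query_count * config.fraction_for(t))
            for t in config.tissues
        }
        coreg_count = config.base_query_count if coreg is not None else 0
        expected = {}
        for t in config.tissues:
            max_count = max(query_counts[t], coreg_count)
            expression_ok = (
                query_counts[t] >= max_count * config.expression_fraction_cutoff
            )
            expected[t] = bool(
                penalty_accepted
                and realized_ratio >= config.min_ratio
                and config.peak_displacement == 0
                and query_counts[t] > 0
                and expression_ok
            )
        truth.append(
            PlantedInteraction(
                srna_sequence=query,
                coreg_sequence=coreg,
                target_id=tr.id,
                target_start=start,
                penalty=config.planted_penalty,
                expected_cleavage_position=cleavage,
                peak_position=cleavage + config.peak_displacement,
                peak_count=peak_count,
                background_count=config.background_count,
                query_raw_count_by_tissue=query_counts,
                coreg_raw_count=coreg_count,
                expected_confirmed_by_tissue=expected,
            )
        )

    # --- decoy sRNAs (shared across tissues) --------------------------------
    decoys: list[tuple[str, int]] = []
    while len(decoys) < config.n_decoy_srnas:
        seq = _random_seq(rng_decoy, L)
        if seq in srna_sequences:
            continue  # deterministic redraw from the same stream
        srna_sequences.add(seq)
        decoys.append((seq, int(rng_decoy.integers(1, 21))))

    # --- per-tissue datasets ------------------------------------------------
    srna_datasets: dict[str, list[AbundantRead]] = {}
    degradome_datasets: dict[str, list[AbundantRead]] = {}
    for ti, tissue in enumerate(config.tissues):
        rng_s = np.random.default_rng(child[3 + 2 * ti])
        rng_d = np.random.default_rng(child[4 + 2 * ti])
        reads: list[AbundantRead] = []
        for p in truth:
            count = p.query_raw_count_by_tissue[tissue]
            if count > 0:
                reads.append(AbundantRead(p.srna_sequence, count, source_label=tissue))
            if p.coreg_sequence is not None:
                reads.append(
                    AbundantRead(p.coreg_sequence, p.coreg_raw_count,
                                 source_label=tissue)
                )
        for seq, count in decoys:
            reads.append(AbundantRead(seq, count, source_label=tissue))
        srna_datasets[tissue] = reads

        frags: list[AbundantRead] = []
        frag_seqs: set[str] = set()
        peak_positions = {p.target_id: p.peak_position for p in truth}
        for p in truth:
            tr = transcripts[[t.id for t in transcripts].index(p.target_id)]
            seq = tr.sequence[p.peak_position - 1:
                              p.peak_position - 1 + config.fragment_length]
            frag_seqs.add(seq)
            frags.append(AbundantRead(seq, p.peak_count, source_label=tissue))
        for tr in transcripts:
            chosen: set[int] = set()
            taboo = {peak_positions.get(tr.id)}
            while len(chosen) < config.n_background_per_transcript:
                pos = int(rng_d.integers(1, T - config.fragment_length + 2))
                if pos in taboo or pos in chosen:
                    continue
                seq = tr.sequence[pos - 1:pos - 1 + config.fragment_length]
                if seq in frag_seqs:
                    continue  # keep sequences unique so counts stay analytic
                chosen.add(pos)
                frag_seqs.add(seq)
                frags.append(
                    AbundantRead(seq, config.background_count, source_label=tissue)
                )
        degradome_datasets[tissue] = frags

    return SynthResult(
        config=config,
        transcripts=transcripts,
        srna_datasets=srna_datasets,
        degradome_datasets=degradome_datasets,
        truth=truth,
    )


#: sRNA position whose paired base is the expected cleavage position;
#: gap-free planted sites put it at target_start + L - 10.
CLEAVAGE_POSITION = 10


def write_truth_table(truth: list[PlantedInteraction], path: str | Path) -> None:
    cols = [
        "srna_sequence", "coreg_sequence", "target_id", "target_start",
        "penalty", "expected_cleavage_position", "peak_position",
        "peak_count", "background_count", "query_raw_count_by_tissue",
        "coreg_raw_count", "expected_confirmed_by_tissue", "expected_confirmed",
    ]
    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(cols)
        for p in truth:
            w.writerow([
                p.srna_sequence, p.coreg_sequence or "", p.target_id,
                p.target_start, f"{p.penalty:g}", p.expected_cleavage_position,
                p.peak_position, p.peak_count, p.background_count,
                json.dumps(p.query_raw_count_by_tissue),
                p.coreg_raw_count,
                json.dumps(p.expected_confirmed_by_tissue),
                int(p.expected_confirmed),
            ])


def write_dataset_dir(result: SynthResult, out_dir: str | Path,
                      dialect: str = "x_suffix") -> None:
    """Write the whole fixture as FASTA files plus the truth table."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_fasta(result.transcripts, out / "transcripts.fasta")
    for tissue, reads in result.srna_datasets.items():
        write_collapsed_reads(reads, out / f"srna_{tissue}.fasta", dialect)
    for tissue, reads in result.degradome_datasets.items():
        write_collapsed_reads(reads, out / f"degradome_{tissue}.fasta", dialect)
    write_truth_table(result.truth, out / "truth_table.tsv")
    cfg = asdict(result.config)
    cfg["tissues"] = list(result.config.tissues)
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(cfg, fh, indent=2, sort_keys=True)
        fh.write("\n")
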