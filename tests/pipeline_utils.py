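"""Shared helpers: run the full forward pipeline on a synthetic fixture and
build random scanner test instances."""

import numpy as np

from srnadig.degradome import build_index
from srnadig.digger import forward_dig
from srnadig.duplex import ScoringConfig
from srnadig.preprocess import preprocess_degradome, preprocess_srna
from srnadig.seqio import AbundantRead, reverse_complement
from srnadig.synth import SynthResult

BASES = "ACGT"


def run_forward_pipeline(result: SynthResult, tissue: str = "tissue1",
                         tolerance: int = 0, min_ratio: float = 5.0,
                         config: ScoringConfig = ScoringConfig()):
    """Preprocess one tissue's datasets and forward-mine every planted query."""
    srna = preprocess_srna(result.srna_datasets[tissue])
    deg = preprocess_degradome(result.degradome_datasets[tissue])
    index = build_index(deg, result.transcripts)
    by_seq = {r.sequence: r for r in srna}
    pairs = []
    for planted in result.truth:
        query = by_seq.get(
            planted.srna_sequence,
            AbundantRead(planted.srna_sequence, 0, source_label=tissue),
        )
        pairs.extend(
            forward_dig(query, result.transcripts, index, srna,
                        config=config, tolerance=tolerance,
                        min_ratio=min_ratio, source_label=tissue)
        )
    return pairs


def confirmed_keys(pairs):
    return {(p.query_srna.sequence, p.target_id) for p in pairs if p.confirmed}


def expected_keys(result: SynthResult, tissue: str = "tissue1"):
    return {
        (p.srna_sequence, p.target_id)
        for p in result.truth
        if p.expected_confirmed_by_tissue[tissue]
    }


def random_scan_instance(rng: np.random.Generator, transcript_len: int = 300):
    """A random (sRNA, transcript) pair; half the draws plant a degenerate
    binding site (mutations and/or a small indel) so accepted alignments of
    every shape class actually occur."""
    tseq = "".join(BASES[i] for i in rng.integers(0, 4, size=transcript_len))
    L = int(rng.integers(20, 25))
    if rng.random() < 0.5:
        srna = "".join(BASES[i] for i in rng.integers(0, 4, size=L))
        return srna, tseq
    start = int(rng.integers(0, transcript_len - L))
    srna = list(reverse_complement(tseq[start:start + L]))
    for _ in range(int(rng.integers(0, 5))):  # substitutions
        pos = int(rng.integers(0, L))
        srna[pos] = BASES[int(rng.integers(0, 4))]
    if rng.random() < 0.5:  # small indel to exercise bulged alignments
        pos = int(rng.integers(1, L - 2))
        if rng.random() < 0.5:
            del srna[pos]
        else:
            srna.insert(pos, BASES[int(rng.integers(0, 4))])
    return "".join(srna), tseq
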