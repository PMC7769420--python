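# srnadig

Bidirectional mining of plant sRNA–target regulatory pairs from small-RNA
high-throughput sequencing (HTS) data, transcript (cDNA) sequences and
degradome/PARE data.

## The problem

Plant small RNAs (miRNAs, ta-siRNAs, siRNAs; 18–30 nt) guide
Argonaute-mediated cleavage of transcripts they pair with almost perfectly.
Degradome sequencing captures the uncapped 5′ ends of the cleavage products,
so a sharp degradome peak opposite sRNA position 10 — the slicer site in the
middle of the binding site — is direct physical evidence of regulation.
Conventional degradome pipelines only mine in one direction (known sRNA →
targets) and therefore cannot tell whether the cleavage attributed to a
known sRNA is actually driven by other, unannotated sRNAs binding the same
site. `srnadig` mines in both directions:

* **forward**: query sRNA → candidate binding sites → specific cleavage
  sites → validated targets;
* **reverse**: cleavage site → a 30-nt bait around it → *every* sRNA in the
  HTS data expressed highly enough to co-regulate the site.

A pair is **confirmed** only when the forward evidence survives the reverse
check: the query must itself be recovered at its own cleavage site and be
expressed at ≥ 1/10 of the best-expressed co-regulator. All co-regulating
sRNAs (annotated or novel) are reported with each confirmed pair.

## The scoring and calling rules

Duplex complementarity is scored with a position-dependent penalty
(`ScoringConfig` defaults):

| rule | penalty |
|---|---|
| G:U wobble | 0.5 each |
| mismatch in the seed (sRNA positions 2–13) | 1.0 each, at most 2 (G:U excluded from the cap) |
| mismatch outside the seed | 0.5 each |
| bulge (either strand) | 2.0 + 0.5 per extra nucleotide, at most 2 bulges |
| mismatch at positions 10/11 | forbidden |
| total | ≤ 5.0 |

Degradome reads are mapped to transcripts by exact 5′-anchored matching.
At a candidate position the **site intensity** is the mean RPM over the
distinct read species starting there, the **background intensity** is the
mean RPM over the distinct species mapped elsewhere on the same transcript,
and positions with site/background ≥ 5 are *specific* cleavage sites.
RPM = raw count / dataset total × 10⁶, computed after removing N-containing
and zero-count reads (and, for sRNA libraries, reads outside 18–30 nt).

## Worked example

Simulate a small experiment with three planted interactions, then mine one
of the planted queries:

```bash
srnadig simulate --out fixture --seed 11 --n-planted 3 --n-transcripts 4 --n-decoys 20
printf '>query1\nAGGTTCTGTTTATGTCCGCGG\n' > query.fa
srnadig forward --query query.fa --cdna fixture/transcripts.fasta \
    --srna-hts fixture/srna_tissue1.fasta \
    --degradome fixture/degradome_tissue1.fasta \
    --labels flower --species AT --out run
```

The log reports one confirmed pair, and `run/confirmed_pairs.tsv` contains
(abridged):

```
transcript_id  site_position  srna_name_or_novel_id  srna_sequence          rpm          penalty_score  alignment_string       site_intensity  background_intensity  ratio    retained_flag
SYNT0001       180            sRNA_AT_1              AGGTTCTGTTTATGTCCGCGG  154655.1191  0              |||||||||||||||||||||  238095.2381     11904.7619            20.0000  1
SYNT0001       180            sRNA_AT_2              AGGTTCTGTTTGTGTCCGCGG  154655.1191  0.5            |||||||||||o|||||||||  238095.2381     11904.7619            20.0000  1
```

Reading the first row: the query (here unannotated, so it gets the stable
novel id `sRNA_AT_1`) binds SYNT0001 with a perfect duplex (penalty 0), the
degradome shows a cleavage signal of 238095 RPM at position 180 — the base
opposite sRNA position 10 — over a background of 11905 RPM (ratio 20, well
above the 5× threshold), and the query passes the expression filter
(`retained_flag 1`). The second row is a co-regulator found by reverse
mining: a second sRNA, one G:U wobble away (penalty 0.5, `o` in the
alignment string), equally expressed at the same site. `run/tplots/` holds
the per-transcript t-plot data (position vs summed degradome RPM); the row
`180,238095.2381` is the cleavage peak.

`srnadig reverse` starts from the transcripts instead and reports every
qualifying sRNA at every specific cleavage site.

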