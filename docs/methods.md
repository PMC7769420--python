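# Methods

## Model and procedure

`srnadig` treats plant sRNA-guided cleavage as the conjunction of three
observable conditions and confirms a pair only when all three hold:

1. **Complementarity.** The sRNA pairs the transcript antiparallel: sRNA
   position *i* (1-based from the 5′ end) pairs the target base at
   `target_end − i + 1` in a gap-free duplex. Deviations are penalised
   (G:U 0.5; seed mismatch 1.0, seed = positions 2–13, at most two, G:U not
   counted; non-seed mismatch 0.5; bulge 2.0 + 0.5 per extra nucleotide, at
   most two bulges; mismatches at positions 10/11 forbidden; total ≤ 5.0).
   All weights and caps live in `ScoringConfig`; the default values are the
   package's operating point and every threshold is exposed on the CLI.
2. **Cleavage evidence.** Degradome reads are exact-matched to transcripts;
   each 5′ end marks a putative cleavage position. A position is a
   *specific* site when site intensity / background intensity ≥ 5, where
   site intensity is the mean RPM over the distinct read species starting
   at the position and background intensity is the mean RPM over the
   distinct species mapped elsewhere on the same transcript. The site must
   fall in the *middle of the binding site*: the target base paired to sRNA
   position 10, the canonical slicer position (configurable ± tolerance,
   default 0).
3. **Reverse recovery.** A 30-nt bait (15 nt upstream, 14 nt downstream of
   the cleavage position, clipped at transcript ends) is used to recover
   every sRNA in the HTS dataset whose duplex with the bait is accepted and
   whose own expected cleavage position is the bait centre. Candidates are
   ranked by expression; those below 1/10 of the highest-expressed
   candidate are dropped. The pair is confirmed only if the query survives
   this filter; all surviving candidates are reported as co-regulators,
   novel ones under stable `sRNA_<tag>_<n>` ids assigned in output order.

Across datasets (tissues), pairs are united by (query sequence, target,
binding-site start) and an interaction counts as true as soon as one
dataset confirms it, reflecting tissue-specific expression.

## Interpretation choices

Several rules admit more than one reading; the package fixes them as
follows, with the alternative reachable where noted:

* *Mismatch weights*: mismatches outside the seed cost 0.5 versus 1.0
  inside, i.e. the non-seed discount reading. Both weights are independent
  `ScoringConfig` fields, so a doubled-seed variant is a configuration, not
  a code change.
* *Penalty span*: the penalty is computed over the sRNA's full length
  (18–30 nt), not a fixed 19-nt window; truncating would silently ignore 3′
  pairing.
* *Background denominator*: the distinct species at the candidate site are
  excluded from both numerator and denominator, so both formulas are means
  over well-defined disjoint sets. `include_site_in_denominator=True`
  selects the alternative (site species counted in the denominator only).
* *Zero background*: the 5× ratio is undefined when nothing else maps to
  the transcript; such sites are specific only above an absolute floor
  (`min_abs_signal`, default 1 RPM), preventing single-spurious-read calls.
* *Counts in the formulas* are RPM-normalized, computed over the reads that
  survive filtering; both intensities share the denominator, so the ratio
  is invariant to it.
* *Filtering*: reads containing N and reads with zero count are always
  removed; the 18–30 nt window applies to sRNA libraries only (degradome
  fragment lengths are a property of the protocol, not of the sRNA).
* *One pair per site*: when several accepted alignments of one query expect
  cleavage at the same position, the site is claimed by the best one
  (lowest penalty); distinct binding sites of the same query on one
  transcript remain independent pairs.
* *Expression filter scope*: the 1/10 cutoff is computed over the
  candidates of one bait within one dataset, because regulatory status is a
  per-tissue statement.
* Pairs that fail only the reverse check are written to a separate rejected
  report with the reason, rather than silently dropped, for auditability.

## The site scanner and its verification

The scanner must be *exhaustive*: every alignment of the query against
every transcript window with up to two bulges and penalty within the cap.
Alignments are organised by shape — gapless, one bulge, two bulges, with
the bulge side/position/length as parameters; anchoring the alignment at
its target end makes each shape a set of diagonal segments at fixed
offsets, so per-offset diagonal prefix-sum arrays score a whole shape
family for every anchor at once (cells outside the transcript or containing
N carry a large exact sentinel cost). A penalty-only prefilter keeps
survivors, which are rebuilt position by position and re-scored by the
scalar rule implementation — the single place the full rule set (seed cap,
forbidden positions, window N check) is enforced. For targets ≤ 64 nt
(e.g. 30-nt baits) the same shape space is searched by a pruned
depth-first recursion instead, because numpy call overhead dominates at
that size. Both paths are tested against an independently written
brute-force enumerator (and that enumerator against a flat, prune-free
shape scorer on tiny instances); equality is exact on accepted starts,
penalties, bulge and mismatch counts.

Ties at one start are resolved by penalty, then fewer bulges, fewer
mismatches, then smallest target end; results are penalty-sorted. All
penalties are multiples of 0.5, so float comparisons are exact.

## Synthetic data: what it emulates, and what it does not

The generator (`srnadig.synth`) produces the three data classes the
pipeline consumes, with planted ground truth:

* random uniform-composition transcripts (default 12 × 300 nt) — sized so a
  full study (10 planted interactions, 5 seeds, a 9-point threshold grid)
  runs in minutes on one core while every code path is exercised;
* per planted interaction: a 21-nt query engineered to an exact duplex
  penalty (deviations at non-seed positions first, then seed mismatches at
  positions 5/6, never at 10/11), a co-regulator one seed G:U (or, if the
  site offers no T/G there, one seed mismatch) away, with disjoint
  deviation positions so the two sequences always differ;
* degradome datasets: one 20-nt peak fragment per interaction whose 5′ end
  sits at the expected cleavage position (optionally displaced), with raw
  count = background count × peak:background ratio, plus six uniform
  background fragments of count 10 per transcript at unique positions with
  unique sequences — so the realized site/background ratio equals the
  configured ratio exactly and every expected outcome is computable from
  the planted parameters alone;
* sRNA datasets: queries at 500 raw counts (scaled by a per-tissue
  expression fraction), co-regulators at 500, plus 50 random decoy 21-mers.

All randomness flows from one seed through per-dataset child generators;
colliding draws (duplicate sequences, repeated positions) are re-drawn
deterministically from the same stream. One subtlety: an sRNA planted to
*fail* (penalty above the cap, or a displaced peak) can occasionally be
rescued by a bulged variant alignment that scores within the cap and still
covers the peak; the generator detects this with the scanner and re-draws
the site, so the analytic truth table is guaranteed, not probabilistic.

What the fixtures do **not** emulate: realistic base composition and
repeats, isoforms, expression gradients, sequencing error, partial adapter
remnants, or genuinely diffuse degradome background. Passing tests
therefore demonstrate that the algorithms implement their definitions
exactly and that the decision thresholds separate planted positives from
negatives; they say nothing about biological precision/recall on real
libraries, which depends on dataset quality and annotation completeness.

## Numerical and degenerate-input choices

* Sequences are normalised U→T and upper-cased at ingest; characters
  outside {A,C,G,T,N} are format errors naming the record.
* The scanner rejects queries containing N or shorter than the seed end.
* Transcripts with no mapped degradome reads yield no sites (not an
  error); an empty dataset after filtering is a warning, not an error;
  normalization of an empty/zero-count dataset is an error.
* If sRNA position 10 is itself bulged, the expected cleavage position is
  extrapolated from the nearest paired position.
* Duplicate sequences within one collapsed-read file are merged by summing
  counts in every header dialect.

## Known limitations

* At most two bulges per duplex (matching the rule set); the scanner
  refuses larger `max_bulges`.
* Degradome matching is exact only — no mismatched or partial mapping, and
  transcriptome-space only (no genome mapping or splice awareness).
* No degradome site categories (0–4 abundance classes) or p-values;
  specificity is the ratio threshold alone.
* The strand-symmetry of scanning holds exactly for Watson–Crick-only
  duplexes; G:U wobbles are not preserved under reverse-complementing both
  sequences (G:U maps to C:A), so no general mirror identity exists.
* Reverse mining requires candidates to expect cleavage exactly at the bait
  centre (± tolerance); sRNAs binding elsewhere within the 30-nt bait are
  deliberately not counted as co-regulators of that site.
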