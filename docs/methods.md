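# Methods

## The chromosome-quotient model

For a candidate reference sequence *S*, the chromosome quotient is
CQ(*S*) = F(*S*)/M(*S*), the ratio of female to male read alignments
under a zero-mismatch, full-read-length criterion. Under an XY/XX system
the per-individual copy numbers (male autosome 2 / X 1 / Y 1; female
autosome 2 / X 2 / Y 0) give expected CQs of 1 for autosomal, 2 for
X-linked and 0 for Y-unique sequence. The model assumes male and female
read pools sample the genome uniformly and independently; deviations in
total depth are absorbed by dividing all raw CQs by the median raw CQ of
fragments known to be autosomal, which pins the autosomal median at
exactly 1. The ratio is undefined when M = 0; such fragments are
reported with an empty CQ and labelled unclassifiable rather than mapped
to infinity, since an infinite placeholder would poison medians and the
male-count gate excludes these fragments anyway.

Classification uses three thresholds, all configurable:

| parameter | default | meaning |
|---|---|---|
| `cq_max` | 0.3 | normalized CQ must be strictly below this; equivalent at factor 1 to M > (10/3)·F |
| `male_min` | 30 | strictly more male alignments than this, else *unclassifiable* |
| `female_max` | 30 | strictly fewer female alignments than this, else *not_Y* (filters repeats with surplus Y copies) |

The count comparisons are strict (`> 30`, `< 30`), taken literally from
the method's description. This makes a fragment with exactly 29 or 30
male alignments unclassifiable even at CQ 0 — a deliberate edge the gate
parameter can relax.

## Fragmentation

Softmasked references are split at **every** lowercase (repeat) or N/n
base; fragments are maximal uppercase-ACGT runs with 0-based half-open
coordinates, and runs under `min_length` (default 250 bp) are discarded
because short fragments attract too few reads for a stable ratio. The
strictest splitting rule — an isolated masked base splits — was chosen
over tolerating isolated masked bases: it can only shorten fragments,
never let repeat-derived reads count.

## Exact matching

A read counts toward a fragment only if the *entire* read matches with
zero mismatches on either strand. The counter is a seed-and-verify
k-mer index (default k = shortest N-free read length): candidate
positions come from a hash of fragment k-mers, and each candidate is
verified over the full read before counting. Reads containing N are
skipped (an N can never match exactly) and tallied. The count reported
per fragment is per-fragment presence by default — each read adds at
most 1 to every fragment it matches — because "number of alignments" is
ambiguous for multi-mapping reads and presence counting is deterministic
and order-independent; an all-occurrences mode (each distinct match
position counts) is available, and the two differ only for fragments
with internal repetition. External aligner output can be ingested from
SAM instead, keeping only mapped, unclipped, mismatch-free records
(NM:i:0, or a pure-match CIGAR with a consistent MD tag when NM is
absent).

## Evaluation

Against truth labels (autosome/X/Y), the false-positive rate is the
percentage of below-threshold fragments that are truly autosomal or
X-linked — a false-discovery proportion whose denominator is the
below-threshold set, not all non-Y fragments. This definition is the one
that reproduces the published benchmark rates from their underlying
counts (135/(135+5408) = 2.44% for the human benchmark, 2/(2+106) =
1.85% for the fly benchmark; the naive definition 135/621,581 does not),
and tests assert both reproductions. The false-negative rate is the
percentage of true Y fragments above the threshold; capture rate is its
complement. By default only the CQ threshold defines "below", matching
how the benchmark rates were tabulated; the count gates can be applied
as well, which is what the male-threshold sweep does as it re-evaluates
classification for every gate value from 1 to 50.

## The simulator

`sexsim` generates random ACGT backbones for five 50 kb autosomes, a
50 kb X and a 20 kb Y (all configurable), then plants:

* **repeat families** — two families of 150 bp units, copied with 2%
  per-copy divergence at 30 copies per autosome/X sequence and 24 on the
  (smaller, repeat-richer) Y, and softmasked in the emitted FASTA. Many
  short interspersed repeats rather than few long ones were chosen so
  that fragmentation of the ~320 kb default genome yields a few hundred
  fragments — the scale at which per-fragment CQ distributions (and
  their rank-sum comparison) are meaningful, mirroring how repeat-masked
  genomes shatter into fragment counts far exceeding chromosome counts.
  2% within-family divergence keeps copies closely related but not
  identical.
* **duplications** — two 500 bp autosome/X donor segments copied onto
  the Y at 95% identity, emulating recent duplications to the Y; these
  are the hard cases exact matching must still classify as Y.
* **expressed Y genes** — two 500 bp intervals on unique Y sequence from
  which transcriptome reads are drawn for the expression screen.

Large features are placed first and repeats fill in around them;
placement is rejection sampling with a failure error when a config
cannot fit. Reads are fixed-length (100 bp), drawn uniformly per
compartment copy at per-individual haploid coverage 20× for each sex
(so autosomes are sequenced at 40× per pool), from either strand with
equal probability. The default error rate is 0 so the CQ expectations
are exact: with error-free reads no female read can match Y-unique
sequence, making Y-unique CQs identically 0. A nonzero substitution
rate removes reads from both pools symmetrically (exact matching drops
any read with an error), lowering counts and raising false negatives
without biasing the ratio — a test asserts the count reduction.

What the simulator does **not** model: indels, GC and coverage bias,
paired ends, heterozygosity and individual-level variation (reads are
drawn from a pooled ideal diploid), gene structure or splicing in the
transcriptome reads. Passing tests therefore demonstrate correctness of
the ratio-and-threshold machinery under the copy-number model, not
robustness to real-data artifacts like allelic divergence between the
reference and the sequenced colony.

## Numerical and reporting choices

* Coordinates: 0-based half-open everywhere, including fragment ids
  (`source:start-end`).
* Medians of even-sized sets: mean of the two central values.
* Reported CQs: rounded to 3 decimals, half away from zero, matching
  the conventional presentation of worked CQ values; full precision is
  kept internally and in the `raw_cq`/`normalized_cq` TSV columns.
* Rates: reported as percentages rounded to 2 decimals; full precision
  internally.
* The rank-sum comparison of CQ groups uses the two-sided Mann–Whitney
  U test with midrank tie handling (ties are heavy: Y-unique fragments
  all score exactly 0).
* Determinism: no randomized tie-breaking anywhere; identical inputs and
  seeds give byte-identical artifacts (asserted in tests).
* The expression screen replaces a 100%-identity local-alignment search
  with full-read-length exact matching of transcriptome reads. This is
  strictly more conservative: every screened hit would also be a
  100%-identity local hit, but partial-read local matches are not
  accepted.

## Problem sizes

The default simulated study is a ~320 kb genome with ~220 autosomal,
~45 X and ~20 Y fragments at 20× per-individual coverage (~230k reads
total), which the full pipeline processes in a few seconds; the test
suite's oracle-equivalence checks run the brute-force all-pairs scan at
up to 80 fragments × 3,000 reads.

## Known limitations

* Per-fragment-presence counting cannot recover whatever multi-mapping
  convention an external aligner's "number of alignments" used; when
  reproducing counts produced elsewhere, ingest the SAM instead.
* Normalization requires at least one known-autosomal fragment with a
  defined, positive raw CQ; otherwise the run must proceed unnormalized.
* The fragment-level truth labels inherit the source sequence's
  compartment; a fragment spanning a duplication is truly Y-linked even
  though its sequence is mostly shared, and is flagged `duplication` in
  the truth table for separate analysis.
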