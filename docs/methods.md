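# Methods

## Problem and pipeline

Conventional DNA barcoding sequences one marker amplicon per single-species
sample. To make that affordable on short-read instruments, many samples and
gene fragments are pooled into one run: each fragment is amplified with a
first-round primer carrying a fixed 14-nt *introducer* (`GTAGACTGCGTACC`), and
a second PCR round prepends a sample-unique 10-nt *DNA label* using the
introducer as priming site. A sequenced amplicon therefore reads

    label + introducer + fwd primer + insert + rc(rev primer) + rc(introducer) + rc(label)

(`rc` = reverse complement). The pipeline reverses this construction:

1. **pairmerge** — paired-end reads are merged by their 3' overlap;
2. **demux** — merged reads are assigned to (sample, gene) by label,
   introducer and degenerate primer, and the artificial regions are trimmed;
3. **readgroup** — each bin is split into putative gene copies / species by
   greedy identity clustering and each group is multiple-aligned;
4. **cotu** — a majority-rule consensus with noise removal, core-range
   detection and thresholded end extension produces the barcode sequence;
5. **metrics** — K2P distances, per-site error profiles and recovery /
   length / depth summaries evaluate the output.

## The consensus model

Let an alignment have `n` rows. For a column, its *bases* are the non-gap
symbols and its *coverage* the base count.

- **Core range.** Scanning left to right, the core starts at the first index
  `i` such that columns `i .. i+w-1` (window `w = core_window = 3`) each have
  coverage strictly greater than `core_fraction x n` (default 0.50); the core
  end is found symmetrically from the right. No qualifying window means no
  consensus (`NoCoreError`). The window is taken over literal column indices;
  a single sparse insertion column inside an otherwise dense region simply
  prevents windows containing it, not the core as a whole, as long as the
  alignment is wide enough for windows on either side.
- **End extension.** Outside the core, a column is dropped as an incorrect
  insertion when its coverage is below `end_threshold x n` (default 0.20);
  at or above the threshold it is normal and the majority rule applies. This
  is what lets agreeing minority read ends extend the sequence beyond what a
  strict >50% coverage cutoff would keep.
- **Insertion elimination.** Inside the core, a column whose gaps strictly
  outnumber its bases is an insertion contributed by occasional reads and is
  dropped. A gap-vs-base tie keeps the base, favouring sequence length.
- **Noise removal.** At every called column, each base whose count is
  strictly below `noise_fraction` (default 0.10) of the column's bases is
  removed before the majority rule, suppressing rare sequencing errors.
- **Majority call.** The surviving base with the highest count is emitted; a
  tie between bases is emitted as the IUPAC code of the tied set (mirroring
  the chromatogram convention of calling two co-dominant peaks a degenerate
  base). The optional `ambiguity_fraction` additionally turns a call into a
  two-base code when the runner-up reaches that fraction of the bases.
- **Depth rules.** Alignments with fewer than `min_depth = 10` rows produce
  no sequence; at most the first `max_reads = 500` rows are used (a
  deterministic cap — first rows in input order, no subsampling).
- **Support.** Each emitted position records the fraction of the column's
  bases agreeing with the call (for an ambiguity code, the bases inside the
  code's set), always in (0, 1].

Interpretation choices worth making explicit: the noise denominator is the
column's bases (not `n`); the end threshold is inclusive (exactly 20%
coverage is "normal") while the core window comparison is strict, both
directions being defensible readings of the rule; and dropped columns outside
the core do not terminate the outward scan, so an isolated low-coverage
column inside a well-covered end region is skipped rather than truncating.

## Alignment and clustering

Pairwise identity is matches / alignment columns of a global end-to-end
alignment with affine gaps (match +1, mismatch −2, gap open −4, gap extend
−1), computed with `Bio.Align.PairwiseAligner`. Greedy clustering processes
reads in decreasing length (ties: input order); a read joins the first
centroid at or above the identity threshold, else founds a new cluster;
clusters are returned by decreasing size. Default thresholds follow marker
variability: 0.97 for ITS-class nuclear markers, 0.99 for the plastid
markers *matK* and *rbcL*.

The group alignment is a center-star MSA: the center is the member with the
highest summed identity to all others, each member is pairwise-aligned to the
center, and the pairwise alignments are merged under once-a-gap-always-a-gap.
For the O(n²) center scoring only, identity is approximated as
`1 − editDistance / max(len)` via edlib; on the near-identical reads this is
applied to, the ranking agrees with the affine identity while being two
orders of magnitude faster. The member-to-center alignments themselves use
the affine scorer. Star alignment is adequate for near-identical amplicon
reads; it is not a general-purpose progressive aligner, and a pre-aligned
FASTA can be supplied to bypass it.

Note the 0.99 plastid threshold leaves little margin at high per-base error:
two reads each carrying 0.5% errors differ by ~1%, so a noticeable fraction
of reads found singleton clusters. That matches the intended use (tight
thresholds on low-error data); for error-rich single-species bins a 0.97
threshold is the safer operating point and is what the end-to-end recovery
experiment uses.

## Demultiplexing

Labels are matched exactly by default (`label_max_mismatch = 0`): the label
set carries no designed error-correction distance, so exactness is the safe
default and tolerance is opt-in. The introducer allows 1 mismatch, primers 2
mismatches (IUPAC-aware: a window base matches any member of the pattern
symbol's degeneracy set). Both orientations are attempted in full; ties at
the minimal mismatch count between labels or genes leave the read unassigned
(`ambiguous_*`) rather than arbitrarily assigned. The 3' construct is located
by the rightmost occurrence of the reverse-complemented introducer and
trimmed together with the reverse primer; if absent (read-through
truncation) the read is kept to its end. The 200-bp minimum length is
applied once, to the trimmed insert. A read whose only intact construct is
its 3' end cannot be assigned (the primer found there is the reverse
primer), a deliberate consequence of anchoring assignment on the forward
primer; such reads are a few percent at 0.5%/base error and are lost at
random, which leaves consensus calling unaffected.

## K2P distance and error profiling

`d = −½ ln(1 − 2P − Q) − ¼ ln(1 − 2Q)` with P and Q the transition and
transversion proportions over compared sites. Sites where either sequence
has anything but literal A/C/G/T are ignored pairwise (gaps included);
non-positive log arguments raise a saturated-distance error rather than
returning NaN. Per-site error profiling ranks the read-base frequencies at
each reference position; the rank of the reference base (1 = most frequent)
estimates per-site sequencing error, and the fraction of rank-1 sites is the
overall base accuracy.

## What the simulator emulates

`simulate_run` generates the full construct per amplicon and reads both ends
at 250 nt with:

- substitutions at 0.005/base and indels at 0.0005/base, indels 10× more
  likely inside homopolymer runs ≥ 4 (the semiconductor-platform profile;
  insertions duplicate the local base, i.e. slippage);
- per-bin depth lognormal with median 100 and log-sigma 0.5, emulating the
  depth bias observed between pooled samples;
- base qualities decaying linearly 38 → 28 along the read;
- degenerate primer positions realised uniformly per amplicon (templates
  differ across species);
- labels generated with minimum pairwise Hamming distance 3, so exact
  matching is unambiguous under one label error.

Default insert ranges sit at ~75–85% of the panel's nominal fragment lengths
minus the primers (e.g. ITS1 280–330 nt). Real runs show mean read lengths
of roughly 62–93% of nominal, and this choice also guarantees read pairs
overlap by ≥ ~30 nt so the merge step is exercised rather than bypassed. The
simulator does **not** model chimeras, PCR duplicates, quality-correlated
error probabilities, flowgram noise, or sample cross-contamination — passing
tests demonstrate correctness of the algorithms under the stated error
model, not robustness to every artefact of real libraries.

## Validation problem sizes

The test suite validates, among others: exact 100-bin end-to-end recovery
(25 samples × 4 genes, depths drawn uniformly in 50–200, 0.5% substitutions,
0.05% indels, fixed seed; ≥ 99/100 bins must reproduce the true insert
byte-exactly); equivalence of the consensus caller with an independent
brute-force per-column evaluator on 1,000 random gapped alignments; the
end-extension guarantee against a 50%-cutoff baseline on 200 ragged
alignments; and error-free demultiplexing of a 10 × 6 × 50-read run with
zero cross-assignments. These sizes were chosen as the smallest that
exercise every code path with meaningful statistics.

## Known limitations

- The star MSA can misplace bases around long homopolymers relative to a
  full progressive aligner; the consensus noise rules absorb this at the
  depths used, but single-digit depths near `min_depth` are fragile.
- GC% of a first-round oligo counts degenerate symbols as non-GC. This
  literal-count convention reproduces the catalogued panel values for ten of
  the twelve primers; the catalogued values for matK-1248R (44.00) and
  rbcLbR (56.76) are not reachable by any literal counting of their stated
  sequences (which give 40.00 and 54.05) and appear to be tabulation errors.
- Demultiplexing anchors on the forward primer (see above); dual-anchor
  assignment would rescue 5'-damaged reads at the cost of a more permissive
  (and more error-prone) gene call.
- The merge step considers ungapped overlaps only; an indel error inside the
  physical overlap usually pushes the mismatch ratio over the limit and the
  pair is reported unmerged rather than merged incorrectly.
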