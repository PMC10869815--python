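# Methods

This note documents the models, rules and numerical choices behind each
stage of `cbekit`, what the simulators do and do not emulate, and the
design decisions taken where the procedure was genuinely open.

## Amplicon quantification

**Editing window.** The assayed region is the gap between the two
zinc-finger binding arms plus exactly one flanking base on each side:
arms `[l0, l1)` and `[r0, r1)` give the window `[l1 − 1, r0 + 1)` on the top
strand. Abutting arms leave a two-base window (the two flanking bases).
Window positions are labeled C1, C2, … by 1-based offset from the window
start on the top strand; this is a labeling convention for reports, not a
biological claim about which bases are cytosines.

**Alignment.** Reads are aligned to the amplicon with Biopython's
`PairwiseAligner`: affine gaps (match +2, mismatch −3, open −6, extend −1),
semi-global (end overhangs free on both sequences). Both the given
orientation and the reverse complement are scored and the better kept, so
input orientation never changes a reported number. Identity is matches
divided by read length — deliberately not per aligned column, so a short
perfectly matching island inside an otherwise unalignable read cannot pass
the floor (default 0.6; discarded reads are always counted). Equal-length
reads at ≥ 0.9 Hamming identity take an ungapped fast path; at that
identity an indel would have to be paired with a compensating indel, which
the gapped aligner would not produce either at these penalties.

**Tabulation.** A read contributes a base call at every reference position
its alignment covers; positions under a deletion contribute to the deletion
row instead, and insertions are tallied separately against the position
they follow. Per-position frequencies therefore sum to ≤ 1.

**Stop-codon fraction.** Denominator: reads that span the target codon with
no indel inside it (deleted codon bases or an insertion between them).
Reads with an indel in the codon are excluded and reported separately.
This keeps the substitution and indel channels separable; the alternative
(counting indel reads as non-stop) would conflate disruption with
non-editing. The codon is read on the annotated strand (`sense` /
`antisense`), so bottom-strand codons are handled by reverse complement.

**Reporting thresholds.** Substitutions at positions outside the window
are flagged at frequency ≥ 0.03; non-reference bases other than the
intended deamination product (T where the reference is C, A where it is G)
are flagged at ≥ 0.02. Both comparisons are inclusive (≥), both thresholds
configurable. Whether the 2% rule should apply only inside the window is
ambiguous in practice, so it is evaluated at every position and each
flagged event carries an `in_window` field, letting the consumer apply
either reading. The indel fraction counts reads with an indel overlapping
the editing window (not anywhere in the amplicon), over all retained reads.

## Break discovery

**Model.** Uracil excision converts deaminated cytosines into single-strand
breaks; shearing adds uniform random breaks. Edited positions are therefore
positions where a large number of reads begin at exactly the same base and
on the same orientation. Counting is per exact position — candidates are
defined at identical 5′ start positions, so no smoothing kernel is applied;
streaming over the genome is an implementation detail.

**Filters and thresholds (defaults).** Mean base quality per read ≥ 14
(the read-level reading of a Q-score cutoff; min-quality or trimming
variants would require raw-read access this stage does not have), MAPQ
≥ 50, 5′ soft clip ≤ 5 bp measured at the sequencing start (reference-left
for forward reads, reference-right for reverse), duplicate-flagged reads
removed. The filter tally attributes each removed read to the first failing
filter in that order. Candidate calling: start count ≥ 10 and start count /
depth ≥ 0.2, where depth is coverage at that position over both strands —
"per position" rules out windowed denominators — while start counting is
strand-separated, since a nick produces same-orientation pile-ups.
Both comparisons are inclusive.

**Duplicate handling.** The pipeline consumes duplicate flags rather than
re-deriving duplicates from coordinates: at a true break site many
legitimate reads share their 5′ start by construction, and naive
coordinate-based deduplication would erase exactly the signal being
measured. Optical-duplicate detection from tile geometry is an upstream
(flag-setting) concern.

**Finalization.** Treated candidates are removed if their position appears
in the unedited candidate list called with identical thresholds (exact
position, either strand; a distance-tolerant variant sits behind
`control_match_distance`), or if the single start position falls inside a
repeat-mask interval (half-open containment). Survivors merge by single
linkage with steps ≤ 50 bp; the cluster representative is the member with
the highest start count, leftmost on ties. Because adjacent clusters are by
construction > 50 bp apart, finalization is idempotent. Both pre- and
post-merge counts are reported, since downstream panel design consumes
merged clusters while raw candidate counts are also of interest.

**Set comparison.** Two finalized candidate sets are compared by greedy
nearest-distance pairing on the same contig within 50 bp (default), each
cluster matched at most once, yielding Venn-style shared/unique counts.

**Coordinates.** 0-based half-open everywhere internally; 1-based only in
human-readable report columns, labeled as such.

## Panel quantification

**Demultiplexing** is exact matching of the read's first 23 nt against the
panel prefixes (a dictionary lookup); `max_mismatches > 0` enables
Hamming-tolerant matching where ambiguous hits go to unassigned. Reads
shorter than 23 nt are unassigned and counted separately. Assignment is a
partition: every read lands in exactly one bin or in unassigned.

**Retention.** An amplicon is kept when (a) at least 2 of 4 replicates
(defaults) have ≥ 1000 assigned reads, and (b) at least 15% of the
unedited-sample reads resemble the expected reference. "Resemble" is
undefined in common usage, so it is implemented as global (Needleman–
Wunsch) identity ≥ 0.85 via edlib edit distance over
`max(len(read), len(ref))`; the floor separates mispriming products from
genuinely edited amplicons, which stay near-identical to the reference.
Every exclusion carries its reason in an audit record.

**Masking.** A position is masked when any non-reference allele frequency
in the unedited sample lies strictly inside (0.04, 0.96) — heterozygous or
otherwise polymorphic positions that would masquerade as editing. The
bounds are exclusive: an allele at exactly 0.04 is not masked. For
biallelic positions, restricting to non-reference alleles is equivalent to
testing any allele.

**Statistic.** Per amplicon, over unmasked positions:
`max(0, max_{pos, B∈{A,T}} (f_treated(B) − f_unedited(B)))`. Negative
changes are floored because the statistic indicates editing, not depletion;
deletion alleles are tallied separately and do not enter it. When every
position is masked the statistic is not-evaluable (`None`), never zero.
The statistic is computed per replicate against the pooled unedited
profile, and the replicate mean is the headline value (per-replicate values
are retained); pooled-read and per-replicate-maximum variants are
computable from the same profiles. An amplicon counts as an edited locus
when its statistic strictly exceeds 0.01.

## Stop-target scanner

The codon set is exactly {CAG, CAA, CGA, TGG}: the three codons whose
sense-strand C at position 1 yields a stop, and tryptophan, whose stops
arise from antisense cytosines opposite the second and/or third G (TAA
requires both, and is listed as achievable even though it needs two events
on the same strand). A TGG codon counts once however many routes it offers;
per-route detail stays in the record. The 5′ context of a target cytosine
is read 5′→3′ on its edited strand: for a sense C at index *i* the neighbor
is base *i − 1*; for an antisense C opposite the sense G at index *i* it is
the complement of base *i + 1*. Classes: 5′-TC (neighbor T), 5′-TCC
(neighbor C whose own 5′ neighbor is T), else 5′-AC / 5′-GC / 5′-CC;
missing flank ⇒ undetermined, flagged. A codon qualifies under a deaminase
context profile when at least one stop-achieving target cytosine's class is
in the profile. Codons that are already stops are not conversion targets.
Residue numbering follows the supplied offset; the CDS (with optional
flanks) is an input — no transcript lookup is embedded.

## Simulators

* **Genomes** are i.i.d. draws with the requested GC fraction.
* **Break libraries**: fragment count = genome length × depth / read
  length, so `mean_depth` is aligned-read fold coverage; fragment lengths
  are truncated normal (mean 300 bp, sd mean/5 — shearing is physical and
  any unimodal model suffices for testing the caller); background reads
  take a uniform fragment start and a random strand; a fragment overlapping
  a truth site is re-anchored with probability `edit_fraction` so its 5′
  end sits exactly on the site, on the site's strand only. Because
  fragments (300 bp) are longer than reads (150 bp), fragment coverage at a
  site is about twice the read depth, which is what makes a 0.25 edit
  fraction recoverable at 30×. Base qualities are constant (Q30) except
  where a low-quality read is injected for filter tests; MAPQ, 5′ soft
  clips and duplicate flags are injectable. Records are single-end,
  coordinate-sorted SAM.
* **Amplicon reads** apply, in order: at most one codon-level haplotype
  event (mutually exclusive rates — needed for joint two-base conversions
  like TGG→TAA that independent per-position draws cannot express), one
  substitution rule per position (mutually exclusive), an optional fixed
  indel, then independent per-base miscalls.
* **Panel runs** draw reads uniformly over amplicons per replicate and
  condition; germline alleles appear at their stated frequency in both
  conditions, treatment edits in treated only; contaminants are random
  sequences guaranteed not to start with any panel prefix.

What the simulators do **not** emulate: instrument-specific error
profiles, quality-score decay along reads, PCR chimeras and index
hopping, optical-duplicate tile geometry, paired-end structure, mapping
ambiguity in repetitive sequence, and real germline haplotype structure.
Passing tests therefore demonstrate that the *rules* are implemented
exactly and that parameters are recovered under clean, calibrated noise —
not that real-data artifact rates are negligible.

## Problem sizes and determinism

Validation runs use a 200-kb genome at 30× (≈ 40,000 reads), 10,000-read
amplicon libraries, 6-amplicon panels with 4 replicates at ~2,400 reads
each, and 400-codon random coding sequences — sizes at which every binomial
recovery bound is tight (3 SDs) yet the whole suite runs in well under a
minute per stage. Every generator takes an explicit seed and is
deterministic given it; statistical assertions use 3-binomial-SD bounds,
so they hold for any seed with ≈ 99.7% per-assertion probability rather
than being tuned to one stream.

## Known limitations

* The break caller assumes the duplicate flags it is given are trustworthy;
  it has no notion of optical versus PCR duplicates.
* The amplicon aligner is exact but quadratic per read; it is sized for
  amplicons (≲ 1 kb), not genomes.
* The panel statistic attributes any A/T gain to deamination; SNV
  contamination in the treated sample only would be indistinguishable.
* The scanner reports achievability, not editability: it does not model
  editing-window placement or efficiency of any particular editor
  architecture around the codon.
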