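# cbekit

Analysis toolkit for dimeric zinc-finger cytosine base editor (ZF-CBE)
experiments. A ZF-CBE pairs two zinc-finger arrays flanking a target site;
a split double-strand cytidine deaminase reconstitutes between them and
converts C•G to T•A within the inter-arm gap. `cbekit` implements the four
computational readouts such an experiment needs, plus a truth-known
simulator so every stage can be validated without touching real data:

* **Amplicon quantification** (`cbekit.amplicon`) — aligns amplicon reads,
  tabulates per-position base calls, calls the fraction of reads whose
  target codon became a premature stop (TAG/TAA/TGA), and measures indels.
  The *editing window* is the gap between the two ZF binding arms widened
  by one base on each side: for arms `[l0, l1)` and `[r0, r1)` the window is
  `[l1 − 1, r0 + 1)`. Substitutions outside the window are reported at
  ≥ 3%, non-reference bases other than the intended C→T / G→A product at
  ≥ 2% (both configurable).
* **Genome-wide break discovery** (`cbekit.breaks`) — uracil excision turns
  each base edit into a single-strand break, so after shearing and WGS the
  edited positions appear as stacks of identical 5′ read starts over a
  uniform background. Reads are filtered (mean base quality ≥ 14,
  MAPQ ≥ 50, 5′ soft clip ≤ 5 bp, duplicates removed), strand-aware 5′
  starts are piled up against coverage depth, and a position is a candidate
  when ≥ 10 reads start exactly there and those starts make up ≥ 20% of its
  depth. Candidates present in the unedited control or inside repeat
  intervals are removed; survivors within 50 bp merge into one cluster.
* **Multiplexed panel quantification** (`cbekit.rhamp`) — demultiplexes
  panel reads by their first 23 nt, retains an amplicon when ≥ 2 of 4
  replicates have ≥ 1000 reads and ≥ 15% of unedited reads resemble the
  expected reference, masks positions whose unedited allele frequency lies
  strictly inside (0.04, 0.96) as germline-like, and reports per amplicon
  the highest treated-minus-unedited increase of an A or T frequency —
  deamination on either strand reads out as a new T (top) or new A
  (bottom). Loci count as edited above a strict 1% threshold.
* **Stop-codon target scanning** (`cbekit.stops`) — enumerates codons a
  single-strand C→T event can convert to a stop (CAG→TAG, CAA→TAA,
  CGA→TGA on the sense strand; TGG→TGA/TAG/TAA via antisense cytosines)
  and classifies each target cytosine's 5′ context on its edited strand
  (5′-TC, 5′-TCC, 5′-AC, 5′-GC, 5′-CC), since strict deaminases only accept
  5′-TC/TCC while relaxed homologs tolerate more.
* **Simulation** (`cbekit.simulate`) — deterministic generators for genomes,
  break libraries (SAM records with MAPQ, soft clips, qualities, duplicate
  flags), amplicon reads with per-position edit rates, and panel runs with
  replicates, germline variants and contaminants; each emits ground truth
  alongside the reads.

## Worked example

`examples/02_discover_breaks.py` simulates a 100-kb genome with four
implanted break sites at edit fractions 1.0, 0.6, 0.4 and 0.25, a matched
unedited control, and runs the full discovery pipeline:

```
treated reads: 20000 retained
candidates before merging: 4
final clusters: 4
  chr1:20000 (+)  starts=70/70 (100% of depth)
  chr1:45000 (-)  starts=38/49 (78% of depth)
  chr1:70000 (+)  starts=28/51 (55% of depth)
  chr1:90000 (-)  starts=13/29 (45% of depth)
implanted sites recovered: 4/4
```

Each line is a putative edited site: the position, the strand the nick sits
on, and how many of the reads covering that base start exactly there. A
uniform shearing background almost never stacks ≥ 10 identical starts at
one position, which is why the null control contributes zero candidates.
The other examples cover amplicon quantification (recovers a simulated 30%
C→T, 10% stop conversion and 5% indels), panel off-targets (recovers a 10%
edit while masking a germline variant), and the stop-target scan.

There is also a thin CLI: `cbekit simulate|quantify-amplicon|discover-breaks|
rhamp-quant|scan-stops|run` (see `cbekit --help`).

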