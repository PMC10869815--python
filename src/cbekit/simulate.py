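"""Truth-known synthetic inputs for every pipeline stage.

The generators here emulate the three kinds of sequencing data the toolkit
consumes:

* whole-genome libraries in which uracil excision has converted base edits
  into single-strand breaks, so that a stated fraction of fragments
  overlapping an edited site have their 5' end exactly at the site, on top
  of a uniform random-fragmentation background;
* amplicon libraries with per-position substitution rates, optional indels
  and independent base-call error;
* multiplexed panel libraries whose reads carry a unique 23-nt amplicon
  prefix, with replicate structure, germline-like intermediate-frequency
  alleles present in every condition, treatment-only edits, and a stated
  fraction of off-panel contaminant reads.

Every generator is deterministic given its seed and emits a truth record
alongside the reads, so recovery can be asserted exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pysam

from .errors import InvalidArgument

_BASES = "ACGT"
_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class ReferenceSequence:
    """A synthetic contig standing in for genomic DNA."""

    name: str
    sequence: str
    seed: int

    def __post_init__(self) -> None:
        if len(self.sequence) == 0:
            raise InvalidArgument("reference sequence must be non-empty")
        if set(self.sequence) - set(_BASES):
            raise InvalidArgument("reference alphabet restricted to A/C/G/T")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class BreakSiteTruth:
    """An implanted single-strand break: base edit made visible by uracil excision."""

    contig: str
    position: int  # 0-based
    strand: str  # '+' or '-'
    edit_fraction: float

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise InvalidArgument(f"strand must be + or -, got {self.strand!r}")
        if not 0.0 <= self.edit_fraction <= 1.0:
            raise InvalidArgument("edit_fraction must lie in [0, 1]")


@dataclass
class TruthSet:
    """Ground truth emitted next to every synthetic read set."""

    break_sites: list[BreakSiteTruth] = field(default_factory=list)
    amplicon_rates: dict = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    def to_bed(self, path: str) -> None:
        with open(path, "w") as fh:
            for site in self.break_sites:
                fh.write(
                    f"{site.contig}\t{site.position}\t{site.position + 1}"
                    f"\t{site.edit_fraction}\t0\t{site.strand}\n"
                )


@dataclass
class AmpliconSimProfile:
    """Per-position edit rates for an amplicon library.

    substitutions maps (0-based position, alternate base) -> rate; rates at the
    same position are mutually exclusive and must sum to <= 1.  codon_events
    lists (codon_start, replacement_codon, rate) haplotype substitutions, also
    mutually exclusive, applied before per-position rules; they express joint
    multi-base edits (e.g. TGG->TAA) that independent per-position draws cannot.
    """

    substitutions: dict[tuple[int, str], float] = field(default_factory=dict)
    codon_events: list[tuple[int, str, float]] = field(default_factory=list)
    indel_rate: float = 0.0
    indel_position: int | None = None
    indel_length: int = 3
    indel_type: str = "del"  # or "ins"
    error_rate: float = 0.0
    n_reads: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        for (pos, alt), rate in self.substitutions.items():
            if not 0.0 <= rate <= 1.0:
                raise InvalidArgument(f"substitution rate {rate} at {pos}->{alt} outside [0,1]")
            if alt not in _BASES:
                raise InvalidArgument(f"alternate base {alt!r} not a DNA base")
        for rate in (self.indel_rate, self.error_rate):
            if not 0.0 <= rate <= 1.0:
                raise InvalidArgument("rates must lie in [0, 1]")
        for _, codon, rate in self.codon_events:
            if len(codon) != 3 or not 0.0 <= rate <= 1.0:
                raise InvalidArgument("codon event needs a 3-mer and a rate in [0,1]")
        if self.indel_rate > 0 and not 1 <= self.indel_length <= 10:
            raise InvalidArgument("indel length must lie in 1..10")


@dataclass
class PanelSimSpec:
    """Inputs for a multiplexed amplicon (rhAmpSeq-style) run.

    amplicons: list of (name, expected reference sequence); the first 23 nt of
    each sequence act as the demultiplexing prefix and must be pairwise
    distinct.  germline maps amplicon name -> list of (position, alt base,
    allele frequency) present in every condition; editing maps amplicon name ->
    (position, alt base, fraction) applied in the treated condition only.
    """

    amplicons: list[tuple[str, str]]
    replicates: int = 4
    reads_per_replicate: int = 1000
    germline: dict[str, list[tuple[int, str, float]]] = field(default_factory=dict)
    editing: dict[str, tuple[int, str, float]] = field(default_factory=dict)
    contaminant_fraction: float = 0.0
    error_rate: float = 0.0

    def __post_init__(self) -> None:
        prefixes = [seq[:23] for _, seq in self.amplicons]
        if any(len(p) < 23 for p in prefixes):
            raise InvalidArgument("every panel sequence must be at least 23 nt")
        if len(set(prefixes)) != len(prefixes):
            raise InvalidArgument("23-nt panel prefixes must be pairwise distinct")
        if not 0.0 <= self.contaminant_fraction <= 1.0:
            raise InvalidArgument("contaminant_fraction must lie in [0, 1]")


# a FASTQ-representable read
@dataclass(frozen=True)
class SimRead:
    name: str
    sequence: str
    quality: str


# ---------------------------------------------------------------------------
# generators


def make_genome(length: int, gc_fraction: float = 0.5, seed: int = 0,
                name: str = "chr1") -> ReferenceSequence:
    """Random contig with expected GC content ``gc_fraction``; deterministic per seed."""
    if length < 1:
        raise InvalidArgument("length must be >= 1")
    if not 0.0 <= gc_fraction <= 1.0:
        raise InvalidArgument("gc_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    at = (1.0 - gc_fraction) / 2.0
    gc = gc_fraction / 2.0
    bases = rng.choice(list(_BASES), size=length, p=[at, gc, gc, at])
    return ReferenceSequence(name=name, sequence="".join(bases), seed=seed)


def _draw_fragment_lengths(rng, n: int, frag_mean: float, lo: int) -> np.ndarray:
    # truncated normal, sd = mean/5; any unimodal model suffices here
    lens = rng.normal(frag_mean, frag_mean / 5.0, size=n)
    return np.clip(np.round(lens), lo, None).astype(np.int64)


def sam_header(genome: ReferenceSequence) -> pysam.AlignmentHeader:
    return pysam.AlignmentHeader.from_dict(
        {"HD": {"VN": "1.6", "SO": "coordinate"},
         "SQ": [{"SN": genome.name, "LN": len(genome)}]}
    )


def simulate_break_library(
    genome: ReferenceSequence,
    truth: Sequence[BreakSiteTruth],
    mean_depth: float = 30.0,
    read_length: int = 150,
    frag_mean: int = 300,
    error_rate: float = 0.0,
    clip5_inject: Mapping[int, int] | None = None,
    mapq_profile: int | Mapping[int, float] = 60,
    dup_fraction: float = 0.0,
    base_quality: int = 30,
    quality_inject: Mapping[int, int] | None = None,
    seed: int = 0,
) -> tuple[list[pysam.AlignedSegment], TruthSet]:
    """Aligned single-end WGS reads with 5'-start pile-ups at implanted break sites.

    ``mean_depth`` is aligned-read fold coverage.  Fragments are drawn with a
    truncated-normal length around ``frag_mean``; background reads take a
    random strand and their fragment-end 5' start, while a fragment that
    overlaps a truth site is, with probability ``edit_fraction``, re-anchored
    so its 5' end sits exactly on the site, on the site's strand.  Records are
    coordinate-sorted and carry MAPQ, base qualities, soft clips and duplicate
    flags per the injection arguments.
    """
    if mean_depth <= 0:
        raise InvalidArgument("mean_depth must be positive")
    L = len(genome)
    for site in truth:
        if site.contig != genome.name or not 0 <= site.position < L:
            raise InvalidArgument(
                f"truth site {site.contig}:{site.position} outside contig {genome.name}:{L}")
    clip5_inject = dict(clip5_inject or {})
    quality_inject = dict(quality_inject or {})
    rng = np.random.default_rng(seed)
    n_frags = max(1, int(round(L * mean_depth / read_length)))
    flens = _draw_fragment_lengths(rng, n_frags, frag_mean, lo=read_length)
    starts = (rng.random(n_frags) * np.maximum(1, L - flens)).astype(np.int64)

    if isinstance(mapq_profile, Mapping):
        vals = np.array(sorted(mapq_profile), dtype=np.int64)
        probs = np.array([mapq_profile[v] for v in vals], dtype=float)
        mapqs = rng.choice(vals, size=n_frags, p=probs / probs.sum())
    else:
        mapqs = np.full(n_frags, int(mapq_profile), dtype=np.int64)
    dup_flags = rng.random(n_frags) < dup_fraction
    bg_strands = rng.random(n_frags) < 0.5  # True -> reverse
    redirect_u = rng.random(n_frags)

    seq = genome.sequence
    records: list[tuple[int, pysam.AlignedSegment]] = []
    header = sam_header(genome)
    n_redirected = 0
    for i in range(n_frags):
        fstart = int(starts[i])
        fend = min(L, fstart + int(flens[i]))
        strand = "-" if bg_strands[i] else "+"
        anchor = None
        for site in truth:
            if fstart <= site.position < fend:
                if redirect_u[i] < site.edit_fraction:
                    anchor = site
                break
        if anchor is not None:
            n_redirected += 1
            strand = anchor.strand
            if strand == "+":
                ref_start = anchor.position
                ref_end = min(L, ref_start + read_length)
            else:
                ref_end = anchor.position + 1
                ref_start = max(0, ref_end - read_length)
        else:
            alen = min(read_length, fend - fstart)
            if strand == "+":
                ref_start, ref_end = fstart, fstart + alen
            else:
                ref_start, ref_end = fend - alen, fend
        alen = ref_end - ref_start
        read_seq = seq[ref_start:ref_end]
        if error_rate > 0:
            read_seq = _apply_errors(read_seq, error_rate, rng)

        a = pysam.AlignedSegment(header)
        a.query_name = f"frag{i}"
        a.flag = 16 if strand == "-" else 0
        if dup_flags[i]:
            a.flag |= 1024
        a.reference_id = 0
        a.reference_start = ref_start
        a.mapping_quality = int(mapqs[i])
        clip = clip5_inject.get(i, 0)
        clip = min(clip, alen - 1) if alen > 1 else 0
        if clip:
            # clipped bases sit at the sequencing start: reference-left for
            # forward reads, reference-right for reverse reads
            if strand == "+":
                a.cigarstring = f"{clip}S{alen - clip}M"
                a.reference_start = ref_start + clip
            else:
                a.cigarstring = f"{alen - clip}M{clip}S"
        else:
            a.cigarstring = f"{alen}M"
        a.query_sequence = read_seq
        q = quality_inject.get(i, base_quality)
        a.query_qualities = pysam.qualitystring_to_array(chr(q + 33) * alen)
        records.append((a.reference_start, a))

    records.sort(key=lambda t: t[0])
    out = [a for _, a in records]
    ts = TruthSet(
        break_sites=list(truth),
        meta={"n_reads": n_frags, "n_redirected": n_redirected,
              "mean_depth": mean_depth, "read_length": read_length,
              "frag_mean": frag_mean, "seed": seed},
    )
    return out, ts


def _apply_errors(read_seq: str, error_rate: float, rng) -> str:
    arr = np.frombuffer(read_seq.encode(), dtype=np.uint8).copy()
    hits = np.nonzero(rng.random(arr.size) < error_rate)[0]
    if hits.size:
        lut = {b: [c for c in b"ACGT" if c != b] for b in b"ACGT"}
        choices = rng.integers(0, 3, size=hits.size)
        for j, pos in enumerate(hits):
            arr[pos] = lut[arr[pos]][choices[j]]
    return arr.tobytes().decode()


def simulate_amplicon_reads(ref_sequence: str, profile: AmpliconSimProfile,
                            name_prefix: str = "amp") -> tuple[list[SimRead], TruthSet]:
    """Amplicon reads with the stated per-position edit profile.

    Each read starts from the reference, applies at most one codon-level event,
    then one substitution rule per position (mutually exclusive draws), then an
    optional indel, then independent base-call error.
    """
    L = len(ref_sequence)
    by_pos: dict[int, list[tuple[str, float]]] = {}
    for (pos, alt), rate in profile.substitutions.items():
        if not 0 <= pos < L:
            raise InvalidArgument(f"substitution position {pos} outside amplicon of length {L}")
        by_pos.setdefault(pos, []).append((alt, rate))
    for pos, rules in by_pos.items():
        if sum(r for _, r in rules) > 1.0 + 1e-9:
            raise InvalidArgument(f"substitution rates at position {pos} sum to more than 1")
    if profile.indel_rate > 0 and profile.indel_position is not None:
        if not 0 <= profile.indel_position < L:
            raise InvalidArgument("indel position outside amplicon")
    codon_total = sum(r for _, _, r in profile.codon_events)
    if codon_total > 1.0 + 1e-9:
        raise InvalidArgument("codon event rates sum to more than 1")

    rng = np.random.default_rng(profile.seed)
    reads: list[SimRead] = []
    qual = chr(30 + 33)
    for i in range(profile.n_reads):
        bases = list(ref_sequence)
        if profile.codon_events:
            u = rng.random()
            acc = 0.0
            for start, codon, rate in profile.codon_events:
                acc += rate
                if u < acc:
                    bases[start:start + 3] = list(codon)
                    break
        for pos, rules in by_pos.items():
            u = rng.random()
            acc = 0.0
            for alt, rate in rules:
                acc += rate
                if u < acc:
                    bases[pos] = alt
                    break
        if profile.indel_rate > 0 and rng.random() < profile.indel_rate:
            p = profile.indel_position if profile.indel_position is not None else L // 2
            if profile.indel_type == "del":
                del bases[p:p + profile.indel_length]
            else:
                ins = "".join(rng.choice(list(_BASES), size=profile.indel_length))
                bases[p:p] = list(ins)
        read_seq = "".join(bases)
        if profile.error_rate > 0:
            read_seq = _apply_errors(read_seq, profile.error_rate, rng)
        reads.append(SimRead(f"{name_prefix}_{i}", read_seq, qual * len(read_seq)))

    truth = TruthSet(
        amplicon_rates={
            "substitutions": dict(profile.substitutions),
            "codon_events": list(profile.codon_events),
            "indel_rate": profile.indel_rate,
        },
        meta={"n_reads": profile.n_reads, "seed": profile.seed,
              "error_rate": profile.error_rate},
    )
    return reads, truth


def simulate_rhamp_run(spec: PanelSimSpec, seed: int = 0
                       ) -> dict[str, list[list[SimRead]]]:
    """Panel reads per condition ('treated', 'unedited') and replicate.

    Reads are drawn uniformly over panel amplicons; germline alleles appear at
    their stated frequency in both conditions, treatment edits only in
    'treated'.  A ``contaminant_fraction`` of reads carry a random sequence
    guaranteed not to start with any panel prefix.
    """
    rng = np.random.default_rng(seed)
    prefixes = {seq[:23] for _, seq in spec.amplicons}
    out: dict[str, list[list[SimRead]]] = {"treated": [], "unedited": []}
    for condition in ("treated", "unedited"):
        for rep in range(spec.replicates):
            reads: list[SimRead] = []
            for i in range(spec.reads_per_replicate):
                if rng.random() < spec.contaminant_fraction:
                    reads.append(_contaminant_read(rng, prefixes,
                                                   f"{condition}_r{rep}_c{i}"))
                    continue
                name, ref = spec.amplicons[int(rng.integers(len(spec.amplicons)))]
                bases = list(ref)
                for pos, alt, af in spec.germline.get(name, []):
                    if rng.random() < af:
                        bases[pos] = alt
                if condition == "treated" and name in spec.editing:
                    pos, alt, frac = spec.editing[name]
                    if rng.random() < frac:
                        bases[pos] = alt
                read_seq = "".join(bases)
                if spec.error_rate > 0:
                    read_seq = _apply_errors(read_seq, spec.error_rate, rng)
                reads.append(SimRead(f"{condition}_r{rep}_{i}", read_seq,
                                     chr(63) * len(read_seq)))
            out[condition].append(reads)
    return out


def _contaminant_read(rng, prefixes: set[str], name: str) -> SimRead:
    while True:
        seq = "".join(rng.choice(list(_BASES), size=60))
        if seq[:23] not in prefixes:
            return SimRead(name, seq, chr(63) * len(seq))
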