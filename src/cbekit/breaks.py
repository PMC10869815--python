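"""Genome-wide discovery of base-edited sites from uracil-excision WGS.

Uracil excision converts each base edit into a single-strand break, so after
shearing and sequencing the edited positions show up as stacks of identical
5' read-start positions over a uniform fragmentation background.  The caller
filters alignments (mean base quality, MAPQ, 5'-soft-clip, duplicate flags),
piles up strand-aware 5' starts against position depth, emits candidates at
>= 10 identical starts making up >= 20% of depth (defaults), subtracts the
unedited control, masks repeat intervals, merges candidates within 50 bp,
and compares candidate sets between constructs.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pysam

from .errors import InvalidArgument


@dataclass
class DiscoveryConfig:
    min_read_quality: float = 14.0  # mean Phred per read
    min_mapq: int = 50
    max_clip5: int = 5  # bases soft-clipped at the sequencing start
    min_start_reads: int = 10
    min_start_fraction: float = 0.2
    merge_distance: int = 50
    remove_duplicates: bool = True
    strand_separated: bool = True
    # 0 = exact-position match against the control candidate list
    control_match_distance: int = 0

    def __post_init__(self) -> None:
        for name in ("min_read_quality", "min_mapq", "max_clip5",
                     "min_start_reads", "merge_distance", "control_match_distance"):
            if getattr(self, name) < 0:
                raise InvalidArgument(f"{name} must be >= 0")
        if not 0.0 < self.min_start_fraction <= 1.0:
            raise InvalidArgument("min_start_fraction must lie in (0, 1]")


@dataclass(frozen=True)
class FilteredAlignment:
    """The per-read facts the pileup needs; 5' position is strand-aware."""

    contig: str
    five_prime_pos: int  # leftmost coordinate (+) or rightmost aligned (-)
    strand: str
    ref_start: int
    ref_end: int
    mapq: int
    clip5: int
    mean_quality: float
    duplicate: bool


def _clip5_of(rec: pysam.AlignedSegment) -> int:
    cig = rec.cigartuples
    if not cig:
        return 0
    if rec.is_reverse:
        op, length = cig[-1]
    else:
        op, length = cig[0]
    return length if op == 4 else 0  # BAM_CSOFT_CLIP


def filter_alignments(records: Iterable[pysam.AlignedSegment],
                      cfg: DiscoveryConfig | None = None
                      ) -> tuple[list[FilteredAlignment], dict[str, int]]:
    """Apply the read filters; returns kept reads and a first-failing-filter tally."""
    cfg = cfg or DiscoveryConfig()
    tally = {"low_quality": 0, "low_mapq": 0, "clip5": 0,
             "duplicate": 0, "unmapped": 0, "retained": 0}
    kept: list[FilteredAlignment] = []
    for rec in records:
        quals = rec.query_qualities
        mean_q = float(np.mean(quals)) if quals is not None and len(quals) else 0.0
        if mean_q < cfg.min_read_quality:
            tally["low_quality"] += 1
            continue
        if rec.mapping_quality < cfg.min_mapq:
            tally["low_mapq"] += 1
            continue
        if not rec.is_unmapped and _clip5_of(rec) > cfg.max_clip5:
            tally["clip5"] += 1
            continue
        if cfg.remove_duplicates and rec.is_duplicate:
            tally["duplicate"] += 1
            continue
        if rec.is_unmapped:
            tally["unmapped"] += 1
            continue
        tally["retained"] += 1
        strand = "-" if rec.is_reverse else "+"
        start, end = rec.reference_start, rec.reference_end
        kept.append(FilteredAlignment(
            contig=rec.reference_name,
            five_prime_pos=end - 1 if rec.is_reverse else start,
            strand=strand,
            ref_start=start,
            ref_end=end,
            mapq=rec.mapping_quality,
            clip5=_clip5_of(rec),
            mean_quality=mean_q,
            duplicate=rec.is_duplicate,
        ))
    return kept, tally


@dataclass
class StartPileup:
    """Per-contig 5'-start counts (strand-separated) and coverage depth."""

    starts: dict[tuple[str, str], np.ndarray]  # (contig, strand) -> counts
    depth: dict[str, np.ndarray]  # contig -> coverage (both strands)

    def start_count(self, contig: str, strand: str, pos: int) -> int:
        arr = self.starts.get((contig, strand))
        if arr is None or pos >= arr.size:
            return 0
        return int(arr[pos])

    def depth_at(self, contig: str, pos: int) -> int:
        arr = self.depth.get(contig)
        if arr is None or pos >= arr.size:
            return 0
        return int(arr[pos])


def pileup_read_starts(filtered: Sequence[FilteredAlignment]) -> StartPileup:
    """Count strand-aware 5' starts and strand-agnostic depth per position."""
    max_end: dict[str, int] = defaultdict(int)
    for fa in filtered:
        max_end[fa.contig] = max(max_end[fa.contig], fa.ref_end)
    starts = {(c, s): np.zeros(max_end[c], dtype=np.int64)
              for c in max_end for s in "+-"}
    diff = {c: np.zeros(max_end[c] + 1, dtype=np.int64) for c in max_end}
    for fa in filtered:
        starts[(fa.contig, fa.strand)][fa.five_prime_pos] += 1
        diff[fa.contig][fa.ref_start] += 1
        diff[fa.contig][fa.ref_end] -= 1
    depth = {c: np.cumsum(d[:-1]) for c, d in diff.items()}
    return StartPileup(starts=starts, depth=depth)


@dataclass(frozen=True)
class BreakCandidate:
    contig: str
    position: int
    strand: str
    start_count: int
    depth: int

    @property
    def start_fraction(self) -> float:
        return self.start_count / self.depth if self.depth else 0.0


def call_break_candidates(pileup: StartPileup,
                          cfg: DiscoveryConfig | None = None) -> list[BreakCandidate]:
    """Every (contig, strand, position) passing both start-count and fraction cuts."""
    cfg = cfg or DiscoveryConfig()
    out: list[BreakCandidate] = []
    if cfg.strand_separated:
        items = pileup.starts.items()
    else:
        merged: dict[tuple[str, str], np.ndarray] = {}
        for (c, _s), arr in pileup.starts.items():
            key = (c, ".")
            merged[key] = merged.get(key, 0) + arr
        items = merged.items()
    for (contig, strand), arr in sorted(items):
        depth = pileup.depth[contig]
        hits = np.nonzero(arr >= cfg.min_start_reads)[0]
        for pos in hits:
            d = int(depth[pos])
            n = int(arr[pos])
            if d > 0 and n / d >= cfg.min_start_fraction:
                out.append(BreakCandidate(contig, int(pos), strand, n, d))
    out.sort(key=lambda c: (c.contig, c.position, c.strand))
    return out


@dataclass
class CandidateCluster:
    contig: str
    representative: BreakCandidate  # member with maximal start_count, leftmost on ties
    members: list[BreakCandidate]
    summed_start_count: int

    @property
    def position(self) -> int:
        return self.representative.position


def finalize_candidates(treated: Sequence[BreakCandidate],
                        unedited: Sequence[BreakCandidate],
                        repeat_mask=None,
                        cfg: DiscoveryConfig | None = None) -> list[CandidateCluster]:
    """Subtract the unedited control, mask repeats, merge within merge_distance.

    Control subtraction is an exact-position match against the unedited
    candidate list (either strand); ``cfg.control_match_distance`` > 0 enables
    a distance-tolerant variant.  ``repeat_mask`` is any object exposing
    ``contains(contig, pos)`` (see io.IntervalSet); candidates whose single
    start position falls inside a masked interval are removed.  Survivors are
    merged by single linkage: members chainable by steps <= merge_distance.
    """
    cfg = cfg or DiscoveryConfig()
    control_pos = defaultdict(list)
    for c in unedited:
        control_pos[c.contig].append(c.position)
    control_arr = {c: np.array(sorted(p)) for c, p in control_pos.items()}

    survivors: list[BreakCandidate] = []
    for cand in treated:
        arr = control_arr.get(cand.contig)
        if arr is not None and arr.size:
            i = int(np.searchsorted(arr, cand.position))
            near = min(
                (abs(int(arr[j]) - cand.position) for j in (i - 1, i) if 0 <= j < arr.size),
                default=None)
            if near is not None and near <= cfg.control_match_distance:
                continue
        if repeat_mask is not None and repeat_mask.contains(cand.contig, cand.position):
            continue
        survivors.append(cand)

    by_contig: dict[str, list[BreakCandidate]] = defaultdict(list)
    for cand in survivors:
        by_contig[cand.contig].append(cand)
    clusters: list[CandidateCluster] = []
    for contig in sorted(by_contig):
        members = sorted(by_contig[contig], key=lambda c: (c.position, c.strand))
        group: list[BreakCandidate] = []
        for cand in members:
            if group and cand.position - group[-1].position > cfg.merge_distance:
                clusters.append(_close_cluster(contig, group))
                group = []
            group.append(cand)
        if group:
            clusters.append(_close_cluster(contig, group))
    return clusters


def _close_cluster(contig: str, members: list[BreakCandidate]) -> CandidateCluster:
    rep = max(members, key=lambda c: (c.start_count, -c.position))
    return CandidateCluster(contig, rep, members, sum(c.start_count for c in members))


@dataclass
class SetComparison:
    shared: list[tuple[CandidateCluster, CandidateCluster]]
    a_only: list[CandidateCluster]
    b_only: list[CandidateCluster]

    @property
    def counts(self) -> dict[str, int]:
        return {"shared": len(self.shared), "a_only": len(self.a_only),
                "b_only": len(self.b_only)}


def compare_candidate_sets(a: Sequence[CandidateCluster],
                           b: Sequence[CandidateCluster],
                           shared_distance: int = 50) -> SetComparison:
    """Venn-style comparison: greedy nearest pairing within shared_distance,
    each cluster matched at most once."""
    pairs: list[tuple[int, int, int]] = []
    for i, ca in enumerate(a):
        for j, cb in enumerate(b):
            if ca.contig != cb.contig:
                continue
            d = abs(ca.position - cb.position)
            if d <= shared_distance:
                pairs.append((d, i, j))
    pairs.sort()
    used_a: set[int] = set()
    used_b: set[int] = set()
    shared: list[tuple[CandidateCluster, CandidateCluster]] = []
    for _d, i, j in pairs:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        shared.append((a[i], b[j]))
    a_only = [c for i, c in enumerate(a) if i not in used_a]
    b_only = [c for j, c in enumerate(b) if j not in used_b]
    return SetComparison(shared, a_only, b_only)


def discover(treated_records: Iterable[pysam.AlignedSegment],
             unedited_records: Iterable[pysam.AlignedSegment],
             repeat_mask=None, cfg: DiscoveryConfig | None = None
             ) -> tuple[list[CandidateCluster], dict]:
    """End-to-end discovery: filter both libraries, call, subtract, mask, merge."""
    cfg = cfg or DiscoveryConfig()
    t_kept, t_tally = filter_alignments(treated_records, cfg)
    u_kept, u_tally = filter_alignments(unedited_records, cfg)
    t_cands = call_break_candidates(pileup_read_starts(t_kept), cfg)
    u_cands = call_break_candidates(pileup_read_starts(u_kept), cfg)
    clusters = finalize_candidates(t_cands, u_cands, repeat_mask, cfg)
    summary = {
        "treated_filter_tally": t_tally,
        "unedited_filter_tally": u_tally,
        "treated_candidates_premerge": len(t_cands),
        "unedited_candidates_premerge": len(u_cands),
        "clusters": len(clusters),
    }
    return clusters, summary
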