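"""Multiplexed amplicon panel off-target quantification.

Reads are demultiplexed by their first 23 nt against the panel prefixes.
An amplicon is retained for a sample if present in >= 2 of 4 replicates with
>= 1000 reads each, and dropped if < 15% of the unedited-sample reads
resemble the expected reference.  Positions whose unedited non-reference
allele frequency lies strictly inside (0.04, 0.96) are masked as
germline-like.  The per-amplicon editing indicator is the highest
treated-minus-unedited frequency increase of an A or a T at any unmasked
position (cytosine deamination on either strand reads out as a new T or a
new A); loci count as edited above a strict 1% threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import edlib
import numpy as np

from .amplicon import (AlignParams, AmpliconReference, PositionProfile,
                       _BASE_INDEX, align_reads, tabulate_positions)
from .errors import InvalidArgument
from .simulate import SimRead

PREFIX_LENGTH = 23


@dataclass(frozen=True)
class PanelAmplicon:
    name: str
    reference: str

    def __post_init__(self) -> None:
        if len(self.reference) < PREFIX_LENGTH:
            raise InvalidArgument(
                f"panel amplicon {self.name} shorter than the {PREFIX_LENGTH}-nt prefix")

    @property
    def prefix(self) -> str:
        return self.reference[:PREFIX_LENGTH]


def build_panel(entries: Iterable[tuple[str, str]]) -> list[PanelAmplicon]:
    panel = [PanelAmplicon(name, seq) for name, seq in entries]
    prefixes = [p.prefix for p in panel]
    if len(set(prefixes)) != len(prefixes):
        raise InvalidArgument("panel prefixes are not pairwise distinct")
    return panel


@dataclass
class RetentionConfig:
    min_replicates: int = 2
    n_replicates: int = 4
    min_reads: int = 1000
    min_reference_fraction: float = 0.15
    similarity_floor: float = 0.85  # identity for a read to "resemble" the reference
    af_low: float = 0.04
    af_high: float = 0.96
    edited_threshold: float = 0.01

    def __post_init__(self) -> None:
        if not 0 < self.min_replicates <= self.n_replicates:
            raise InvalidArgument("need 0 < min_replicates <= n_replicates")
        if not 0.0 <= self.af_low < self.af_high <= 1.0:
            raise InvalidArgument("need 0 <= af_low < af_high <= 1")


# ---------------------------------------------------------------------------
# demultiplexing


@dataclass
class DemuxResult:
    bins: dict[str, list[SimRead]]
    unassigned: list[SimRead]
    too_short: int

    @property
    def assigned(self) -> int:
        return sum(len(v) for v in self.bins.values())

    @property
    def total(self) -> int:
        return self.assigned + len(self.unassigned)


def demultiplex_by_prefix(reads: Iterable[SimRead], panel: Sequence[PanelAmplicon],
                          max_mismatches: int = 0) -> DemuxResult:
    """Assign each read by its first 23 nt; ambiguous or non-matching -> unassigned."""
    exact = {p.prefix: p.name for p in panel}
    if len(exact) != len(panel):
        raise InvalidArgument("panel prefixes are not unique")
    bins: dict[str, list[SimRead]] = {p.name: [] for p in panel}
    unassigned: list[SimRead] = []
    too_short = 0
    for read in reads:
        head = read.sequence[:PREFIX_LENGTH]
        if len(head) < PREFIX_LENGTH:
            too_short += 1
            unassigned.append(read)
            continue
        name = exact.get(head)
        if name is None and max_mismatches > 0:
            hits = []
            for p in panel:
                mm = sum(a != b for a, b in zip(head, p.prefix))
                if mm <= max_mismatches:
                    hits.append((mm, p.name))
            if hits:
                hits.sort()
                best = [n for mm, n in hits if mm == hits[0][0]]
                name = best[0] if len(best) == 1 else None
        if name is None:
            unassigned.append(read)
        else:
            bins[name].append(read)
    return DemuxResult(bins, unassigned, too_short)


# ---------------------------------------------------------------------------
# retention filters


def read_resembles_reference(read: SimRead, reference: str,
                             floor: float) -> bool:
    """Global (NW) identity of the read against the expected reference."""
    aln = edlib.align(read.sequence, reference, mode="NW", task="distance")
    span = max(len(read.sequence), len(reference))
    identity = 1.0 - aln["editDistance"] / span if span else 0.0
    return identity >= floor


@dataclass
class AmpliconAudit:
    name: str
    retained: bool
    reads_per_replicate: list[int]
    replicates_passing: int
    reference_fraction: float | None
    reasons: list[str] = field(default_factory=list)


def apply_amplicon_filters(
    replicate_bins: Mapping[str, Sequence[Sequence[SimRead]]],
    unedited_bins: Mapping[str, Sequence[SimRead]],
    panel: Sequence[PanelAmplicon],
    cfg: RetentionConfig | None = None,
) -> tuple[set[str], list[AmpliconAudit]]:
    """Retention per amplicon: replicate/read-count rule, then the unedited-sample
    reference-similarity rule.  Every exclusion carries its reason.

    ``replicate_bins`` maps amplicon name -> per-replicate read lists for the
    sample under test; ``unedited_bins`` maps amplicon name -> pooled unedited
    reads used for the similarity rule.
    """
    cfg = cfg or RetentionConfig()
    known = {p.name: p for p in panel}
    for name in replicate_bins:
        if name not in known:
            raise InvalidArgument(f"amplicon {name!r} absent from panel")
    retained: set[str] = set()
    audits: list[AmpliconAudit] = []
    for name, reps in replicate_bins.items():
        counts = [len(r) for r in reps]
        passing = sum(1 for c in counts if c >= cfg.min_reads)
        reasons: list[str] = []
        if passing < cfg.min_replicates:
            reasons.append(
                f"only {passing} of {len(counts)} replicates with >= {cfg.min_reads} reads")
        ref_fraction = None
        if not reasons:
            unedited = unedited_bins.get(name, [])
            if unedited:
                n_similar = sum(
                    read_resembles_reference(r, known[name].reference,
                                             cfg.similarity_floor)
                    for r in unedited)
                ref_fraction = n_similar / len(unedited)
            else:
                ref_fraction = 0.0
            if ref_fraction < cfg.min_reference_fraction:
                reasons.append(
                    f"reference-resembling fraction {ref_fraction:.3f} below "
                    f"{cfg.min_reference_fraction}")
        ok = not reasons
        if ok:
            retained.add(name)
        audits.append(AmpliconAudit(name, ok, counts, passing, ref_fraction, reasons))
    return retained, audits


# ---------------------------------------------------------------------------
# allele frequencies and the max A/T-change statistic


def position_allele_frequencies(reads: Sequence[SimRead], expected_reference: str,
                                params: AlignParams | None = None) -> PositionProfile:
    """Align a bin to its expected reference and tabulate per-position base counts."""
    ref = AmpliconReference(id="panel", sequence=expected_reference)
    if not reads:
        L = len(expected_reference)
        return PositionProfile(expected_reference,
                               np.zeros((5, L), dtype=np.int64),
                               np.zeros(L, dtype=np.int64), 0)
    alignments, _ = align_reads(reads, ref, params)
    return tabulate_positions(alignments, ref)


def mask_background(unedited_af: PositionProfile,
                    cfg: RetentionConfig | None = None) -> set[int]:
    """Positions whose unedited non-reference allele frequency is strictly inside
    (af_low, af_high) — germline-like, removed from editing calculations."""
    cfg = cfg or RetentionConfig()
    freqs = unedited_af.frequencies()
    masked: set[int] = set()
    for pos, ref_base in enumerate(unedited_af.ref_sequence):
        if unedited_af.informative[pos] == 0:
            continue
        for base, row in _BASE_INDEX.items():
            if base == ref_base:
                continue
            f = float(freqs[row, pos])
            if cfg.af_low < f < cfg.af_high:
                masked.add(pos)
                break
    return masked


@dataclass
class OffTargetStat:
    amplicon: str
    max_at_change: float | None  # None when every position is masked (not evaluable)
    argmax_position: int | None
    argmax_base: str | None
    masked_positions: set[int] = field(default_factory=set)
    per_replicate: list[float] = field(default_factory=list)

    @property
    def evaluable(self) -> bool:
        return self.max_at_change is not None


def max_at_change(treated_af: PositionProfile, unedited_af: PositionProfile,
                  masked: set[int], amplicon: str = "") -> OffTargetStat:
    """Highest per-position increase of A or T frequency (treated - unedited),
    floored at zero, over unmasked positions; the editing indicator per amplicon."""
    if len(treated_af.ref_sequence) != len(unedited_af.ref_sequence):
        raise InvalidArgument("profiles computed on different references")
    L = len(treated_af.ref_sequence)
    unmasked = [p for p in range(L) if p not in masked]
    if not unmasked:
        return OffTargetStat(amplicon, None, None, None, set(masked))
    tf = treated_af.frequencies()
    uf = unedited_af.frequencies()
    best, best_pos, best_base = 0.0, None, None
    for pos in unmasked:
        for base in ("A", "T"):
            row = _BASE_INDEX[base]
            delta = float(tf[row, pos] - uf[row, pos])
            if delta > best:
                best, best_pos, best_base = delta, pos, base
    return OffTargetStat(amplicon, max(0.0, best), best_pos, best_base, set(masked))


def count_edited_loci(stats: Sequence[OffTargetStat],
                      threshold: float = 0.01) -> int:
    """Amplicons whose editing indicator strictly exceeds the threshold."""
    return sum(1 for s in stats
               if s.max_at_change is not None and s.max_at_change > threshold)


# ---------------------------------------------------------------------------
# end-to-end panel quantification


@dataclass
class PanelResult:
    retained: set[str]
    audits: list[AmpliconAudit]
    stats: dict[str, OffTargetStat]
    unassigned_fraction: float
    edited_loci: int


def quantify_panel(treated_replicates: Sequence[Sequence[SimRead]],
                   unedited_replicates: Sequence[Sequence[SimRead]],
                   panel: Sequence[PanelAmplicon],
                   cfg: RetentionConfig | None = None,
                   params: AlignParams | None = None) -> PanelResult:
    """Demultiplex every replicate, apply retention, mask on the pooled unedited
    profile, and report the per-amplicon statistic (per replicate + mean)."""
    cfg = cfg or RetentionConfig()
    t_demux = [demultiplex_by_prefix(reads, panel) for reads in treated_replicates]
    u_demux = [demultiplex_by_prefix(reads, panel) for reads in unedited_replicates]
    total = sum(d.total for d in t_demux + u_demux)
    unassigned = sum(len(d.unassigned) for d in t_demux + u_demux)

    replicate_bins = {p.name: [d.bins[p.name] for d in t_demux] for p in panel}
    unedited_pooled = {p.name: [r for d in u_demux for r in d.bins[p.name]]
                       for p in panel}
    retained, audits = apply_amplicon_filters(replicate_bins, unedited_pooled,
                                              panel, cfg)
    stats: dict[str, OffTargetStat] = {}
    by_name = {p.name: p for p in panel}
    for name in sorted(retained):
        ref = by_name[name].reference
        u_af = position_allele_frequencies(unedited_pooled[name], ref, params)
        masked = mask_background(u_af, cfg)
        per_rep: list[float] = []
        for rep_reads in replicate_bins[name]:
            if not rep_reads:
                continue
            t_af = position_allele_frequencies(rep_reads, ref, params)
            s = max_at_change(t_af, u_af, masked, name)
            if s.max_at_change is not None:
                per_rep.append(s.max_at_change)
        pooled_t = [r for rep in replicate_bins[name] for r in rep]
        t_af = position_allele_frequencies(pooled_t, ref, params)
        stat = max_at_change(t_af, u_af, masked, name)
        if per_rep and stat.max_at_change is not None:
            # replicate mean is the headline value; pooled argmax retained
            stat = OffTargetStat(name, float(np.mean(per_rep)),
                                 stat.argmax_position, stat.argmax_base,
                                 stat.masked_positions, per_rep)
        stats[name] = stat
    edited = count_edited_loci(list(stats.values()), cfg.edited_threshold)
    return PanelResult(retained, audits, stats,
                       unassigned / total if total else 0.0, edited)
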