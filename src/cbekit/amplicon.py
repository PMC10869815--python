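"""Base-editing, stop-codon and indel quantification from amplicon reads.

The editing window of a dimeric zinc-finger base editor is the gap between
the two ZF-array binding sites widened by one flanking base on each side;
deamination is assayed there.  Reads are aligned to the amplicon reference
(both orientations tried, affine gap penalties), per-position base calls are
tabulated, and a report applies the standard thresholds: substitutions
outside the window are listed at >= 3%, non-reference bases other than the
intended C->T / G->A product at >= 2%.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from Bio import Align

from .errors import InvalidArgument, NotApplicable
from .simulate import SimRead, revcomp

STOP_CODONS = frozenset({"TGA", "TAG", "TAA"})


@dataclass(frozen=True)
class AmpliconReference:
    """An amplicon with ZF binding-arm annotations (all intervals 0-based, half-open)."""

    id: str
    sequence: str
    left_arm: tuple[int, int] | None = None
    right_arm: tuple[int, int] | None = None
    target_codon_start: int | None = None
    codon_strand: str = "sense"  # codon read on the top strand or its complement

    def __post_init__(self) -> None:
        if self.codon_strand not in ("sense", "antisense"):
            raise InvalidArgument("codon_strand must be 'sense' or 'antisense'")
        if self.target_codon_start is not None:
            if not 0 <= self.target_codon_start <= len(self.sequence) - 3:
                raise InvalidArgument("target codon must lie fully inside the amplicon")

    @property
    def window(self) -> tuple[int, int]:
        return derive_editing_window(self)


def derive_editing_window(ref: AmpliconReference) -> tuple[int, int]:
    """Inter-arm gap plus the first 5' and 3' flanking base, on the top strand."""
    if ref.left_arm is None or ref.right_arm is None:
        raise InvalidArgument("both binding arms must be annotated")
    ls, le = ref.left_arm
    rs, re_ = ref.right_arm
    if not (ls < le <= rs < re_):
        raise InvalidArgument(
            f"arms must be ordered and non-overlapping, got {ref.left_arm} / {ref.right_arm}")
    if re_ > len(ref.sequence):
        raise InvalidArgument("right arm extends past the amplicon")
    return (le - 1, rs + 1)


# ---------------------------------------------------------------------------
# alignment


@dataclass
class AlignParams:
    match: float = 2.0
    mismatch: float = -3.0
    gap_open: float = -6.0
    gap_extend: float = -1.0
    identity_floor: float = 0.6
    # equal-length reads at >= this hamming identity skip the gapped aligner
    fast_path_identity: float = 0.9


@dataclass
class ReadAlignment:
    """A read's placement on the amplicon, as (reference position, base) pairs."""

    read_id: str
    pairs: list[tuple[int, str | None]]  # base None marks a deleted reference position
    insertions: list[tuple[int, str]]  # (reference position the insert follows, sequence)
    mean_quality: float
    orientation: str  # '+' as given, '-' reverse-complemented
    identity: float

    @property
    def ref_start(self) -> int:
        return self.pairs[0][0]

    @property
    def ref_end(self) -> int:
        return self.pairs[-1][0] + 1

    def covers(self, start: int, end: int) -> bool:
        return self.ref_start <= start and self.ref_end >= end

    def has_indel_in(self, start: int, end: int) -> bool:
        """True if a deletion touches [start, end) or an insertion breaks it apart."""
        for pos, base in self.pairs:
            if base is None and start <= pos < end:
                return True
        # an insertion anchored after pos interrupts the interval if both pos
        # and pos+1 lie inside it
        return any(start <= pos < end - 1 for pos, _ in self.insertions)

    def base_at(self, pos: int) -> str | None:
        i = pos - self.ref_start
        if 0 <= i < len(self.pairs) and self.pairs[i][0] == pos:
            return self.pairs[i][1]
        for p, b in self.pairs:  # pragma: no cover - pairs are dense in practice
            if p == pos:
                return b
        return None


def _make_aligner(params: AlignParams) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = params.match
    aligner.mismatch_score = params.mismatch
    aligner.open_gap_score = params.gap_open
    aligner.extend_gap_score = params.gap_extend
    # semi-global: end overhangs on either sequence are free
    aligner.end_insertion_score = 0.0
    aligner.end_deletion_score = 0.0
    return aligner


def _hamming_identity(a: str, b: str) -> float:
    n = len(a)
    matches = sum(x == y for x, y in zip(a, b))
    return matches / n if n else 0.0


def _pairs_from_biopython(aln, read_seq: str) -> tuple[list, list]:
    pairs: list[tuple[int, str | None]] = []
    insertions: list[tuple[int, str]] = []
    blocks_t, blocks_q = aln.aligned
    prev_t = prev_q = None
    for (ts, te), (qs, qe) in zip(blocks_t, blocks_q):
        if prev_t is not None:
            if ts > prev_t:  # reference skipped -> deletion in the read
                pairs.extend((p, None) for p in range(prev_t, ts))
            if qs > prev_q:  # read skipped -> insertion after prev_t - 1
                insertions.append((prev_t - 1, read_seq[prev_q:qs]))
        pairs.extend((ts + i, read_seq[qs + i]) for i in range(te - ts))
        prev_t, prev_q = te, qe
    return pairs, insertions


def align_amplicon_read(read: SimRead, ref: AmpliconReference,
                        params: AlignParams | None = None) -> ReadAlignment | None:
    """Align one read to the amplicon; returns None when below the identity floor.

    Both the given orientation and the reverse complement are scored and the
    better one kept, so input orientation never changes any downstream number.
    """
    if len(read.sequence) == 0:
        raise InvalidArgument("empty read")
    params = params or AlignParams()
    mean_q = float(np.mean([ord(c) - 33 for c in read.quality])) if read.quality else 0.0
    ref_seq = ref.sequence

    candidates = [(read.sequence, "+"), (revcomp(read.sequence), "-")]
    # fast path: ungapped placement for equal-length, high-identity reads
    if len(read.sequence) == len(ref_seq):
        best_seq, best_ori, best_ident = None, None, -1.0
        for seq, ori in candidates:
            ident = _hamming_identity(seq, ref_seq)
            if ident > best_ident:
                best_seq, best_ori, best_ident = seq, ori, ident
        if best_ident >= params.fast_path_identity:
            pairs = [(i, b) for i, b in enumerate(best_seq)]
            return ReadAlignment(read.name, pairs, [], mean_q, best_ori, best_ident)

    aligner = _make_aligner(params)
    best = None
    for seq, ori in candidates:
        aln = aligner.align(ref_seq, seq)[0]
        if best is None or aln.score > best[0].score:
            best = (aln, seq, ori)
    aln, seq, ori = best
    pairs, insertions = _pairs_from_biopython(aln, seq)
    if not pairs:
        return None
    matched = sum(1 for p, b in pairs if b == ref_seq[p])
    # identity over the full read, so a short perfectly matching island inside
    # an otherwise unalignable read cannot pass the floor
    identity = matched / len(seq) if seq else 0.0
    if identity < params.identity_floor:
        return None
    return ReadAlignment(read.name, pairs, insertions, mean_q, ori, identity)


def align_reads(reads: Iterable[SimRead], ref: AmpliconReference,
                params: AlignParams | None = None
                ) -> tuple[list[ReadAlignment], int]:
    """Align a read set; returns (kept alignments, number discarded below the floor)."""
    kept: list[ReadAlignment] = []
    discarded = 0
    for read in reads:
        aln = align_amplicon_read(read, ref, params)
        if aln is None:
            discarded += 1
        else:
            kept.append(aln)
    return kept, discarded


# ---------------------------------------------------------------------------
# tabulation

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}
_ROW_DEL = 4


@dataclass
class PositionProfile:
    """Per-position A/C/G/T/deletion counts plus insertion anchors."""

    ref_sequence: str
    counts: np.ndarray  # shape (5, L): A, C, G, T, deletion
    insertion_counts: np.ndarray  # shape (L,), anchored after the position
    n_reads: int

    @property
    def informative(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def frequencies(self) -> np.ndarray:
        denom = np.maximum(self.informative, 1)
        return self.counts / denom

    def base_frequency(self, pos: int, base: str) -> float:
        info = self.informative[pos]
        if info == 0:
            return 0.0
        return float(self.counts[_BASE_INDEX[base], pos] / info)


def tabulate_positions(alignments: Sequence[ReadAlignment],
                       ref: AmpliconReference) -> PositionProfile:
    L = len(ref.sequence)
    counts = np.zeros((5, L), dtype=np.int64)
    ins = np.zeros(L, dtype=np.int64)
    for aln in alignments:
        for pos, base in aln.pairs:
            if pos >= L:
                continue
            if base is None:
                counts[_ROW_DEL, pos] += 1
            elif base in _BASE_INDEX:
                counts[_BASE_INDEX[base], pos] += 1
        for pos, _seq in aln.insertions:
            if 0 <= pos < L:
                ins[pos] += 1
    return PositionProfile(ref.sequence, counts, ins, len(alignments))


@dataclass
class StopCallResult:
    stop_fraction: float
    per_stop_counts: dict[str, int]
    n_informative: int
    n_indel_in_codon: int


def call_stop_codon_fraction(alignments: Sequence[ReadAlignment],
                             ref: AmpliconReference) -> StopCallResult:
    """Fraction of codon-spanning, indel-free reads whose target codon is a stop.

    The codon is read on ``ref.codon_strand``; reads with an indel inside the
    codon are excluded from the denominator and reported separately.
    """
    if ref.target_codon_start is None:
        raise NotApplicable(f"amplicon {ref.id} has no target codon annotation")
    s = ref.target_codon_start
    per_stop = {c: 0 for c in sorted(STOP_CODONS)}
    n_info = n_indel = 0
    for aln in alignments:
        if not aln.covers(s, s + 3):
            continue
        if aln.has_indel_in(s, s + 3):
            n_indel += 1
            continue
        bases = [aln.base_at(p) for p in range(s, s + 3)]
        if any(b is None for b in bases):
            n_indel += 1
            continue
        codon = "".join(bases)
        if ref.codon_strand == "antisense":
            codon = revcomp(codon)
        n_info += 1
        if codon in STOP_CODONS:
            per_stop[codon] += 1
    total_stop = sum(per_stop.values())
    frac = total_stop / n_info if n_info else 0.0
    return StopCallResult(frac, per_stop, n_info, n_indel)


def indel_fraction(alignments: Sequence[ReadAlignment],
                   window: tuple[int, int]) -> float:
    """Fraction of retained reads carrying an indel that overlaps the editing window."""
    if not alignments:
        return 0.0
    n = sum(1 for a in alignments if a.has_indel_in(*window))
    return n / len(alignments)


# ---------------------------------------------------------------------------
# reporting


def intended_product(ref_base: str) -> str | None:
    """The on-pathway deamination outcome at a position: C->T on the top strand,
    G->A when the edited cytosine sits on the bottom strand."""
    return {"C": "T", "G": "A"}.get(ref_base)


@dataclass
class FlaggedEvent:
    position: int  # 0-based
    base: str
    frequency: float
    threshold: float
    in_window: bool


@dataclass
class EditingReport:
    amplicon_id: str
    window: tuple[int, int]
    stop_fraction: float
    per_stop_counts: dict[str, int]
    indel_fraction: float
    n_reads: int
    n_discarded: int
    flagged_outside_window: list[FlaggedEvent]
    flagged_unintended_bases: list[FlaggedEvent]
    window_labels: dict[int, str]
    substitution_frequencies: dict[tuple[int, str], float]

    def to_dict(self) -> dict:
        return {
            "amplicon_id": self.amplicon_id,
            "window": list(self.window),
            "stop_fraction": self.stop_fraction,
            "per_stop_counts": self.per_stop_counts,
            "indel_fraction": self.indel_fraction,
            "n_reads": self.n_reads,
            "n_discarded": self.n_discarded,
            "flagged_outside_window": [vars(e) for e in self.flagged_outside_window],
            "flagged_unintended_bases": [vars(e) for e in self.flagged_unintended_bases],
            "window_labels": {str(k): v for k, v in self.window_labels.items()},
            "substitution_frequencies": {
                f"{p}:{b}": f for (p, b), f in self.substitution_frequencies.items()},
        }


def build_editing_report(profile: PositionProfile, ref: AmpliconReference,
                         stop_result: StopCallResult | None,
                         indel_frac: float, n_discarded: int = 0,
                         outside_threshold: float = 0.03,
                         unintended_threshold: float = 0.02,
                         min_report_frequency: float = 1e-4) -> EditingReport:
    """Apply the reporting rules to a tabulated profile.

    Substitutions at positions outside the editing window are flagged at
    frequency >= ``outside_threshold`` (default 3%); non-reference bases other
    than the intended deamination product are flagged at >= ``unintended_threshold``
    (default 2%), both inside and outside the window (the in_window field
    distinguishes them).
    """
    window = ref.window
    ws, we = window
    freqs = profile.frequencies()
    outside: list[FlaggedEvent] = []
    unintended: list[FlaggedEvent] = []
    sub_freqs: dict[tuple[int, str], float] = {}
    for pos in range(len(ref.sequence)):
        ref_base = ref.sequence[pos]
        if profile.informative[pos] == 0:
            continue
        in_window = ws <= pos < we
        intended = intended_product(ref_base)
        for base, row in _BASE_INDEX.items():
            if base == ref_base:
                continue
            f = float(freqs[row, pos])
            if f >= min_report_frequency:
                sub_freqs[(pos, base)] = f
            if not in_window and f >= outside_threshold:
                outside.append(FlaggedEvent(pos, base, f, outside_threshold, in_window))
            if base != intended and f >= unintended_threshold:
                unintended.append(FlaggedEvent(pos, base, f, unintended_threshold, in_window))
    labels = {pos: f"C{pos - ws + 1}" for pos in range(ws, we)}
    return EditingReport(
        amplicon_id=ref.id,
        window=window,
        stop_fraction=stop_result.stop_fraction if stop_result else 0.0,
        per_stop_counts=stop_result.per_stop_counts if stop_result else {},
        indel_fraction=indel_frac,
        n_reads=profile.n_reads,
        n_discarded=n_discarded,
        flagged_outside_window=outside,
        flagged_unintended_bases=unintended,
        window_labels=labels,
        substitution_frequencies=sub_freqs,
    )


def quantify_amplicon(reads: Iterable[SimRead], ref: AmpliconReference,
                      params: AlignParams | None = None,
                      outside_threshold: float = 0.03,
                      unintended_threshold: float = 0.02) -> EditingReport:
    """End-to-end: align, tabulate, call stops and indels, build the report."""
    alignments, discarded = align_reads(reads, ref, params)
    profile = tabulate_positions(alignments, ref)
    stop = (call_stop_codon_fraction(alignments, ref)
            if ref.target_codon_start is not None else None)
    ifrac = indel_fraction(alignments, ref.window)
    return build_editing_report(profile, ref, stop, ifrac, discarded,
                                outside_threshold, unintended_threshold)
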