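"""Stop-codon target scanning with deaminase 5'-context classification.

A single-strand C->T deamination can convert four codons into premature
stops: CAG->TAG, CAA->TAA and CGA->TGA via the sense-strand cytosine at the
first codon position, and TGG->TGA/TAG/TAA via cytosines on the antisense
strand opposite the second and/or third G (seen as G->A on the sense
strand).  Whether a deaminase can act on a given target cytosine depends on
the base immediately 5' of it on the edited strand: the canonical
double-strand deaminase requires 5'-TC (or 5'-TCC), while relaxed homologs
accept 5'-AC and 5'-GC as well.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .errors import InvalidArgument
from .simulate import revcomp

STOP_CODONS = ("TAG", "TAA", "TGA")

# codon -> list of (achievable stop, edited strand, 0-based target C offsets in codon)
_ROUTES: dict[str, list[tuple[str, str, tuple[int, ...]]]] = {
    "CAG": [("TAG", "sense", (0,))],
    "CAA": [("TAA", "sense", (0,))],
    "CGA": [("TGA", "sense", (0,))],
    "TGG": [
        ("TAG", "antisense", (1,)),  # C opposite the middle G
        ("TGA", "antisense", (2,)),  # C opposite the last G
        ("TAA", "antisense", (1, 2)),
    ],
}

CONTEXT_CLASSES = ("5'-TC", "5'-TCC", "5'-AC", "5'-GC", "5'-CC", "undetermined")


@dataclass(frozen=True)
class CodingRegion:
    """An in-frame CDS (sense strand) with optional flanking context.

    ``upstream``/``downstream`` flanks let terminal codons get a 5'-context
    call; ``residue_offset`` is the residue number of the first codon.
    """

    id: str
    cds: str
    upstream: str = ""
    downstream: str = ""
    residue_offset: int = 1

    def __post_init__(self) -> None:
        if len(self.cds) % 3 != 0:
            raise InvalidArgument(f"CDS length {len(self.cds)} not divisible by 3")

    @property
    def n_residues(self) -> int:
        return len(self.cds) // 3

    def codon(self, residue: int) -> str:
        i = (residue - self.residue_offset) * 3
        return self.cds[i:i + 3]

    def base(self, cds_index: int) -> str | None:
        """Base at a CDS coordinate, reaching into the flanks; None when absent."""
        if cds_index < 0:
            i = len(self.upstream) + cds_index
            return self.upstream[i] if i >= 0 else None
        if cds_index < len(self.cds):
            return self.cds[cds_index]
        i = cds_index - len(self.cds)
        return self.downstream[i] if i < len(self.downstream) else None


@dataclass
class TargetCytosine:
    cds_index: int  # index of the sense base the C sits on/opposite
    strand: str  # the edited strand
    context: str  # one of CONTEXT_CLASSES
    stops: tuple[str, ...]  # stops this C participates in


@dataclass
class StopTargetCodon:
    residue: int
    codon: str
    achievable_stops: tuple[str, ...]
    edited_strand: str
    cytosines: list[TargetCytosine]

    def qualifies(self, allowed_contexts: Iterable[str]) -> bool:
        allowed = set(allowed_contexts)
        return any(c.context in allowed for c in self.cytosines)


def _classify_context(region: CodingRegion, cds_index: int, strand: str) -> str:
    """5'-neighbor class of a target cytosine, read 5'->3' on its edited strand.

    Sense C at index i: neighbor is base i-1, and for a 5'-TCC call the base
    5' of that neighbor is i-2.  Antisense C opposite a sense G at index i:
    the neighbor is the complement of base i+1, its own 5' neighbor the
    complement of base i+2.
    """
    if strand == "sense":
        n1 = region.base(cds_index - 1)
        n2 = region.base(cds_index - 2)
    else:
        b1 = region.base(cds_index + 1)
        b2 = region.base(cds_index + 2)
        n1 = revcomp(b1) if b1 else None
        n2 = revcomp(b2) if b2 else None
    if n1 is None:
        return "undetermined"
    if n1 == "T":
        return "5'-TC"
    if n1 == "C":
        if n2 is None:
            return "undetermined"
        return "5'-TCC" if n2 == "T" else "5'-CC"
    return f"5'-{n1}C"


def scan_stop_codons(region: CodingRegion,
                     residue_range: tuple[int, int] | None = None
                     ) -> list[StopTargetCodon]:
    """Every codon in the (inclusive) residue range convertible to a stop by
    single-strand C->T events, with routes, strands and 5'-context classes."""
    lo = region.residue_offset
    hi = region.residue_offset + region.n_residues - 1
    if residue_range is None:
        residue_range = (lo, hi)
    if not (lo <= residue_range[0] <= residue_range[1] <= hi):
        raise InvalidArgument(
            f"residue range {residue_range} outside CDS residues {lo}..{hi}")
    out: list[StopTargetCodon] = []
    for residue in range(residue_range[0], residue_range[1] + 1):
        codon = region.codon(residue)
        routes = _ROUTES.get(codon)
        if not routes:
            continue
        codon_start = (residue - region.residue_offset) * 3
        stops = tuple(dict.fromkeys(stop for stop, _, _ in routes))
        strand = routes[0][1]
        seen: dict[tuple[int, str], TargetCytosine] = {}
        for stop, c_strand, offsets in routes:
            for off in offsets:
                key = (codon_start + off, c_strand)
                if key in seen:
                    seen[key].stops = tuple(dict.fromkeys(seen[key].stops + (stop,)))
                else:
                    seen[key] = TargetCytosine(
                        cds_index=codon_start + off,
                        strand=c_strand,
                        context=_classify_context(region, codon_start + off, c_strand),
                        stops=(stop,),
                    )
        out.append(StopTargetCodon(residue, codon, stops, strand,
                                   list(seen.values())))
    return out


def classify_deaminase_context(region: CodingRegion,
                               target: StopTargetCodon) -> dict[int, str]:
    """Context class per target cytosine of one codon (cds_index -> class)."""
    return {c.cds_index: _classify_context(region, c.cds_index, c.strand)
            for c in target.cytosines}


@dataclass
class ScanSummary:
    total: int
    per_codon: dict[str, int]
    qualifying: list[StopTargetCodon]
    profile: tuple[str, ...]


def summarize_scan(targets: Sequence[StopTargetCodon],
                   deaminase_profile: Iterable[str] = CONTEXT_CLASSES
                   ) -> ScanSummary:
    """Counts per codon type plus the subset qualifying under a context profile
    (e.g. {5'-TC, 5'-TCC} for the canonical deaminase; add 5'-AC/5'-GC for
    relaxed homologs)."""
    profile = tuple(deaminase_profile)
    per_codon: dict[str, int] = {}
    for t in targets:
        per_codon[t.codon] = per_codon.get(t.codon, 0) + 1
    qualifying = [t for t in targets if t.qualifies(profile)]
    return ScanSummary(len(targets), per_codon, qualifying, profile)
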