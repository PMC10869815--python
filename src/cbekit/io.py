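"""Readers, writers, run configuration and the pipeline drivers.

Coordinates are 0-based half-open everywhere internally; human-readable
reports label 1-based columns explicitly.  Every run emits a summary that
echoes the full configuration, so any invocation is reproducible from its
own output.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import pysam
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from intervaltree import IntervalTree

from . import __version__
from .errors import FormatError, InvalidArgument
from .simulate import SimRead

# ---------------------------------------------------------------------------
# sequence formats (Biopython-backed)


def write_fasta(sequences: Iterable[tuple[str, str]], path: str | Path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]


def write_fastq(reads: Iterable[SimRead], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.name}\n{r.sequence}\n+\n{r.quality}\n")


def read_fastq(path: str | Path) -> list[SimRead]:
    out = []
    for rec in SeqIO.parse(str(path), "fastq"):
        quals = rec.letter_annotations["phred_quality"]
        out.append(SimRead(rec.id, str(rec.seq).upper(),
                           "".join(chr(q + 33) for q in quals)))
    return out


# ---------------------------------------------------------------------------
# alignments (pysam-backed)


def write_sam(records: Sequence[pysam.AlignedSegment],
              header: pysam.AlignmentHeader, path: str | Path) -> None:
    with pysam.AlignmentFile(str(path), "w", header=header) as fh:
        for rec in records:
            fh.write(rec)


def read_alignments(path: str | Path) -> Iterator[pysam.AlignedSegment]:
    """Stream SAM/BAM records; header required, malformed records named."""
    try:
        fh = pysam.AlignmentFile(str(path), check_sq=True)
    except (ValueError, OSError) as exc:
        raise FormatError(f"cannot open alignment file {path}: {exc}") from exc
    with fh:
        try:
            for rec in fh:
                yield rec
        except (ValueError, OSError) as exc:
            raise FormatError(f"malformed record in {path}: {exc}") from exc


# ---------------------------------------------------------------------------
# intervals (BED)


class IntervalSet:
    """Per-contig interval container over 0-based half-open coordinates."""

    def __init__(self, intervals: Iterable[tuple[str, int, int]] = ()) -> None:
        self._trees: dict[str, IntervalTree] = {}
        for contig, start, end in intervals:
            self.add(contig, start, end)

    def add(self, contig: str, start: int, end: int) -> None:
        if end <= start:
            raise InvalidArgument(f"interval end {end} <= start {start} on {contig}")
        self._trees.setdefault(contig, IntervalTree()).addi(start, end)

    def contains(self, contig: str, pos: int) -> bool:
        tree = self._trees.get(contig)
        return bool(tree is not None and tree.overlaps_point(pos))

    def __len__(self) -> int:
        return sum(len(t) for t in self._trees.values())

    def items(self) -> list[tuple[str, int, int]]:
        out = []
        for contig in sorted(self._trees):
            for iv in sorted(self._trees[contig]):
                out.append((contig, iv.begin, iv.end))
        return out


def read_intervals(path: str | Path) -> IntervalSet:
    """Load a BED file (0-based half-open); end <= start is a format error."""
    ivs = IntervalSet()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: fewer than 3 BED columns")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates") from exc
            if end <= start:
                raise FormatError(f"{path}:{lineno}: end {end} <= start {start}")
            ivs.add(parts[0], start, end)
    return ivs


def write_bed(rows: Iterable[tuple], path: str | Path) -> None:
    """Write (contig, start, end, name, score, strand) rows; trailing fields optional."""
    with open(path, "w") as fh:
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")


# ---------------------------------------------------------------------------
# run configuration and pipeline drivers


@dataclass
class RunConfig:
    """Stage selection plus per-stage threshold blocks; echoed into every summary."""

    stages: list[str] = field(default_factory=list)
    discovery: dict = field(default_factory=dict)
    retention: dict = field(default_factory=dict)
    amplicon: dict = field(default_factory=dict)
    inputs: dict = field(default_factory=dict)
    seed: int = 0
    out_dir: str = "."

    KNOWN_STAGES = ("simulate", "discover", "amplicon", "rhamp", "scan")

    def validate(self) -> None:
        for stage in self.stages:
            if stage not in self.KNOWN_STAGES:
                raise InvalidArgument(f"unknown stage {stage!r}")
        from .breaks import DiscoveryConfig
        from .rhamp import RetentionConfig
        DiscoveryConfig(**self.discovery)  # raises with the field name
        RetentionConfig(**self.retention)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        cfg = cls(**data)
        cfg.validate()
        return cfg

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class RunSummary:
    version: str
    config: dict
    stage_counts: dict[str, dict]
    warnings: list[str] = field(default_factory=list)

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, default=_json_default)


def _json_default(o):
    if isinstance(o, set):
        return sorted(o)
    if dataclasses.is_dataclass(o):
        return dataclasses.asdict(o)
    raise TypeError(f"not JSON serializable: {type(o)}")


def run_pipeline(config: RunConfig) -> RunSummary:
    """Execute the selected stages in dependency order and write their outputs.

    The discovery stage needs ``inputs: {treated, unedited, mask?}`` (SAM/BAM
    and BED paths); outputs land in ``config.out_dir``.
    """
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for name in ("treated", "unedited", "mask", "reads", "cds"):
        p = config.inputs.get(name)
        if p is not None and not Path(p).exists():
            raise InvalidArgument(f"input file for {name!r} not found: {p}")
    stage_counts: dict[str, dict] = {}
    warnings: list[str] = []

    if "discover" in config.stages:
        from .breaks import DiscoveryConfig, discover
        cfg = DiscoveryConfig(**config.discovery)
        mask_path = config.inputs.get("mask")
        mask = read_intervals(mask_path) if mask_path else None
        clusters, summary = discover(
            read_alignments(config.inputs["treated"]),
            read_alignments(config.inputs["unedited"]),
            mask, cfg)
        write_bed(
            ((c.contig, c.position, c.position + 1,
              f"cluster_{i}", c.summed_start_count, c.representative.strand)
             for i, c in enumerate(clusters)),
            out_dir / "clusters.bed")
        _write_candidate_table(clusters, out_dir / "candidates.tsv")
        stage_counts["discover"] = summary

    summary = RunSummary(__version__, config.to_dict(), stage_counts, warnings)
    summary.write(out_dir / "run_summary.json")
    return summary


def _write_candidate_table(clusters, path: str | Path) -> None:
    import pandas as pd
    rows = [{
        "contig": c.contig,
        "position_1based": c.position + 1,
        "strand": c.representative.strand,
        "start_count": c.representative.start_count,
        "depth": c.representative.depth,
        "start_fraction": round(c.representative.start_fraction, 4),
        "n_members": len(c.members),
        "summed_start_count": c.summed_start_count,
    } for c in clusters]
    pd.DataFrame(rows, columns=[
        "contig", "position_1based", "strand", "start_count", "depth",
        "start_fraction", "n_members", "summed_start_count",
    ]).to_csv(path, sep="\t", index=False)
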