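"""Per-base depth ingestion and relative coverage.

Relative coverage at a base is its depth divided by the mean depth over all
bases of all retained contigs of the genome (zeros included — dropout is the
phenomenon under study, not missing data).  The genome-wide mean of relative
coverage is therefore exactly 1 for any non-empty input.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .genome_io import GenomeSequence, WindowRecord

try:  # pysam is only needed for BAM ingestion
    import pysam
except ImportError:  # pragma: no cover
    pysam = None


class DepthFormatError(ValueError):
    """Raised for malformed depth files, with the offending line number."""


@dataclass
class CoverageTrack:
    """Raw per-base depth for one contig."""

    contig_id: str
    depth: np.ndarray

    def __post_init__(self) -> None:
        self.depth = np.asarray(self.depth, dtype=float)
        if self.depth.ndim != 1:
            raise ValueError("depth must be one-dimensional")
        if (self.depth < 0).any():
            raise ValueError(f"contig {self.contig_id!r}: negative depth")


@dataclass
class RelativeCoverageTrack:
    """Per-base relative coverage for one contig.

    ``genome_mean_depth`` records the normalizer that was applied (for the
    mock-community mode this is the copy-number-corrected per-species mean).
    """

    contig_id: str
    rel: np.ndarray
    genome_mean_depth: float


def load_depth(
    path: str | Path,
    dialect: str,
    genome: Sequence[GenomeSequence],
) -> list[CoverageTrack]:
    """Load a depth file into one CoverageTrack per contig of ``genome``.

    Dialects:
      * ``samtools_depth`` — 3 columns: contig, 1-based position, depth
      * ``bedgraph`` — 4 columns: contig, 0-based start, end (exclusive), depth

    Positions absent from the file get depth 0.  Unknown contig names and
    out-of-range positions are errors.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"depth file not found: {path}")
    if dialect not in ("samtools_depth", "bedgraph"):
        raise ValueError(f"unknown depth dialect: {dialect!r}")
    lengths = {g.contig_id: g.length for g in genome}
    tracks = {cid: np.zeros(n, dtype=float) for cid, n in lengths.items()}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            cid = fields[0]
            if cid not in tracks:
                raise DepthFormatError(
                    f"{path}:{lineno}: contig {cid!r} not present in the genome"
                )
            try:
                if dialect == "samtools_depth":
                    pos, d = int(fields[1]), float(fields[2])
                    if not 1 <= pos <= lengths[cid]:
                        raise DepthFormatError(
                            f"{path}:{lineno}: position {pos} outside contig "
                            f"{cid!r} (length {lengths[cid]})"
                        )
                    tracks[cid][pos - 1] = d
                else:
                    start, end, d = int(fields[1]), int(fields[2]), float(fields[3])
                    if not (0 <= start < end <= lengths[cid]):
                        raise DepthFormatError(
                            f"{path}:{lineno}: interval [{start},{end}) outside "
                            f"contig {cid!r} (length {lengths[cid]})"
                        )
                    tracks[cid][start:end] = d
            except (ValueError, IndexError) as exc:
                if isinstance(exc, DepthFormatError):
                    raise
                raise DepthFormatError(f"{path}:{lineno}: {exc}") from exc
    return [CoverageTrack(g.contig_id, tracks[g.contig_id]) for g in genome]


def load_depth_from_bam(
    path: str | Path,
    genome: Sequence[GenomeSequence],
    min_mapq: int = 0,
) -> list[CoverageTrack]:
    """Pileup depth per base from a coordinate-sorted, indexed BAM.

    Each primary, non-duplicate alignment with MAPQ >= ``min_mapq``
    contributes 1 to every reference base its aligned blocks span.
    Duplicate-flagged reads are excluded (duplicates are assumed to have
    been marked upstream).
    """
    if pysam is None:  # pragma: no cover
        raise ImportError("pysam is required for BAM ingestion")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"alignment file not found: {path}")
    lengths = {g.contig_id: g.length for g in genome}
    with pysam.AlignmentFile(str(path), "rb") as bam:
        extra = set(bam.references) - set(lengths)
        if extra:
            raise ValueError(
                f"alignment references not in genome: {sorted(extra)}"
            )
        if not bam.has_index():
            raise ValueError(f"{path} has no index; sort and index it first")
        tracks = {cid: np.zeros(n, dtype=float) for cid, n in lengths.items()}
        for cid in lengths:
            if cid not in bam.references:
                continue
            depth = tracks[cid]
            for read in bam.fetch(cid):
                if (
                    read.is_unmapped
                    or read.is_secondary
                    or read.is_supplementary
                    or read.is_duplicate
                    or read.mapping_quality < min_mapq
                ):
                    continue
                for start, end in read.get_blocks():
                    depth[start : min(end, lengths[cid])] += 1
    return [CoverageTrack(g.contig_id, tracks[g.contig_id]) for g in genome]


def relative_coverage(
    tracks: Sequence[CoverageTrack],
) -> list[RelativeCoverageTrack]:
    """Divide per-base depth by the genome-wide mean depth.

    The mean is taken jointly over all bases of all supplied tracks, so the
    pooled mean of the result is exactly 1.  All-zero coverage is an error.
    """
    if not tracks:
        raise ValueError("no coverage tracks supplied")
    total = sum(float(t.depth.sum()) for t in tracks)
    n_bases = sum(t.depth.size for t in tracks)
    if n_bases == 0 or total == 0:
        raise ValueError("empty coverage: no base has depth > 0")
    mean_depth = total / n_bases
    return [
        RelativeCoverageTrack(t.contig_id, t.depth / mean_depth, mean_depth)
        for t in tracks
    ]


def window_relative_coverage(
    rel_tracks: Sequence[RelativeCoverageTrack],
    windows: Sequence[WindowRecord],
) -> list[WindowRecord]:
    """Fill each window's relative_coverage with the mean of rel over [start, end).

    Returns new WindowRecord objects; the inputs are left untouched.
    """
    by_contig: dict[str, np.ndarray] = {}
    for t in rel_tracks:
        # prefix sums make each window mean an O(1) difference
        by_contig[t.contig_id] = np.concatenate(([0.0], np.cumsum(t.rel)))
    out: list[WindowRecord] = []
    for w in windows:
        if w.contig_id not in by_contig:
            raise ValueError(f"no coverage track for contig {w.contig_id!r}")
        csum = by_contig[w.contig_id]
        if w.end > csum.size - 1:
            raise ValueError(
                f"window [{w.start},{w.end}) outside track for {w.contig_id!r}"
            )
        mean_rel = (csum[w.end] - csum[w.start]) / (w.end - w.start)
        out.append(replace(w, relative_coverage=float(mean_rel)))
    return out
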