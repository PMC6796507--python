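"""Reference sequence handling: FASTA input, GC content, fixed-width windows.

Sequences are normalized to the alphabet {A, C, G, T, N} (upper case).  Any
other IUPAC ambiguity code is coerced to N with a warning so that public
draft genomes parse.  All coordinates are 0-based half-open; every emitted
table carries explicit ``start``/``end`` columns in that convention.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

_VALID = set(b"ACGTN")
# byte codes used for vectorized window arithmetic
_A, _C, _G, _T, _N = (ord(x) for x in "ACGTN")


class FastaFormatError(ValueError):
    """Raised for structurally invalid FASTA records."""


@dataclass(frozen=True)
class GenomeSequence:
    """One contig: identifier plus normalized base string."""

    contig_id: str
    bases: str

    def __post_init__(self) -> None:
        bad = set(self.bases) - {"A", "C", "G", "T", "N"}
        if bad:
            raise ValueError(
                f"contig {self.contig_id!r}: non-normalized characters {sorted(bad)}"
            )

    @property
    def length(self) -> int:
        return len(self.bases)

    def byte_array(self) -> np.ndarray:
        """Sequence as a uint8 array (ASCII codes), for vectorized ops."""
        return np.frombuffer(self.bases.encode("ascii"), dtype=np.uint8)


@dataclass(frozen=True)
class WindowSpec:
    """Tiling parameters: window width in bp and N tolerance per window."""

    window_size: int = 200
    max_n_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.window_size < 1:
            raise ValueError("window_size must be >= 1")
        if not 0.0 <= self.max_n_fraction <= 1.0:
            raise ValueError("max_n_fraction must be in [0, 1]")


@dataclass
class WindowRecord:
    """One non-overlapping window with its GC content.

    ``relative_coverage`` is filled later by the coverage module; it stays
    None until then.
    """

    contig_id: str
    start: int
    end: int
    gc_percent: float
    n_count: int
    relative_coverage: float | None = None


def normalize_bases(raw: str, contig_id: str = "?") -> str:
    """Upper-case and coerce non-{A,C,G,T,N} IUPAC codes to N."""
    up = raw.upper()
    arr = np.frombuffer(up.encode("ascii"), dtype=np.uint8)
    mask = ~np.isin(arr, np.frombuffer(b"ACGTN", dtype=np.uint8))
    n_coerced = int(mask.sum())
    if n_coerced:
        logger.warning(
            "contig %s: coerced %d ambiguity code(s) to N", contig_id, n_coerced
        )
        arr = arr.copy()
        arr[mask] = _N
        return arr.tobytes().decode("ascii")
    return up


def read_fasta(path: str | Path) -> list[GenomeSequence]:
    """Read a (multi-)FASTA file into normalized GenomeSequence records.

    Record order is preserved.  Empty records are rejected with the record
    index in the message.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"FASTA file not found: {path}")
    genomes: list[GenomeSequence] = []
    for idx, rec in enumerate(SeqIO.parse(str(path), "fasta")):
        seq = str(rec.seq)
        if not seq:
            raise FastaFormatError(f"record {idx} ({rec.id!r}) in {path} is empty")
        if not rec.id:
            raise FastaFormatError(f"record {idx} in {path} has an empty header")
        genomes.append(GenomeSequence(rec.id, normalize_bases(seq, rec.id)))
    if not genomes:
        raise FastaFormatError(f"no FASTA records found in {path}")
    return genomes


def gc_fraction(bases: str) -> float:
    """GC fraction over non-N bases; NaN when there is no non-N base.

    The undefined marker is ``math.nan`` — a value, not an error, so that
    all-N windows can be filtered downstream rather than aborting a run.
    """
    gc = bases.count("G") + bases.count("C")
    denom = len(bases) - bases.count("N")
    if denom == 0:
        return math.nan
    return gc / denom


def genome_mean_gc(genomes: Sequence[GenomeSequence]) -> float:
    """Mean GC of a genome in percent, pooled over all contigs (N excluded)."""
    gc = 0
    denom = 0
    for g in genomes:
        arr = g.byte_array()
        gc += int(((arr == _G) | (arr == _C)).sum())
        denom += int((arr != _N).sum())
    if denom == 0:
        return math.nan
    return 100.0 * gc / denom


def make_windows(
    genome: GenomeSequence,
    spec: WindowSpec = WindowSpec(),
    *,
    return_stats: bool = False,
):
    """Tile one contig into non-overlapping windows of ``spec.window_size``.

    Windows run [0, w), [w, 2w), ...; a trailing partial window is dropped.
    Windows whose N fraction exceeds ``spec.max_n_fraction`` (or whose GC is
    undefined because every base is N) are dropped and tallied.

    Returns the retained windows; with ``return_stats=True`` also returns a
    dict with the drop tally.
    """
    w = spec.window_size
    n_full = genome.length // w
    windows: list[WindowRecord] = []
    n_dropped = 0
    if n_full > 0:
        arr = genome.byte_array()[: n_full * w].reshape(n_full, w)
        gc_counts = ((arr == _G) | (arr == _C)).sum(axis=1)
        n_counts = (arr == _N).sum(axis=1)
        denom = w - n_counts
        for k in range(n_full):
            if denom[k] == 0 or n_counts[k] / w > spec.max_n_fraction:
                n_dropped += 1
                continue
            windows.append(
                WindowRecord(
                    contig_id=genome.contig_id,
                    start=k * w,
                    end=(k + 1) * w,
                    gc_percent=100.0 * gc_counts[k] / denom[k],
                    n_count=int(n_counts[k]),
                )
            )
    if n_dropped:
        logger.info(
            "contig %s: dropped %d window(s) exceeding max_n_fraction=%g",
            genome.contig_id,
            n_dropped,
            spec.max_n_fraction,
        )
    if return_stats:
        return windows, {"n_full": n_full, "n_dropped": n_dropped}
    return windows


def make_windows_genome(
    genomes: Iterable[GenomeSequence], spec: WindowSpec = WindowSpec()
) -> list[WindowRecord]:
    """Tile every contig of a genome; windows never span contig boundaries."""
    out: list[WindowRecord] = []
    for g in genomes:
        out.extend(make_windows(g, spec))
    return out


def windows_to_frame(windows: Sequence[WindowRecord]) -> pd.DataFrame:
    """Window records as a DataFrame (columns: contig, start, end, gc_percent,
    n_count, relative_coverage).  start/end are 0-based half-open."""
    return pd.DataFrame(
        {
            "contig": [w.contig_id for w in windows],
            "start": [w.start for w in windows],
            "end": [w.end for w in windows],
            "gc_percent": [w.gc_percent for w in windows],
            "n_count": [w.n_count for w in windows],
            "relative_coverage": [
                math.nan if w.relative_coverage is None else w.relative_coverage
                for w in windows
            ],
        }
    )


def write_window_table(windows: Sequence[WindowRecord], path: str | Path) -> None:
    """Write the window table as TSV (0-based half-open start/end)."""
    windows_to_frame(windows).to_csv(path, sep="\t", index=False)
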