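"""Assembly contiguity metrics and reference-preparation filters.

Covers the support computations around the bias analysis: the 300-bp
minimum contig length filter, N50/L50/N90, exclusion of contigs shorter
than N90 from draft references (short contigs are suspected multicopy
elements), the completeness/contamination genome quality gate, and
subsampling reads to a target fold-coverage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence, TypeVar

import numpy as np

logger = logging.getLogger(__name__)

T = TypeVar("T")


@dataclass(frozen=True)
class AssemblyStats:
    n_contigs: int
    total_length: int
    n50: int
    n90: int
    l50: int


def _length_of(contig) -> int:
    """Length of a contig given as an int, a GenomeSequence, or a sequence."""
    if isinstance(contig, (int, np.integer)):
        return int(contig)
    if hasattr(contig, "length"):
        return int(contig.length)
    return len(contig)


def filter_contigs_min_length(
    contigs: Sequence[T], min_len: int = 300
) -> tuple[list[T], int]:
    """Keep contigs of length >= min_len; returns (retained, n_removed).

    The boundary is inclusive: a contig of exactly ``min_len`` bases is kept
    (the exclusion rule is "shorter than").
    """
    kept = [c for c in contigs if _length_of(c) >= min_len]
    removed = len(contigs) - len(kept)
    if not kept:
        logger.warning("all %d contigs shorter than %d bp", removed, min_len)
    return kept, removed


def assembly_stats(lengths: Sequence[int]) -> AssemblyStats:
    """N50/N90/L50 from contig lengths.

    Lengths are sorted descending; N50 is the length of the first contig at
    which the cumulative length reaches >= 50% of the total, L50 its 1-based
    rank; N90 is analogous at 90%.
    """
    lens = [_length_of(c) for c in lengths]
    if not lens:
        raise ValueError("no contigs")
    if any(l <= 0 for l in lens):
        raise ValueError("contig lengths must be positive")
    desc = np.sort(np.asarray(lens, dtype=np.int64))[::-1]
    total = int(desc.sum())
    csum = np.cumsum(desc)
    i50 = int(np.searchsorted(csum, 0.5 * total))
    i90 = int(np.searchsorted(csum, 0.9 * total))
    return AssemblyStats(
        n_contigs=len(desc),
        total_length=total,
        n50=int(desc[i50]),
        n90=int(desc[i90]),
        l50=i50 + 1,
    )


def n90_reference_filter(contigs: Sequence[T]) -> tuple[list[T], int]:
    """Drop contigs shorter than the assembly's N90 (ties at N90 kept).

    Intended for draft references: the shortest contigs are plausibly
    multicopy genetic elements whose coverage would distort the genome mean.
    Returns (retained, n90).
    """
    if not contigs:
        raise ValueError("no contigs")
    n90 = assembly_stats([_length_of(c) for c in contigs]).n90
    return [c for c in contigs if _length_of(c) >= n90], n90


def genome_quality_filter(
    completeness: float,
    contamination: float,
    min_completeness: float = 85.0,
    max_contamination: float = 5.0,
) -> tuple[bool, str]:
    """Gate a genome on its quality metrics; returns (passed, reason).

    Fails iff completeness < min_completeness or contamination >
    max_contamination; the boundaries themselves pass (the exclusion rules
    are strict inequalities).
    """
    for name, v in (("completeness", completeness), ("contamination", contamination)):
        if not 0.0 <= v <= 100.0:
            raise ValueError(f"{name} must be in [0, 100], got {v}")
    if completeness < min_completeness:
        return False, f"completeness {completeness}% < {min_completeness}%"
    if contamination > max_contamination:
        return False, f"contamination {contamination}% > {max_contamination}%"
    return True, "pass"


def _record_bases(record) -> int:
    """Base count of a read record; a tuple/list is a read pair."""
    if isinstance(record, (tuple, list)):
        return sum(_record_bases(r) for r in record)
    if isinstance(record, (int, np.integer)):
        return int(record)
    return len(record)


def subsample_to_coverage(
    read_records: Sequence[T],
    genome_length: int,
    target_coverage: float = 30.0,
    seed: int = 0,
) -> tuple[list[T], float]:
    """Randomly pick reads until cumulative bases reach target x genome length.

    Records are sampled uniformly without replacement in a seeded random
    order; a record that is a tuple/list counts as a read pair and is kept or
    dropped as a unit.  Selection stops at the first record whose inclusion
    makes cumulative bases >= target_coverage * genome_length, so the
    achieved coverage overshoots the target by at most one record.

    Returns (selected records in sampling order, achieved coverage).
    """
    if genome_length <= 0:
        raise ValueError("genome_length must be positive")
    if target_coverage < 0:
        raise ValueError("target_coverage must be non-negative")
    needed = target_coverage * genome_length
    if target_coverage == 0:
        return [], 0.0
    total_available = sum(_record_bases(r) for r in read_records)
    if total_available < needed:
        raise ValueError(
            f"insufficient input: {total_available} bases give at most "
            f"{total_available / genome_length:.2f}x, target {target_coverage}x"
        )
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(read_records))
    selected: list[T] = []
    acc = 0
    for idx in order:
        rec = read_records[int(idx)]
        selected.append(rec)
        acc += _record_bases(rec)
        if acc >= needed:
            break
    return selected, acc / genome_length
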