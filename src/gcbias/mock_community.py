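"""Mock-community abundance normalization and per-species coverage bias.

A defined mixture of genomic DNAs is sequenced as one library; reads are
assigned per species upstream (competitive mapping) and arrive here as a
counts table.  Relative genome abundance is the mapped read (or base) count
divided by genome length and by the species' ddPCR copy number, renormalized
to sum to 1.  Copy numbers enter as relative values and are rescaled to mean
1 internally, so absolute ddPCR units never matter.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .coverage import CoverageTrack, RelativeCoverageTrack

logger = logging.getLogger(__name__)


@dataclass
class SpeciesQuant:
    """Per-species quantification inputs and the normalized abundance."""

    species_id: str
    mapped_reads: float  # read count, or base count when unit="bases"
    genome_length: int
    copy_number: float
    normalized_abundance: float | None = None


def read_quant_table(path: str | Path) -> list[SpeciesQuant]:
    """Read a TSV with columns species_id, mapped_reads, genome_length,
    copy_number."""
    df = pd.read_csv(path, sep="\t")
    required = {"species_id", "mapped_reads", "genome_length", "copy_number"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return [
        SpeciesQuant(
            species_id=str(r.species_id),
            mapped_reads=float(r.mapped_reads),
            genome_length=int(r.genome_length),
            copy_number=float(r.copy_number),
        )
        for r in df.itertuples()
    ]


def normalized_abundance(
    quants: Sequence[SpeciesQuant],
) -> list[SpeciesQuant]:
    """Fill normalized_abundance: a_s = m_s / (L_s k_s), renormalized to sum 1.

    m is the mapped read (or base) count, L the genome length and k the
    species' relative ddPCR copy number.  Dividing by L removes genome-size
    advantage; dividing by k removes unequal molarity of the input mixture,
    so for a perfectly equimolar design the expected abundance is 1/S.
    """
    if len(quants) < 2:
        raise ValueError("at least 2 species are required")
    for q in quants:
        if q.genome_length <= 0 or q.copy_number <= 0:
            raise ValueError(
                f"species {q.species_id!r}: genome_length and copy_number "
                "must be positive"
            )
        if q.mapped_reads < 0:
            raise ValueError(f"species {q.species_id!r}: negative read count")
    raw = np.array(
        [q.mapped_reads / (q.genome_length * q.copy_number) for q in quants]
    )
    total = raw.sum()
    if total == 0:
        raise ValueError("zero mapped reads across all species")
    return [
        replace(q, normalized_abundance=float(a)) for q, a in zip(quants, raw / total)
    ]


def per_species_relative_coverage(
    tracks_by_species: Mapping[str, Sequence[CoverageTrack]],
    copy_numbers: Mapping[str, float],
) -> dict[str, list[RelativeCoverageTrack]]:
    """Copy-number-corrected relative coverage, per species of a community.

    All species of one library share a single normalization scale: the
    community mean depth per copy-weighted base,

        mu = sum_s total_depth_s / sum_s (L_s * k_hat_s),
        k_hat_s = k_s / mean(k),   rel_s[b] = depth_s[b] / (mu * k_hat_s).

    mu * k_hat_s is the depth species s would show if reads were drawn
    purely in proportion to its molarity, so rel = 1 marks unbiased
    coverage: a species merely over-represented in the DNA mixture (high
    copy number) is not mistaken for one with coverage bias, while a
    species depleted by library chemistry shows a curve genuinely below 1.
    Doubling a species' copy number together with its depth leaves rel
    unchanged (exact cancellation); with equal copy numbers the result is
    plain relative coverage against the pooled community mean.  Species
    with all-zero coverage are excluded with a warning.  Downstream
    windowing, GC binning and C_GC per species proceed through the
    coverage and bias_stats modules unchanged.
    """
    if set(tracks_by_species) - set(copy_numbers):
        raise ValueError("copy number missing for some species")
    ks = {s: float(copy_numbers[s]) for s in tracks_by_species}
    if any(k <= 0 for k in ks.values()):
        raise ValueError("copy numbers must be positive")
    k_mean = sum(ks.values()) / len(ks)
    totals = {
        sp: sum(float(t.depth.sum()) for t in tracks)
        for sp, tracks in tracks_by_species.items()
    }
    lengths = {
        sp: sum(t.depth.size for t in tracks)
        for sp, tracks in tracks_by_species.items()
    }
    live = [sp for sp, tot in totals.items() if tot > 0]
    for sp in set(totals) - set(live):
        logger.warning("species %s: all-zero coverage, excluded", sp)
    if not live:
        raise ValueError("empty coverage: every species has zero depth")
    mu = sum(totals[sp] for sp in live) / sum(
        lengths[sp] * ks[sp] / k_mean for sp in live
    )
    out: dict[str, list[RelativeCoverageTrack]] = {}
    for sp in live:
        normalizer = mu * ks[sp] / k_mean
        out[sp] = [
            RelativeCoverageTrack(t.contig_id, t.depth / normalizer, normalizer)
            for t in tracks_by_species[sp]
        ]
    return out


def expected_vs_observed_report(
    quants: Sequence[SpeciesQuant],
) -> pd.DataFrame:
    """Observed abundance against the equimolar expectation 1/S.

    After copy-number correction the design target of an (approximately)
    equimolar mixture is an equal share per species; log2(observed/expected)
    quantifies over-/under-representation.
    """
    obs = [q.normalized_abundance for q in quants]
    if any(a is None for a in obs):
        raise ValueError("normalized_abundance not filled; run normalized_abundance")
    total = sum(obs)
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"abundances must sum to 1 (got {total})")
    expected = 1.0 / len(quants)
    return pd.DataFrame(
        {
            "species_id": [q.species_id for q in quants],
            "observed": obs,
            "expected": expected,
            "log2_ratio": [
                math.log2(a / expected) if a > 0 else -math.inf for a in obs
            ],
        }
    )


def quants_to_frame(quants: Sequence[SpeciesQuant]) -> pd.DataFrame:
    df = pd.DataFrame(
        {
            "species_id": [q.species_id for q in quants],
            "mapped_reads": [q.mapped_reads for q in quants],
            "genome_length": [q.genome_length for q in quants],
            "copy_number": [q.copy_number for q in quants],
            "normalized_abundance": [
                math.nan if q.normalized_abundance is None else q.normalized_abundance
                for q in quants
            ],
        }
    )
    return df
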