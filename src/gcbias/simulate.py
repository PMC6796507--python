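"""Synthetic genomes and GC-bias-aware coverage simulation.

Provides a fully controlled test bed for the bias pipeline: genomes with a
prescribed GC landscape (piecewise-constant target GC, emulating bacterial
genomes spanning roughly 25-72% mean GC), coverage whose expectation is a
known function of local window GC, and closed-form expectations for the
C_GC curve and the overall bias statistic under the Poisson sampling model.

Bias is a function of the 200-bp analysis window's GC content (not of each
fragment's own GC), which keeps the expected C_GC in closed form:

    E[C_i] = f(g_i) / Z,   Z = sum_j (n_j / n_T) f(g_j)

Two sampling modes exist.  ``poisson_site`` draws each base's depth from an
independent Poisson with that rate scaled to the requested mean depth; it
decouples statistical tests from read-placement artifacts.  ``fragment``
places whole reads with GC-weighted start positions and produces realistic
depth files for end-to-end demonstrations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .bias_stats import GCBinTable, overall_bias
from .coverage import CoverageTrack
from .genome_io import GenomeSequence, WindowSpec, make_windows

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class GCLandscapeSpec:
    """A genome as ordered segments of (length in bp, target GC fraction)."""

    segments: tuple[tuple[int, float], ...]
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValueError("at least one segment required")
        for length, gc in self.segments:
            if length <= 0:
                raise ValueError("segment lengths must be positive")
            if not 0.0 <= gc <= 1.0:
                raise ValueError("target GC must be in [0, 1]")

    @property
    def total_length(self) -> int:
        return sum(l for l, _ in self.segments)


@dataclass(frozen=True)
class BiasFunction:
    """A strictly positive coverage-bias weight as a function of GC fraction.

    Families:
      * uniform — f = 1 everywhere (no bias).
      * logistic_low_gc — smooth suppression of low-GC windows, the
        tagmentation-like signature: f rises from ``floor`` below the
        midpoint ``g0`` to ~1 above it with steepness ``s``.
      * linear — f = clip(1 + slope * (g - 0.5), floor, inf).
      * extreme_suppression — coverage dips away from a preferred GC
        ``center``: f = 1 - depth * (1 - exp(-((g - center) / width)^2)),
        the PCR-amplification-like signature at both GC extremes.
    """

    family: str
    params: tuple[tuple[str, float], ...] = ()

    def param(self, name: str) -> float:
        return dict(self.params)[name]

    @classmethod
    def uniform(cls) -> "BiasFunction":
        return cls("uniform")

    @classmethod
    def logistic_low_gc(
        cls, g0: float = 0.4, s: float = 0.03, floor: float = 0.2
    ) -> "BiasFunction":
        if not 0 < floor <= 1:
            raise ValueError("floor must be in (0, 1]")
        if s <= 0:
            raise ValueError("steepness must be positive")
        return cls(
            "logistic_low_gc", (("g0", g0), ("s", s), ("floor", floor))
        )

    @classmethod
    def linear(cls, slope: float, floor: float = 0.05) -> "BiasFunction":
        if floor <= 0:
            raise ValueError("floor must be positive")
        return cls("linear", (("slope", slope), ("floor", floor)))

    @classmethod
    def extreme_suppression(
        cls, center: float = 0.5, width: float = 0.15, depth: float = 0.5
    ) -> "BiasFunction":
        if not 0 <= depth < 1:
            raise ValueError("depth must be in [0, 1)")
        if width <= 0:
            raise ValueError("width must be positive")
        return cls(
            "extreme_suppression",
            (("center", center), ("width", width), ("depth", depth)),
        )

    def __call__(self, gc: np.ndarray | float) -> np.ndarray | float:
        g = np.asarray(gc, dtype=float)
        if self.family == "uniform":
            out = np.ones_like(g)
        elif self.family == "logistic_low_gc":
            p = dict(self.params)
            logistic = 1.0 / (1.0 + np.exp(-(g - p["g0"]) / p["s"]))
            out = p["floor"] + (1.0 - p["floor"]) * logistic
        elif self.family == "linear":
            p = dict(self.params)
            out = np.maximum(1.0 + p["slope"] * (g - 0.5), p["floor"])
        elif self.family == "extreme_suppression":
            p = dict(self.params)
            dip = 1.0 - np.exp(-(((g - p["center"]) / p["width"]) ** 2))
            out = 1.0 - p["depth"] * dip
        else:
            raise ValueError(f"unknown bias family {self.family!r}")
        return float(out) if np.isscalar(gc) else out


def generate_genome(
    spec: GCLandscapeSpec, contig_id: str = "synthetic_contig"
) -> GenomeSequence:
    """Draw a genome with iid bases per segment at the segment's target GC.

    Within a segment each base is G or C with probability target_gc/2 each,
    A or T with (1 - target_gc)/2 each.  Deterministic given spec.seed.
    """
    rng = np.random.default_rng(spec.seed)
    parts = []
    for length, gc in spec.segments:
        p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
        parts.append(rng.choice(_BASES, size=length, p=p))
    seq = np.concatenate(parts).tobytes().decode("ascii")
    return GenomeSequence(contig_id, seq)


def _window_rates(
    genome: GenomeSequence, bias: BiasFunction, window_size: int
) -> tuple[np.ndarray, np.ndarray, float]:
    """Per-base bias weight from the enclosing window's GC, plus Z.

    Returns (per-base weights f(g_w(b))/Z, per-window GC percents, Z).
    Z is the window-average of f over full windows, so the expected genome
    mean of weight/Z is 1 over windowed bases.  Trailing partial-window
    bases (if any) are weighted by their own partial window's GC.
    """
    windows = make_windows(genome, WindowSpec(window_size=window_size))
    if not windows:
        raise ValueError("genome shorter than one window")
    gc_pct = np.array([w.gc_percent for w in windows])
    f_w = np.asarray(bias(gc_pct / 100.0), dtype=float)
    z = float(f_w.mean())
    per_base = np.repeat(f_w / z, window_size)
    tail = genome.length - per_base.size
    if tail > 0:
        from .genome_io import gc_fraction

        g_tail = gc_fraction(genome.bases[-tail:])
        f_tail = bias(g_tail) / z if not math.isnan(g_tail) else 1.0
        per_base = np.concatenate([per_base, np.full(tail, f_tail)])
    return per_base, gc_pct, z


def simulate_coverage(
    genome: GenomeSequence,
    mean_depth: float,
    bias: BiasFunction,
    mode: str = "poisson_site",
    read_length: int = 150,
    seed: int = 0,
    window_size: int = 200,
) -> CoverageTrack:
    """Simulate a per-base depth track with GC-dependent expected coverage.

    poisson_site: depth[b] ~ Poisson(mean_depth * f(g_w(b)) / Z)
    independently per base, normalized so the expected genome mean depth is
    ``mean_depth``.  fragment: read start positions are drawn with weight
    f(g_w(start)); each read adds 1 over [start, start + read_length),
    truncated at the contig end.
    """
    if mean_depth <= 0:
        raise ValueError("mean_depth must be positive")
    rng = np.random.default_rng(seed)
    weights, _, _ = _window_rates(genome, bias, window_size)
    if mode == "poisson_site":
        depth = rng.poisson(mean_depth * weights).astype(float)
    elif mode == "fragment":
        n_reads = max(1, round(mean_depth * genome.length / read_length))
        p = weights / weights.sum()
        starts = rng.choice(genome.length, size=n_reads, p=p)
        diff = np.zeros(genome.length + 1)
        np.add.at(diff, starts, 1.0)
        np.add.at(diff, np.minimum(starts + read_length, genome.length), -1.0)
        depth = np.cumsum(diff[:-1])
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return CoverageTrack(genome.contig_id, depth)


def expected_cgc(
    bias: BiasFunction, bin_composition: Sequence[tuple[float, int]]
) -> pd.DataFrame:
    """Exact expected C_i per GC bin under poisson_site sampling.

    ``bin_composition`` lists (gc_label in percent, n_i) for the genome's
    windows; the expectation is E[C_i] = f(g_i) / Z with
    Z = sum_j (n_j / n_T) f(g_j).
    """
    labels = np.array([g for g, _ in bin_composition], dtype=float)
    n = np.array([c for _, c in bin_composition], dtype=float)
    f = np.asarray(bias(labels / 100.0), dtype=float)
    z = float((n * f).sum() / n.sum())
    return pd.DataFrame(
        {"gc_label": labels, "n_windows": n.astype(int), "expected_cgc": f / z}
    )


def expected_overall_bias(
    bias: BiasFunction,
    bin_composition: Sequence[tuple[float, int]],
    variant: str = "mean_squared",
) -> float:
    """Analytic expected B: expected_cgc composed with the bias statistic."""
    exp = expected_cgc(bias, bin_composition)
    table = GCBinTable(
        gc_label=exp["gc_label"].to_numpy(),
        n=exp["n_windows"].to_numpy(),
        c=exp["expected_cgc"].to_numpy(),
    )
    return overall_bias(table, variant=variant).B


@dataclass(frozen=True)
class CommunityMember:
    """One mock-community species: its genome spec, molarity and bias."""

    species_id: str
    landscape: GCLandscapeSpec
    copy_number: float
    bias: BiasFunction


def simulate_community(
    members: Sequence[CommunityMember],
    total_reads: int,
    read_length: int = 150,
    seed: int = 0,
    window_size: int = 200,
) -> tuple[dict[str, GenomeSequence], dict[str, CoverageTrack], pd.DataFrame]:
    """Simulate one metagenomic library over a defined community.

    Reads are allocated to species s with probability proportional to
    L_s * k_s * F_s, where F_s is the genome-average bias weight (the
    fraction of library molecules the species contributes), then placed
    within the genome fragment-mode.  Returns (genomes, coverage tracks,
    truth table with the realized read counts).
    """
    if len(members) < 2:
        raise ValueError("a community needs at least 2 species")
    rng = np.random.default_rng(seed)
    genomes: dict[str, GenomeSequence] = {}
    per_base_w: dict[str, np.ndarray] = {}
    rows = []
    for m in members:
        g = generate_genome(m.landscape, contig_id=m.species_id)
        genomes[m.species_id] = g
        w, _, z = _window_rates(g, m.bias, window_size)
        per_base_w[m.species_id] = w
        f_avg = z  # Z is the window-average of f: the genome-average bias weight F_s
        rows.append(
            {
                "species_id": m.species_id,
                "genome_length": g.length,
                "copy_number": m.copy_number,
                "bias_weight": f_avg,
            }
        )
    truth = pd.DataFrame(rows)
    alloc = (
        truth["genome_length"]
        * truth["copy_number"]
        * truth["bias_weight"]
    ).to_numpy(dtype=float)
    counts = rng.multinomial(total_reads, alloc / alloc.sum())
    truth["reads"] = counts
    tracks: dict[str, CoverageTrack] = {}
    for m, n_reads in zip(members, counts):
        g = genomes[m.species_id]
        depth = np.zeros(g.length)
        if n_reads > 0:
            w = per_base_w[m.species_id]
            starts = rng.choice(g.length, size=int(n_reads), p=w / w.sum())
            diff = np.zeros(g.length + 1)
            np.add.at(diff, starts, 1.0)
            np.add.at(diff, np.minimum(starts + read_length, g.length), -1.0)
            depth = np.cumsum(diff[:-1])
        tracks[m.species_id] = CoverageTrack(m.species_id, depth)
    return genomes, tracks, truth


def bimodal_landscape(
    total_length: int = 2_000_000,
    gc_modes: tuple[float, float] = (0.32, 0.58),
    gc_range: tuple[float, float] = (0.25, 0.65),
    ramp_fraction: float = 0.1,
    seed: int = 0,
) -> GCLandscapeSpec:
    """A realistic genome-scale GC landscape spanning ``gc_range``.

    Real bacterial genomes concentrate most windows near their mean GC;
    this landscape places the bulk of the sequence in two dominant GC
    modes (so central GC bins are well populated and individually
    testable) and a small multi-segment ramp across the full range (so
    extreme bins exist too).
    """
    ramp_steps = 8
    ramp_total = int(total_length * ramp_fraction)
    step_len = max(200, ramp_total // ramp_steps)
    ramp = tuple(
        (step_len, float(gc))
        for gc in np.linspace(gc_range[0], gc_range[1], ramp_steps)
    )
    body = total_length - step_len * ramp_steps
    half = body // 2
    segments = ramp + ((half, gc_modes[0]), (body - half, gc_modes[1]))
    return GCLandscapeSpec(segments=segments, seed=seed)


def simulate_bias_gc_points(
    n_genomes: int,
    slope: float,
    intercept: float,
    noise_sd: float,
    gc_range: tuple[float, float] = (25.0, 72.0),
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Synthetic (mean_gc, B) cohort with a known linear bias-GC relation.

    Genome mean GC values are drawn uniformly over ``gc_range`` (percent);
    B = intercept + slope * gc + Gaussian noise, truncated at 0 since the
    bias statistic is non-negative.  Used to validate regression recovery.
    """
    if n_genomes < 3:
        raise ValueError("need at least 3 genomes")
    rng = np.random.default_rng(seed)
    gc = rng.uniform(*gc_range, size=n_genomes)
    b = intercept + slope * gc + rng.normal(0.0, noise_sd, size=n_genomes)
    return gc, np.maximum(b, 0.0)
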