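"""End-to-end orchestration: genome + depth -> windows -> bins -> C_GC -> B.

Single-genome mode profiles one reference/library pair and writes the full
stage output (window table, bin table, C_GC curve, bias JSON, manifest).
Cohort mode repeats that over many genomes, applies the genome quality gate,
and regresses overall bias on genome mean GC.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import __version__
from .assembly_qc import genome_quality_filter, n90_reference_filter
from .bias_stats import (
    BiasResult,
    bias_gc_regression,
    bin_by_gc,
    cgc_curve,
    overall_bias,
)
from .coverage import (
    load_depth,
    load_depth_from_bam,
    relative_coverage,
    window_relative_coverage,
)
from .genome_io import (
    WindowSpec,
    genome_mean_gc,
    make_windows_genome,
    read_fasta,
    write_window_table,
)


class PipelineError(RuntimeError):
    """A stage failure, annotated with the stage name and file context."""


@dataclass
class RunConfig:
    """All inputs and knobs for one single-genome bias profile."""

    fasta: str
    depth: str
    dialect: str = "samtools_depth"  # samtools_depth | bedgraph | bam
    label: str = ""
    window_size: int = 200
    max_n_fraction: float = 0.0
    bin_width: float = 0.5
    min_bin_fraction: float = 0.005
    variant: str = "mean_squared"
    n90_filter: bool = False
    min_mapq: int = 0
    completeness: float = 100.0
    contamination: float = 0.0
    min_completeness: float = 85.0
    max_contamination: float = 5.0
    outdir: str | None = None
    seed: int = 0

    def validate(self) -> None:
        for name in ("fasta", "depth"):
            p = Path(getattr(self, name))
            if not p.exists():
                raise PipelineError(f"stage config: {name} file not found: {p}")
        if self.dialect not in ("samtools_depth", "bedgraph", "bam"):
            raise PipelineError(f"stage config: unknown dialect {self.dialect!r}")
        if self.window_size < 1 or self.bin_width <= 0:
            raise PipelineError("stage config: invalid window_size/bin_width")


def run_single_genome(config: RunConfig) -> dict:
    """Profile one genome/library: windows, GC bins, C_GC curve and B.

    Returns a dict with the in-memory results; when ``config.outdir`` is set
    the stage tables (TSV), bias JSON and a manifest are also written there.
    """
    config.validate()
    try:
        genomes = read_fasta(config.fasta)
    except Exception as exc:
        raise PipelineError(f"stage read_fasta ({config.fasta}): {exc}") from exc

    n90_value = None
    if config.n90_filter and len(genomes) > 1:
        genomes, n90_value = n90_reference_filter(genomes)

    try:
        if config.dialect == "bam":
            tracks = load_depth_from_bam(config.depth, genomes, config.min_mapq)
        else:
            tracks = load_depth(config.depth, config.dialect, genomes)
    except Exception as exc:
        raise PipelineError(f"stage load_depth ({config.depth}): {exc}") from exc

    try:
        rel = relative_coverage(tracks)
        spec = WindowSpec(config.window_size, config.max_n_fraction)
        windows = window_relative_coverage(rel, make_windows_genome(genomes, spec))
        bins = bin_by_gc(windows, config.bin_width)
        curve = cgc_curve(bins, config.min_bin_fraction)
        mean_gc = genome_mean_gc(genomes)
        bias = overall_bias(bins, variant=config.variant, mean_gc=mean_gc)
    except Exception as exc:
        raise PipelineError(f"stage bias_stats ({config.fasta}): {exc}") from exc

    result = {
        "label": config.label or Path(config.fasta).stem,
        "windows": windows,
        "bins": bins,
        "cgc": curve,
        "bias": bias,
        "mean_gc": mean_gc,
        "n90_applied": n90_value,
    }
    if config.outdir is not None:
        out = Path(config.outdir)
        out.mkdir(parents=True, exist_ok=True)
        write_window_table(windows, out / "windows.tsv")
        bins.to_frame().to_csv(out / "bins.tsv", sep="\t", index=False)
        curve.to_csv(out / "cgc.tsv", sep="\t", index=False)
        (out / "bias.json").write_text(json.dumps(bias.to_dict(), indent=2))
        manifest = {
            "tool": "gcbias",
            "version": __version__,
            "config": asdict(config),
            "n_windows": len(windows),
            "n_bins": bins.n_bins,
            "n90_applied": n90_value,
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return result


def run_cohort(configs: Sequence[RunConfig], outdir: str | None = None) -> dict:
    """Profile many genomes and regress overall bias B on genome mean GC.

    Genomes failing the completeness/contamination gate are excluded and
    listed in the manifest.  Requires at least 3 retained genomes.
    """
    if len(configs) < 3:
        raise PipelineError("cohort mode needs at least 3 genomes")
    results, excluded = [], []
    for cfg in configs:
        ok, reason = genome_quality_filter(
            cfg.completeness,
            cfg.contamination,
            cfg.min_completeness,
            cfg.max_contamination,
        )
        if not ok:
            excluded.append({"label": cfg.label or Path(cfg.fasta).stem, "reason": reason})
            continue
        results.append(run_single_genome(cfg))
    if len(results) < 3:
        raise PipelineError(
            f"cohort mode needs at least 3 retained genomes "
            f"({len(excluded)} excluded by the quality filter)"
        )
    scatter = pd.DataFrame(
        {
            "label": [r["label"] for r in results],
            "mean_gc": [r["mean_gc"] for r in results],
            "B": [r["bias"].B for r in results],
        }
    )
    try:
        regression = bias_gc_regression(
            list(zip(scatter["mean_gc"], scatter["B"]))
        )
    except ValueError as exc:
        raise PipelineError(f"stage regression: {exc}") from exc
    out = {
        "results": results,
        "scatter": scatter,
        "regression": regression,
        "excluded": excluded,
    }
    if outdir is not None:
        path = Path(outdir)
        path.mkdir(parents=True, exist_ok=True)
        scatter.to_csv(path / "cohort_bias.tsv", sep="\t", index=False)
        (path / "regression.json").write_text(
            json.dumps(regression.to_dict(), indent=2)
        )
        manifest = {
            "tool": "gcbias",
            "version": __version__,
            "n_genomes": len(results),
            "excluded": excluded,
        }
        (path / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out
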