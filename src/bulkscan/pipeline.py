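"""End-to-end orchestration: scan a VCF, call intervals, nominate candidates.

These functions are what the command-line interface wraps. Each run writes
a machine-readable manifest (configuration + package version) alongside its
outputs so a result can be reproduced bit-exactly; numeric TSV/BED files
are the contract, the ED⁴ scatter image is a convenience artifact.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import __version__
from .candidate_genes import genes_in_intervals, rank_candidates, shared_degs, venn_counts
from .ed_mapping import (
    CandidateInterval,
    FilterParams,
    WindowStat,
    call_significant_intervals,
    ed_profile,
    filter_snps,
    window_scan,
)
from .variant_io import DataError, read_bulk_vcf, read_deg_table, read_gff3_genes

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of a scan/candidates run (CLI flags mirror these names)."""

    vcf: str | None = None
    mut_sample: str = "mut_bulk"
    wt_sample: str = "wt_bulk"
    gff3: str | None = None
    deg_tables: dict[str, str] = field(default_factory=dict)  # stage -> path
    min_depth: int = 3
    min_variant_freq: float = 0.05
    window: int = 100
    step: int = 1
    threshold: float = 4.0
    merge_gap_bp: int = 1_000_000
    out_dir: str = "bulkscan_out"
    seed: int = 1
    force: bool = False

    @property
    def filter_params(self) -> FilterParams:
        return FilterParams(min_depth=self.min_depth, min_variant_freq=self.min_variant_freq)


def _prepare_out_dir(config: RunConfig, filenames: Sequence[str]) -> Path:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if not config.force:
        existing = [f for f in filenames if (out / f).exists()]
        if existing:
            raise FileExistsError(
                f"outputs already present in {out}: {existing} (use force to overwrite)"
            )
    return out


def _write_manifest(out: Path, config: RunConfig, extra: dict) -> None:
    manifest = {
        "package": "bulkscan",
        "version": __version__,
        "config": dataclasses.asdict(config),
        **extra,
    }
    (out / "run_manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))


def windows_to_dataframe(windows: Sequence[WindowStat]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": [w.chrom for w in windows],
            "mid_bp": [w.mid_bp for w in windows],
            "start_bp": [w.start_bp for w in windows],
            "end_bp": [w.end_bp for w in windows],
            "n_snps": [w.n_snps for w in windows],
            "ed_sum": [w.ed_sum for w in windows],
            "ed4": [w.ed4 for w in windows],
        }
    )


def intervals_to_dataframe(intervals: Sequence[CandidateInterval]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": [iv.chrom for iv in intervals],
            "start_bp": [iv.start_bp for iv in intervals],
            "end_bp": [iv.end_bp for iv in intervals],
            "peak_ed4": [iv.peak_ed4 for iv in intervals],
            "n_windows": [iv.n_windows for iv in intervals],
        }
    )


def write_intervals_bed(intervals: Sequence[CandidateInterval], path: Path) -> None:
    """BED (0-based half-open) with peak ED⁴ in the score-ish 5th column."""
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            fh.write(
                f"{iv.chrom}\t{iv.start_bp - 1}\t{iv.end_bp}\tinterval_{i}\t{iv.peak_ed4:.6g}\n"
            )


def read_intervals_tsv(path: str | Path) -> list[CandidateInterval]:
    df = pd.read_csv(path, sep="\t")
    return [
        CandidateInterval(
            chrom=str(r.chrom),
            start_bp=int(r.start_bp),
            end_bp=int(r.end_bp),
            peak_ed4=float(r.peak_ed4),
            n_windows=int(r.n_windows),
        )
        for r in df.itertuples(index=False)
    ]


def plot_ed4_scatter(windows: Sequence[WindowStat], path: str | Path) -> None:
    """Per-chromosome scatter of window ED⁴ against genomic position (Mb)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    chroms = sorted({w.chrom for w in windows})
    n = max(len(chroms), 1)
    fig, axes = plt.subplots(1, n, figsize=(1.6 * n + 2, 3), sharey=True, squeeze=False)
    for ax, chrom in zip(axes[0], chroms):
        ws = [w for w in windows if w.chrom == chrom]
        ax.scatter([w.mid_bp / 1e6 for w in ws], [w.ed4 for w in ws], s=3, color="tab:red")
        ax.set_title(chrom, fontsize=8)
        ax.tick_params(labelsize=6)
    if chroms:
        axes[0][0].set_ylabel("ED$^4$")
        fig.supxlabel("position (Mb)", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


SCAN_OUTPUTS = ("windows.tsv", "intervals.tsv", "intervals.bed", "ed4_scatter.png")


def run_scan(config: RunConfig) -> tuple[list[WindowStat], list[CandidateInterval]]:
    """Full mapping scan: VCF → filter → ED profile → windows → intervals.

    Writes windows.tsv, intervals.tsv, intervals.bed, an ED⁴ scatter image
    and the run manifest into ``config.out_dir``. Deterministic for fixed
    inputs and configuration; an empty post-filter SNP set yields empty
    outputs with a warning rather than an error.
    """
    if not config.vcf:
        raise DataError("run_scan requires a vcf path")
    out = _prepare_out_dir(config, SCAN_OUTPUTS)
    observations = read_bulk_vcf(config.vcf, config.mut_sample, config.wt_sample)
    kept = filter_snps(observations, config.filter_params)
    logger.info("scan: %d SNPs read, %d retained after filtering", len(observations), len(kept))
    if not kept:
        logger.warning("scan: no SNPs pass the filters; writing empty outputs")
    eds = ed_profile(kept)
    windows = window_scan(eds, window=config.window, step=config.step)
    intervals = call_significant_intervals(
        windows, threshold=config.threshold, merge_gap_bp=config.merge_gap_bp
    )
    logger.info("scan: %d windows, %d significant intervals", len(windows), len(intervals))

    windows_to_dataframe(windows).to_csv(out / "windows.tsv", sep="\t", index=False)
    intervals_to_dataframe(intervals).to_csv(out / "intervals.tsv", sep="\t", index=False)
    write_intervals_bed(intervals, out / "intervals.bed")
    plot_ed4_scatter(windows, out / "ed4_scatter.png")
    _write_manifest(
        out,
        config,
        {
            "n_snps_read": len(observations),
            "n_snps_filtered": len(kept),
            "n_windows": len(windows),
            "n_intervals": len(intervals),
        },
    )
    return windows, intervals


CANDIDATE_OUTPUTS = ("candidates.tsv", "venn_counts.tsv")


def run_candidates(
    config: RunConfig, intervals: Sequence[CandidateInterval] | None = None
) -> pd.DataFrame:
    """Interval × stage-shared-DEG intersection, written as candidates.tsv.

    ``intervals`` defaults to the intervals.tsv of a previous scan in the
    same output directory. Requires a GFF3 and at least two stage DEG
    tables; duplicate stage labels are a hard error.
    """
    if not config.gff3:
        raise DataError("run_candidates requires a gff3 path")
    if len(config.deg_tables) < 2:
        raise DataError("run_candidates requires DEG tables for at least two stages")
    out = _prepare_out_dir(config, CANDIDATE_OUTPUTS)
    if intervals is None:
        intervals_path = out / "intervals.tsv"
        if not intervals_path.exists():
            raise DataError(f"no intervals given and {intervals_path} not found; run scan first")
        intervals = read_intervals_tsv(intervals_path)

    genes = read_gff3_genes(config.gff3)
    deg_records = []
    stage_sets: dict[str, set[str]] = {}
    for stage, path in config.deg_tables.items():
        records = read_deg_table(path, stage)
        deg_records.extend(records)
        stage_sets[stage] = {r.gene_id for r in records}
    shared = shared_degs(stage_sets)
    pairs = genes_in_intervals(genes, list(intervals))
    candidates = rank_candidates(pairs, shared, deg_records)
    if not candidates:
        logger.warning("candidates: no stage-shared DEG falls in a significant interval")

    stages = sorted(stage_sets)
    df = pd.DataFrame(
        {
            "gene_id": [c.gene_id for c in candidates],
            "chrom": [c.chrom for c in candidates],
            "start_bp": [c.start_bp for c in candidates],
            "end_bp": [c.end_bp for c in candidates],
            "interval": [
                f"{c.interval.chrom}:{c.interval.start_bp}-{c.interval.end_bp}"
                for c in candidates
            ],
            "stages": [",".join(sorted(c.stages)) for c in candidates],
            **{
                f"log2fc_{s}": [c.log2fc.get(s, float("nan")) for c in candidates]
                for s in stages
            },
        }
    )
    df.to_csv(out / "candidates.tsv", sep="\t", index=False)

    venn = venn_counts(stage_sets)
    venn_df = pd.DataFrame(
        {
            "region": ["&".join(sorted(k)) for k in sorted(venn, key=lambda k: (len(k), sorted(k)))],
            "n_genes": [venn[k] for k in sorted(venn, key=lambda k: (len(k), sorted(k)))],
        }
    )
    venn_df.to_csv(out / "venn_counts.tsv", sep="\t", index=False)
    _write_manifest(
        out,
        config,
        {
            "n_genes": len(genes),
            "n_shared_degs": len(shared),
            "n_candidates": len(candidates),
        },
    )
    return df
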