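r"""Euclidean-distance (ED / ED⁴) genome scan for bulked-segregant mapping.

For each SNP the statistic compares the nucleotide composition of the two
phenotype bulks:

.. math::

    \mathrm{ED}_{SNP} = \sqrt{(A_m-A_w)^2 + (C_m-C_w)^2 + (G_m-G_w)^2 + (T_m-T_w)^2}

where each letter is the read frequency of that nucleotide in the mutant
(:math:`m`) or wild-type (:math:`w`) bulk. ED_SNP is 0 when the bulks have
identical composition and reaches its maximum √2 when they are fixed for
different bases. ED is the sum of ED_SNP over a window of 100 consecutive
SNPs (the window slides one SNP at a time by default), and ED⁴ — ED raised
to the fourth power — sharpens real peaks against background noise.
Windows whose ED⁴ exceeds a significance cutoff are merged into candidate
intervals.

SNPs are pre-filtered: both bulks need read depth ≥ 3 and the pooled
non-reference allele frequency must be ≥ 0.05, the defaults used for
20×-per-bulk maize pools.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .variant_io import NUCLEOTIDES, BulkAlleleObservation

#: Analytic maximum of ED_SNP (opposite fixation of the two bulks).
ED_MAX = math.sqrt(2.0)


@dataclass(frozen=True)
class FilterParams:
    """SNP inclusion thresholds applied before the scan."""

    min_depth: int = 3
    min_variant_freq: float = 0.05

    def __post_init__(self) -> None:
        if self.min_depth < 0:
            raise ValueError("min_depth must be >= 0")
        if not 0.0 <= self.min_variant_freq <= 1.0:
            raise ValueError("min_variant_freq must be in [0, 1]")


@dataclass(frozen=True)
class NucleotideFrequencies:
    """Read frequencies of the four nucleotides within one bulk."""

    fA: float
    fC: float
    fG: float
    fT: float

    @classmethod
    def from_counts(cls, counts) -> "NucleotideFrequencies":
        total = sum(counts.get(b, 0) for b in NUCLEOTIDES)
        if total <= 0:
            raise ValueError("zero-depth bulk: nucleotide frequencies undefined")
        return cls(*(counts.get(b, 0) / total for b in NUCLEOTIDES))

    def as_array(self) -> np.ndarray:
        return np.array([self.fA, self.fC, self.fG, self.fT], dtype=float)


@dataclass(frozen=True)
class SnpEd:
    """Per-SNP Euclidean distance between the two bulks."""

    chrom: str
    pos: int
    ed: float


@dataclass(frozen=True)
class WindowStat:
    """One window of consecutive SNPs and its ED / ED⁴ statistic.

    SNP indices are 0-based inclusive within the chromosome's SNP order;
    ``mid_bp`` is the position of the window's median SNP (the lower median
    for an even window size) and anchors the window when plotting.
    """

    chrom: str
    first_snp_index: int
    last_snp_index: int
    start_bp: int
    end_bp: int
    mid_bp: int
    ed_sum: float
    ed4: float
    n_snps: int


@dataclass(frozen=True)
class CandidateInterval:
    """Merged genomic span of significant windows on one chromosome."""

    chrom: str
    start_bp: int
    end_bp: int
    peak_ed4: float
    n_windows: int

    def __post_init__(self) -> None:
        if self.start_bp > self.end_bp:
            raise ValueError("interval start after end")

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start_bp <= pos <= self.end_bp


# ---------------------------------------------------------------------------
# filtering


def filter_snps(
    observations: Sequence[BulkAlleleObservation],
    params: FilterParams = FilterParams(),
    *,
    per_bulk_freq: bool = False,
) -> list[BulkAlleleObservation]:
    """Drop low-coverage and near-monomorphic SNPs, preserving order.

    A record is retained when BOTH bulks have depth ≥ ``min_depth`` and the
    variant (non-reference) read frequency is ≥ ``min_variant_freq``. By
    default the frequency is pooled over both bulks; ``per_bulk_freq=True``
    instead requires each bulk to pass on its own.
    """
    kept: list[BulkAlleleObservation] = []
    for obs in observations:
        d_mut, d_wt = obs.depth_mut, obs.depth_wt
        if d_mut < params.min_depth or d_wt < params.min_depth:
            continue
        ref_mut = obs.counts_mut.get(obs.ref_base, 0)
        ref_wt = obs.counts_wt.get(obs.ref_base, 0)
        if per_bulk_freq:
            ok = all(
                depth > 0 and (depth - ref) / depth >= params.min_variant_freq
                for depth, ref in ((d_mut, ref_mut), (d_wt, ref_wt))
            )
        else:
            total = d_mut + d_wt
            ok = total > 0 and (total - ref_mut - ref_wt) / total >= params.min_variant_freq
        if ok:
            kept.append(obs)
    return kept


# ---------------------------------------------------------------------------
# per-SNP statistic


def ed_snp(mut, wt) -> float:
    """Euclidean distance between two bulks' nucleotide frequency vectors.

    Accepts :class:`NucleotideFrequencies` or any length-4 sequence ordered
    A, C, G, T. Symmetric in its arguments; ranges from 0 to √2.
    """
    m = mut.as_array() if isinstance(mut, NucleotideFrequencies) else np.asarray(mut, float)
    w = wt.as_array() if isinstance(wt, NucleotideFrequencies) else np.asarray(wt, float)
    if m.shape != (4,) or w.shape != (4,):
        raise ValueError("expected 4 nucleotide frequencies per bulk")
    return float(np.sqrt(np.sum((m - w) ** 2)))


def ed_profile(observations: Sequence[BulkAlleleObservation]) -> list[SnpEd]:
    """Compute ED_SNP for every observation (vectorised).

    Raises ``ValueError`` on a zero-depth bulk — such records should have
    been removed by :func:`filter_snps`.
    """
    if not observations:
        return []
    counts_mut = np.array(
        [[o.counts_mut.get(b, 0) for b in NUCLEOTIDES] for o in observations], float
    )
    counts_wt = np.array(
        [[o.counts_wt.get(b, 0) for b in NUCLEOTIDES] for o in observations], float
    )
    depth_mut = counts_mut.sum(axis=1)
    depth_wt = counts_wt.sum(axis=1)
    bad = np.flatnonzero((depth_mut == 0) | (depth_wt == 0))
    if bad.size:
        o = observations[bad[0]]
        raise ValueError(f"zero-depth bulk at {o.chrom}:{o.pos}; filter first")
    freq_mut = counts_mut / depth_mut[:, None]
    freq_wt = counts_wt / depth_wt[:, None]
    eds = np.sqrt(((freq_mut - freq_wt) ** 2).sum(axis=1))
    return [
        SnpEd(chrom=o.chrom, pos=o.pos, ed=float(e)) for o, e in zip(observations, eds)
    ]


# ---------------------------------------------------------------------------
# windowing


def _chromosome_runs(eds: Sequence[SnpEd]) -> list[tuple[str, int, int]]:
    """Split the SNP list into per-chromosome runs, validating sort order."""
    runs: list[tuple[str, int, int]] = []
    seen: set[str] = set()
    i = 0
    n = len(eds)
    while i < n:
        chrom = eds[i].chrom
        if chrom in seen:
            raise ValueError(f"input not grouped by chromosome: {chrom} reappears")
        seen.add(chrom)
        j = i
        while j + 1 < n and eds[j + 1].chrom == chrom:
            if eds[j + 1].pos < eds[j].pos:
                raise ValueError(
                    f"input not sorted by position on {chrom} near {eds[j].pos}"
                )
            j += 1
        runs.append((chrom, i, j + 1))
        i = j + 1
    return runs


def window_scan(
    eds: Sequence[SnpEd], window: int = 100, step: int = 1
) -> list[WindowStat]:
    """Slide a ``window``-SNP window along each chromosome and sum ED_SNP.

    Emits one :class:`WindowStat` per window position (advancing ``step``
    SNPs at a time) with ED = Σ ED_SNP and ED⁴ = ED⁴. Windows never span
    chromosomes; a chromosome with fewer than ``window`` SNPs yields none.
    Input must be sorted by (chromosome, position) — unsorted input is a
    hard error.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    if step < 1:
        raise ValueError("step must be >= 1")
    out: list[WindowStat] = []
    for chrom, lo, hi in _chromosome_runs(eds):
        run = eds[lo:hi]
        n = len(run)
        if n < window:
            continue
        vals = np.array([s.ed for s in run])
        pos = np.array([s.pos for s in run])
        csum = np.concatenate([[0.0], np.cumsum(vals)])
        for first in range(0, n - window + 1, step):
            last = first + window - 1
            ed_sum = float(csum[first + window] - csum[first])
            out.append(
                WindowStat(
                    chrom=chrom,
                    first_snp_index=first,
                    last_snp_index=last,
                    start_bp=int(pos[first]),
                    end_bp=int(pos[last]),
                    mid_bp=int(pos[first + (window - 1) // 2]),
                    ed_sum=ed_sum,
                    ed4=ed_sum**4,
                    n_snps=window,
                )
            )
    return out


# ---------------------------------------------------------------------------
# interval calling


def call_significant_intervals(
    windows: Iterable[WindowStat],
    threshold: float = 4.0,
    merge_gap_bp: int = 1_000_000,
) -> list[CandidateInterval]:
    """Call candidate intervals from windows whose ED⁴ strictly exceeds ``threshold``.

    Significant windows on the same chromosome are merged when their spans
    overlap or lie within ``merge_gap_bp`` of each other; each merged
    interval reports the union span, its peak ED⁴ and the number of member
    windows. Output is sorted by (chromosome, start).
    """
    selected = [w for w in windows if w.ed4 > threshold]
    by_chrom: dict[str, list[WindowStat]] = {}
    for w in selected:
        by_chrom.setdefault(w.chrom, []).append(w)
    intervals: list[CandidateInterval] = []
    for chrom in sorted(by_chrom):
        ws = sorted(by_chrom[chrom], key=lambda w: (w.start_bp, w.end_bp))
        cur_start, cur_end = ws[0].start_bp, ws[0].end_bp
        cur_peak, cur_n = ws[0].ed4, 1
        for w in ws[1:]:
            if w.start_bp <= cur_end + merge_gap_bp:
                cur_end = max(cur_end, w.end_bp)
                cur_peak = max(cur_peak, w.ed4)
                cur_n += 1
            else:
                intervals.append(
                    CandidateInterval(chrom, cur_start, cur_end, cur_peak, cur_n)
                )
                cur_start, cur_end, cur_peak, cur_n = w.start_bp, w.end_bp, w.ed4, 1
        intervals.append(CandidateInterval(chrom, cur_start, cur_end, cur_peak, cur_n))
    intervals.sort(key=lambda iv: (iv.chrom, iv.start_bp))
    return intervals


def top_interval(intervals: Sequence[CandidateInterval]) -> CandidateInterval | None:
    """The interval with the highest peak ED⁴ (leftmost on ties)."""
    if not intervals:
        return None
    return min(intervals, key=lambda iv: (-iv.peak_ed4, iv.chrom, iv.start_bp))
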