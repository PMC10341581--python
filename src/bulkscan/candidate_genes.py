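"""Candidate-gene nomination: significant intervals × stage-shared DEGs.

The mapping scan yields candidate intervals; RNA-seq yields per-stage sets
of differentially expressed genes (DEGs). A gene becomes a candidate when
it (a) overlaps a significant interval and (b) is differentially expressed
at every profiled developmental stage. Overlap means sharing at least one
base pair with the interval (computed in 0-based half-open space); strict
containment is available as an option. DEG identity is by gene_id string —
no cross-annotation ID mapping is attempted — and direction of change is
not required for candidacy: the stage sets are intersected undirected.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping, Sequence

from intervaltree import IntervalTree

from .ed_mapping import CandidateInterval
from .variant_io import DegRecord, GeneModel

StageSets = Mapping[str, frozenset[str] | set[str]]


def shared_degs(stage_sets: StageSets) -> set[str]:
    """Genes differentially expressed at every stage (intersection over stages)."""
    if len(stage_sets) < 2:
        raise ValueError("need at least two stages to intersect")
    sets = [set(s) for s in stage_sets.values()]
    return set.intersection(*sets)


def venn_counts(stage_sets: StageSets) -> dict[frozenset[str], int]:
    """Exclusive Venn region sizes for the given stage sets.

    For three stages this returns the 7 regions (each keyed by the exact
    set of stages its genes belong to); the region sizes sum to the size of
    the union.
    """
    stages = list(stage_sets)
    sets = {s: set(stage_sets[s]) for s in stages}
    regions: dict[frozenset[str], int] = {}
    for r in range(1, len(stages) + 1):
        for members in combinations(stages, r):
            inside = set.intersection(*(sets[s] for s in members))
            for s in stages:
                if s not in members:
                    inside -= sets[s]
            regions[frozenset(members)] = len(inside)
    return regions


@dataclass(frozen=True)
class CandidateGene:
    """A stage-shared DEG lying in a significant mapping interval."""

    gene_id: str
    chrom: str
    start_bp: int
    end_bp: int
    interval: CandidateInterval
    stages: frozenset[str] = frozenset()
    log2fc: Mapping[str, float] = field(default_factory=dict)


def genes_in_intervals(
    genes: Sequence[GeneModel],
    intervals: Sequence[CandidateInterval],
    *,
    containment: bool = False,
) -> list[tuple[GeneModel, CandidateInterval]]:
    """Pair every gene with every interval it overlaps (≥1 shared bp).

    Gene coordinates (1-based inclusive) are converted to 0-based half-open
    before the query, so touching-but-adjacent features do not match. With
    ``containment=True`` the gene must lie entirely inside the interval.
    """
    trees: dict[str, IntervalTree] = {}
    for idx, iv in enumerate(intervals):
        # 1-based inclusive [start, end] -> 0-based half-open [start-1, end)
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start_bp - 1, iv.end_bp, idx)
    pairs: list[tuple[GeneModel, CandidateInterval]] = []
    for gene in genes:
        tree = trees.get(gene.chrom)
        if tree is None:
            continue
        g0, g1 = gene.start - 1, gene.end
        for hit in sorted(tree.overlap(g0, g1), key=lambda h: h.data):
            iv = intervals[hit.data]
            if containment and not (iv.start_bp <= gene.start and gene.end <= iv.end_bp):
                continue
            pairs.append((gene, iv))
    return pairs


def rank_candidates(
    pairs: Iterable[tuple[GeneModel, CandidateInterval]],
    shared: set[str],
    deg_records: Sequence[DegRecord] | None = None,
) -> list[CandidateGene]:
    """Keep in-interval genes that are stage-shared DEGs; sort by position.

    When per-stage DEG records are supplied, each candidate is annotated
    with the stages where it is differentially expressed and its per-stage
    log2 fold change.
    """
    per_gene_stages: dict[str, set[str]] = {}
    per_gene_fc: dict[str, dict[str, float]] = {}
    for rec in deg_records or ():
        per_gene_stages.setdefault(rec.gene_id, set()).add(rec.stage)
        per_gene_fc.setdefault(rec.gene_id, {})[rec.stage] = rec.log2fc
    out = [
        CandidateGene(
            gene_id=gene.gene_id,
            chrom=gene.chrom,
            start_bp=gene.start,
            end_bp=gene.end,
            interval=interval,
            stages=frozenset(per_gene_stages.get(gene.gene_id, set())),
            log2fc=per_gene_fc.get(gene.gene_id, {}),
        )
        for gene, interval in pairs
        if gene.gene_id in shared
    ]
    out.sort(key=lambda c: (c.chrom, c.start_bp, c.gene_id))
    return out
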