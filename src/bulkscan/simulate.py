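"""Synthetic F2 bulked-segregant experiment and DEG-table generator.

The simulator reproduces the statistical structure a single-locus recessive
BSA-Seq experiment assumes: an F2 population from two fully informative
inbred parents segregating one causal locus, two phenotype bulks of plants
sampled by ear phenotype, and shotgun read counts per marker per bulk. Its
defaults mirror the study design the pipeline targets — bulks of 30 plants
each, ~20× mean read depth per bulk, markers spread over the 10 maize
chromosomes — so a default run exercises every pipeline stage end to end.

Recombination uses the Haldane (no-interference) model: per gamete and
chromosome the number of crossovers is Poisson with mean equal to the
genetic length in Morgans, crossover positions are uniform on the genetic
map, and the physical-to-genetic map is linear within a chromosome. Parent
A contributes the reference base and parent B the alternate base at every
marker, so every marker is fully informative; the recessive mutant allele
(rk1) rides on the parent-B haplotype.

At the causal marker the mutant (reversed-ear) bulk is fixed for the mutant
allele while the normal-ear bulk — a ⅓ +/+ : ⅔ rk1/+ genotype mixture in
expectation — has expected mutant-allele frequency ⅓, giving an expected
per-SNP Euclidean distance of (2/3)·√2 ≈ 0.943 at the locus and a decay
with genetic distance on either side.

A second generator builds per-stage DEG tables with an exactly prescribed
Venn structure, so the set-intersection step can be tested against known
region sizes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .segregation import EarPhenotype, PlantGenotype, ear_phenotype
from .variant_io import (
    NUCLEOTIDES,
    BulkAlleleObservation,
    GeneModel,
    write_bulk_vcf,
    write_gff3_genes,
)


@dataclass(frozen=True)
class ChromosomeSpec:
    """One chromosome's physical and genetic length."""

    name: str
    length_bp: int
    length_cm: float


#: Approximate B73 chromosome physical lengths with a flat 150 cM genetic
#: length each (maize consensus map ≈ 1500 cM total).
MAIZE_CHROMOSOMES: tuple[ChromosomeSpec, ...] = tuple(
    ChromosomeSpec(f"chr{i + 1}", length_bp, 150.0)
    for i, length_bp in enumerate(
        [
            307_000_000,
            244_000_000,
            235_000_000,
            247_000_000,
            224_000_000,
            174_000_000,
            182_000_000,
            181_000_000,
            160_000_000,
            151_000_000,
        ]
    )
)


@dataclass(frozen=True)
class BsaSimParams:
    """Design parameters of the simulated BSA-Seq experiment.

    Defaults follow the target study design: two bulks of 30 F2 plants
    (reversed-kernel vs normal-kernel ears), ~20× mean depth per bulk,
    2,000 markers per chromosome over 10 chromosomes, causal locus on chr9.
    ``n_plants`` is the F2 population size the bulks are drawn from;
    ``misassignment_rate`` lets a plant be bulked under the wrong phenotype
    label for robustness experiments (default 0 = full penetrance).
    """

    chromosomes: tuple[ChromosomeSpec, ...] = MAIZE_CHROMOSOMES
    markers_per_chrom: int = 2000
    causal: tuple[str, int] = ("chr9", 106_000_000)
    n_plants: int = 240
    n_mut_bulk: int = 30
    n_wt_bulk: int = 30
    depth_per_bulk: float = 20.0
    error_rate: float = 0.001
    misassignment_rate: float = 0.0
    seed: int = 1

    def __post_init__(self) -> None:
        names = [c.name for c in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome names")
        chrom, pos = self.causal
        spec = {c.name: c for c in self.chromosomes}.get(chrom)
        if spec is None:
            raise ValueError(f"causal chromosome {chrom!r} not in chromosome list")
        if not 1 <= pos <= spec.length_bp:
            raise ValueError(f"causal position {pos} outside {chrom} (1..{spec.length_bp})")
        for name, value in [
            ("markers_per_chrom", self.markers_per_chrom),
            ("n_plants", self.n_plants),
            ("n_mut_bulk", self.n_mut_bulk),
            ("n_wt_bulk", self.n_wt_bulk),
        ]:
            if value < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.depth_per_bulk <= 0:
            raise ValueError("depth_per_bulk must be > 0")
        if not 0 <= self.error_rate < 1:
            raise ValueError("error_rate must be in [0, 1)")


_DOSE_TO_GENOTYPE = {0: PlantGenotype.WILD, 1: PlantGenotype.HET, 2: PlantGenotype.MUTANT}


@dataclass
class BsaTruth:
    """Ground truth of one simulated experiment, for recovery tests.

    ``genotypes[chrom]`` holds parent-B allele indicators with shape
    (n_plants, 2 gametes, n_loci); allele 1 is the parent-B (alt, mutant
    at the causal locus) allele. ``marker_positions`` includes the causal
    locus itself as a marker on its chromosome (``causal_index`` gives its
    column). Bulk membership and the per-marker true bulk allele
    frequencies are precomputed from the ear phenotypes.
    """

    params: BsaSimParams
    marker_positions: dict[str, np.ndarray]
    genotypes: dict[str, np.ndarray]
    causal_index: int
    plant_genotypes: np.ndarray  # causal-locus mutant-allele dose per plant (0/1/2)
    phenotypes: np.ndarray  # "N"/"R" per plant, after any misassignment
    mut_bulk_plants: np.ndarray
    wt_bulk_plants: np.ndarray
    bulk_alt_freq: dict[str, dict[str, np.ndarray]] = field(default_factory=dict)

    @property
    def causal_chrom(self) -> str:
        return self.params.causal[0]

    @property
    def causal_pos(self) -> int:
        return self.params.causal[1]


def _marker_positions(spec: ChromosomeSpec, n_markers: int, causal_pos: int | None) -> np.ndarray:
    """Evenly spaced marker positions, with the causal site inserted as a marker."""
    pos = np.linspace(1, spec.length_bp, n_markers, dtype=np.int64)
    if causal_pos is not None and causal_pos not in pos:
        pos = np.sort(np.append(pos, np.int64(causal_pos)))
    return pos


def _simulate_gametes(
    rng: np.random.Generator, cm_pos: np.ndarray, length_cm: float, n_gametes: int
) -> np.ndarray:
    """Parent-B indicators for ``n_gametes`` recombinant gametes at each locus.

    Haldane model: crossover count ~ Poisson(length in Morgans), positions
    uniform on the genetic map, starting phase fair. The allele at a locus
    is the starting allele flipped once per crossover to its left.
    """
    n_xo = rng.poisson(length_cm / 100.0, size=n_gametes)
    start = rng.integers(0, 2, size=n_gametes, dtype=np.int8)
    alleles = np.empty((n_gametes, cm_pos.size), dtype=np.int8)
    for k in np.unique(n_xo):
        idx = np.flatnonzero(n_xo == k)
        if k == 0:
            alleles[idx] = start[idx, None]
            continue
        xo = rng.uniform(0.0, length_cm, size=(idx.size, k))
        parity = (xo[:, :, None] < cm_pos[None, None, :]).sum(axis=1).astype(np.int8) & 1
        alleles[idx] = start[idx, None] ^ parity
    return alleles


def simulate_f2_population(params: BsaSimParams = BsaSimParams()) -> BsaTruth:
    """Simulate an F2 population and assemble the two phenotype bulks.

    Every plant receives two independent recombinant gametes per chromosome
    from a uniformly heterozygous F1. Ear phenotype follows the
    sporophyte-determined recessive model (reversed iff the plant is
    homozygous mutant at the causal locus); bulks take the first
    ``n_mut_bulk`` reversed-ear and ``n_wt_bulk`` normal-ear plants.

    Raises ``ValueError`` when a phenotype class is too small to fill its
    bulk — enlarge ``n_plants`` or re-seed.
    """
    rng = np.random.default_rng(params.seed)
    causal_chrom, causal_pos = params.causal

    marker_positions: dict[str, np.ndarray] = {}
    genotypes: dict[str, np.ndarray] = {}
    causal_index = -1
    for spec in params.chromosomes:
        on_causal = spec.name == causal_chrom
        pos = _marker_positions(spec, params.markers_per_chrom, causal_pos if on_causal else None)
        marker_positions[spec.name] = pos
        cm_pos = pos / spec.length_bp * spec.length_cm
        gam = _simulate_gametes(rng, cm_pos, spec.length_cm, 2 * params.n_plants)
        genotypes[spec.name] = gam.reshape(params.n_plants, 2, pos.size)
        if on_causal:
            causal_index = int(np.searchsorted(pos, causal_pos))

    dose = genotypes[causal_chrom][:, :, causal_index].sum(axis=1)
    phen = np.where(dose == 2, "R", "N")
    if params.misassignment_rate > 0:
        flip = rng.random(params.n_plants) < params.misassignment_rate
        phen = np.where(flip, np.where(phen == "R", "N", "R"), phen)

    mut_idx = np.flatnonzero(phen == "R")
    wt_idx = np.flatnonzero(phen == "N")
    if mut_idx.size < params.n_mut_bulk or wt_idx.size < params.n_wt_bulk:
        raise ValueError(
            f"cannot fill bulks: {mut_idx.size} reversed / {wt_idx.size} normal plants "
            f"for bulks of {params.n_mut_bulk}/{params.n_wt_bulk}; "
            "increase n_plants or change seed"
        )
    mut_bulk = mut_idx[: params.n_mut_bulk]
    wt_bulk = wt_idx[: params.n_wt_bulk]

    bulk_alt_freq: dict[str, dict[str, np.ndarray]] = {"mut": {}, "wt": {}}
    for name, geno in genotypes.items():
        bulk_alt_freq["mut"][name] = geno[mut_bulk].sum(axis=1).mean(axis=0) / 2.0
        bulk_alt_freq["wt"][name] = geno[wt_bulk].sum(axis=1).mean(axis=0) / 2.0

    return BsaTruth(
        params=params,
        marker_positions=marker_positions,
        genotypes=genotypes,
        causal_index=causal_index,
        plant_genotypes=dose.astype(np.int8),
        phenotypes=phen,
        mut_bulk_plants=mut_bulk,
        wt_bulk_plants=wt_bulk,
        bulk_alt_freq=bulk_alt_freq,
    )


def causal_genotype(truth: BsaTruth, plant: int) -> PlantGenotype:
    """Genotype of one plant at the causal locus."""
    return _DOSE_TO_GENOTYPE[int(truth.plant_genotypes[plant])]


def plant_ear_phenotype(truth: BsaTruth, plant: int) -> EarPhenotype:
    """Ear phenotype of one plant under the sporophyte-determined model."""
    return ear_phenotype(causal_genotype(truth, plant))


def bulk_and_sequence(
    truth: BsaTruth,
    params: BsaSimParams | None = None,
    vcf_path: str | Path | None = None,
) -> list[BulkAlleleObservation]:
    """Draw sequencing reads for both bulks and optionally write a VCF.

    Per marker and bulk the total depth is Poisson(``depth_per_bulk``); each
    read samples a true base from the bulk's allele frequency and is
    miscalled to a uniformly chosen other base with ``error_rate``. REF/ALT
    bases are assigned per marker (REF uniform over A/C/G/T, ALT uniform
    over the rest); error reads on a third base extend the record's ALT
    list so the VCF ``AD`` field accounts for every read.
    """
    params = params or truth.params
    rng = np.random.default_rng(np.random.SeedSequence([params.seed, 17]))
    e = params.error_rate
    observations: list[BulkAlleleObservation] = []
    for spec in params.chromosomes:
        name = spec.name
        pos = truth.marker_positions[name]
        m = pos.size
        ref_idx = rng.integers(0, 4, size=m)
        alt_offset = rng.integers(1, 4, size=m)
        alt_idx = (ref_idx + alt_offset) % 4

        counts = {}
        for bulk in ("mut", "wt"):
            f_alt = truth.bulk_alt_freq[bulk][name]
            depth = rng.poisson(params.depth_per_bulk, size=m)
            # per-base sampling probabilities: true base drawn from (ref, alt)
            # frequency, then miscalled uniformly to one of the 3 other bases
            p = np.full((m, 4), 0.0)
            p[np.arange(m), ref_idx] = (1 - f_alt) * (1 - e)
            p[np.arange(m), alt_idx] = f_alt * (1 - e)
            p += ((1 - f_alt)[:, None] * _other_base_mask(ref_idx)
                  + f_alt[:, None] * _other_base_mask(alt_idx)) * (e / 3.0)
            counts[bulk] = rng.multinomial(depth, p)

        for j in range(m):
            ref = NUCLEOTIDES[ref_idx[j]]
            alt = NUCLEOTIDES[alt_idx[j]]
            extra = [
                NUCLEOTIDES[b]
                for b in range(4)
                if b not in (ref_idx[j], alt_idx[j])
                and (counts["mut"][j, b] or counts["wt"][j, b])
            ]
            observations.append(
                BulkAlleleObservation(
                    chrom=name,
                    pos=int(pos[j]),
                    ref_base=ref,
                    alt_bases=(alt, *extra),
                    counts_mut={b: int(counts["mut"][j, k]) for k, b in enumerate(NUCLEOTIDES)},
                    counts_wt={b: int(counts["wt"][j, k]) for k, b in enumerate(NUCLEOTIDES)},
                )
            )
    if vcf_path is not None:
        write_bulk_vcf(observations, vcf_path)
    return observations


def _other_base_mask(idx: np.ndarray) -> np.ndarray:
    """(m, 4) mask that is 1 on the three bases other than ``idx`` per row."""
    m = idx.size
    mask = np.ones((m, 4))
    mask[np.arange(m), idx] = 0.0
    return mask


def simulate_bsa_experiment(
    params: BsaSimParams = BsaSimParams(), vcf_path: str | Path | None = None
) -> tuple[BsaTruth, list[BulkAlleleObservation]]:
    """Convenience wrapper: population + bulks + reads in one call."""
    truth = simulate_f2_population(params)
    observations = bulk_and_sequence(truth, params, vcf_path)
    return truth, observations


def write_truth_tsv(truth: BsaTruth, path: str | Path) -> None:
    """Write the causal locus and per-plant genotype/phenotype/bulk table."""
    bulk = np.full(truth.params.n_plants, "", dtype=object)
    bulk[truth.mut_bulk_plants] = "mut"
    bulk[truth.wt_bulk_plants] = "wt"
    df = pd.DataFrame(
        {
            "plant": np.arange(truth.params.n_plants),
            "causal_chrom": truth.causal_chrom,
            "causal_pos": truth.causal_pos,
            "genotype": [causal_genotype(truth, i).value for i in range(truth.params.n_plants)],
            "ear_phenotype": truth.phenotypes,
            "bulk": bulk,
        }
    )
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# synthetic gene models


def simulate_gene_models(
    chromosomes: Sequence[ChromosomeSpec] = MAIZE_CHROMOSOMES,
    genes_per_chrom: int = 100,
    gene_length_bp: int = 4000,
    seed: int = 1,
    gff3_path: str | Path | None = None,
) -> list[GeneModel]:
    """Uniformly placed synthetic gene models, optionally written as GFF3."""
    rng = np.random.default_rng(seed)
    genes: list[GeneModel] = []
    for spec in chromosomes:
        starts = np.sort(
            rng.integers(1, spec.length_bp - gene_length_bp + 1, size=genes_per_chrom)
        )
        for i, s in enumerate(starts):
            genes.append(
                GeneModel(
                    gene_id=f"GSYN_{spec.name}_{i:04d}",
                    chrom=spec.name,
                    start=int(s),
                    end=int(s) + gene_length_bp - 1,
                    strand="+" if rng.random() < 0.5 else "-",
                )
            )
    if gff3_path is not None:
        write_gff3_genes(genes, gff3_path)
    return genes


# ---------------------------------------------------------------------------
# DEG tables with a prescribed Venn structure

#: Default three-stage Venn region sizes. Stage totals III=2918, IV=827 and
#: the triple intersection 307 follow the target study; stage V uses the
#: component (up+down = 804+847 = 1651) total. Pairwise-only overlaps are
#: not reported there and are set to plausible values consistent with the
#: totals.
DEFAULT_VENN_REGIONS: dict[frozenset[str], int] = {
    frozenset({"III"}): 2161,
    frozenset({"IV"}): 270,
    frozenset({"V"}): 944,
    frozenset({"III", "IV"}): 150,
    frozenset({"III", "V"}): 300,
    frozenset({"IV", "V"}): 100,
    frozenset({"III", "IV", "V"}): 307,
}


def simulate_deg_tables(
    region_sizes: Mapping[frozenset[str], int] | None = None,
    stages: Sequence[str] = ("III", "IV", "V"),
    gene_pool: Sequence[str] | None = None,
    seed: int = 1,
    out_dir: str | Path | None = None,
) -> dict[str, pd.DataFrame]:
    """Build per-stage DEG tables whose Venn diagram matches ``region_sizes``.

    Each Venn region (keyed by the exact stage subset its genes belong to)
    receives distinct gene ids, so stage set sizes and all pairwise/triple
    intersections are exact by construction. log2 fold changes are drawn as
    ±Uniform(0.58, 4) (|log2FC| ≥ 0.58 ≈ 1.5-fold) independently per stage,
    adjusted p-values as Uniform(0, 0.05). With ``out_dir`` set, one
    ``deg_stage_<stage>.tsv`` per stage is written.
    """
    rng = np.random.default_rng(seed)
    regions = dict(DEFAULT_VENN_REGIONS) if region_sizes is None else dict(region_sizes)
    for subset, size in regions.items():
        if size < 0:
            raise ValueError(f"negative region size for {sorted(subset)}")
        if not subset or not set(subset).issubset(stages):
            raise ValueError(f"region {sorted(subset)} not a subset of stages {list(stages)}")
    n_total = sum(regions.values())
    if gene_pool is None:
        gene_pool = [f"GSYN_DEG_{i:06d}" for i in range(n_total)]
    if len(set(gene_pool)) < n_total:
        raise ValueError(f"gene pool ({len(set(gene_pool))}) smaller than total DEGs ({n_total})")

    pool = list(dict.fromkeys(gene_pool))
    rng.shuffle(pool)
    cursor = 0
    stage_genes: dict[str, list[str]] = {s: [] for s in stages}
    for subset in sorted(regions, key=lambda s: sorted(s)):
        size = regions[subset]
        ids = pool[cursor : cursor + size]
        cursor += size
        for s in subset:
            stage_genes[s].extend(ids)

    tables: dict[str, pd.DataFrame] = {}
    for s in stages:
        ids = sorted(stage_genes[s])
        sign = rng.choice([-1.0, 1.0], size=len(ids))
        log2fc = sign * rng.uniform(0.58, 4.0, size=len(ids))
        padj = rng.uniform(0.0, 0.05, size=len(ids))
        tables[s] = pd.DataFrame({"gene_id": ids, "log2fc": log2fc, "padj": padj})
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for s, df in tables.items():
            df.to_csv(out_dir / f"deg_stage_{s}.tsv", sep="\t", index=False)
    return tables
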