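"""Readers and writers for the formats the mapping pipeline touches.

Three kinds of input feed a bulked-segregant scan: a two-sample VCF carrying
per-bulk allele depths (FORMAT ``AD``), GFF3 gene models for the
interval-to-gene step, and per-stage tables of differentially expressed
genes (DEGs). Coordinates stay 1-based inclusive at this boundary, exactly
as VCF and GFF3 define them; conversion to 0-based half-open space happens
only inside interval arithmetic (:mod:`bulkscan.candidate_genes`).

Counts are taken from ``AD`` only; ``DP`` is ignored where the two disagree,
because the Euclidean-distance statistic needs per-nucleotide read counts
and ``AD`` is the field that carries them.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

NUCLEOTIDES = ("A", "C", "G", "T")


class DataError(Exception):
    """Malformed or inconsistent input data."""


@dataclass(frozen=True)
class BulkAlleleObservation:
    """One SNP's per-bulk A/C/G/T read counts.

    ``counts_mut`` / ``counts_wt`` map each nucleotide to its read count in
    the mutant-phenotype and wild-phenotype bulk respectively; bases not
    among REF/ALT carry count 0. Only single-nucleotide records are
    represented — indels and symbolic alleles are rejected upstream.
    """

    chrom: str
    pos: int
    ref_base: str
    alt_bases: tuple[str, ...]
    counts_mut: Mapping[str, int]
    counts_wt: Mapping[str, int]

    def __post_init__(self) -> None:
        if self.ref_base not in NUCLEOTIDES:
            raise ValueError(f"ref_base must be one of {NUCLEOTIDES}: {self.ref_base!r}")
        for b in self.alt_bases:
            if b not in NUCLEOTIDES:
                raise ValueError(f"alt base must be one of {NUCLEOTIDES}: {b!r}")
        if self.ref_base in self.alt_bases:
            raise ValueError(f"ref_base {self.ref_base!r} also listed as alt")
        for counts in (self.counts_mut, self.counts_wt):
            for b, c in counts.items():
                if b not in NUCLEOTIDES or c < 0:
                    raise ValueError(f"bad count entry {b!r}: {c}")

    def count(self, base: str, bulk: str) -> int:
        counts = self.counts_mut if bulk == "mut" else self.counts_wt
        return int(counts.get(base, 0))

    @property
    def depth_mut(self) -> int:
        return sum(self.counts_mut.get(b, 0) for b in NUCLEOTIDES)

    @property
    def depth_wt(self) -> int:
        return sum(self.counts_wt.get(b, 0) for b in NUCLEOTIDES)


@dataclass(frozen=True)
class GeneModel:
    """A gene's genomic span; 1-based inclusive, as in GFF3."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"gene {self.gene_id}: start {self.start} > end {self.end}")


@dataclass(frozen=True)
class DegRecord:
    """A differentially expressed gene at one developmental stage."""

    gene_id: str
    stage: str
    log2fc: float
    padj: float

    @property
    def direction(self) -> str:
        return "up" if self.log2fc >= 0 else "down"


def normalize_chrom_name(name: str) -> str:
    """Strip a leading ``chr`` prefix (case-insensitive)."""
    return name[3:] if name.lower().startswith("chr") else name


# ---------------------------------------------------------------------------
# VCF


def read_bulk_vcf(
    path: str | Path,
    mut_sample: str,
    wt_sample: str,
    *,
    strip_chr_prefix: bool = False,
) -> list[BulkAlleleObservation]:
    """Read a two-bulk VCF with per-sample ``AD`` into allele observations.

    Each biallelic or multiallelic SNP record becomes one observation: the
    REF depth maps onto the reference base and each ALT depth onto its base;
    the remaining nucleotides get count 0. Records that are not pure SNPs
    (indels, symbolic or multi-base alleles) and records without ``AD`` for
    either sample are skipped, with skip totals logged.

    Raises
    ------
    DataError
        If either sample name is absent from the VCF header (the message
        names the available samples).
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    for name in (mut_sample, wt_sample):
        if name not in samples:
            raise DataError(
                f"sample {name!r} not in VCF {path}; available samples: {samples}"
            )
    i_mut = samples.index(mut_sample)
    i_wt = samples.index(wt_sample)

    observations: list[BulkAlleleObservation] = []
    n_not_snp = 0
    n_no_ad = 0
    for variant in vcf:
        ref = variant.REF
        alts = variant.ALT
        if (
            ref not in NUCLEOTIDES
            or not alts
            or any(a not in NUCLEOTIDES for a in alts)
        ):
            n_not_snp += 1
            continue
        ad = variant.format("AD")
        if ad is None:
            n_no_ad += 1
            continue
        row_mut = ad[i_mut]
        row_wt = ad[i_wt]
        if min(row_mut.min(), row_wt.min()) < 0:  # htslib encodes missing as negative
            n_no_ad += 1
            continue
        alleles = (ref, *alts)
        counts_mut = {b: 0 for b in NUCLEOTIDES}
        counts_wt = {b: 0 for b in NUCLEOTIDES}
        for j, base in enumerate(alleles):
            counts_mut[base] = int(row_mut[j])
            counts_wt[base] = int(row_wt[j])
        chrom = normalize_chrom_name(variant.CHROM) if strip_chr_prefix else variant.CHROM
        observations.append(
            BulkAlleleObservation(
                chrom=chrom,
                pos=variant.POS,
                ref_base=ref,
                alt_bases=tuple(alts),
                counts_mut=counts_mut,
                counts_wt=counts_wt,
            )
        )
    vcf.close()
    if n_not_snp or n_no_ad:
        logger.info(
            "read_bulk_vcf(%s): skipped %d non-SNP records, %d records without AD",
            path,
            n_not_snp,
            n_no_ad,
        )
    logger.info("read_bulk_vcf(%s): %d SNP observations", path, len(observations))
    return observations


VCF_HEADER_TEMPLATE = """\
##fileformat=VCFv4.2
##source=bulkscan
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths for the ref and alt alleles in the order listed">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
{contigs}#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{mut}\t{wt}
"""


def write_bulk_vcf(
    observations: Iterable[BulkAlleleObservation],
    path: str | Path,
    mut_sample: str = "mut_bulk",
    wt_sample: str = "wt_bulk",
) -> None:
    """Write observations as a minimal two-sample VCF v4.2 with ``AD`` and ``DP``.

    Every non-zero count must sit on the REF base or one of the ALT bases,
    otherwise the record cannot be represented and a :class:`DataError` is
    raised.
    """
    path = Path(path)
    observations = list(observations)
    max_pos: dict[str, int] = {}
    for obs in observations:
        max_pos[obs.chrom] = max(max_pos.get(obs.chrom, 0), obs.pos)
    contigs = "".join(
        f"##contig=<ID={chrom},length={end}>\n" for chrom, end in max_pos.items()
    )
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "wt") as fh:
        fh.write(VCF_HEADER_TEMPLATE.format(contigs=contigs, mut=mut_sample, wt=wt_sample))
        for obs in observations:
            alleles = (obs.ref_base, *obs.alt_bases)
            for counts in (obs.counts_mut, obs.counts_wt):
                stray = [b for b in NUCLEOTIDES if b not in alleles and counts.get(b, 0)]
                if stray:
                    raise DataError(
                        f"{obs.chrom}:{obs.pos}: reads on base(s) {stray} not in REF/ALT"
                    )
            ad_mut = ",".join(str(obs.counts_mut.get(b, 0)) for b in alleles)
            ad_wt = ",".join(str(obs.counts_wt.get(b, 0)) for b in alleles)
            fh.write(
                f"{obs.chrom}\t{obs.pos}\t.\t{obs.ref_base}\t{','.join(obs.alt_bases)}"
                f"\t.\tPASS\t.\tAD:DP\t{ad_mut}:{obs.depth_mut}\t{ad_wt}:{obs.depth_wt}\n"
            )


# ---------------------------------------------------------------------------
# GFF3


def read_gff3_genes(path: str | Path, *, strip_chr_prefix: bool = False) -> list[GeneModel]:
    """Extract gene models from a GFF3 file (rows with feature type ``gene``).

    mRNA/exon/CDS rows are ignored; the gene identifier comes from the ``ID``
    attribute (a ``gene:`` prefix, as in Ensembl Plants dumps, is stripped).
    Unparseable rows are skipped with a warning.
    """
    import gffutils

    path = Path(path)
    if path.suffix == ".gz":
        with gzip.open(path, "rt") as fh:
            data = fh.read()
        db = gffutils.create_db(
            data, ":memory:", from_string=True, merge_strategy="create_unique"
        )
    else:
        db = gffutils.create_db(str(path), ":memory:", merge_strategy="create_unique")

    genes: list[GeneModel] = []
    for feat in db.features_of_type("gene"):
        raw_id = feat.attributes.get("ID", [feat.id])[0]
        gene_id = raw_id.split(":", 1)[1] if raw_id.startswith("gene:") else raw_id
        chrom = normalize_chrom_name(feat.seqid) if strip_chr_prefix else feat.seqid
        try:
            genes.append(
                GeneModel(
                    gene_id=gene_id,
                    chrom=chrom,
                    start=feat.start,
                    end=feat.end,
                    strand=feat.strand or ".",
                )
            )
        except ValueError as exc:
            logger.warning("read_gff3_genes(%s): skipping %s: %s", path, raw_id, exc)
    return genes


def write_gff3_genes(genes: Iterable[GeneModel], path: str | Path, source: str = "bulkscan") -> None:
    """Write gene models as minimal GFF3 gene rows (round-trips with the reader)."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "wt") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(
                f"{g.chrom}\t{source}\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID={g.gene_id};biotype=protein_coding\n"
            )


# ---------------------------------------------------------------------------
# DEG tables


def read_deg_table(path: str | Path, stage: str) -> list[DegRecord]:
    """Read a delimited DEG table (columns gene_id, log2fc, padj) for one stage.

    The delimiter is sniffed (TSV or CSV both work, gzipped or plain). A
    non-numeric log2fc or padj is a hard error naming the offending line.
    """
    try:
        df = pd.read_csv(path, sep=None, engine="python")
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise DataError(f"cannot parse DEG table {path}: {exc}") from exc
    df.columns = [c.strip().lower() for c in df.columns]
    required = {"gene_id", "log2fc", "padj"}
    if not required.issubset(df.columns):
        raise DataError(
            f"DEG table {path} must have columns {sorted(required)}; got {list(df.columns)}"
        )
    records: list[DegRecord] = []
    for i, row in enumerate(df.itertuples(index=False)):
        lineno = i + 2  # 1-based, after the header line
        try:
            log2fc = float(getattr(row, "log2fc"))
            padj = float(getattr(row, "padj"))
        except (TypeError, ValueError) as exc:
            raise DataError(f"{path} line {lineno}: non-numeric log2fc/padj") from exc
        records.append(
            DegRecord(gene_id=str(getattr(row, "gene_id")).strip(), stage=stage,
                      log2fc=log2fc, padj=padj)
        )
    return records
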