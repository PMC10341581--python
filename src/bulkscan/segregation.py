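"""Mendelian segregation analysis for the reversed-kernel (rk1) locus.

rk1 behaves as a single recessive locus whose ear phenotype is
sporophyte-determined: whether the kernels on an ear are reversed depends on
the genotype of the plant BEARING the ear, not on the genotype of each
kernel. An rk1/rk1 mother therefore carries reversed kernels even when the
kernels themselves are heterozygous F1s, and selfing a heterozygote yields a
3:1 ratio of normal- to reversed-ear plants in the next generation.

The goodness-of-fit test is plain Pearson χ² against an expected ratio
(3:1 by default, critical value χ²₀.₀₅ = 3.84 at df = 1), with Yates
continuity correction available behind a flag.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
from scipy import stats

#: χ² critical value at α = 0.05 for df = 1.
CHI2_CRITICAL_P05_DF1 = 3.84


class PlantGenotype(str, Enum):
    """Diploid genotype at the biallelic rk1 locus."""

    MUTANT = "rk1/rk1"
    HET = "rk1/+"
    WILD = "+/+"

    @property
    def alleles(self) -> tuple[str, str]:
        return tuple(self.value.split("/"))  # type: ignore[return-value]


class EarPhenotype(str, Enum):
    NORMAL = "N"
    REVERSED = "R"


@dataclass(frozen=True)
class SegregationResult:
    """Observed two-class counts tested against an expected ratio."""

    observed: tuple[int, int]
    ratio: tuple[float, float]
    chi2: float
    df: int
    critical_value: float

    @property
    def consistent(self) -> bool:
        """True when the observed counts fit the ratio (χ² ≤ critical value)."""
        return self.chi2 <= self.critical_value


def chi_square_ratio_test(
    observed: tuple[int, int],
    ratio: tuple[float, float] = (3, 1),
    critical_value: float = CHI2_CRITICAL_P05_DF1,
    *,
    yates: bool = False,
) -> SegregationResult:
    """Pearson χ² goodness-of-fit of two-class counts to an expected ratio.

    Expected counts are E_i = N·r_i/(r_1+r_2) with N the total. No
    continuity correction is applied unless ``yates=True``.
    """
    n1, n2 = observed
    r1, r2 = ratio
    total = n1 + n2
    if total <= 0:
        raise ValueError("total count must be positive")
    if r1 <= 0 or r2 <= 0:
        raise ValueError("ratio components must be positive")
    expected = np.array([r1, r2], float) * total / (r1 + r2)
    obs = np.array([n1, n2], float)
    if yates:
        chi2 = float(np.sum((np.abs(obs - expected) - 0.5) ** 2 / expected))
    else:
        chi2 = float(stats.chisquare(obs, expected).statistic)
    return SegregationResult(
        observed=(n1, n2),
        ratio=(float(r1), float(r2)),
        chi2=chi2,
        df=1,
        critical_value=critical_value,
    )


def ear_phenotype(plant: PlantGenotype) -> EarPhenotype:
    """Ear phenotype of a plant: reversed kernels iff the plant is rk1/rk1.

    rk1 is recessive and sporophyte-acting, so heterozygous and wild-type
    plants both bear normal kernels.
    """
    return EarPhenotype.REVERSED if plant is PlantGenotype.MUTANT else EarPhenotype.NORMAL


_GENOTYPE_BY_MUTANT_DOSE = {0: PlantGenotype.WILD, 1: PlantGenotype.HET, 2: PlantGenotype.MUTANT}


def _gamete_mutant_prob(parent: PlantGenotype) -> float:
    return {"rk1/rk1": 1.0, "rk1/+": 0.5, "+/+": 0.0}[parent.value]


def simulate_selfing(
    parent: PlantGenotype, n_offspring: int, seed: int | None = None
) -> dict[PlantGenotype, int]:
    """Simulate selfing: offspring genotype counts under Mendelian transmission.

    Each offspring receives two independent gametes from the parent; a
    heterozygote transmits each allele with probability ½. Returns a count
    per genotype, reproducible given ``seed`` (one generator stream per
    call).
    """
    if n_offspring < 1:
        raise ValueError("n_offspring must be >= 1")
    rng = np.random.default_rng(seed)
    p = _gamete_mutant_prob(parent)
    dose = rng.binomial(1, p, size=n_offspring) + rng.binomial(1, p, size=n_offspring)
    values, counts = np.unique(dose, return_counts=True)
    result = {g: 0 for g in PlantGenotype}
    for v, c in zip(values, counts):
        result[_GENOTYPE_BY_MUTANT_DOSE[int(v)]] = int(c)
    return result


def ear_phenotype_counts(genotype_counts: dict[PlantGenotype, int]) -> dict[EarPhenotype, int]:
    """Collapse genotype counts to normal/reversed ear counts."""
    out = {EarPhenotype.NORMAL: 0, EarPhenotype.REVERSED: 0}
    for g, n in genotype_counts.items():
        out[ear_phenotype(g)] += n
    return out


@dataclass(frozen=True)
class ReciprocalCrossResult:
    """Outcome of a cross between two homozygous parents.

    ``maternal_ear`` is the phenotype of the kernels sitting on the female
    parent's ear (determined by HER genotype); ``f1_ear`` is the phenotype
    the F1 plants themselves will show once grown.
    """

    f1_genotype: PlantGenotype
    maternal_ear: EarPhenotype
    f1_ear: EarPhenotype


def simulate_reciprocal_f1(
    female: PlantGenotype, male: PlantGenotype
) -> ReciprocalCrossResult:
    """Cross two homozygous parents and track where the reversed ears appear.

    With an rk1/rk1 female the kernels on the maternal ear are reversed even
    though every F1 kernel is heterozygous — the hallmark of a
    sporophyte-determined trait. The F1 plants' own ears are normal either
    way.
    """
    if female is PlantGenotype.HET or male is PlantGenotype.HET:
        raise ValueError("reciprocal-cross check expects homozygous parents")
    dose = int(female is PlantGenotype.MUTANT) + int(male is PlantGenotype.MUTANT)
    f1 = _GENOTYPE_BY_MUTANT_DOSE[dose]
    return ReciprocalCrossResult(
        f1_genotype=f1,
        maternal_ear=ear_phenotype(female),
        f1_ear=ear_phenotype(f1),
    )
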