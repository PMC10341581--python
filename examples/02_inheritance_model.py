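"""The sporophyte-determined recessive model of the reversed-kernel trait.

Reciprocal crosses distinguish whether a seed phenotype is controlled by
the kernel's own genotype or by the plant bearing the ear: a homozygous
mutant mother carries reversed kernels even though every F1 kernel on her
ear is heterozygous. Selfing the F1 then gives a 3:1 normal:reversed ratio
among F2 plants' OWN ears, because only rk1/rk1 plants show the phenotype.
"""

from bulkscan import (
    PlantGenotype,
    ear_phenotype_counts,
    simulate_reciprocal_f1,
    simulate_selfing,
)

for female, male in [
    (PlantGenotype.MUTANT, PlantGenotype.WILD),
    (PlantGenotype.WILD, PlantGenotype.MUTANT),
]:
    res = simulate_reciprocal_f1(female, male)
    print(
        f"female {female.value} x male {male.value}: kernels on mother "
        f"{res.maternal_ear.value}, F1 plants' own ears {res.f1_ear.value} "
        f"(F1 genotype {res.f1_genotype.value})"
    )

counts = simulate_selfing(PlantGenotype.HET, 100_000, seed=1)
phen = ear_phenotype_counts(counts)
n, r = phen.values()
print(f"selfed heterozygote, 100,000 offspring: N={n} R={r} ratio={n / r:.3f}")
print("a ratio near 3 confirms the single-locus recessive model")
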