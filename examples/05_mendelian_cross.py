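"""Mendelian segregation of a zygotic-lethal allele.

Simulates a cross of two heterozygous parents (en/+ x en/+) and tallies
offspring genotypes and phenotypes: one quarter of progeny should be
homozygous mutant, the fraction in which a purely zygotic phenotype appears.
"""

from zygotrace import GenotypeSpec, simulate_cross

spec = GenotypeSpec(
    locus="en",
    parent1=("en", "+"),
    parent2=("en", "+"),
    phenotype_map={"en/en": "mutant", "+/en": "normal", "+/+": "normal"},
)
n = 100_000
genotypes, phenotypes = simulate_cross(spec, n, seed=17)
print("genotypes: ", dict(genotypes))
print("phenotypes:", dict(phenotypes))
print(f"mutant fraction: {phenotypes['mutant'] / n:.4f} (expected 0.25)")
print("A ~1/4 mutant fraction among offspring of phenotypically normal parents")
print("is the signature of a strictly zygotic requirement for the gene.")
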