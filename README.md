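# gsicross

Gametophytic self-incompatibility (GSI) genetics for rose breeding:
cross-compatibility prediction, S-locus linkage analysis, candidate
S-RNase screening, marker-based genotype calling, and introgression-trend
analysis — with seeded synthetic-data generators for every input format.

## Who this is for

Rose (and more broadly Rosaceae) geneticists and breeders working with
S-RNase-based self-incompatibility. Diploid roses carry a single
multi-allelic S-locus: the pistil expresses one S-RNase per haplotype,
and a haploid pollen grain is rejected whenever its S-allele matches
either pistil allele (non-self recognition). Because the S-locus sits on
chromosome 3 near the loci controlling continuous flowering (*KSN*) and
double flower (*AP2-like*), self-incompatibility interacts with the
breeding of those traits.

## The model

For a diploid parent with haplotypes h₁ = (S₁, t₁) and h₂ = (S₂, t₂) and
a linked locus at recombination fraction *r*, gametes are

    P(S₁,t₁) = P(S₂,t₂) = (1−r)/2        (parental)
    P(S₁,t₂) = P(S₂,t₁) = r/2            (recombinant)

Pollen is then filtered by the GSI rule — rejected iff its S-allele
matches a pistil allele — and renormalised; the offspring distribution is
the product of the ovule distribution (no selection) and the accepted
pollen distribution. A cross is *half-compatible* when the parents share
exactly one S-allele: the shared allele never transmits through pollen,
which is the signature used to validate S-genotyping from seed
S-genotypes. Tetraploids produce diploid pollen (random bivalent
pairing, no double reduction); heteroallelic diploid pollen is accepted
unconditionally, reproducing the breakdown of SI after chromosome
doubling.

Downstream, the package estimates recombination fractions from phased F1
genotypes (r̂ = recombinants/total), tests shared-allele transmission
with an exact binomial test, places genes physically by local cM→bp OLS
regression, screens candidate S-RNases by pistil-specific expression and
allelic divergence, calls S/KSN/AP2 genotypes from allele-specific
marker panels, and tracks per-breeding-period carrier frequencies of the
Chinese S-alleles (S_C1..S_C5) with Fisher exact contrasts.

## Worked example

A breeder wants continuous-flowering (CF) seedlings. CF is recessive:
seedlings must be homozygous for a non-functional *ksn* allele. The CF
seed parent is *ksn*-S1 / *ksn*-S2; the pollen donor carries *ksn*
linked to the same S1 plus a wild KSN on S3, with r = 0.20 between the
S-locus and *KSN*:

```python
from gsicross import Haplotype, PlantGenotype, SAllele, TraitAllele
from gsicross import cross, expected_trait_fraction, cf_predicate

ksn = TraitAllele("KSN", "ksn_copia", functional=False)
KSN = TraitAllele("KSN", "KSN_W", functional=True)
mother = PlantGenotype.diploid("cf_mother",
    Haplotype(SAllele("S1"), (ksn,)), Haplotype(SAllele("S2"), (ksn,)))
father = PlantGenotype.diploid("father",
    Haplotype(SAllele("S1"), (ksn,)), Haplotype(SAllele("S3"), (KSN,)))

result = cross(mother, father, {"KSN": 0.20})
print(result.compatibility.name)                              # HALF_COMPATIBLE
print(result.accepted_fraction)                               # 0.5
print(expected_trait_fraction(result, "KSN", cf_predicate))   # 0.2
```

Because the pistil rejects all S1 pollen, every accepted pollen grain
carries S3 — and only the recombinant fraction r of those carries *ksn*.
Hence only 20% of seedlings are expected to be CF, even though a naive
Mendelian calculation (ignoring SI) would predict 50%. Knowing which
S-allele *ksn* is linked to is therefore directly actionable in parent
selection.

The same engine is exposed on the command line:

```bash
gsicross cross --plants plants.tsv --seed-parent cf_mother \
    --pollen-parent father --rmap rmap.yaml --predicate CF
gsicross genotype --panel panel.tsv
gsicross trends --panel panel.tsv --group sc
gsicross simulate f1 --config config.yaml --seed 7
```

Bundled reference tables (`gsicross.datasets`) cover nine
half-compatible pollination series (469 seeds, zero shared-allele pollen
transmissions), the S-locus feature coordinates of the two Old Blush
haplotypes (S_C1 span 500 619 bp ≈ 500 kbp), F1 linkage tallies
(S–KSN 19/97 → 20%; S–AP2 13/97, 39/97, 11/50 → 13%, 40%, 22%), and the
15-cultivar Chinese panel (five distinct S_C alleles among CF types).

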