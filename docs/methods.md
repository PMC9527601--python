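# Methods

## Transmission model (`si_core`)

The engine models S-RNase-based gametophytic self-incompatibility (GSI)
with collaborative non-self recognition. Assumptions:

* **Haploid pollen rule.** Pollen is rejected iff its S-allele matches
  either pistil S-allele by exact label. Anonymous alleles (labels `Sx`,
  `Sy`, or any `S?…`) stand for unidentified S-RNases and never match
  anything — including another anonymous label, since two plants typed
  `Sx` need not share an allele.
* **Heteroallelic pollen.** Diploid pollen carrying two *distinct*
  S-alleles is accepted unconditionally: the union of the two SLF
  repertoires detoxifies every pistil S-RNase. This is the mechanism by
  which chromosome doubling yields self-compatible tetraploids, and it is
  adopted as a rule rather than derived, because the alternative
  (rejection) contradicts that observation. Homoallelic diploid pollen
  falls back to the haploid rule.
* **Recombination.** Gene order is S–locusᵢ independently per linked
  locus with fraction rᵢ ∈ [0, 0.5] and no interference; the multi-locus
  gamete distribution is the product of per-locus outcomes. Loci missing
  from the map default to r = 0.5 (unlinked). The engine never uses more
  than pairwise S–locus distances, so ordering among trait loci is
  irrelevant to any supported query.
* **Tetraploid meiosis.** Four haplotypes pair at random into two
  bivalents (three pairings, 1/3 each); the diploid gamete takes one
  chromatid per bivalent, recombined within its bivalent; no double
  reduction. Marginally every unordered haplotype pair transmits at 1/6.
  This is the simplest model consistent with SI breakdown in
  neo-tetraploids; chromatid-level double reduction would add rare
  homoallelic pollen and is deliberately omitted.
* **Triploids** are genotype-callable (marker panel side) but excluded
  from transmission: their aneuploid gametes are not modelled, and
  requesting them raises an explicit error.

Probabilities are IEEE doubles. All distribution identities (gametes sum
to 1; post-acceptance pollen sums to 1 when any pollen is accepted;
offspring sum to 1) are maintained and tested at 1e-12. Classes whose
probability underflows to exactly zero are dropped. Compatibility is
INCOMPATIBLE at accepted fraction 0, FULLY_COMPATIBLE at 1 (within
tolerance), HALF_COMPATIBLE otherwise.

The CF breeding prediction follows analytically: with a ksn-homozygous
seed parent and a pollen donor sharing one S-allele in coupling with
*ksn*, all accepted pollen carries the non-shared S-allele, of which a
fraction r is recombinant onto *ksn*; the expected CF seedling share is
exactly r (20% at r = 0.20). With a ksn/KSN heterozygous seed parent the
share is r/2. Both configurations are exposed; neither is silently
assumed, because the headline claim does not state the parental
configuration and only the homozygous one yields r exactly.

## Segregation inference (`segregation_mapping`)

* **Pollen inference** removes one maternal allele (by label) from a
  seed genotype; two valid removals with different remainders →
  AMBIGUOUS, no maternal allele → INCONSISTENT. Ambiguous and
  inconsistent seeds are excluded from ratio tests and reported, never
  guessed. The half-compatible experimental design avoids ambiguity by
  construction, but synthetic or miscalled data can produce it.
* **Shared-allele ratio test**: exact binomial (scipy `binomtest`)
  against equal transmission (p = 0.5), the null without SI.
* **Recombination estimation** requires parental phase as input (de novo
  phasing is out of scope). r̂ = recombinants/total over individuals with
  informative, non-missing calls at both loci. Percentages are reported
  with round-half-away-from-zero to integer percent (so 19/97 → 20%,
  1/8 → 13%), matching how such tables are conventionally printed.
* **Physical positioning** fits ordinary (unweighted) least squares
  bp ~ cM through the k nearest markers on each side of the target
  (default k = 3, fewer at map ends) and evaluates at the target cM.
  Non-monotone cM-vs-bp among the chosen markers — e.g. across an
  assembly inversion — sets a `monotone=False` flag rather than raising;
  the estimate is still returned. Marker input order never affects the
  result (markers are sorted internally with deterministic tie-breaks).

## Candidate screening (`srnase_screen`)

* **Percent identity** uses a global alignment (match +1, mismatch 0,
  linear gap −1; Biopython `PairwiseAligner`); identity = matching
  columns / alignment columns × 100, one decimal. The denominator
  includes internal gap columns but excludes terminal overhangs, so the
  SNP arithmetic (8 SNPs per 500 bp → 98.4%) holds exactly on
  equal-length gapless comparisons.
* **Expression bins** (mean FPKM): `***` > 100, `**` (50, 100], `*`
  [10, 50], NONE below 10. The bins are half-open downward to resolve
  the overlapping printed endpoints ("50–100" / "10–50"); 100 → `**`,
  50 → `*`.
* **Pistil specificity**: pistil mean ≥ 10 FPKM and every non-pistil
  tissue < 2 FPKM. The thresholds sit between the observed S-RNase
  pattern (pistil 44–100, stamen 0) and the SLF pattern (stamen 4–22,
  pistil 0–1), so both classes are separated with wide margin.
* **Primary-candidate rule**: pistil-specific AND pistil expression in
  {`***`, `**`} AND mean allele identity < 80% (balancing selection
  keeps true S-RNase alleles far more diverged than that; observed
  classes sit near 65% vs > 94%) AND best identity to a reference
  S-RNase ≥ 30%. The reference-identity cutoff stands in for
  phylogenetic clustering with known Rosaceae S-RNases; tree building is
  out of scope.
* **F-box typing**: a homology group present in ≥ 4 of the 6 surveyed
  S-haplotypes is SLF, otherwise FBX; the undefined exactly-3 case
  resolves to FBX (the conservative call: SLF status implies shared
  pollen function).
* **ORF checks** scan the three forward reading frames for
  ATG-initiated ORFs: TRUNCATED if none reaches 1 kbp (the S-locus
  F-box extraction threshold), PSEUDOGENE if an expected intact length
  is declared and the longest ORF stops short of it (frameshift /
  nonsense signature).
* **Locus span** is max − min over both coordinates of every feature on
  a haplotype — invariant to feature order and strand encoding
  (start > end on reverse strand is kept as printed).

## Marker panels and breeding history (`breeding_history`)

Presence/absence PCR cannot observe dosage, so KSN typing uses the
diploid dosage assumption: a single non-functional marker without the
wild allele is read as homozygous (copia-only → Type 2, null-only →
Type 3). The mapping is total over all 8 patterns: five types (1–3 CF,
4–5 OF), plus MISSING (nothing amplified), UNKNOWN (null + wild, a
pattern never observed), and TRIPLOID (all three, impossible for a
diploid). S-genotype calls pad with anonymous placeholders up to ploidy
and flag ploidy conflicts instead of discarding alleles.

Breeding periods are I: before 1850, II: 1850–1900, III: 1900–1940,
IV: 1940–1980, V: 1980–2020, with closed lower bounds (1850 → II) since
the boundary convention is otherwise undefined. Period contrasts use the
two-sided Fisher exact test under the standard minimum-likelihood
convention (sum of hypergeometric probabilities ≤ the observed table's);
tables with a zero margin return p = 1 with a degenerate flag.

## Synthetic data (`synthetic_data`)

All generators draw from one `numpy.random.default_rng(seed)` stream;
fixed seed → byte-identical output. What they emulate, and what not:

* **Seed sets** are multinomial draws from the engine's offspring
  distribution — they carry GSI selection and recombination but no
  genotyping error, no seed mortality, and no inbreeding-depression
  losses. A passing recovery test therefore validates the estimator
  arithmetic, not robustness to miscalls.
* **F1 tables** draw one gamete per parent per individual at the stated
  r (default study sizes: n = 97 per population, r = 0.20 for S–KSN);
  no missing data unless injected, no genotyping error.
* **Marker panels** draw carrier status per cultivar per marker group
  (Bernoulli at the stated per-period fractions; the reference trend is
  0.25/0.86/0.83/0.80/0.82 across periods I–V); an optional linkage
  parameter couples S_C carriage to ksn carriage, emulating hitchhiking.
  Real panels additionally show pedigree correlation between cultivars,
  which is not modelled.
* **Sequences**: substitutions at uniformly chosen distinct sites, never
  back to the original state, so identity is exactly (L − n)/L;
  transition/transversion bias is not modelled. Allele sets at a target
  divergence mutate a common ancestor on mutually disjoint site sets, so
  every pair differs at exactly 2·round(L·d/2) positions — the target
  pairwise identity holds by construction, which is what makes
  generator-parameter recovery a sharp test.
* **Screen fixtures** instantiate four archetypes (two pistil-specific
  highly diverged true-S-RNase profiles at ~35% divergence; one
  low-divergence ~2% relic; one stamen-expressed ~5% relic) whose
  expected screening partition is known by construction.

## Problem sizes

The test suite uses n = 10 000 draws for single-shot r recovery,
300–1000 replicates of n = 97 for estimator unbiasedness, 200–500
cultivars per period for panel recovery, and exhaustive Fisher
enumeration up to table total 30; the full suite runs in well under a
minute. The acceptance computation itself is analytic (a four-class
offspring distribution) and uses no randomness.

## Known limitations

* No pollen-tube growth or partial-rejection kinetics: acceptance is
  binary.
* Triploid transmission, double reduction, and preferential pairing in
  tetraploids are unmodelled.
* De novo phasing, linkage-map construction and interval mapping are out
  of scope; phase and map positions are inputs.
* The screen replaces phylogenetic placement with a single identity
  cutoff; borderline homologues near 30% identity may be
  misclassified.
* Bundled reference tables are cultivar-scale summaries; raw sequencing
  data is neither shipped nor consumed.
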