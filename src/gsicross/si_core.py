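"""Gametophytic self-incompatibility (GSI) transmission model.

Under GSI a haploid pollen grain expresses its single S-allele and is
rejected whenever that allele matches either S-allele of the (diploid)
pistil — "non-self recognition": the pistil's S-RNases are cytotoxic to
pollen tubes unless the pollen's SLF repertoire detoxifies them, which it
can do for every S-RNase except its own.  Two consequences drive the
arithmetic here:

* a cross between diploids sharing one S-allele is *half-compatible*: only
  pollen carrying the non-shared allele fertilises, so the shared allele
  never transmits through pollen;
* diploid (heteroallelic) pollen from a tetraploid carries two different
  S-alleles whose combined SLF repertoires detoxify *all* pistil S-RNases,
  so chromosome doubling breaks SI down.

The module models pollen/ovule haplotype distributions with recombination
between the S-locus and linked trait loci (e.g. the floral repressor KSN
whose non-functional alleles confer continuous flowering), filters pollen
by the acceptance rule, and predicts offspring genotype/phenotype
distributions for a cross.

Probabilities are IEEE doubles; all distribution identities hold to 1e-12.
"""

from __future__ import annotations

import enum
import itertools
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

from .errors import DomainError, MissingLocusError, UnsupportedPloidyError

__all__ = [
    "SAllele",
    "TraitAllele",
    "Haplotype",
    "PlantGenotype",
    "RecombinationMap",
    "PollenClass",
    "Compatibility",
    "CrossResult",
    "gamete_distribution",
    "pollen_accepted",
    "cross",
    "expected_trait_fraction",
    "cf_predicate",
    "UNLINKED",
]

#: recombination fraction assigned to loci absent from a RecombinationMap
UNLINKED = 0.5

_PROB_TOL = 1e-12


@dataclass(frozen=True, order=True)
class SAllele:
    """An S-locus allele, compared by exact label.

    Labels such as ``Sx`` / ``Sy`` denote *anonymous* alleles: placeholders
    for unidentified S-RNases.  An anonymous allele never matches any
    concrete allele nor another anonymous label (two plants both typed
    ``Sx`` need not share an allele), so anonymous pollen is always
    accepted.  Labels beginning with ``S?`` are anonymous automatically;
    any allele can be flagged explicitly.
    """

    id: str
    anonymous: bool = False

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("S-allele label must be non-empty")
        if self.id.startswith("S?") and not self.anonymous:
            object.__setattr__(self, "anonymous", True)

    def matches(self, other: "SAllele") -> bool:
        """Recognition match: drives pollen rejection, not label identity."""
        if self.anonymous or other.anonymous:
            return False
        return self.id == other.id

    def __str__(self) -> str:  # pragma: no cover - repr sugar
        return self.id


@dataclass(frozen=True, order=True)
class TraitAllele:
    """An allele at a locus linked to the S-locus (e.g. KSN, AP2)."""

    locus: str
    allele: str
    functional: bool = True

    def __str__(self) -> str:  # pragma: no cover - repr sugar
        return f"{self.allele}"


@dataclass(frozen=True, order=True)
class Haplotype:
    """One chromosome: an S-allele phased with its linked trait alleles."""

    s: SAllele
    traits: tuple[TraitAllele, ...] = ()

    def __post_init__(self) -> None:
        loci = [t.locus for t in self.traits]
        if len(set(loci)) != len(loci):
            raise ValueError("at most one trait allele per locus on a haplotype")
        # canonical order so haplotypes hash/compare structurally
        object.__setattr__(self, "traits", tuple(sorted(self.traits)))

    @property
    def loci(self) -> frozenset[str]:
        return frozenset(t.locus for t in self.traits)

    def trait(self, locus: str) -> TraitAllele:
        for t in self.traits:
            if t.locus == locus:
                return t
        raise MissingLocusError(locus)

    def with_trait(self, allele: TraitAllele) -> "Haplotype":
        others = tuple(t for t in self.traits if t.locus != allele.locus)
        return Haplotype(self.s, others + (allele,))

    def label(self) -> str:
        parts = [self.s.id] + [t.allele for t in self.traits]
        return "-".join(parts)


@dataclass(frozen=True)
class PlantGenotype:
    """A plant: id, ploidy and exactly ``ploidy`` phased haplotypes."""

    id: str
    ploidy: int
    haplotypes: tuple[Haplotype, ...]

    def __post_init__(self) -> None:
        if self.ploidy not in (2, 3, 4):
            raise ValueError(f"ploidy must be 2, 3 or 4, got {self.ploidy}")
        object.__setattr__(self, "haplotypes", tuple(self.haplotypes))
        if len(self.haplotypes) != self.ploidy:
            raise ValueError(
                f"{self.id}: {len(self.haplotypes)} haplotypes for ploidy {self.ploidy}"
            )
        loci = {h.loci for h in self.haplotypes}
        if len(loci) > 1:
            raise ValueError(f"{self.id}: trait loci differ between haplotypes")

    @property
    def s_alleles(self) -> tuple[SAllele, ...]:
        return tuple(h.s for h in self.haplotypes)

    @property
    def loci(self) -> frozenset[str]:
        return self.haplotypes[0].loci

    @classmethod
    def diploid(cls, id: str, h1: Haplotype, h2: Haplotype) -> "PlantGenotype":
        return cls(id, 2, (h1, h2))


class RecombinationMap:
    """Recombination fractions between the S-locus and each linked locus.

    Loci without an entry are unlinked (r = 0.5).  Fractions must lie in
    [0, 0.5]; gene order is S-locus_i independently per locus, with no
    interference (the multi-locus distribution is the product of the
    per-locus ones).
    """

    def __init__(self, r: Mapping[str, float] | None = None):
        self._r: dict[str, float] = {}
        for locus, value in (r or {}).items():
            self._validate(locus, value)
            self._r[locus] = float(value)

    @staticmethod
    def _validate(locus: str, value: float) -> None:
        if not (0.0 <= value <= 0.5):
            raise DomainError(f"r({locus}) = {value} outside [0, 0.5]")

    def __getitem__(self, locus: str) -> float:
        return self._r.get(locus, UNLINKED)

    def items(self):
        return self._r.items()

    def __repr__(self) -> str:  # pragma: no cover
        return f"RecombinationMap({self._r})"


@dataclass(frozen=True)
class PollenClass:
    """A gamete class: 1 (haploid) or 2 (diploid pollen) haplotypes + probability."""

    haplotypes: tuple[Haplotype, ...]
    probability: float

    def __post_init__(self) -> None:
        if len(self.haplotypes) not in (1, 2):
            raise ValueError("pollen carries 1 or 2 haplotypes")
        object.__setattr__(self, "haplotypes", tuple(sorted(self.haplotypes)))

    @property
    def s_alleles(self) -> tuple[SAllele, ...]:
        return tuple(h.s for h in self.haplotypes)

    def label(self) -> str:
        return "/".join(h.label() for h in self.haplotypes)


class Compatibility(enum.Enum):
    INCOMPATIBLE = "incompatible"
    HALF_COMPATIBLE = "half_compatible"
    FULLY_COMPATIBLE = "fully_compatible"


#: offspring genotype key: the sorted tuple of transmitted haplotypes
GenotypeKey = tuple[Haplotype, ...]


@dataclass
class CrossResult:
    """Outcome of a cross: accepted-pollen distribution and offspring genotypes."""

    compatibility: Compatibility
    accepted_fraction: float
    pollen_distribution: list[PollenClass]
    offspring: dict[GenotypeKey, float] = field(default_factory=dict)

    def offspring_s_genotypes(self) -> dict[tuple[str, ...], float]:
        """Marginalise offspring onto unordered S-allele label tuples."""
        out: dict[tuple[str, ...], float] = {}
        for key, p in self.offspring.items():
            label = tuple(sorted(h.s.id for h in key))
            out[label] = out.get(label, 0.0) + p
        return out


def _single_haplotype_transmission(
    own: Haplotype, partner: Haplotype, rmap: RecombinationMap
) -> dict[Haplotype, float]:
    """Distribution of the chromatid transmitted from the bivalent (own, partner),
    conditioned on the centromere/S-allele coming from ``own``.

    Each linked locus crosses over independently with its fraction r: with
    probability 1 - r the transmitted chromatid keeps ``own``'s allele,
    with probability r it carries ``partner``'s.
    """
    out: dict[Haplotype, float] = {own: 1.0}
    for locus in sorted(own.loci):
        r = rmap[locus]
        RecombinationMap._validate(locus, r)
        nxt: dict[Haplotype, float] = {}
        for hap, p in out.items():
            for allele, q in ((own.trait(locus), 1.0 - r), (partner.trait(locus), r)):
                if q == 0.0:
                    continue
                h2 = hap.with_trait(allele)
                nxt[h2] = nxt.get(h2, 0.0) + p * q
        out = nxt
    return out


def gamete_distribution(
    parent: PlantGenotype, rmap: RecombinationMap | Mapping[str, float] | None = None
) -> list[PollenClass]:
    """Gamete (pollen or ovule) classes of a parent, before any SI selection.

    Diploid parent with haplotypes h1 = (s1, t1), h2 = (s2, t2) and one
    linked locus at fraction r: parental classes (s1, t1), (s2, t2) each at
    (1 - r)/2 and recombinant classes (s1, t2), (s2, t1) each at r/2.
    Several linked loci recombine independently (no interference).

    Tetraploid parent: the four haplotypes pair at random into two
    bivalents (three pairings, equiprobable) and the diploid gamete takes
    one chromatid from each bivalent, recombined within its bivalent as
    above; there is no double reduction.  Marginally every unordered pair
    of the four haplotypes is transmitted with probability 1/6 when r plays
    no role.

    Triploid parents produce aneuploid gametes and are not modelled.
    """
    if not isinstance(rmap, RecombinationMap):
        rmap = RecombinationMap(rmap)
    if parent.ploidy == 2:
        h1, h2 = parent.haplotypes
        classes: dict[tuple[Haplotype, ...], float] = {}
        for own, partner in ((h1, h2), (h2, h1)):
            for hap, p in _single_haplotype_transmission(own, partner, rmap).items():
                key = (hap,)
                classes[key] = classes.get(key, 0.0) + 0.5 * p
        return [PollenClass(k, p) for k, p in sorted(classes.items()) if p > 0.0]
    if parent.ploidy == 4:
        haps = parent.haplotypes
        classes = {}
        # three bivalent pairings of four chromosomes, each 1/3
        pairings = [((0, 1), (2, 3)), ((0, 2), (1, 3)), ((0, 3), (1, 2))]
        for biv_a, biv_b in pairings:
            for ia, ib in itertools.product(biv_a, biv_b):
                # choose one chromatid per bivalent: 1/2 * 1/2
                base_p = (1.0 / 3.0) * 0.25
                ja = biv_a[1] if ia == biv_a[0] else biv_a[0]
                jb = biv_b[1] if ib == biv_b[0] else biv_b[0]
                dist_a = _single_haplotype_transmission(haps[ia], haps[ja], rmap)
                dist_b = _single_haplotype_transmission(haps[ib], haps[jb], rmap)
                for (ha, pa), (hb, pb) in itertools.product(
                    dist_a.items(), dist_b.items()
                ):
                    key = tuple(sorted((ha, hb)))
                    classes[key] = classes.get(key, 0.0) + base_p * pa * pb
        return [PollenClass(k, p) for k, p in sorted(classes.items()) if p > 0.0]
    raise UnsupportedPloidyError(
        f"{parent.id}: ploidy {parent.ploidy} gametes are not modelled "
        "(triploid meiosis is aneuploid)"
    )


def pollen_accepted(pollen: PollenClass, pistil: PlantGenotype) -> bool:
    """Non-self recognition acceptance rule.

    Haploid pollen is rejected iff its S-allele matches either pistil
    S-allele (anonymous alleles never match anything).  Heteroallelic
    diploid pollen — two *distinct* S-alleles — is accepted
    unconditionally: the combined SLF repertoires of the two haplotypes
    detoxify every pistil S-RNase (the breakdown of SI in neo-tetraploids).
    Diploid pollen homoallelic at S behaves like haploid pollen.
    """
    s_alleles = pollen.s_alleles
    if len(s_alleles) == 2 and s_alleles[0].id != s_alleles[1].id:
        return True
    pollen_s = s_alleles[0]
    return not any(pollen_s.matches(ps) for ps in pistil.s_alleles)


def cross(
    seed_parent: PlantGenotype,
    pollen_parent: PlantGenotype,
    rmap: RecombinationMap | Mapping[str, float] | None = None,
) -> CrossResult:
    """Predict a cross: pollen acceptance, compatibility class and offspring.

    Ovules come from the seed parent's gamete distribution without
    selection; pollen classes are filtered by :func:`pollen_accepted` and
    renormalised.  The offspring distribution is the product of the two.
    A cross is INCOMPATIBLE when no pollen class is accepted (offspring
    empty), FULLY_COMPATIBLE when all are, HALF_COMPATIBLE otherwise.
    """
    if seed_parent.ploidy != 2:
        raise UnsupportedPloidyError(
            f"seed parent {seed_parent.id} must be diploid (ploidy 2)"
        )
    if not isinstance(rmap, RecombinationMap):
        rmap = RecombinationMap(rmap)
    pollen_classes = gamete_distribution(pollen_parent, rmap)
    accepted = [pc for pc in pollen_classes if pollen_accepted(pc, seed_parent)]
    accepted_fraction = sum(pc.probability for pc in accepted)
    if accepted_fraction <= _PROB_TOL:
        return CrossResult(Compatibility.INCOMPATIBLE, 0.0, [], {})
    renorm = [
        PollenClass(pc.haplotypes, pc.probability / accepted_fraction)
        for pc in accepted
    ]
    ovules = gamete_distribution(seed_parent, rmap)
    offspring: dict[GenotypeKey, float] = {}
    for ov, po in itertools.product(ovules, renorm):
        key = tuple(sorted(ov.haplotypes + po.haplotypes))
        p = ov.probability * po.probability
        offspring[key] = offspring.get(key, 0.0) + p
    if accepted_fraction >= 1.0 - _PROB_TOL:
        compat = Compatibility.FULLY_COMPATIBLE
        accepted_fraction = 1.0
    else:
        compat = Compatibility.HALF_COMPATIBLE
    return CrossResult(compat, accepted_fraction, renorm, offspring)


def cf_predicate(alleles: Sequence[TraitAllele]) -> bool:
    """Continuous flowering: every allele at the locus is non-functional.

    CF is recessive — a single functional (wild-type) KSN copy represses
    flowering after the first flush.
    """
    return all(not a.functional for a in alleles)


def expected_trait_fraction(
    result: CrossResult,
    locus: str,
    predicate: Callable[[Sequence[TraitAllele]], bool],
) -> float:
    """Fraction of offspring whose trait genotype satisfies ``predicate``.

    ``predicate`` receives the offspring's alleles at ``locus`` (one per
    transmitted haplotype).  E.g. with :func:`cf_predicate` this is the
    expected share of continuous-flowering seedlings.
    """
    if not result.offspring:
        return 0.0
    total = 0.0
    for key, p in result.offspring.items():
        alleles = [h.trait(locus) for h in key]
        if predicate(alleles):
            total += p
    return total


def brute_force_cross(
    seed_parent: PlantGenotype,
    pollen_parent: PlantGenotype,
    rmap: RecombinationMap | Mapping[str, float] | None = None,
) -> dict[GenotypeKey, float]:
    """Exhaustive diploid x diploid offspring enumeration (test oracle).

    Enumerates every ovule x pollen gamete pair over all per-locus
    recombination outcomes explicitly, applies the acceptance rule per
    pollen grain, and renormalises.  Kept deliberately independent of
    :func:`cross`'s aggregation path.
    """
    if not isinstance(rmap, RecombinationMap):
        rmap = RecombinationMap(rmap)

    def enumerate_gametes(parent: PlantGenotype) -> list[tuple[Haplotype, float]]:
        h = parent.haplotypes
        loci = sorted(parent.loci)
        out: list[tuple[Haplotype, float]] = []
        for own_i in (0, 1):
            own, partner = h[own_i], h[1 - own_i]
            for pattern in itertools.product((0, 1), repeat=len(loci)):
                hap = own
                p = 0.5
                for locus, swapped in zip(loci, pattern):
                    r = rmap[locus]
                    if swapped:
                        hap = hap.with_trait(partner.trait(locus))
                        p *= r
                    else:
                        hap = hap.with_trait(own.trait(locus))
                        p *= 1.0 - r
                if p > 0.0:
                    out.append((hap, p))
        return out

    ovules = enumerate_gametes(seed_parent)
    pollen = [
        (hap, p)
        for hap, p in enumerate_gametes(pollen_parent)
        if pollen_accepted(PollenClass((hap,), p), seed_parent)
    ]
    z = sum(p for _, p in pollen)
    offspring: dict[GenotypeKey, float] = {}
    if z <= _PROB_TOL:
        return offspring
    for (ho, po), (hp, pp) in itertools.product(ovules, pollen):
        key = tuple(sorted((ho, hp)))
        offspring[key] = offspring.get(key, 0.0) + po * (pp / z)
    return offspring
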