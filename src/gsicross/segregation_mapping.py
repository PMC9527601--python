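"""Inference from observed segregation data.

Covers the downstream half of a pollination/mapping experiment: inferring
which pollen S-allele fertilised each seed from the seed's S-genotype and
the mother's, testing the transmission ratio of a shared allele against
the no-SI null, estimating recombination fractions from phased F1
two-locus genotypes, checking perfect co-segregation, and placing a gene
on a physical map by local cM-to-bp regression.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InsufficientDataError
from .si_core import PlantGenotype, SAllele

__all__ = [
    "InferenceStatus",
    "SeedGenotypeCounts",
    "F1GenotypeTable",
    "MappedMarker",
    "infer_pollen_allele",
    "pollen_ratio_test",
    "PollenRatioResult",
    "estimate_recombination",
    "RecombinationEstimate",
    "cosegregation_test",
    "estimate_physical_position",
    "PositionEstimate",
    "percent_recombination",
]


class InferenceStatus(enum.Enum):
    AMBIGUOUS = "ambiguous"
    INCONSISTENT = "inconsistent"


def _labels(genotype: Iterable[str | SAllele]) -> tuple[str, ...]:
    return tuple(a.id if isinstance(a, SAllele) else str(a) for a in genotype)


@dataclass
class SeedGenotypeCounts:
    """Observed seed S-genotype counts from one cross.

    ``counts`` maps an unordered offspring S-genotype (tuple of allele
    labels, one per offspring haplotype) to a non-negative count.
    """

    cross_id: str
    maternal: PlantGenotype
    counts: dict[tuple[str, ...], int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        norm: dict[tuple[str, ...], int] = {}
        for genotype, n in self.counts.items():
            if n < 0:
                raise ValueError(f"{self.cross_id}: negative count for {genotype}")
            norm[tuple(sorted(_labels(genotype)))] = int(n)
        self.counts = norm

    @property
    def total(self) -> int:
        return sum(self.counts.values())


def infer_pollen_allele(
    seed: Sequence[str | SAllele], maternal: PlantGenotype
) -> str | InferenceStatus:
    """Infer the pollen-derived S-allele of a diploid seed.

    Removes one maternal allele (by label) from the seed genotype; the
    remaining allele came from the pollen.  Returns ``AMBIGUOUS`` when two
    valid removals leave different pollen alleles (e.g. seed identical to
    the mother), ``INCONSISTENT`` when no maternal allele is present.
    """
    seed_labels = _labels(seed)
    maternal_labels = [a.id for a in maternal.s_alleles]
    candidates: set[str] = set()
    for i, allele in enumerate(seed_labels):
        if allele in maternal_labels:
            rest = seed_labels[:i] + seed_labels[i + 1 :]
            if len(rest) == 1:
                candidates.add(rest[0])
    if not candidates:
        return InferenceStatus.INCONSISTENT
    if len(candidates) > 1:
        return InferenceStatus.AMBIGUOUS
    return candidates.pop()


@dataclass
class PollenRatioResult:
    """Tally of pollen-derived alleles against the no-SI (0.5 : 0.5) null."""

    n_shared: int
    n_other: int
    total: int
    expected_under_no_SI: float
    p_value: float
    excluded: dict[tuple[str, ...], int] = field(default_factory=dict)


def pollen_ratio_test(
    counts: SeedGenotypeCounts, shared_allele: str | SAllele
) -> PollenRatioResult:
    """Test whether the shared allele transmits through pollen.

    Under GSI a half-compatible cross transmits zero shared-allele pollen;
    without SI both pollen alleles transmit equally (binomial p = 0.5).
    Seeds whose pollen allele is ambiguous or inconsistent are excluded
    from the tally and reported.
    """
    shared = shared_allele.id if isinstance(shared_allele, SAllele) else str(shared_allele)
    n_shared = n_other = 0
    excluded: dict[tuple[str, ...], int] = {}
    for genotype, n in counts.counts.items():
        if n == 0:
            continue
        inferred = infer_pollen_allele(genotype, counts.maternal)
        if isinstance(inferred, InferenceStatus):
            excluded[genotype] = excluded.get(genotype, 0) + n
        elif inferred == shared:
            n_shared += n
        else:
            n_other += n
    total = n_shared + n_other
    if total == 0:
        p_value = 1.0
    else:
        p_value = stats.binomtest(n_shared, total, 0.5, alternative="two-sided").pvalue
    return PollenRatioResult(
        n_shared=n_shared,
        n_other=n_other,
        total=total,
        expected_under_no_SI=total / 2.0,
        p_value=float(p_value),
        excluded=excluded,
    )


# ---------------------------------------------------------------------------
# F1 two-locus analysis


@dataclass
class F1GenotypeTable:
    """Phased transmitted alleles of an F1 population at >= 2 loci.

    ``calls`` has one row per individual x parent with one column per
    locus holding the allele label that parent transmitted (NaN/None =
    missing).  ``parent_phases`` gives each parent's two haplotypes as
    {locus: allele} mappings; phase is an input, not inferred.
    """

    calls: pd.DataFrame  # columns: individual, parent, <locus...>
    parent_phases: dict[str, tuple[Mapping[str, str], Mapping[str, str]]]

    def __post_init__(self) -> None:
        required = {"individual", "parent"}
        missing = required - set(self.calls.columns)
        if missing:
            raise ValueError(f"F1 table missing columns: {sorted(missing)}")
        if len(self.calls) == 0:
            raise ValueError("F1 table is empty")

    @property
    def n_individuals(self) -> int:
        return self.calls["individual"].nunique()

    @classmethod
    def from_counts(
        cls,
        recombinants: int,
        total: int,
        locus_a: str = "S",
        locus_b: str = "KSN",
        parent: str = "P",
    ) -> "F1GenotypeTable":
        """Build a minimal phased table with the given recombinant count.

        Convenience for re-analysing published recombinant/total tallies:
        the informative parent is made heterozygous A1/A2 x B1/B2 with
        parental haplotypes (A1, B1) and (A2, B2).
        """
        if not 0 <= recombinants <= total:
            raise ValueError("need 0 <= recombinants <= total")
        rows = []
        for i in range(total):
            if i < recombinants:
                a, b = "A1", "B2"  # non-parental combination
            else:
                a, b = "A1", "B1"
            rows.append({"individual": f"f1_{i:04d}", "parent": parent, locus_a: a, locus_b: b})
        calls = pd.DataFrame(rows)
        phases = {parent: ({locus_a: "A1", locus_b: "B1"}, {locus_a: "A2", locus_b: "B2"})}
        return cls(calls, phases)


@dataclass
class RecombinationEstimate:
    recombinants: int
    total: int
    r_hat: float
    percent: int
    parent: str
    n_missing: int = 0


def percent_recombination(recombinants: int, total: int) -> int:
    """Integer percent, round-half-away-from-zero (13/97 -> 13, 19/97 -> 20)."""
    if total <= 0:
        raise InsufficientDataError("no informative individuals")
    value = 100.0 * recombinants / total
    return int(math.floor(value + 0.5))


def _phase_index(
    phases: tuple[Mapping[str, str], Mapping[str, str]], locus: str, allele: str
) -> int | None:
    """Which parental haplotype (0/1) carries ``allele`` at ``locus``.

    Returns None when the parent is homozygous there (uninformative) or
    the allele is not parental.
    """
    h0, h1 = phases
    if h0.get(locus) == h1.get(locus):
        return None
    if allele == h0.get(locus):
        return 0
    if allele == h1.get(locus):
        return 1
    return None


def estimate_recombination(
    table: F1GenotypeTable,
    locus_a: str,
    locus_b: str,
    parent: str | None = None,
) -> RecombinationEstimate:
    """Estimate r between two loci as recombinants / total in phased F1 calls.

    An individual is recombinant (for the informative parent) when the two
    transmitted alleles come from different parental haplotypes.
    Individuals with a missing or non-parental call at either locus are
    excluded and counted in ``n_missing``.
    """
    if parent is None:
        informative = [
            p
            for p, (h0, h1) in table.parent_phases.items()
            if h0.get(locus_a) != h1.get(locus_a) and h0.get(locus_b) != h1.get(locus_b)
        ]
        if len(informative) != 1:
            raise InsufficientDataError(
                f"cannot choose informative parent automatically from {informative!r}; "
                "pass parent= explicitly"
            )
        parent = informative[0]
    phases = table.parent_phases[parent]
    sub = table.calls[table.calls["parent"] == parent]
    for locus in (locus_a, locus_b):
        if locus not in sub.columns:
            raise InsufficientDataError(f"locus {locus!r} absent from F1 table")
    recombinants = total = missing = 0
    for _, row in sub.iterrows():
        a, b = row[locus_a], row[locus_b]
        if pd.isna(a) or pd.isna(b):
            missing += 1
            continue
        ia = _phase_index(phases, locus_a, str(a))
        ib = _phase_index(phases, locus_b, str(b))
        if ia is None or ib is None:
            missing += 1
            continue
        total += 1
        if ia != ib:
            recombinants += 1
    if total == 0:
        raise InsufficientDataError(
            f"no informative individuals for {locus_a}-{locus_b} in parent {parent}"
        )
    return RecombinationEstimate(
        recombinants=recombinants,
        total=total,
        r_hat=recombinants / total,
        percent=percent_recombination(recombinants, total),
        parent=parent,
        n_missing=missing,
    )


@dataclass
class CosegregationResult:
    n: int
    n_discordant: int
    perfectly_cosegregating: bool


def cosegregation_test(
    table: F1GenotypeTable, locus_a: str, locus_b: str, parent: str | None = None
) -> CosegregationResult:
    """Do two loci segregate as one?  Perfect co-segregation = 0 discordant."""
    est = estimate_recombination(table, locus_a, locus_b, parent=parent)
    return CosegregationResult(
        n=est.total,
        n_discordant=est.recombinants,
        perfectly_cosegregating=est.recombinants == 0,
    )


# ---------------------------------------------------------------------------
# cM -> bp regression positioning


@dataclass(frozen=True, order=True)
class MappedMarker:
    """A marker with both a genetic (cM) and a physical (bp) coordinate."""

    cm: float
    bp: int
    name: str = ""

    def __post_init__(self) -> None:
        if self.cm < 0:
            raise ValueError(f"{self.name}: cM must be >= 0")
        if self.bp < 1:
            raise ValueError(f"{self.name}: bp must be >= 1 (1-based)")


@dataclass
class PositionEstimate:
    bp: float
    slope_bp_per_cm: float
    intercept_bp: float
    markers_used: list[MappedMarker]
    monotone: bool


def estimate_physical_position(
    markers: Sequence[MappedMarker],
    target_cm: float,
    k_flank: int = 3,
) -> PositionEstimate:
    """Predict the physical position of a map location by local OLS.

    Fits an ordinary least-squares line bp ~ cM through the ``k_flank``
    nearest markers on each side of ``target_cm`` (fewer at map ends) and
    evaluates it at the target.  A non-monotone cM-vs-bp relation among
    the chosen markers (e.g. across an assembly inversion) is flagged via
    ``monotone=False`` rather than raised.
    """
    if k_flank < 1:
        raise ValueError("k_flank must be >= 1")
    usable = sorted(markers)  # by (cm, bp, name): deterministic under permutation
    if len(usable) < 2:
        raise InsufficientDataError("need at least two markers with cM and bp")
    below = [m for m in usable if m.cm <= target_cm][-k_flank:]
    above = [m for m in usable if m.cm > target_cm][:k_flank]
    chosen = below + above
    if len(chosen) < 2:
        # target beyond the map end with only one flanking marker: widen
        chosen = usable[:k_flank] if target_cm < usable[0].cm else usable[-k_flank:]
    if len(chosen) < 2:
        raise InsufficientDataError("fewer than two usable flanking markers")
    x = np.array([m.cm for m in chosen], dtype=float)
    y = np.array([m.bp for m in chosen], dtype=float)
    if np.ptp(x) == 0:
        raise InsufficientDataError("flanking markers share one cM position")
    slope, intercept = np.polyfit(x, y, 1)
    diffs = np.diff(y)
    monotone = bool(np.all(diffs >= 0) or np.all(diffs <= 0))
    return PositionEstimate(
        bp=float(slope * target_cm + intercept),
        slope_bp_per_cm=float(slope),
        intercept_bp=float(intercept),
        markers_used=list(chosen),
        monotone=monotone,
    )
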