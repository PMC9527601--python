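"""Marker-based genotype calling and historical introgression analysis.

Allele-specific PCR gives presence/absence of the Chinese S-alleles
(S_C1..S_C5), the three KSN alleles (ksn_copia, ksn_null, KSN_W) and the
double-flower allele ap2 across cultivar panels.  This module calls
S-genotypes and KSN types from such panels, bins cultivars into breeding
periods, computes per-period carrier frequencies of Chinese-origin
alleles (the introgression trend), and supplies the Fisher exact test
used to contrast periods.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd
from scipy import stats

from .si_core import SAllele

__all__ = [
    "S_MARKERS",
    "KSN_MARKERS",
    "PERIOD_BINS",
    "BreedingPeriod",
    "KsnType",
    "KsnStatus",
    "MarkerPanel",
    "call_s_genotype",
    "SGenotypeCall",
    "classify_ksn",
    "period_frequencies",
    "PeriodFrequency",
    "fisher_exact_2x2",
    "FisherResult",
    "year_to_period",
]

#: Chinese S-allele marker columns
S_MARKERS = ("S_C1", "S_C2", "S_C3", "S_C4", "S_C5")
#: KSN allele marker columns; ksn_copia/ksn_null are non-functional (CF), KSN_W wild (OF)
KSN_MARKERS = ("ksn_copia", "ksn_null", "KSN_W")


class BreedingPeriod(enum.Enum):
    I = "I"
    II = "II"
    III = "III"
    IV = "IV"
    V = "V"


#: closed lower bounds: [1850, 1900) = II etc.; before 1850 = I
PERIOD_BINS: list[tuple[float, float, BreedingPeriod]] = [
    (-math.inf, 1850, BreedingPeriod.I),
    (1850, 1900, BreedingPeriod.II),
    (1900, 1940, BreedingPeriod.III),
    (1940, 1980, BreedingPeriod.IV),
    (1980, math.inf, BreedingPeriod.V),
]


def year_to_period(year: int | float) -> BreedingPeriod:
    for lo, hi, period in PERIOD_BINS:
        if lo <= year < hi:
            return period
    raise ValueError(f"year {year} maps to no breeding period")  # pragma: no cover


class KsnStatus(enum.Enum):
    """Non-type outcomes of KSN classification."""

    UNKNOWN = "unknown"  # ksn_null + KSN_W without copia: unobserved pattern
    MISSING = "missing"  # no marker amplified
    TRIPLOID = "triploid"  # all three alleles present: impossible for a diploid


@dataclass(frozen=True)
class KsnType:
    """KSN genotype type 1-5; types 1-3 are continuous-flowering (CF)."""

    type_code: int
    genotype: str

    @property
    def phenotype(self) -> str:
        return "CF" if self.type_code in (1, 2, 3) else "OF"


_KSN_TABLE: dict[tuple[bool, bool, bool], KsnType | KsnStatus] = {
    # (copia, null, W) under the diploid dosage assumption: a single
    # non-functional marker with no wild allele means homozygosity.
    (True, True, False): KsnType(1, "ksn_copia/ksn_null"),
    (True, False, False): KsnType(2, "ksn_copia/ksn_copia"),
    (False, True, False): KsnType(3, "ksn_null/ksn_null"),
    (True, False, True): KsnType(4, "ksn_copia/KSN_W"),
    (False, False, True): KsnType(5, "KSN_W/KSN_W"),
    (False, True, True): KsnStatus.UNKNOWN,
    (False, False, False): KsnStatus.MISSING,
    (True, True, True): KsnStatus.TRIPLOID,
}


def classify_ksn(
    row: Mapping[str, object] | pd.Series,
    copia_col: str = "ksn_copia",
    null_col: str = "ksn_null",
    w_col: str = "KSN_W",
) -> KsnType | KsnStatus:
    """Map a presence/absence pattern of the three KSN markers to a type.

    Presence/absence PCR cannot see dosage, so a lone non-functional
    marker is read as homozygous (Type 2/3).  Total on all 8 patterns:
    five types plus UNKNOWN (null+W), MISSING (nothing amplified) and
    TRIPLOID (all three present — impossible in a diploid).
    """
    pattern = (bool(row[copia_col]), bool(row[null_col]), bool(row[w_col]))
    return _KSN_TABLE[pattern]


@dataclass(frozen=True)
class SGenotypeCall:
    """Called S-genotype: known S_C alleles padded to ploidy with anonymous ones."""

    alleles: tuple[SAllele, ...]
    n_anonymous: int
    ploidy_conflict: bool = False

    @property
    def known(self) -> tuple[str, ...]:
        return tuple(a.id for a in self.alleles if not a.anonymous)


def call_s_genotype(
    row: Mapping[str, object] | pd.Series,
    ploidy: int = 2,
    markers: Sequence[str] = S_MARKERS,
) -> SGenotypeCall:
    """Call a plant's S-genotype from allele-specific marker presence.

    Present markers become concrete S-alleles; if fewer than ``ploidy``
    the call is padded with anonymous placeholders (``S?1``, ``S?2``, ...).
    More present markers than ploidy yields a ploidy-conflict flag (the
    plant is likely polyploid) and the call keeps all observed alleles.
    """
    present = [m for m in markers if m in row and bool(row[m])]
    conflict = len(present) > ploidy
    alleles = [SAllele(m) for m in present]
    for i in range(max(0, ploidy - len(alleles))):
        alleles.append(SAllele(f"S?{i + 1}", anonymous=True))
    return SGenotypeCall(tuple(alleles), sum(a.anonymous for a in alleles), conflict)


@dataclass
class MarkerPanel:
    """Cultivar x allele-specific-marker presence panel with breeding periods.

    ``rows`` holds one record per cultivar: a ``name`` column, a ``year``
    and/or ``period`` column, an optional ``ploidy`` column, and one
    boolean column per marker.
    """

    rows: pd.DataFrame

    def __post_init__(self) -> None:
        if "name" not in self.rows.columns:
            raise ValueError("panel needs a 'name' column")
        if "period" not in self.rows.columns and "year" not in self.rows.columns:
            raise ValueError("panel needs a 'period' or 'year' column")

    def periods(self) -> pd.Series:
        if "period" in self.rows.columns and self.rows["period"].notna().all():
            return self.rows["period"].map(
                lambda p: p if isinstance(p, BreedingPeriod) else BreedingPeriod(str(p))
            )
        return self.rows["year"].map(year_to_period)

    def markers(self) -> list[str]:
        reserved = {"name", "year", "period", "ploidy", "bloom", "flower"}
        return [c for c in self.rows.columns if c not in reserved]


@dataclass(frozen=True)
class PeriodFrequency:
    period: BreedingPeriod
    n: int
    carriers: int

    @property
    def fraction(self) -> float:
        return self.carriers / self.n


def period_frequencies(
    panel: MarkerPanel, marker_group: Iterable[str]
) -> dict[BreedingPeriod, PeriodFrequency]:
    """Per-period fraction of cultivars carrying >= 1 marker of the group.

    E.g. with ``marker_group=S_MARKERS`` this is the introgression trend
    of Chinese S-alleles across breeding periods; empty periods are
    simply absent from the result.
    """
    group = [m for m in marker_group if m in panel.rows.columns]
    if not group:
        raise ValueError("none of the requested markers are in the panel")
    periods = panel.periods()
    carrier = panel.rows[group].astype(bool).any(axis=1)
    out: dict[BreedingPeriod, PeriodFrequency] = {}
    for period in BreedingPeriod:
        mask = periods == period
        n = int(mask.sum())
        if n == 0:
            continue
        out[period] = PeriodFrequency(period, n, int(carrier[mask].sum()))
    return out


@dataclass(frozen=True)
class FisherResult:
    p_value: float
    odds_ratio: float
    degenerate: bool = False


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> FisherResult:
    """Two-sided Fisher exact test on [[a, b], [c, d]].

    Two-sided by the minimum-likelihood convention: sum hypergeometric
    probabilities of every table (with the margins fixed) whose
    probability does not exceed the observed table's.  A zero margin
    makes the table degenerate and p = 1.
    """
    for x in (a, b, c, d):
        if x < 0 or x != int(x):
            raise ValueError("counts must be non-negative integers")
    if min(a + b, c + d, a + c, b + d) == 0:
        return FisherResult(1.0, math.nan, degenerate=True)
    odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return FisherResult(float(p), float(odds))
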