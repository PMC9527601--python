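"""Candidate S-RNase / SLF screening.

A true S-RNase is expected to (i) be expressed strongly and specifically
in the pistil, (ii) resemble known Rosaceae S-RNases, and (iii) show the
extreme allelic divergence that balancing selection maintains at the
S-locus.  Conversely the pollen-side SLF genes are stamen-expressed and
shared across most S-haplotypes, while haplotype-sparse F-box genes (FBX)
are not.  This module implements those screening rules plus the sequence
utilities behind them: global-alignment percent identity, ORF/pseudogene
checks, locus span, and allele-origin tracing across wild species.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from Bio import Align

from .errors import (
    DomainError,
    EmptySelectionError,
    InsufficientAllelesError,
    MissingTissueError,
    ParseError,
)

__all__ = [
    "ExpressionSummary",
    "CandidateGene",
    "HaplotypePresence",
    "GeneFlag",
    "ExpressionClass",
    "FboxType",
    "pairwise_identity",
    "average_divergence",
    "expression_class",
    "pistil_specific",
    "rank_candidates",
    "CandidateReport",
    "orf_pseudogene_check",
    "classify_fbox",
    "locus_span",
    "trace_allele_origin",
    "OriginCall",
]

#: default screening thresholds
PISTIL_MIN_FPKM = 10.0
NON_PISTIL_MAX_FPKM = 2.0
DIVERGENCE_IDENTITY_CUTOFF = 80.0  # % identity below which alleles count as diverged
REFERENCE_IDENTITY_CUTOFF = 30.0  # % identity to a reference S-RNase required
MIN_ORF_LENGTH = 1000  # bp; shorter genes are flagged TRUNCATED


class GeneFlag(enum.Enum):
    PSEUDOGENE = "pseudogene"
    TRUNCATED = "truncated"


class ExpressionClass(enum.Enum):
    """FPKM bins: *** > 100; ** in (50, 100]; * in [10, 50]; NONE below."""

    HIGH = "***"
    MODERATE = "**"
    LOW = "*"
    NONE = "none"


class FboxType(enum.Enum):
    SLF = "SLF"
    FBX = "FBX"


@dataclass(frozen=True)
class ExpressionSummary:
    """Mean +/- SE FPKM of one gene in one tissue."""

    gene: str
    tissue: str
    mean_fpkm: float
    se_fpkm: float = 0.0
    n_reps: int = 1

    def __post_init__(self) -> None:
        if self.mean_fpkm < 0 or self.se_fpkm < 0:
            raise DomainError(f"{self.gene}/{self.tissue}: negative FPKM")
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")


@dataclass
class CandidateGene:
    """A screening unit: coordinates, allele sequences, expression."""

    name: str
    chromosome: str = ""
    start: int = 1
    end: int = 1
    alleles: list[str] = field(default_factory=list)
    expression: list[ExpressionSummary] = field(default_factory=list)
    flags: set[GeneFlag] = field(default_factory=set)
    s_haplotype: str = ""

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < 1:
            raise ValueError(f"{self.name}: coordinates are 1-based positive")

    def tissue_mean(self, tissue: str) -> float | None:
        for summary in self.expression:
            if summary.tissue == tissue:
                return summary.mean_fpkm
        return None


@dataclass(frozen=True)
class HaplotypePresence:
    """Presence of an F-box homology group across a universe of S-haplotypes."""

    fbox_group: str
    present_in: frozenset[str]
    universe: frozenset[str]

    def __post_init__(self) -> None:
        extra = self.present_in - self.universe
        if extra:
            raise ValueError(f"{self.fbox_group}: haplotypes outside universe: {sorted(extra)}")


# ---------------------------------------------------------------------------
# sequence identity

_aligner = Align.PairwiseAligner(
    mode="global",
    match_score=1,
    mismatch_score=0,
    open_gap_score=-1,
    extend_gap_score=-1,
)


def pairwise_identity(seq_a: str, seq_b: str) -> float:
    """Percent identity between two sequences under global alignment.

    Scoring: match +1, mismatch 0, linear gap -1.  Identity = matching
    columns / alignment columns x 100, to one decimal; columns are counted
    over the aligned span including internal gaps but excluding terminal
    overhangs.  For equal-length gapless alignments this reduces to
    (L - SNPs) / L x 100.
    """
    if not seq_a or not seq_b:
        raise DomainError("sequences must be non-empty")
    seq_a, seq_b = seq_a.upper(), seq_b.upper()
    alignment = _aligner.align(seq_a, seq_b)[0]
    col_a, col_b = alignment[0], alignment[1]
    # trim terminal overhangs: columns where either row is still gap-only
    start = 0
    end = len(col_a)
    while start < end and (col_a[start] == "-" or col_b[start] == "-"):
        start += 1
    while end > start and (col_a[end - 1] == "-" or col_b[end - 1] == "-"):
        end -= 1
    if end <= start:
        return 0.0
    matches = sum(1 for a, b in zip(col_a[start:end], col_b[start:end]) if a == b and a != "-")
    return round(100.0 * matches / (end - start), 1)


def average_divergence(gene: CandidateGene) -> float:
    """Mean pairwise percent identity over all unordered allele pairs.

    Low values (e.g. ~65%) are the signature of balancing selection at a
    functional S-locus; housekeeping-like genes sit above 94%.
    """
    alleles = gene.alleles
    if len(alleles) < 2:
        raise InsufficientAllelesError(f"{gene.name}: need >= 2 alleles for divergence")
    identities = [
        pairwise_identity(alleles[i], alleles[j])
        for i in range(len(alleles))
        for j in range(i + 1, len(alleles))
    ]
    return round(sum(identities) / len(identities), 1)


# ---------------------------------------------------------------------------
# expression rules


def expression_class(summary: ExpressionSummary | float) -> ExpressionClass:
    """Bin a mean FPKM: *** > 100, ** in (50, 100], * in [10, 50], else NONE."""
    mean = summary.mean_fpkm if isinstance(summary, ExpressionSummary) else float(summary)
    if mean < 0:
        raise DomainError("negative FPKM")
    if mean > 100:
        return ExpressionClass.HIGH
    if mean > 50:
        return ExpressionClass.MODERATE
    if mean >= 10:
        return ExpressionClass.LOW
    return ExpressionClass.NONE


def pistil_specific(
    gene: CandidateGene,
    pistil_tissue: str = "pistil",
    min_pistil: float = PISTIL_MIN_FPKM,
    max_other: float = NON_PISTIL_MAX_FPKM,
) -> bool:
    """True iff expression is pistil-specific.

    Pistil mean must reach ``min_pistil`` (default 10 FPKM) while every
    other tissue stays below ``max_other`` (default 2 FPKM) — S-RNases
    show pistil 44-100 / stamen 0, SLFs the inverse.
    """
    pistil = gene.tissue_mean(pistil_tissue)
    if pistil is None:
        raise MissingTissueError(f"{gene.name}: no {pistil_tissue} expression record")
    others = [s.mean_fpkm for s in gene.expression if s.tissue != pistil_tissue]
    if not others:
        raise MissingTissueError(f"{gene.name}: need at least one non-{pistil_tissue} tissue")
    return pistil >= min_pistil and all(v < max_other for v in others)


@dataclass
class CandidateReport:
    gene: CandidateGene
    primary: bool
    failed_criteria: list[str]
    divergence_identity: float | None
    best_reference_identity: float | None
    expression: ExpressionClass


def rank_candidates(
    genes: Sequence[CandidateGene],
    references: Sequence[str],
    divergence_cutoff: float = DIVERGENCE_IDENTITY_CUTOFF,
    reference_cutoff: float = REFERENCE_IDENTITY_CUTOFF,
) -> list[CandidateReport]:
    """Screen candidate genes for true S-RNases.

    A gene is PRIMARY iff it is pistil-specific, expressed at *** or **
    in the pistil, its alleles average below ``divergence_cutoff`` %
    identity (high divergence), and its best identity to any reference
    S-RNase reaches ``reference_cutoff`` %.  Non-primary genes carry the
    list of criteria they failed.  PRIMARY genes sort first, by pistil
    expression descending.
    """
    if not references:
        raise ValueError("need at least one reference S-RNase sequence")
    reports: list[CandidateReport] = []
    for gene in genes:
        failed: list[str] = []
        try:
            specific = pistil_specific(gene)
        except MissingTissueError:
            specific = False
            failed.append("missing_tissue_data")
        if not specific and "missing_tissue_data" not in failed:
            failed.append("pistil_specificity")
        pistil = gene.tissue_mean("pistil")
        cls = expression_class(pistil if pistil is not None else 0.0)
        if cls not in (ExpressionClass.HIGH, ExpressionClass.MODERATE):
            failed.append("pistil_expression_level")
        divergence = None
        if len(gene.alleles) >= 2:
            divergence = average_divergence(gene)
            if divergence >= divergence_cutoff:
                failed.append("allelic_divergence")
        else:
            failed.append("single_allele")
        best_ref = None
        if gene.alleles:
            best_ref = max(
                pairwise_identity(allele, ref)
                for allele in gene.alleles
                for ref in references
            )
            if best_ref < reference_cutoff:
                failed.append("reference_similarity")
        else:
            failed.append("no_sequence")
        reports.append(
            CandidateReport(
                gene=gene,
                primary=not failed,
                failed_criteria=failed,
                divergence_identity=divergence,
                best_reference_identity=best_ref,
                expression=cls,
            )
        )
    reports.sort(
        key=lambda rep: (
            not rep.primary,
            -(rep.gene.tissue_mean("pistil") or 0.0),
            rep.gene.name,
        )
    )
    return reports


# ---------------------------------------------------------------------------
# ORF / pseudogene checks

_DNA_RE = re.compile(r"^[ACGTN]+$")
_STOPS = {"TAA", "TAG", "TGA"}


def _orfs(seq: str) -> list[tuple[int, int, bool]]:
    """(start, end, stopped) of every ATG-initiated ORF in the 3 forward frames.

    ``end`` is exclusive of the stop codon; ``stopped`` is False when the
    ORF runs off the end of the sequence.
    """
    found = []
    for frame in range(3):
        i = frame
        while i + 3 <= len(seq):
            if seq[i : i + 3] == "ATG":
                j = i
                stopped = False
                while j + 3 <= len(seq):
                    codon = seq[j : j + 3]
                    if codon in _STOPS:
                        stopped = True
                        break
                    j += 3
                found.append((i, j, stopped))
                i = j + 3
            else:
                i += 3
    return found


def orf_pseudogene_check(
    cds: str, min_orf: int = MIN_ORF_LENGTH, expected_length: int | None = None
) -> set[GeneFlag]:
    """Flag a coding sequence as TRUNCATED and/or PSEUDOGENE.

    TRUNCATED: no open reading frame of at least ``min_orf`` bases (the
    extraction threshold for S-locus F-box genes is 1 kbp).  PSEUDOGENE:
    ``expected_length`` is declared (the intact CDS length) and the
    longest ORF stops short of it — the signature of a frameshift or
    nonsense mutation.
    """
    cds = cds.upper().replace("U", "T")
    if not cds or not _DNA_RE.match(cds):
        raise ParseError("sequence contains non-DNA characters")
    orfs = _orfs(cds)
    flags: set[GeneFlag] = set()
    longest = max((end - start for start, end, _ in orfs), default=0)
    if longest < min_orf:
        flags.add(GeneFlag.TRUNCATED)
    if expected_length is not None and longest < expected_length:
        flags.add(GeneFlag.PSEUDOGENE)
    return flags


# ---------------------------------------------------------------------------
# F-box typing and locus geometry


def classify_fbox(presence: HaplotypePresence, min_shared: int = 4) -> FboxType:
    """SLF iff the homology group is present in >= ``min_shared`` haplotypes.

    With the default universe of six S-haplotypes: >= 4 -> SLF, otherwise
    FBX (the exactly-3 case resolves to FBX).
    """
    return FboxType.SLF if len(presence.present_in) >= min_shared else FboxType.FBX


def locus_span(features: Sequence[CandidateGene], haplotype_label: str) -> int:
    """Physical span (bp) of all features annotated to one S-haplotype.

    Orientation-agnostic: both start and end of every feature enter the
    max - min, so strand flips (start > end) cannot change the answer.
    """
    coords: list[int] = []
    for feature in features:
        if feature.s_haplotype == haplotype_label:
            coords.extend((feature.start, feature.end))
    if not coords:
        raise EmptySelectionError(f"no features labelled {haplotype_label!r}")
    return max(coords) - min(coords)


# ---------------------------------------------------------------------------
# allele-origin tracing


class OriginStatus(enum.Enum):
    MATCH_100 = "match_100"
    NEAR_MATCH = "near_match"
    NO_AMPLIFICATION = "no_amplification"


@dataclass(frozen=True)
class OriginCall:
    species: str
    status: OriginStatus
    identity: float | None = None
    snps: int | None = None


def trace_allele_origin(
    query: str, wild_hits: Mapping[str, str | None]
) -> dict[str, OriginCall]:
    """Compare a cultivar S-allele against wild-species amplicons.

    Per species: MATCH_100 for 100% identity over the compared region
    (candidate wild ancestor of the allele), NEAR_MATCH with identity and
    SNP count otherwise, NO_AMPLIFICATION when no sequence was obtained.
    """
    if not query:
        raise DomainError("query sequence must be non-empty")
    calls: dict[str, OriginCall] = {}
    for species, hit in wild_hits.items():
        if hit is None or hit == "":
            calls[species] = OriginCall(species, OriginStatus.NO_AMPLIFICATION)
            continue
        identity = pairwise_identity(query, hit)
        if identity == 100.0:
            calls[species] = OriginCall(species, OriginStatus.MATCH_100, identity, 0)
        else:
            alignment = _aligner.align(query.upper(), hit.upper())[0]
            col_a, col_b = alignment[0], alignment[1]
            snps = sum(
                1 for a, b in zip(col_a, col_b) if a != "-" and b != "-" and a != b
            )
            calls[species] = OriginCall(species, OriginStatus.NEAR_MATCH, identity, snps)
    return calls
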