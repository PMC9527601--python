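"""Generators for synthetic study data.

Every analysis stage in the package consumes tables or sequences with a
specific statistical structure: GSI-filtered seed genotypes from a cross,
phased F1 two-locus genotypes with a fixed recombination fraction,
cultivar marker panels with per-period carrier frequencies, and allele
sequence sets at a chosen divergence.  These generators produce exactly
those structures from explicit parameters, so each estimator can be
validated by parameter recovery without any external data.

All generators draw from a single ``numpy.random.default_rng(seed)``
stream; a fixed seed reproduces outputs exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import si_core
from .breeding_history import KSN_MARKERS, MarkerPanel, S_MARKERS
from .errors import DomainError
from .segregation_mapping import F1GenotypeTable, SeedGenotypeCounts
from .si_core import (
    Compatibility,
    PlantGenotype,
    RecombinationMap,
    cross,
    gamete_distribution,
)
from .srnase_screen import CandidateGene, ExpressionSummary

__all__ = [
    "SimulationConfig",
    "simulate_seed_set",
    "simulate_f1",
    "simulate_panel",
    "mutate_sequence",
    "random_sequence",
    "diverged_alleles",
    "simulate_screen_fixture",
    "DNA_ALPHABET",
    "PROTEIN_ALPHABET",
]

DNA_ALPHABET = "ACGT"
PROTEIN_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"


@dataclass
class SimulationConfig:
    """Bundle of generator parameters (used by the CLI ``simulate`` command)."""

    seed: int = 0
    n: int = 100
    true_r: dict[str, float] = field(default_factory=dict)
    panel_periods: dict[str, dict[str, float | int]] = field(default_factory=dict)
    sequence_length: int = 500
    divergence: float = 0.35
    alphabet: str = DNA_ALPHABET


def simulate_seed_set(
    seed_parent: PlantGenotype,
    pollen_parent: PlantGenotype,
    rmap: RecombinationMap | Mapping[str, float] | None,
    n: int,
    seed: int,
    cross_id: str | None = None,
) -> SeedGenotypeCounts:
    """Draw ``n`` seed S-genotypes from a cross's offspring distribution.

    The offspring distribution already incorporates GSI pollen selection;
    an incompatible cross yields a zero-seed table.  Counts conserve n.
    """
    rng = np.random.default_rng(seed)
    result = cross(seed_parent, pollen_parent, rmap)
    cross_id = cross_id or f"{seed_parent.id}x{pollen_parent.id}"
    if result.compatibility is Compatibility.INCOMPATIBLE:
        return SeedGenotypeCounts(cross_id, seed_parent, {})
    genotypes = result.offspring_s_genotypes()
    keys = sorted(genotypes)
    probs = np.array([genotypes[k] for k in keys])
    draws = rng.multinomial(n, probs / probs.sum())
    return SeedGenotypeCounts(
        cross_id, seed_parent, {k: int(c) for k, c in zip(keys, draws)}
    )


def simulate_f1(
    seed_parent: PlantGenotype,
    pollen_parent: PlantGenotype,
    rmap: RecombinationMap | Mapping[str, float] | None,
    n: int,
    seed: int,
    apply_si: bool = False,
) -> F1GenotypeTable:
    """Simulate ``n`` F1 individuals with phased multi-locus calls.

    Each parent transmits a gamete drawn from its own gamete
    distribution; recombinants therefore occur at rate r per meiosis per
    parent.  With ``apply_si=True`` pollen gametes are filtered by the
    acceptance rule first (as in a real cross); mapping populations are
    usually analysed without it.
    """
    if not isinstance(rmap, RecombinationMap):
        rmap = RecombinationMap(rmap)
    rng = np.random.default_rng(seed)
    rows: list[dict[str, object]] = []
    phases: dict[str, tuple[dict[str, str], dict[str, str]]] = {}
    for parent, is_pollen in ((seed_parent, False), (pollen_parent, True)):
        classes = gamete_distribution(parent, rmap)
        if is_pollen and apply_si:
            classes = [c for c in classes if si_core.pollen_accepted(c, seed_parent)]
        probs = np.array([c.probability for c in classes])
        probs = probs / probs.sum()
        picks = rng.choice(len(classes), size=n, p=probs)
        loci = sorted(parent.loci)
        phases[parent.id] = tuple(
            {"S": h.s.id, **{locus: h.trait(locus).allele for locus in loci}}
            for h in parent.haplotypes
        )
        for i, pick in enumerate(picks):
            hap = classes[pick].haplotypes[0]
            record: dict[str, object] = {
                "individual": f"f1_{i:05d}",
                "parent": parent.id,
                "S": hap.s.id,
            }
            for locus in loci:
                record[locus] = hap.trait(locus).allele
            rows.append(record)
    return F1GenotypeTable(pd.DataFrame(rows), phases)


def simulate_panel(
    periods: Mapping[str, Mapping[str, object]],
    seed: int,
    markers: Sequence[str] = S_MARKERS + KSN_MARKERS + ("ap2",),
    groups: Mapping[str, Sequence[str]] | None = None,
    linkage: float = 0.0,
) -> MarkerPanel:
    """Simulate a cultivar marker panel with per-period carrier fractions.

    ``periods`` maps a period label ("I".."V") to ``{"n": int,
    "fractions": {group: carrier fraction}}``; ``groups`` maps a group
    name to its marker columns (default: ``ksn`` = the two non-functional
    KSN markers, ``sc`` = the five S_C markers, ``ap2`` = ap2).  A carrier
    of a group gets one of the group's markers (uniformly); non-carriers
    get none.  ``linkage`` in [0, 1] makes an ``sc`` carrier state copy
    the ``ksn`` state with that probability (hitchhiking of the linked
    S-allele during selection for continuous flowering).
    """
    if not 0.0 <= linkage <= 1.0:
        raise DomainError("linkage must lie in [0, 1]")
    if groups is None:
        groups = {
            "ksn": ("ksn_copia", "ksn_null"),
            "sc": S_MARKERS,
            "ap2": ("ap2",),
        }
    rng = np.random.default_rng(seed)
    records: list[dict[str, object]] = []
    for period, spec in periods.items():
        n = int(spec["n"])
        fractions: Mapping[str, float] = spec["fractions"]  # type: ignore[assignment]
        for i in range(n):
            record: dict[str, object] = {
                "name": f"cv_{period}_{i:04d}",
                "period": period,
            }
            for m in markers:
                record[m] = False
            carrier_state: dict[str, bool] = {}
            for group, frac in fractions.items():
                if group == "sc" and linkage > 0 and "ksn" in carrier_state:
                    if rng.random() < linkage:
                        carrier = carrier_state["ksn"]
                    else:
                        carrier = rng.random() < float(frac)
                else:
                    carrier = rng.random() < float(frac)
                carrier_state[group] = carrier
                if carrier:
                    cols = [c for c in groups[group] if c in markers]
                    record[cols[rng.integers(len(cols))]] = True
            records.append(record)
    return MarkerPanel(pd.DataFrame(records))


def random_sequence(length: int, seed: int, alphabet: str = DNA_ALPHABET) -> str:
    rng = np.random.default_rng(seed)
    return "".join(rng.choice(list(alphabet), size=length))


def mutate_sequence(
    seq: str,
    n_snps: int,
    seed: int,
    alphabet: str = DNA_ALPHABET,
    positions: Sequence[int] | None = None,
) -> str:
    """Introduce exactly ``n_snps`` substitutions at distinct positions.

    A substituted site never keeps its original state, so the Hamming
    distance to the input is exactly ``n_snps`` (identity (L - n)/L).
    ``positions`` restricts the candidate sites (used to keep mutation
    sets disjoint between alleles).
    """
    rng = np.random.default_rng(seed)
    pool = list(range(len(seq))) if positions is None else list(positions)
    if n_snps > len(pool):
        raise DomainError(f"n_snps={n_snps} exceeds {len(pool)} available sites")
    sites = rng.choice(pool, size=n_snps, replace=False)
    out = list(seq)
    for site in sites:
        choices = [c for c in alphabet if c != out[site]]
        out[site] = choices[rng.integers(len(choices))]
    return "".join(out)


def diverged_alleles(
    length: int,
    n_alleles: int,
    divergence: float,
    seed: int,
    alphabet: str = PROTEIN_ALPHABET,
) -> list[str]:
    """Generate an allele set whose pairwise identity is 1 - divergence.

    Each allele mutates a common ancestor at divergence/2 of its sites,
    using mutually disjoint site sets, so every allele pair differs at
    exactly ``2 * round(length * divergence / 2)`` positions — the target
    pairwise identity holds by construction, not just in expectation.
    """
    if not 0.0 <= divergence <= 1.0:
        raise DomainError("divergence must lie in [0, 1]")
    per_allele = round(length * divergence / 2)
    if n_alleles * per_allele > length:
        raise DomainError(
            f"{n_alleles} alleles x {per_allele} sites exceed length {length}"
        )
    rng = np.random.default_rng(seed)
    ancestor = "".join(rng.choice(list(alphabet), size=length))
    sites = rng.permutation(length)
    alleles = []
    for i in range(n_alleles):
        block = sites[i * per_allele : (i + 1) * per_allele]
        alleles.append(
            mutate_sequence(
                ancestor,
                per_allele,
                seed=int(rng.integers(2**31)),
                alphabet=alphabet,
                positions=list(map(int, block)),
            )
        )
    return alleles


#: expression/divergence archetypes of the four candidate-gene profiles a
#: genome screen turns up: a true S-RNase is pistil-specific, highly
#: expressed and highly diverged; relic RNase-like genes are neither.
SCREEN_ARCHETYPES: dict[str, dict[str, float]] = {
    "true_srnase_A": {"pistil": 150.0, "stamen": 0.0, "divergence": 0.35},
    "true_srnase_B": {"pistil": 120.0, "stamen": 0.5, "divergence": 0.37},
    "relic_low_divergence": {"pistil": 20.0, "stamen": 1.0, "divergence": 0.02},
    "relic_moderate": {"pistil": 60.0, "stamen": 22.0, "divergence": 0.05},
}


def simulate_screen_fixture(
    seed: int,
    length: int = 220,
    archetypes: Mapping[str, Mapping[str, float]] | None = None,
) -> tuple[list[CandidateGene], list[str]]:
    """Build a candidate-gene set with a known screening partition.

    Emits one gene per archetype plus reference S-RNase sequences related
    to the true-S-RNase alleles (so only those clear the
    reference-similarity bar).  The expected outcome is known by
    construction: the two ``true_srnase`` genes are PRIMARY, the relics
    are rejected on divergence (and expression/specificity).
    """
    archetypes = dict(archetypes or SCREEN_ARCHETYPES)
    rng = np.random.default_rng(seed)
    genes: list[CandidateGene] = []
    references: list[str] = []
    for name, spec in sorted(archetypes.items()):
        sub_seed = int(rng.integers(2**31))
        alleles = diverged_alleles(length, 3, float(spec["divergence"]), sub_seed)
        expression = [
            ExpressionSummary(name, "pistil", float(spec["pistil"]), n_reps=3),
            ExpressionSummary(name, "stamen", float(spec["stamen"]), n_reps=3),
        ]
        genes.append(
            CandidateGene(name=name, alleles=alleles, expression=expression)
        )
        if name.startswith("true_srnase"):
            # a homologue at ~40% divergence from one allele: close enough
            # to clear the 30%-identity reference bar, far enough to be a
            # distinct gene
            references.append(
                mutate_sequence(
                    alleles[0],
                    round(0.4 * length),
                    seed=int(rng.integers(2**31)),
                    alphabet=PROTEIN_ALPHABET,
                )
            )
    return genes, references
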