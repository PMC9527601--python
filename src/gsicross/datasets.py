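"""Bundled reference tables for the rose S-locus.

Small curated TSVs shipped with the package:

* ``pollination_seed_counts`` — seed S-genotype counts from nine
  half-compatible pollination series between diploid roses sharing one
  S-allele (Chinese alleles S_C1/S_C2 and their *R. multiflora*
  orthologues); the classic validation design for S-RNase genotyping.
* ``linkage_counts`` — recombinant/total tallies between the S-locus and
  the KSN (continuous flowering) and AP2-like (double flower) loci in two
  diploid F1 populations.
* ``slocus_features`` — the S-RNase and flanking SLF/FBX gene coordinates
  of the two Old Blush S-haplotypes, with stamen/pistil FPKM summaries.
* ``chinese_cultivar_panel`` — allele-specific marker presence/absence
  for 15 old Chinese cultivars with their flowering phenotypes.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from . import io
from .breeding_history import MarkerPanel
from .segregation_mapping import SeedGenotypeCounts
from .srnase_screen import CandidateGene

__all__ = [
    "pollination_seed_counts",
    "linkage_counts",
    "slocus_features",
    "chinese_cultivar_panel",
    "data_path",
]


def data_path(name: str):
    return resources.files("gsicross").joinpath("data", name)


def pollination_seed_counts() -> dict[str, SeedGenotypeCounts]:
    """Seed counts per cross; extra per-cross metadata via :func:`pollination_table`."""
    with resources.as_file(data_path("pollination_seed_counts.tsv")) as path:
        return io.load_seed_counts(path)


def pollination_table() -> pd.DataFrame:
    """The raw pollination table (incl. series and shared-allele columns)."""
    with resources.as_file(data_path("pollination_seed_counts.tsv")) as path:
        return io.read_table(path)


def linkage_counts() -> pd.DataFrame:
    with resources.as_file(data_path("linkage_counts.tsv")) as path:
        df = io.read_table(path, required=("population", "parent", "locus_a", "locus_b"))
    df["recombinants"] = df["recombinants"].astype(int)
    df["total"] = df["total"].astype(int)
    return df


def slocus_features() -> list[CandidateGene]:
    with resources.as_file(data_path("slocus_features.tsv")) as path:
        return io.load_features(path)


def chinese_cultivar_panel() -> MarkerPanel:
    with resources.as_file(data_path("chinese_cultivar_panel.tsv")) as path:
        return io.load_panel(path)
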