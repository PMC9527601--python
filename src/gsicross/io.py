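"""Readers and writers for the package's table and sequence formats.

Tables are TSV or CSV (auto-detected by extension); boolean marker
columns accept the field notation (``●`` present / ``×`` absent) as well
as 1/0/true/false and are written back as ASCII 1/0.  Coordinates are
1-based inclusive; a feature on the reverse strand is encoded start > end
and kept that way (span computations are orientation-agnostic).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml
from Bio import SeqIO

from .breeding_history import MarkerPanel
from .errors import ParseError, SchemaError
from .segregation_mapping import MappedMarker, SeedGenotypeCounts
from .si_core import Haplotype, PlantGenotype, RecombinationMap, SAllele, TraitAllele
from .srnase_screen import CandidateGene, ExpressionSummary, GeneFlag

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_table",
    "write_table",
    "load_plants",
    "load_recombination_map",
    "load_seed_counts",
    "load_markers",
    "load_panel",
    "load_features",
    "load_expression",
    "write_json",
]

_TRUE = {"1", "true", "yes", "y", "●"}  # ● = present
_FALSE = {"0", "false", "no", "n", "×", "x", ""}  # × = absent

#: trait-allele functional status by conventional allele name; anything
#: else defaults to functional unless the name is lower-case (mutant style)
KNOWN_TRAIT_FUNCTION = {
    "KSN_W": True,
    "ksn_copia": False,
    "ksn_null": False,
    "AP2_W": True,
    "ap2": False,
}


def _to_bool(value: object, where: str) -> bool:
    if isinstance(value, bool):
        return value
    if isinstance(value, (int, float)) and value in (0, 1):
        return bool(value)
    text = str(value).strip().lower()
    if text in _TRUE:
        return True
    if text in _FALSE:
        return False
    raise SchemaError(f"{where}: cannot read {value!r} as presence/absence")


def _sep(path: str | Path) -> str:
    return "," if str(path).lower().endswith(".csv") else "\t"


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an order-preserving ``{id: sequence}`` map.

    Rejects duplicate ids and empty records, naming the record and its
    line number.  Wrapping is normalised away by construction.
    """
    path = Path(path)
    # pre-scan header lines so errors can cite line numbers
    header_lines: dict[int, str] = {}
    with open(path) as handle:
        for lineno, line in enumerate(handle, 1):
            if line.startswith(">"):
                header_lines[lineno] = line[1:].split()[0] if line[1:].split() else ""
    line_of = {}
    for lineno, rid in header_lines.items():
        line_of.setdefault(rid, lineno)
    records: dict[str, str] = {}
    with open(path) as handle:
        for record in SeqIO.parse(handle, "fasta"):
            if record.id in records:
                raise ParseError(
                    f"{path}:{line_of.get(record.id, '?')}: duplicate sequence id {record.id!r}"
                )
            seq = str(record.seq).upper()
            if not seq:
                raise ParseError(
                    f"{path}:{line_of.get(record.id, '?')}: empty record {record.id!r}"
                )
            if not seq.isalpha():
                raise ParseError(
                    f"{path}:{line_of.get(record.id, '?')}: illegal characters in {record.id!r}"
                )
            records[record.id] = seq
    return records


def write_fasta(path: str | Path, sequences: Mapping[str, str], width: int = 60) -> None:
    with open(path, "w") as handle:
        for name, seq in sequences.items():
            handle.write(f">{name}\n")
            for i in range(0, len(seq), width):
                handle.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# generic tables


def read_table(
    path: str | Path,
    required: Sequence[str] = (),
    bool_columns: Sequence[str] = (),
) -> pd.DataFrame:
    """Read a TSV/CSV into a DataFrame, validating columns and booleans."""
    df = pd.read_csv(path, sep=_sep(path), dtype=object, keep_default_na=False)
    missing = set(required) - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing columns {sorted(missing)}")
    for col in bool_columns:
        if col in df.columns:
            df[col] = [
                _to_bool(v, f"{path}: row {i + 2}, column {col}")
                for i, v in enumerate(df[col])
            ]
    return df


def write_table(path: str | Path, df: pd.DataFrame) -> None:
    out = df.copy()
    for col in out.columns:
        if out[col].dtype == bool:
            out[col] = out[col].astype(int)
    out.to_csv(path, sep=_sep(path), index=False)


def write_json(path: str | Path, payload: Mapping[str, object]) -> None:
    with open(path, "w") as handle:
        json.dump(payload, handle, indent=2, sort_keys=True, default=str)
        handle.write("\n")


# ---------------------------------------------------------------------------
# domain loaders


def _mk_s_allele(label: str) -> SAllele:
    # Sx / Sy / S? labels denote anonymous (unidentified) alleles
    return SAllele(label, anonymous=label in ("Sx", "Sy") or label.startswith("S?"))


def _mk_trait(locus: str, allele: str) -> TraitAllele:
    if allele in KNOWN_TRAIT_FUNCTION:
        functional = KNOWN_TRAIT_FUNCTION[allele]
    else:
        functional = not allele.islower()
    return TraitAllele(locus, allele, functional)


def load_plants(path: str | Path) -> dict[str, PlantGenotype]:
    """Load phased plant genotypes.

    Columns: ``plant_id``, ``ploidy``, ``hap_index``, ``s_allele``, then
    one column per trait locus (e.g. ``KSN``, ``AP2``) holding the allele
    name on that haplotype.
    """
    df = read_table(path, required=("plant_id", "ploidy", "hap_index", "s_allele"))
    loci = [c for c in df.columns if c not in ("plant_id", "ploidy", "hap_index", "s_allele")]
    plants: dict[str, PlantGenotype] = {}
    for plant_id, group in df.groupby("plant_id", sort=False):
        ploidies = set(group["ploidy"])
        if len(ploidies) != 1:
            raise SchemaError(f"{path}: {plant_id}: inconsistent ploidy values")
        ploidy = int(ploidies.pop())
        group = group.sort_values("hap_index", key=lambda s: s.astype(int))
        haps = []
        for _, row in group.iterrows():
            traits = tuple(
                _mk_trait(locus, str(row[locus])) for locus in loci if str(row[locus])
            )
            haps.append(Haplotype(_mk_s_allele(str(row["s_allele"])), traits))
        try:
            plants[str(plant_id)] = PlantGenotype(str(plant_id), ploidy, tuple(haps))
        except ValueError as exc:
            raise SchemaError(f"{path}: {plant_id}: {exc}") from exc
    return plants


def load_recombination_map(path: str | Path) -> RecombinationMap:
    """Load a locus -> r map from YAML (``{locus: r}``) or TSV (locus, r)."""
    path = Path(path)
    if path.suffix.lower() in (".yaml", ".yml"):
        with open(path) as handle:
            payload = yaml.safe_load(handle) or {}
        if not isinstance(payload, Mapping):
            raise SchemaError(f"{path}: expected a mapping locus -> r")
        return RecombinationMap({str(k): float(v) for k, v in payload.items()})
    df = read_table(path, required=("locus", "r"))
    return RecombinationMap({str(row["locus"]): float(row["r"]) for _, row in df.iterrows()})


def load_seed_counts(path: str | Path) -> dict[str, SeedGenotypeCounts]:
    """Load seed S-genotype count tables, one entry per cross.

    Columns: ``cross_id``, ``mother_id``, ``mother_s1``, ``mother_s2``,
    ``seed_genotype`` (alleles joined by ``/``), ``count`` — plus any
    extra annotation columns, which are ignored here.
    """
    df = read_table(
        path,
        required=("cross_id", "mother_id", "mother_s1", "mother_s2", "seed_genotype", "count"),
    )
    crosses: dict[str, SeedGenotypeCounts] = {}
    for cross_id, group in df.groupby("cross_id", sort=False):
        first = group.iloc[0]
        mother = PlantGenotype.diploid(
            str(first["mother_id"]),
            Haplotype(_mk_s_allele(str(first["mother_s1"]))),
            Haplotype(_mk_s_allele(str(first["mother_s2"]))),
        )
        counts: dict[tuple[str, ...], int] = {}
        for i, row in group.iterrows():
            try:
                n = int(row["count"])
            except ValueError as exc:
                raise SchemaError(f"{path}: row {i + 2}: non-integer count") from exc
            if n < 0:
                raise SchemaError(f"{path}: row {i + 2}: negative count")
            genotype = tuple(sorted(str(row["seed_genotype"]).split("/")))
            counts[genotype] = counts.get(genotype, 0) + n
        crosses[str(cross_id)] = SeedGenotypeCounts(str(cross_id), mother, counts)
    return crosses


def load_markers(path: str | Path) -> list[MappedMarker]:
    """Load mapped markers: columns ``name``, ``cm``, ``bp``."""
    df = read_table(path, required=("name", "cm", "bp"))
    return [
        MappedMarker(cm=float(row["cm"]), bp=int(row["bp"]), name=str(row["name"]))
        for _, row in df.iterrows()
    ]


def load_panel(path: str | Path) -> MarkerPanel:
    """Load a cultivar marker panel; marker columns are parsed as booleans."""
    df = read_table(path, required=("name",))
    reserved = {"name", "year", "period", "ploidy", "bloom", "flower", "ksn_type"}
    marker_cols = [c for c in df.columns if c not in reserved]
    for col in marker_cols:
        df[col] = [
            _to_bool(v, f"{path}: row {i + 2}, column {col}")
            for i, v in enumerate(df[col])
        ]
    if "year" in df.columns:
        df["year"] = [int(v) if str(v) else None for v in df["year"]]
    if "ploidy" in df.columns:
        df["ploidy"] = [int(v) if str(v) else 2 for v in df["ploidy"]]
    return MarkerPanel(df)


def load_features(path: str | Path) -> list[CandidateGene]:
    """Load an S-locus gene feature table into CandidateGene records."""
    df = read_table(
        path, required=("gene", "s_haplotype", "chromosome", "start", "end")
    )
    genes: list[CandidateGene] = []
    for i, row in df.iterrows():
        flags = set()
        raw_flags = str(row.get("flags", "")).strip()
        if raw_flags:
            for token in raw_flags.split(","):
                flags.add(GeneFlag(token.strip().lower()))
        expression = []
        for tissue in ("stamen", "pistil"):
            mean_col, se_col = f"{tissue}_fpkm", f"{tissue}_se"
            if mean_col in df.columns and str(row[mean_col]).strip():
                expression.append(
                    ExpressionSummary(
                        gene=str(row["gene"]),
                        tissue=tissue,
                        mean_fpkm=float(row[mean_col]),
                        se_fpkm=float(row[se_col]) if str(row.get(se_col, "")).strip() else 0.0,
                        n_reps=3,
                    )
                )
        try:
            genes.append(
                CandidateGene(
                    name=str(row["gene"]),
                    chromosome=str(row["chromosome"]),
                    start=int(row["start"]),
                    end=int(row["end"]),
                    expression=expression,
                    flags=flags,
                    s_haplotype=str(row["s_haplotype"]),
                )
            )
        except ValueError as exc:
            raise SchemaError(f"{path}: row {i + 2}: {exc}") from exc
    return genes


def load_expression(path: str | Path) -> list[ExpressionSummary]:
    """Load a long-format expression table: gene, tissue, mean_fpkm[, se, n]."""
    df = read_table(path, required=("gene", "tissue", "mean_fpkm"))
    out = []
    for i, row in df.iterrows():
        try:
            out.append(
                ExpressionSummary(
                    gene=str(row["gene"]),
                    tissue=str(row["tissue"]),
                    mean_fpkm=float(row["mean_fpkm"]),
                    se_fpkm=float(row["se"]) if "se" in df.columns and str(row["se"]) else 0.0,
                    n_reps=int(row["n"]) if "n" in df.columns and str(row["n"]) else 1,
                )
            )
        except ValueError as exc:
            raise SchemaError(f"{path}: row {i + 2}: {exc}") from exc
    return out
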