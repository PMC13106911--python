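"""Readers and writers for every external artifact of the pipeline.

Formats handled
---------------
* long-format precursor reports (TSV, one row per precursor × run) in a
  configurable column dialect whose defaults mirror a Spectronaut-style
  export;
* protein FASTA with UniProt-style headers (``db|ACC|NAME ... OS=... GN=...``);
* GMT gene-set collections;
* feature × cell abundance matrices as TSV with empty fields for missing
  values (lossless round-trip of values and missingness);
* JSON run manifests.

Raw report intensities are linear; matrices written by the pipeline are in
log2 space after the transform stage — the boundary is recorded in the run
manifest, not in the files themselves.
"""

from __future__ import annotations

import json
import logging
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from .annotations import ProteinAnnotation, flag_contaminant_classes
from .errors import FormatError

logger = logging.getLogger(__name__)

#: Logical field -> column header, Spectronaut-like defaults.  ``genes`` is
#: optional in the input; all other fields are mandatory.
SPECTRONAUT_DIALECT: dict[str, str] = {
    "run_id": "R.FileName",
    "protein_group": "PG.ProteinGroups",
    "genes": "PG.Genes",
    "organisms": "PG.Organisms",
    "modified_sequence": "EG.ModifiedSequence",
    "charge": "FG.Charge",
    "q_value": "EG.Qvalue",
    "intensity": "FG.MS2Quantity",
}

MANDATORY_FIELDS = (
    "run_id",
    "protein_group",
    "organisms",
    "modified_sequence",
    "charge",
    "q_value",
    "intensity",
)

#: Accepted encodings of a missing intensity (case-insensitive), plus zero.
MISSING_INTENSITY_TOKENS = frozenset({"", "na", "nan", "filtered", "#n/a", "none", "null"})


@dataclass
class PrecursorRecord:
    """One identification of a precursor (modified sequence + charge) in one run."""

    run_id: str
    protein_group: tuple[str, ...]
    gene_symbols: tuple[str, ...]
    organisms: tuple[str, ...]
    modified_sequence: str
    charge: int
    q_value: float
    intensity: float | None  # linear scale; None when missing

    @property
    def precursor_key(self) -> str:
        return f"{self.modified_sequence}/{self.charge}"

    @property
    def group_key(self) -> str:
        return ";".join(self.protein_group)


@dataclass
class GeneSet:
    term_id: str
    term_name: str
    member_genes: frozenset[str]


@dataclass
class GeneSetCollection:
    """GO-style gene sets keyed by term id."""

    sets: dict[str, GeneSet] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.values())

    def __getitem__(self, term_id: str) -> GeneSet:
        return self.sets[term_id]


def _split_multi(value: str) -> tuple[str, ...]:
    return tuple(part.strip() for part in str(value).split(";"))


def _parse_intensity(raw: object, row_number: int) -> float | None:
    if raw is None or (isinstance(raw, float) and math.isnan(raw)):
        return None
    token = str(raw).strip()
    if token.lower() in MISSING_INTENSITY_TOKENS:
        return None
    try:
        value = float(token)
    except ValueError:
        return None  # unparseable -> missing-intensity record
    if math.isnan(value) or value == 0.0:
        return None
    if value < 0:
        raise FormatError(f"negative intensity {value!r} in data row {row_number}")
    return value


def read_precursor_report(
    path: str | Path,
    dialect: Mapping[str, str] | None = None,
) -> list[PrecursorRecord]:
    """Parse a long-format TSV precursor report into records.

    ``dialect`` maps logical field names (keys of
    :data:`SPECTRONAUT_DIALECT`) to the file's column headers; omitted keys
    fall back to the Spectronaut-like defaults.  Parsing is order-preserving
    and total: one record per data row.
    """
    cols = dict(SPECTRONAUT_DIALECT)
    if dialect:
        unknown = set(dialect) - set(cols)
        if unknown:
            raise FormatError(f"unknown dialect fields: {sorted(unknown)}")
        cols.update(dialect)

    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for logical in MANDATORY_FIELDS:
        if cols[logical] not in frame.columns:
            raise FormatError(
                f"precursor report is missing mandatory column "
                f"{cols[logical]!r} (field {logical!r})"
            )
    has_genes = cols["genes"] in frame.columns

    records: list[PrecursorRecord] = []
    for i, row in enumerate(frame.itertuples(index=False), start=1):
        row = dict(zip(frame.columns, row))
        group = _split_multi(row[cols["protein_group"]])
        organisms = _split_multi(row[cols["organisms"]])
        if len(organisms) == 1 and len(group) > 1:
            organisms = organisms * len(group)
        if len(organisms) != len(group):
            raise FormatError(
                f"row {i}: {len(group)} accessions but {len(organisms)} organisms"
            )
        if has_genes and str(row[cols["genes"]]).strip():
            genes = _split_multi(row[cols["genes"]])
            if len(genes) == 1 and len(group) > 1:
                genes = genes * len(group)
            if len(genes) != len(group):
                raise FormatError(
                    f"row {i}: {len(group)} accessions but {len(genes)} gene symbols"
                )
        else:
            genes = group
        try:
            charge = int(float(row[cols["charge"]]))
        except ValueError as exc:
            raise FormatError(f"row {i}: unparseable charge {row[cols['charge']]!r}") from exc
        if charge <= 0:
            raise FormatError(f"row {i}: charge must be positive, got {charge}")
        try:
            q_value = float(row[cols["q_value"]])
        except ValueError as exc:
            raise FormatError(f"row {i}: unparseable q-value {row[cols['q_value']]!r}") from exc
        if not 0.0 <= q_value <= 1.0:
            raise FormatError(f"row {i}: q-value {q_value} outside [0, 1]")
        records.append(
            PrecursorRecord(
                run_id=str(row[cols["run_id"]]).strip(),
                protein_group=group,
                gene_symbols=genes,
                organisms=organisms,
                modified_sequence=str(row[cols["modified_sequence"]]).strip(),
                charge=charge,
                q_value=q_value,
                intensity=_parse_intensity(row[cols["intensity"]], i),
            )
        )
    return records


def write_precursor_report(
    records: Iterable[PrecursorRecord],
    path: str | Path,
    dialect: Mapping[str, str] | None = None,
) -> None:
    """Write records in the same TSV dialect :func:`read_precursor_report` reads."""
    cols = dict(SPECTRONAUT_DIALECT)
    if dialect:
        cols.update(dialect)
    rows = []
    for rec in records:
        rows.append(
            {
                cols["run_id"]: rec.run_id,
                cols["protein_group"]: ";".join(rec.protein_group),
                cols["genes"]: ";".join(rec.gene_symbols),
                cols["organisms"]: ";".join(rec.organisms),
                cols["modified_sequence"]: rec.modified_sequence,
                cols["charge"]: rec.charge,
                cols["q_value"]: f"{rec.q_value:.6g}",
                cols["intensity"]: "" if rec.intensity is None else f"{rec.intensity:.6f}",
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# FASTA


def _parse_uniprot_header(description: str) -> tuple[str, str | None, str | None]:
    """Return (accession, organism, gene) from a UniProt-style description.

    The organism is everything after ``OS=`` up to the next `` XX=`` token;
    the gene is the token after ``GN=``.
    """
    first = description.split()[0]
    parts = first.split("|")
    accession = parts[1] if len(parts) >= 2 else first

    organism = None
    os_idx = description.find("OS=")
    if os_idx >= 0:
        rest = description[os_idx + 3 :]
        m = re.search(r"\s[A-Z][A-Z0-9]=", rest)
        organism = (rest[: m.start()] if m else rest).strip()

    gene = None
    gn_idx = description.find("GN=")
    if gn_idx >= 0:
        gene = description[gn_idx + 3 :].split()[0].strip() or None
    return accession, organism, gene


def read_fasta(
    path: str | Path,
    histone_list: frozenset[str] | None = None,
) -> dict[str, ProteinAnnotation]:
    """Parse a protein FASTA into annotations keyed by accession.

    A header without ``GN=`` falls back to the accession as gene symbol;
    contaminant-class flags (keratin / histone) are computed from the gene
    symbol.
    """
    annotations: dict[str, ProteinAnnotation] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        accession, organism, gene = _parse_uniprot_header(record.description)
        sequence = str(record.seq).strip().upper()
        if not sequence:
            raise FormatError(f"empty sequence for accession {accession!r}")
        if accession in annotations:
            raise FormatError(f"duplicate accession {accession!r} in FASTA")
        annotations[accession] = ProteinAnnotation(
            accession=accession,
            gene_symbol=gene or accession,
            organism=organism or "",
            sequence=sequence,
        )
    flag_contaminant_classes(annotations, histone_list)
    return annotations


def write_fasta(annotations: Iterable[ProteinAnnotation], path: str | Path) -> None:
    with open(path, "w") as fh:
        for ann in annotations:
            fh.write(
                f">sp|{ann.accession}|{ann.gene_symbol}_SYN synthetic protein "
                f"OS={ann.organism} GN={ann.gene_symbol}\n"
            )
            for i in range(0, len(ann.sequence), 60):
                fh.write(ann.sequence[i : i + 60] + "\n")


# ---------------------------------------------------------------------------
# GMT


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a GMT file: ``term_id TAB description TAB gene TAB gene ...``."""
    collection = GeneSetCollection()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"GMT line {lineno} has {len(fields)} fields (< 3)")
            term_id, term_name = fields[0], fields[1]
            genes = frozenset(g.strip() for g in fields[2:] if g.strip())
            if not genes:
                raise FormatError(f"GMT line {lineno}: term {term_id!r} has no members")
            if term_id in collection.sets:
                raise FormatError(f"duplicate GMT term id {term_id!r}")
            collection.sets[term_id] = GeneSet(term_id, term_name, genes)
    if not collection.sets:
        logger.warning("GMT file %s contains no gene sets", path)
    return collection


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for gs in collection:
            members = "\t".join(sorted(gs.member_genes))
            fh.write(f"{gs.term_id}\t{gs.term_name}\t{members}\n")


# ---------------------------------------------------------------------------
# Matrices and tables


def write_matrix(matrix: pd.DataFrame, path: str | Path, index_label: str = "feature") -> None:
    """Write a feature × cell matrix as TSV; missing values become empty fields."""
    matrix.to_csv(path, sep="\t", na_rep="", index_label=index_label)


def read_matrix(path: str | Path) -> pd.DataFrame:
    """Read a matrix written by :func:`write_matrix` (empty field = missing)."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_metadata(metadata: pd.DataFrame, path: str | Path) -> None:
    metadata.to_csv(path, sep="\t", index=False)


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read the cell metadata table (cell_id, chip_id, diameter_um[, passed_image_qc])."""
    meta = pd.read_csv(path, sep="\t")
    for col in ("cell_id", "chip_id", "diameter_um"):
        if col not in meta.columns:
            raise FormatError(f"metadata table is missing column {col!r}")
    if meta["cell_id"].duplicated().any():
        dupes = meta.loc[meta["cell_id"].duplicated(), "cell_id"].tolist()
        raise FormatError(f"duplicate cell ids in metadata: {dupes}")
    if (meta["diameter_um"] <= 0).any():
        raise FormatError("diameter_um must be positive")
    if "passed_image_qc" not in meta.columns:
        meta["passed_image_qc"] = True
    return meta


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (set, frozenset)):
        return sorted(obj)
    if isinstance(obj, Path):
        return str(obj)
    return str(obj)


def write_manifest(manifest: Mapping, path: str | Path) -> None:
    """Serialize the run manifest (parameters, seeds, stage counts) as JSON."""
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=False, default=_json_default)
        fh.write("\n")


def read_manifest(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)
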