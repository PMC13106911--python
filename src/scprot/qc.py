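"""Filtering cascade from raw precursor records to an analysis-ready matrix.

The stages run in a fixed order, mirroring how post-search processing of
single-cell DIA data is usually described:

1. q-value filter (strict ``< threshold``);
2. species-unambiguity filter (every accession of the protein group must be
   the target organism);
3. keratin contaminant removal (any group member a keratin);
4. matrix construction (precursor × cell, log2 intensity, explicit missing);
5. per-cell minimum identified-precursor filter (strict ``< min``) — counts
   are taken *after* the record-level filters;
6. per-precursor sample-coverage filter (precursors observed in fewer than
   ``min_fraction`` of the remaining cells are dropped; exactly the boundary
   fraction is retained).

Every stage logs its in/out counts into a :class:`FilterReport` so that the
run manifest reconciles exactly with the input record count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotations import (
    ProteinAnnotation,
    flag_contaminant_classes,
    is_histone_gene,
    is_keratin_gene,
)
from .errors import AnnotationLookupError, IntegrityError, PipelineError
from .io_formats import PrecursorRecord

__all__ = [
    "FilterReport",
    "PrecursorMatrix",
    "flag_contaminant_classes",
    "filter_qvalue",
    "filter_species_unambiguous",
    "filter_keratins",
    "build_matrix",
    "filter_cells_min_precursors",
    "filter_precursor_coverage",
    "completeness_profile",
]

logger = logging.getLogger(__name__)


@dataclass
class FilterReport:
    """Ordered per-stage record/feature counts plus removed cells."""

    stages: list[dict] = field(default_factory=list)
    cells_removed: list[str] = field(default_factory=list)

    def log(self, stage_name: str, records_in: int, records_out: int, **extra) -> None:
        if records_out > records_in:
            raise IntegrityError(
                f"stage {stage_name!r}: records_out {records_out} > records_in {records_in}"
            )
        entry = {"stage": stage_name, "records_in": records_in, "records_out": records_out}
        entry.update(extra)
        self.stages.append(entry)
        logger.info(
            "stage %-22s in=%d out=%d removed=%d",
            stage_name,
            records_in,
            records_out,
            records_in - records_out,
        )

    def to_dict(self) -> dict:
        return {"stages": self.stages, "cells_removed": self.cells_removed}


@dataclass
class PrecursorMatrix:
    """Precursor × cell log2-abundance matrix with explicit missingness.

    ``values`` has one row per precursor (index ``"<modified_sequence>/<charge>"``)
    and one column per cell; NaN marks an unobserved precursor.  ``precursors``
    carries per-row metadata (modified_sequence, charge, protein_group,
    genes) aligned to ``values.index``.
    """

    values: pd.DataFrame
    precursors: pd.DataFrame

    @property
    def mask(self) -> pd.DataFrame:
        """Observed-value indicator."""
        return self.values.notna()

    def copy(self) -> "PrecursorMatrix":
        return PrecursorMatrix(self.values.copy(), self.precursors.copy())


def filter_qvalue(
    records: list[PrecursorRecord],
    threshold: float = 0.01,
    report: FilterReport | None = None,
) -> list[PrecursorRecord]:
    """Keep records identified below the q-value threshold (strict ``<``)."""
    kept = [r for r in records if r.q_value < threshold]
    if report is not None:
        report.log("q_value", len(records), len(kept), threshold=threshold)
    return kept


def filter_species_unambiguous(
    records: list[PrecursorRecord],
    annotations: dict[str, ProteinAnnotation],
    target_organism: str = "Homo sapiens",
    report: FilterReport | None = None,
) -> list[PrecursorRecord]:
    """Keep records whose every protein-group member is the target organism.

    A precursor shared between a human and a bovine protein cannot be
    attributed unambiguously and is removed wholesale.
    """
    kept = []
    for rec in records:
        organisms = []
        for acc in rec.protein_group:
            if acc not in annotations:
                raise AnnotationLookupError(f"no annotation for accession {acc!r}")
            organisms.append(annotations[acc].organism)
        if all(org == target_organism for org in organisms):
            kept.append(rec)
    if report is not None:
        report.log("species_unambiguous", len(records), len(kept), target=target_organism)
    return kept


def filter_keratins(
    records: list[PrecursorRecord],
    annotations: dict[str, ProteinAnnotation],
    report: FilterReport | None = None,
) -> list[PrecursorRecord]:
    """Remove records where ANY protein-group member is flagged as keratin."""
    kept = []
    for rec in records:
        keratin = False
        for acc in rec.protein_group:
            ann = annotations.get(acc)
            if ann is not None:
                keratin = keratin or ann.is_keratin
            else:
                keratin = keratin or any(is_keratin_gene(g) for g in rec.gene_symbols)
        if not keratin:
            kept.append(rec)
    if report is not None:
        report.log("keratin_removal", len(records), len(kept))
    return kept


def build_matrix(
    records: list[PrecursorRecord],
    report: FilterReport | None = None,
    on_duplicate: str = "error",
) -> PrecursorMatrix:
    """Pivot records into a precursor × cell log2-intensity matrix.

    Records with missing intensity contribute no observation.  A duplicate
    (precursor, run) pair raises an :class:`IntegrityError` unless
    ``on_duplicate="max"`` resolves it by keeping the larger intensity.
    """
    if on_duplicate not in ("error", "max"):
        raise ValueError(f"on_duplicate must be 'error' or 'max', got {on_duplicate!r}")
    meta: dict[str, dict] = {}
    cells: list[str] = []
    cell_seen = set()
    obs_key: list[str] = []
    obs_run: list[str] = []
    obs_int: list[float] = []
    for rec in records:
        key = rec.precursor_key
        if key not in meta:
            meta[key] = {
                "modified_sequence": rec.modified_sequence,
                "charge": rec.charge,
                "protein_group": rec.group_key,
                "genes": ";".join(rec.gene_symbols),
            }
        if rec.run_id not in cell_seen:
            cell_seen.add(rec.run_id)
            cells.append(rec.run_id)
        if rec.intensity is None:
            continue
        obs_key.append(key)
        obs_run.append(rec.run_id)
        obs_int.append(rec.intensity)
    obs = pd.DataFrame({"key": obs_key, "run": obs_run, "intensity": obs_int})
    dup = obs.duplicated(subset=["key", "run"], keep=False)
    if dup.any():
        if on_duplicate == "error":
            first = obs.loc[dup, ["key", "run"]].iloc[0]
            raise IntegrityError(
                f"duplicate precursor-run pair ({first['key']!r}, {first['run']!r})"
            )
        obs = obs.groupby(["key", "run"], as_index=False, sort=False)["intensity"].max()
    index = list(meta)
    if obs.empty:
        values = pd.DataFrame(np.nan, index=index, columns=cells, dtype=float)
    else:
        obs["log2"] = np.log2(obs["intensity"].to_numpy())
        values = (
            obs.pivot(index="key", columns="run", values="log2")
            .reindex(index=index, columns=cells)
        )
        values.index.name = None
        values.columns.name = None
    precursors = pd.DataFrame.from_dict(meta, orient="index").loc[index]
    matrix = PrecursorMatrix(values, precursors)
    if report is not None:
        report.log(
            "build_matrix",
            len(records),
            len(records),
            n_precursors=len(index),
            n_cells=len(cells),
            n_observed=int(matrix.mask.to_numpy().sum()),
        )
    return matrix


def filter_cells_min_precursors(
    matrix: PrecursorMatrix,
    min_precursors: int = 500,
    report: FilterReport | None = None,
) -> tuple[PrecursorMatrix, list[str]]:
    """Drop cells identifying fewer than ``min_precursors`` precursors (strict ``<``)."""
    if matrix.values.empty:
        raise PipelineError("cell filter received an empty matrix")
    counts = matrix.mask.sum(axis=0)
    keep = counts[counts >= min_precursors].index
    removed = [c for c in matrix.values.columns if c not in set(keep)]
    if len(keep) == 0:
        raise PipelineError(
            f"all {matrix.values.shape[1]} cells fall below min_precursors="
            f"{min_precursors}; review the threshold"
        )
    out = PrecursorMatrix(matrix.values.loc[:, keep], matrix.precursors)
    if report is not None:
        report.log(
            "cell_min_precursors",
            matrix.values.shape[1],
            len(keep),
            min_precursors=min_precursors,
            cells_removed=removed,
        )
        report.cells_removed.extend(removed)
    return out, removed


def filter_precursor_coverage(
    matrix: PrecursorMatrix,
    min_fraction: float = 0.5,
    report: FilterReport | None = None,
) -> PrecursorMatrix:
    """Drop precursors observed in fewer than ``min_fraction`` of cells.

    The boundary is inclusive: a precursor observed in exactly the minimum
    fraction of cells is retained.
    """
    n_cells = matrix.values.shape[1]
    frac = matrix.mask.sum(axis=1) / n_cells
    keep = frac[frac >= min_fraction].index
    out = PrecursorMatrix(matrix.values.loc[keep], matrix.precursors.loc[keep])
    if report is not None:
        report.log(
            "precursor_coverage",
            matrix.values.shape[0],
            len(keep),
            min_fraction=min_fraction,
        )
    return out


def completeness_profile(matrix: PrecursorMatrix) -> dict:
    """Precursor counts at coverage thresholds 0.1..1.0 plus overall completeness."""
    thresholds = [round(0.1 * t, 1) for t in range(1, 11)]
    if matrix.values.size == 0:
        return {
            "counts_at_threshold": {t: 0 for t in thresholds},
            "overall_completeness": 0.0,
        }
    frac = matrix.mask.sum(axis=1) / matrix.values.shape[1]
    counts = {t: int((frac >= t).sum()) for t in thresholds}
    overall = float(matrix.mask.to_numpy().mean())
    return {"counts_at_threshold": counts, "overall_completeness": overall}
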