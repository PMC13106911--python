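"""Protein-level quantitation: scaling, imputation, MaxLFQ, and iBAQ.

The stage order follows standard post-search processing of DIA data:
per-precursor median-centering to a relative scale, iterative-SVD imputation
of the remaining missing values, MaxLFQ least-squares summarization of
precursors to protein groups, and (from the *pre*-normalization linear
intensities) iBAQ absolute-abundance estimates.

MaxLFQ here is the pairwise-median / least-squares core: for every pair of
cells the protein's log2 ratio is the median of the shared precursors'
differences, and per-cell protein abundances are the least-squares solution
of the resulting (possibly incomplete) system, solved independently on each
connected component of the cell-pair graph.  The gauge freedom (one additive
constant per component) is fixed by anchoring each component's mean estimate
to the mean of its cells' observed precursor values.
"""

from __future__ import annotations

import logging
import re
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import connected_components
from scipy.sparse import csr_matrix

from .annotations import AMINO_ACIDS, ProteinAnnotation
from .errors import FormatError, ParameterError, PipelineError
from .qc import PrecursorMatrix

logger = logging.getLogger(__name__)


@dataclass
class ProteinMatrix:
    """Protein-group × cell log2 abundance matrix (relative scale).

    ``values`` is indexed by protein-group key (``;``-joined accessions);
    ``proteins`` carries the lead accession and gene symbol per row.
    """

    values: pd.DataFrame
    proteins: pd.DataFrame

    def copy(self) -> "ProteinMatrix":
        return ProteinMatrix(self.values.copy(), self.proteins.copy())


@dataclass
class ImputeResult:
    values: pd.DataFrame
    converged: bool
    n_iter: int


# ---------------------------------------------------------------------------
# Relative scaling


def median_center_rows(values: pd.DataFrame) -> pd.DataFrame:
    """Convert to a relative scale: subtract each row's observed median.

    Missing entries stay missing; the median is taken over observed values
    only, so each row's observed values end up with median exactly 0.
    Idempotent.
    """
    arr = values.to_numpy(dtype=float)
    if np.all(np.isnan(arr), axis=1).any():
        bad = values.index[np.all(np.isnan(arr), axis=1)][:5].tolist()
        raise PipelineError(f"rows with no observed values cannot be centered: {bad}")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        med = np.nanmedian(arr, axis=1, keepdims=True)
    return pd.DataFrame(arr - med, index=values.index, columns=values.columns)


# ---------------------------------------------------------------------------
# Iterative-SVD imputation


def svd_impute(
    values: pd.DataFrame,
    n_components: int = 5,
    tol: float = 1e-2,
    max_iter: int = 100,
) -> ImputeResult:
    """Fill missing entries by iterative rank-``n_components`` SVD reconstruction.

    Missing entries start at 0 (the matrix is expected to be row-centered);
    each iteration takes the truncated SVD of the current matrix and replaces
    *only* the missing entries with the low-rank reconstruction.  Iteration
    stops when the relative change of the imputed entries
    (``‖Δimputed‖₂ / ‖imputed‖₂``) drops below ``tol``.  Observed entries are
    never modified.
    """
    arr = values.to_numpy(dtype=float)
    missing = np.isnan(arr)
    n_rows, n_cols = arr.shape
    if n_components >= min(n_rows, n_cols):
        raise ParameterError(
            f"n_components={n_components} must be < min(rows, cols)={min(n_rows, n_cols)}"
        )
    if np.all(missing, axis=1).any() or np.all(missing, axis=0).any():
        raise ParameterError("every row and column must have at least one observed value")
    if not missing.any():
        return ImputeResult(values.copy(), converged=True, n_iter=0)

    current = np.where(missing, 0.0, arr)
    converged = False
    iteration = 0
    for iteration in range(1, max_iter + 1):
        u, s, vt = np.linalg.svd(current, full_matrices=False)
        recon = (u[:, :n_components] * s[:n_components]) @ vt[:n_components]
        new_imputed = recon[missing]
        delta = np.sqrt(np.sum((new_imputed - current[missing]) ** 2))
        scale = np.sqrt(np.sum(new_imputed**2))
        current = np.where(missing, 0.0, arr)
        current[missing] = new_imputed
        if scale == 0.0:
            rel = 0.0 if delta == 0.0 else np.inf
        else:
            rel = delta / scale
        if rel < tol:
            converged = True
            break
    if not converged:
        logger.warning(
            "svd_impute did not converge in %d iterations (last rel change %.3g)",
            max_iter,
            rel,
        )
    out = pd.DataFrame(current, index=values.index, columns=values.columns)
    return ImputeResult(out, converged=converged, n_iter=iteration)


# ---------------------------------------------------------------------------
# MaxLFQ


def maxlfq(values: np.ndarray | pd.DataFrame, min_shared: int = 1) -> np.ndarray:
    """Estimate per-cell protein log2 abundance from one group's precursors.

    ``values`` is a precursor × cell log2 matrix (NaN = missing).  For every
    cell pair with at least ``min_shared`` precursors observed in both, the
    pairwise ratio is the median of the per-precursor differences; the
    per-cell abundances solve the least-squares system of those ratios on
    each connected component of the pair graph, anchored so that the mean
    estimate of a component equals the mean of all observed values in its
    cells.  Cells with no observations get NaN.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 2 or x.shape[0] < 1 or x.shape[1] < 1:
        raise ParameterError("maxlfq needs a non-empty 2-D precursor × cell matrix")
    n_prec, n_cells = x.shape
    observed = ~np.isnan(x)
    result = np.full(n_cells, np.nan)

    if n_cells == 1:
        if observed[:, 0].any():
            result[0] = np.nanmean(x[:, 0])
        return result

    # Pairwise medians of differences x[:, b] - x[:, a] over shared precursors.
    shared = observed.astype(np.int64).T @ observed.astype(np.int64)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        diffs = x[:, None, :] - x[:, :, None]  # [prec, a, b]
        ratio = np.nanmedian(diffs, axis=0)  # [a, b]
    valid = (shared >= max(1, min_shared)) & ~np.eye(n_cells, dtype=bool)
    valid &= ~np.isnan(ratio)

    adjacency = csr_matrix(valid)
    n_comp, labels = connected_components(adjacency, directed=False)
    for comp in range(n_comp):
        cells = np.flatnonzero(labels == comp)
        comp_obs = observed[:, cells]
        if not comp_obs.any():
            continue  # no observations anywhere in this component
        anchor = np.nanmean(x[:, cells])
        if len(cells) == 1:
            result[cells[0]] = anchor
            continue
        pos = {c: i for i, c in enumerate(cells)}
        rows_a, rows_b = np.nonzero(np.triu(valid[np.ix_(cells, cells)], k=1))
        n_eq = len(rows_a)
        a_mat = np.zeros((n_eq, len(cells)))
        rhs = np.empty(n_eq)
        for e, (ia, ib) in enumerate(zip(rows_a, rows_b)):
            a_mat[e, ia] = -1.0
            a_mat[e, ib] = 1.0
            rhs[e] = ratio[cells[ia], cells[ib]]
        w, *_ = np.linalg.lstsq(a_mat, rhs, rcond=None)
        w = w - w.mean() + anchor
        result[cells] = w
    return result


def summarize_all_proteins(
    matrix: PrecursorMatrix,
    min_shared: int = 1,
) -> ProteinMatrix:
    """MaxLFQ-summarize every protein group of a precursor matrix.

    Rows of the result are ordered deterministically by lead accession
    (ties broken by the full group key).
    """
    groups = matrix.precursors["protein_group"].to_numpy()
    genes = matrix.precursors.get("genes")
    group_pos: dict[str, list[int]] = {}
    for i, g in enumerate(groups):
        group_pos.setdefault(g, []).append(i)
    order = sorted(group_pos, key=lambda g: (g.split(";")[0], g))
    values = np.empty((len(order), matrix.values.shape[1]))
    meta_rows = []
    arr = matrix.values.to_numpy(dtype=float)
    for i, group_key in enumerate(order):
        pos = group_pos[group_key]
        values[i] = maxlfq(arr[pos], min_shared=min_shared)
        meta_rows.append(
            {
                "lead_accession": group_key.split(";")[0],
                "gene": (
                    str(genes.iloc[pos[0]]).split(";")[0] if genes is not None else ""
                ),
                "n_precursors": len(pos),
            }
        )
    frame = pd.DataFrame(values, index=order, columns=matrix.values.columns)
    proteins = pd.DataFrame(meta_rows, index=order)
    return ProteinMatrix(frame, proteins)


# ---------------------------------------------------------------------------
# In-silico tryptic digestion and iBAQ


def digest_tryptic(
    sequence: str,
    missed_cleavages: int = 0,
    proline_rule: bool = False,
) -> list[str]:
    """Cleave C-terminal of K/R (optionally not before P); return peptides.

    With ``missed_cleavages`` > 0 the result also contains concatenations of
    up to that many consecutive fragments; peptides are positional, so
    repeated sequences are counted every time they occur.
    """
    seq = sequence.strip().upper()
    bad = set(seq) - AMINO_ACIDS
    if bad:
        raise FormatError(f"invalid residues in sequence: {sorted(bad)}")
    if not seq:
        return []
    pattern = r"(?<=[KR])(?!P)" if proline_rule else r"(?<=[KR])"
    fragments = [f for f in re.split(pattern, seq) if f]
    peptides = list(fragments)
    for mc in range(1, missed_cleavages + 1):
        for i in range(len(fragments) - mc):
            peptides.append("".join(fragments[i : i + mc + 1]))
    return peptides


def theoretical_tryptic_peptides(
    sequence: str,
    min_len: int = 6,
    max_len: int = 50,
    missed_cleavages: int = 0,
    proline_rule: bool = False,
) -> int:
    """Number of theoretically observable tryptic peptides of a protein.

    Counts digestion products with ``min_len <= length <= max_len``; with the
    defaults these are the maximal fragments between K/R cleavage sites of
    6–50 residues, the denominator of the iBAQ estimate.
    """
    peptides = digest_tryptic(sequence, missed_cleavages, proline_rule)
    return sum(1 for p in peptides if min_len <= len(p) <= max_len)


def compute_ibaq(
    matrix: PrecursorMatrix,
    annotations: dict[str, ProteinAnnotation],
    min_len: int = 6,
    max_len: int = 50,
    missed_cleavages: int = 0,
    proline_rule: bool = False,
    top_n: int | None = None,
    min_coverage_for_top: float = 0.5,
    reference_genes: frozenset[str] | None = None,
) -> pd.DataFrame:
    """iBAQ absolute abundances from *pre-normalization* linear intensities.

    Per protein group and cell: sum of the observed linear intensities of the
    group's precursors, divided by the theoretical tryptic peptide count of
    the group's lead accession.  The summary column ``median_log10_ibaq`` is
    the median over cells of log10(iBAQ); ``rank`` 1 is the most abundant.
    ``top_n`` restricts the table to the N most abundant proteins observed in
    more than ``min_coverage_for_top`` of cells.
    """
    linear = np.power(2.0, matrix.values.to_numpy(dtype=float))
    groups = matrix.precursors["protein_group"].to_numpy()
    group_pos: dict[str, list[int]] = {}
    for i, g in enumerate(groups):
        group_pos.setdefault(g, []).append(i)
    order = sorted(group_pos, key=lambda g: (g.split(";")[0], g))
    n_cells = matrix.values.shape[1]

    rows = []
    ibaq_per_cell = {}
    for group_key in order:
        sub = linear[group_pos[group_key]]
        observed_any = ~np.all(np.isnan(sub), axis=0)
        summed = np.where(observed_any, np.nansum(sub, axis=0), np.nan)
        lead = group_key.split(";")[0]
        ann = annotations.get(lead)
        if ann is None:
            logger.warning("no annotation/sequence for lead accession %s; iBAQ missing", lead)
            count = 0
        else:
            count = theoretical_tryptic_peptides(
                ann.sequence, min_len, max_len, missed_cleavages, proline_rule
            )
        if count > 0:
            ibaq = summed / count
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                median_log10 = float(np.nanmedian(np.log10(ibaq)))
            if np.isnan(median_log10):
                median_log10 = np.nan
        else:
            ibaq = np.full(n_cells, np.nan)
            median_log10 = np.nan
            logger.info("protein %s has no observable tryptic peptides; iBAQ missing", lead)
        ibaq_per_cell[group_key] = ibaq
        gene = ann.gene_symbol if ann is not None else lead
        rows.append(
            {
                "protein_group": group_key,
                "accession": lead,
                "gene": gene,
                "theoretical_peptides": count,
                "summed_intensity_median": float(np.nanmedian(summed))
                if not np.all(np.isnan(summed))
                else np.nan,
                "median_log10_ibaq": median_log10,
                "coverage": float(observed_any.mean()),
                "in_reference_set": bool(reference_genes and gene in reference_genes),
            }
        )
    table = pd.DataFrame(rows).set_index("protein_group")

    # ranks over proteins with a defined iBAQ: 1 = most abundant
    defined = table["median_log10_ibaq"].notna()
    ranks = (-table.loc[defined, "median_log10_ibaq"]).rank(method="first").astype(int)
    table["rank"] = pd.array([pd.NA] * len(table), dtype="Int64")
    table.loc[defined, "rank"] = ranks.to_numpy()

    if top_n is not None:
        eligible = table[(table["coverage"] > min_coverage_for_top) & defined]
        keep = eligible.sort_values("median_log10_ibaq", ascending=False).head(top_n).index
        table = table.loc[table.index.isin(set(keep))]
    table.attrs["ibaq_per_cell"] = pd.DataFrame(
        ibaq_per_cell, index=matrix.values.columns
    ).T
    return table
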