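"""GO-term rollup, PCA, and PC–phenotype correlation.

The rollup mirrors reference-based protein rollup ("rrollup"): within each
gene set the member with the most observed values is the reference (ties:
higher median abundance, then lexicographic accession); every other member
is shifted by the median difference to the reference over cells where both
are observed, and the term profile is the per-cell median of the shifted
members.  The construction makes term profiles invariant to per-member
additive offsets.

PCA treats cells as observations and proteins (or terms) as variables,
centred and by default unscaled — the input is already relative log2
abundance, so variables share a scale.  A deterministic sign convention
(largest-|loading| element positive) removes the SVD sign ambiguity.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ParameterError, PipelineError
from .io_formats import GeneSetCollection
from .quantify import ProteinMatrix

logger = logging.getLogger(__name__)


@dataclass
class PcaResult:
    scores: pd.DataFrame  # cell × component
    loadings: pd.DataFrame  # feature × component
    explained_variance_fraction: np.ndarray
    n_components: int
    mean_: np.ndarray  # per-feature mean removed before the SVD
    scale_: np.ndarray | None  # per-feature SD, when scaling was requested


@dataclass
class EigencorResult:
    """Pearson correlations between PC scores and metadata variables."""

    table: pd.DataFrame  # columns: component, variable, r, p, p_bh, significant
    alpha: float


def rollup_go(
    matrix: ProteinMatrix,
    genesets: GeneSetCollection,
    min_members: int = 3,
) -> pd.DataFrame:
    """Summarize protein profiles into term × cell profiles.

    Gene symbols of the matrix rows are matched against each term's member
    genes; terms mapping to fewer than ``min_members`` rows are dropped
    (logged).  Raises when no term survives.
    """
    genes = matrix.proteins["gene"].astype(str)
    gene_rows: dict[str, list[str]] = {}
    for row, gene in genes.items():
        gene_rows.setdefault(gene, []).append(row)

    values = matrix.values
    obs_counts = values.notna().sum(axis=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        medians = values.median(axis=1)

    term_profiles = {}
    dropped = 0
    for gs in genesets:
        member_rows: list[str] = []
        for g in gs.member_genes:
            member_rows.extend(gene_rows.get(g, []))
        member_rows = sorted(set(member_rows))
        if len(member_rows) < min_members:
            dropped += 1
            continue
        # reference member: most observed, then higher median, then accession
        ref = min(
            member_rows,
            key=lambda r: (-int(obs_counts[r]), -float(medians[r]), r),
        )
        ref_vals = values.loc[ref]
        shifted = []
        for r in member_rows:
            row = values.loc[r]
            if r == ref:
                shifted.append(row)
                continue
            both = row.notna() & ref_vals.notna()
            if not both.any():
                logger.debug("term %s: member %s shares no cells with reference", gs.term_id, r)
                continue
            offset = float((ref_vals[both] - row[both]).median())
            shifted.append(row + offset)
        block = pd.concat(shifted, axis=1).T
        term_profiles[gs.term_id] = block.median(axis=0, skipna=True)
    if not term_profiles:
        raise PipelineError(
            f"no gene sets with >= {min_members} mapped proteins "
            f"({len(genesets)} sets tested)"
        )
    if dropped:
        logger.info("rollup_go dropped %d terms below min_members=%d", dropped, min_members)
    out = pd.DataFrame(term_profiles).T
    out = out.loc[sorted(out.index)]
    out.columns = values.columns
    return out


def pca(
    matrix: pd.DataFrame,
    n_components: int = 10,
    center: bool = True,
    scale: bool = False,
) -> PcaResult:
    """SVD-based PCA of a complete feature × cell matrix (cells = observations)."""
    if matrix.isna().to_numpy().any():
        raise ParameterError("pca requires a complete matrix")
    data = matrix.to_numpy(dtype=float).T  # cells × features
    n_obs, n_feat = data.shape
    mean = data.mean(axis=0) if center else np.zeros(n_feat)
    x = data - mean
    scale_vec = None
    if scale:
        scale_vec = x.std(axis=0, ddof=1)
        scale_vec[scale_vec == 0] = 1.0
        x = x / scale_vec

    u, s, vt = np.linalg.svd(x, full_matrices=False)
    # singular values at the level of floating-point residue of the raw data
    # are numerical noise, not variance (e.g. perfectly identical cells)
    floor = np.linalg.norm(data) * 1e-10
    s = np.where(s > floor, s, 0.0)
    total = float(np.sum(s**2))
    if n_components > min(n_obs, n_feat):
        logger.warning(
            "n_components=%d clipped to %d", n_components, min(n_obs, n_feat)
        )
    k = min(n_components, len(s))
    scores = u[:, :k] * s[:k]
    loadings = vt[:k].T
    # deterministic sign: largest-|loading| element of each component positive
    for j in range(k):
        i = int(np.argmax(np.abs(loadings[:, j])))
        if loadings[i, j] < 0:
            loadings[:, j] *= -1.0
            scores[:, j] *= -1.0
    explained = (s[:k] ** 2) / total if total > 0 else np.zeros(k)

    comp_names = [f"PC{j + 1}" for j in range(k)]
    return PcaResult(
        scores=pd.DataFrame(scores, index=matrix.columns, columns=comp_names),
        loadings=pd.DataFrame(loadings, index=matrix.index, columns=comp_names),
        explained_variance_fraction=explained,
        n_components=k,
        mean_=mean,
        scale_=scale_vec,
    )


def eigencor(
    pca_result: PcaResult,
    metadata: pd.DataFrame,
    variables: list[str],
    n_components: int = 10,
    alpha: float = 0.05,
) -> EigencorResult:
    """Pearson correlation of PC scores with numeric phenotype variables.

    Two-sided p-values (t-test, n−2 df) are Benjamini–Hochberg corrected
    across the whole component × variable grid.  Constant variables yield a
    missing correlation with a warning.
    """
    meta = metadata.set_index("cell_id") if "cell_id" in metadata.columns else metadata
    meta = meta.reindex(pca_result.scores.index)
    if meta.isna().all(axis=1).any():
        missing = pca_result.scores.index[meta.isna().all(axis=1)].tolist()
        raise ParameterError(f"metadata missing for cells: {missing[:5]}")
    k = min(n_components, pca_result.n_components)
    rows = []
    for comp in pca_result.scores.columns[:k]:
        sc = pca_result.scores[comp].to_numpy(dtype=float)
        for var in variables:
            vals = meta[var].to_numpy(dtype=float)
            if np.nanstd(vals) == 0 or np.nanstd(sc) == 0:
                logger.warning("constant variable %r or scores %s: r undefined", var, comp)
                rows.append({"component": comp, "variable": var, "r": np.nan, "p": np.nan})
                continue
            r, p = stats.pearsonr(sc, vals)
            rows.append({"component": comp, "variable": var, "r": float(r), "p": float(p)})
    table = pd.DataFrame(rows)
    table["p_bh"] = np.nan
    table["significant"] = False
    defined = table["p"].notna()
    if defined.any():
        reject, p_adj, *_ = multipletests(table.loc[defined, "p"], alpha=alpha, method="fdr_bh")
        table.loc[defined, "p_bh"] = p_adj
        table.loc[defined, "significant"] = reject
    return EigencorResult(table=table, alpha=alpha)


def top_loadings(pca_result: PcaResult, k: int) -> dict[str, pd.DataFrame]:
    """Per component, the ``k`` features with largest |loading| (signed values)."""
    out = {}
    for comp in pca_result.loadings.columns:
        col = pca_result.loadings[comp]
        ranked = col.reindex(col.abs().sort_values(ascending=False).index)
        out[comp] = ranked.head(k).rename("loading").to_frame()
    return out
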