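"""Batch-effect removal and per-cell histone normalization.

ComBat-style empirical-Bayes correction: per protein the model is

    x_gck = alpha_g + gamma_gk + delta_gk * eps,   eps ~ N(0, sigma_g^2)

with additive (location) and multiplicative (scale) batch effects.  Batch
parameters are estimated per protein, then shrunk toward per-batch priors —
normal for the locations, inverse-gamma for the scales — whose
hyperparameters come from moment matching across proteins.  The adjusted
data subtracts the shrunken location, divides by the shrunken scale, and
restores the protein's grand mean and pooled scale.  After adjustment each
protein row is re-centred exactly on its original grand mean, so the
correction never moves a protein's overall level.

Histone normalization follows: each cell's median relative abundance over
the histone-flagged proteins is used as a per-cell reference level
(chromatin content tracks ploidy, making histones a natural per-cell
anchor) and subtracted from all proteins of that cell.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ParameterError, PipelineError
from .quantify import ProteinMatrix

logger = logging.getLogger(__name__)

VARIANCE_FLOOR = 1e-8


@dataclass
class BatchModel:
    """Fitted empirical-Bayes batch parameters."""

    batches: list[str]
    alpha: np.ndarray  # per-protein grand effect (weighted over batches)
    sigma2: np.ndarray  # per-protein pooled variance
    gamma_hat: pd.DataFrame  # protein × batch standardized batch means
    delta2_hat: pd.DataFrame  # protein × batch standardized batch variances
    gamma_star: pd.DataFrame  # EB-shrunken locations
    delta2_star: pd.DataFrame  # EB-shrunken variances
    gamma_bar: dict = field(default_factory=dict)  # per-batch prior mean
    tau2: dict = field(default_factory=dict)  # per-batch prior variance
    lambda_: dict = field(default_factory=dict)  # inverse-gamma shape
    theta: dict = field(default_factory=dict)  # inverse-gamma scale


@dataclass
class NormalizationFactors:
    """Per-cell histone-median normalization factors (log2)."""

    histone_median_log2: pd.Series
    histone_proteins: list[str]


def _postmean(gamma_hat, gamma_bar, n, delta2_star, tau2):
    return (tau2 * n * gamma_hat + delta2_star * gamma_bar) / (tau2 * n + delta2_star)


def _postvar(ssq, n, lambda_, theta):
    return (theta + 0.5 * ssq) / (n / 2.0 + lambda_ - 1.0)


def _eb_iterate(z_batch, gamma_hat, delta2_hat, gamma_bar, tau2, lambda_, theta,
                conv=1e-4, max_iter=500):
    """Iterative solution of the EB posterior for one batch (all proteins)."""
    n = z_batch.shape[1]
    g_old = gamma_hat.copy()
    d_old = delta2_hat.copy()
    for _ in range(max_iter):
        g_new = _postmean(gamma_hat, gamma_bar, n, d_old, tau2)
        ssq = np.sum((z_batch - g_new[:, None]) ** 2, axis=1)
        d_new = _postvar(ssq, n, lambda_, theta)
        change = max(
            np.max(np.abs(g_new - g_old) / (np.abs(g_old) + 1e-12)),
            np.max(np.abs(d_new - d_old) / (np.abs(d_old) + 1e-12)),
        )
        g_old, d_old = g_new, d_new
        if change < conv:
            break
    return g_old, np.maximum(d_old, VARIANCE_FLOOR)


def combat_correct(
    matrix: ProteinMatrix,
    batch_labels: pd.Series,
    parametric: bool = True,
) -> tuple[ProteinMatrix, BatchModel | None]:
    """Empirical-Bayes location/scale batch correction of a complete matrix.

    ``batch_labels`` maps cell id -> batch (chip) id and must cover every
    column.  With a single batch the input is returned unchanged (with a
    warning); every batch must contain at least two cells.
    """
    if not parametric:
        raise ParameterError("only parametric priors are implemented")
    values = matrix.values
    if values.isna().to_numpy().any():
        raise ParameterError("combat_correct requires a complete matrix (no missing values)")
    labels = batch_labels.reindex(values.columns)
    if labels.isna().any():
        missing = values.columns[labels.isna()].tolist()
        raise ParameterError(f"cells without batch label: {missing[:5]}")

    batches = sorted(labels.unique())
    if len(batches) == 1:
        logger.warning("single batch %r: ComBat is the identity", batches[0])
        return matrix, None
    sizes = labels.value_counts()
    small = sizes[sizes < 2]
    if len(small):
        raise ParameterError(f"batches with fewer than 2 cells: {small.index.tolist()}")

    x = values.to_numpy(dtype=float)
    n_prot, n_cells = x.shape
    n = n_cells
    batch_cols = {b: np.flatnonzero((labels == b).to_numpy()) for b in batches}

    # Per-protein batch means; grand effect weighted by batch size; pooled
    # variance of residuals from the batch means.
    batch_means = np.column_stack([x[:, cols].mean(axis=1) for b, cols in batch_cols.items()])
    weights = np.array([len(batch_cols[b]) / n for b in batches])
    alpha = batch_means @ weights
    resid = x.copy()
    for j, b in enumerate(batches):
        resid[:, batch_cols[b]] -= batch_means[:, [j]]
    sigma2 = np.maximum((resid**2).mean(axis=1), VARIANCE_FLOOR)
    sigma = np.sqrt(sigma2)

    z = (x - alpha[:, None]) / sigma[:, None]

    gamma_hat = np.empty((n_prot, len(batches)))
    delta2_hat = np.empty((n_prot, len(batches)))
    for j, b in enumerate(batches):
        cols = batch_cols[b]
        gamma_hat[:, j] = z[:, cols].mean(axis=1)
        delta2_hat[:, j] = np.maximum(z[:, cols].var(axis=1, ddof=1), VARIANCE_FLOOR)

    gamma_star = np.empty_like(gamma_hat)
    delta2_star = np.empty_like(delta2_hat)
    gamma_bar, tau2, lambda_, theta = {}, {}, {}, {}
    for j, b in enumerate(batches):
        gb = float(gamma_hat[:, j].mean())
        t2 = float(gamma_hat[:, j].var(ddof=1))
        m = float(delta2_hat[:, j].mean())
        s2 = float(delta2_hat[:, j].var(ddof=1))
        s2 = max(s2, VARIANCE_FLOOR)
        lam = (2.0 * s2 + m**2) / s2
        th = (m**3 + m * s2) / s2
        gamma_bar[b], tau2[b], lambda_[b], theta[b] = gb, t2, lam, th
        g_star, d_star = _eb_iterate(
            z[:, batch_cols[b]], gamma_hat[:, j], delta2_hat[:, j], gb, t2, lam, th
        )
        gamma_star[:, j] = g_star
        delta2_star[:, j] = d_star

    adjusted = np.empty_like(z)
    for j, b in enumerate(batches):
        cols = batch_cols[b]
        adjusted[:, cols] = (z[:, cols] - gamma_star[:, [j]]) / np.sqrt(delta2_star[:, [j]])
    adjusted = adjusted * sigma[:, None] + alpha[:, None]
    # exact grand-mean preservation (re-centre on the pooled estimate)
    adjusted += (x.mean(axis=1) - adjusted.mean(axis=1))[:, None]

    frame = pd.DataFrame(adjusted, index=values.index, columns=values.columns)
    model = BatchModel(
        batches=list(batches),
        alpha=alpha,
        sigma2=sigma2,
        gamma_hat=pd.DataFrame(gamma_hat, index=values.index, columns=batches),
        delta2_hat=pd.DataFrame(delta2_hat, index=values.index, columns=batches),
        gamma_star=pd.DataFrame(gamma_star, index=values.index, columns=batches),
        delta2_star=pd.DataFrame(delta2_star, index=values.index, columns=batches),
        gamma_bar=gamma_bar,
        tau2=tau2,
        lambda_=lambda_,
        theta=theta,
    )
    return ProteinMatrix(frame, matrix.proteins), model


def histone_normalize(
    matrix: ProteinMatrix,
    is_histone: pd.Series,
    min_histones: int = 3,
) -> tuple[ProteinMatrix, NormalizationFactors]:
    """Subtract each cell's median histone abundance from all its proteins.

    ``is_histone`` is a boolean series over ``matrix.values.index`` flagging
    histone protein groups.  After normalization the per-cell median over
    histone proteins is exactly zero; the operation is idempotent and
    shift-equivariant.
    """
    flags = is_histone.reindex(matrix.values.index).fillna(False).astype(bool)
    histone_rows = matrix.values.index[flags].tolist()
    if len(histone_rows) < min_histones:
        detected = [
            f"{r} ({matrix.proteins.loc[r, 'gene']})" if r in matrix.proteins.index else r
            for r in histone_rows
        ]
        raise PipelineError(
            f"only {len(histone_rows)} histone proteins detected "
            f"(minimum {min_histones}): {detected}"
        )
    factors = matrix.values.loc[histone_rows].median(axis=0)
    normalized = matrix.values.sub(factors, axis=1)
    return (
        ProteinMatrix(normalized, matrix.proteins),
        NormalizationFactors(histone_median_log2=factors, histone_proteins=histone_rows),
    )
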