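"""Phylogenetic generalized least squares screening of lifespan on RES.

Every alignment column is regressed: lifespan (years, response) on the
column's RES scores (predictor), with error covariance proportional to the
Brownian-motion matrix V — the standard PGLS correction for shared ancestry.
Columns whose slope has p < alpha (0.05 by default, no multiple-testing
correction unless requested) form the RPLAR set: RES-predicted
longevity-associated residues.  RPLAR columns are mapped back to 1-based
residue numbers of a chosen reference ortholog by skipping its gaps.

All solves go through Cholesky whitening (V = L L^T; regress L^{-1}y on
L^{-1}X), never an explicit inverse.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import linalg, stats

from .phylo import BMCovariance, PhyloError
from .res_scoring import RESMatrix
from .seqio import Alignment, TraitTable

logger = logging.getLogger("resphylo")

_RESID_TOL = 1e-12  # relative residual variance below this => exact fit


class PGLSError(ValueError):
    pass


@dataclass(frozen=True)
class SiteFit:
    """Per-column PGLS result.

    status is 'ok' for a completed fit, 'constant_predictor' when the
    column's RES vector has no variance (slope/p undefined).
    """

    column: int
    slope: float | None
    intercept: float | None
    se_slope: float | None
    t_stat: float | None
    p_value: float | None
    n_used: int
    status: str = "ok"


@dataclass(frozen=True)
class ModelFitSummary:
    """Joint GLS fit of lifespan on several columns' RES."""

    aic: float
    loglik: float
    k: int
    predictors: tuple[int, ...]


def _whiten(V: np.ndarray) -> np.ndarray:
    try:
        return linalg.cholesky(V, lower=True)
    except linalg.LinAlgError as exc:
        raise PGLSError(
            f"singular covariance (condition number {np.linalg.cond(V):.3g})"
        ) from exc


def pgls_fit(x, y, V: BMCovariance | np.ndarray, column: int = 0) -> SiteFit:
    """GLS of y on [1, x] with covariance V; two-sided t test, n-2 df."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    Vm = V.V if isinstance(V, BMCovariance) else np.asarray(V, dtype=float)
    n = len(y)
    if x.shape != (n,) or Vm.shape != (n, n):
        raise PGLSError("x, y and V are not conformable")
    if n < 3:
        raise PGLSError("PGLS needs >= 3 taxa")
    if np.ptp(x) == 0:
        return SiteFit(column, None, None, None, None, None, n,
                       status="constant_predictor")
    L = _whiten(Vm)
    X = np.column_stack([np.ones(n), x])
    Xw = linalg.solve_triangular(L, X, lower=True)
    yw = linalg.solve_triangular(L, y, lower=True)
    beta, _, rank, _ = np.linalg.lstsq(Xw, yw, rcond=None)
    if rank < 2:
        return SiteFit(column, None, None, None, None, None, n,
                       status="constant_predictor")
    resid = yw - Xw @ beta
    rss = float(resid @ resid)
    sigma2 = rss / (n - 2)
    XtX_inv = np.linalg.inv(Xw.T @ Xw)
    se = float(np.sqrt(max(sigma2 * XtX_inv[1, 1], 0.0)))
    scale = float(yw @ yw) if float(yw @ yw) > 0 else 1.0
    if rss / scale < _RESID_TOL or se == 0.0:
        # exact fit (e.g. constant response): slope test is vacuous
        t = 0.0 if abs(beta[1]) < np.sqrt(_RESID_TOL) else np.inf
        p = 1.0 if t == 0.0 else 0.0
    else:
        t = float(beta[1] / se)
        p = float(2 * stats.t.sf(abs(t), df=n - 2))
    return SiteFit(
        column=column,
        slope=float(beta[1]),
        intercept=float(beta[0]),
        se_slope=se,
        t_stat=t,
        p_value=p,
        n_used=n,
        status="ok",
    )


def site_fits_frame(fits: Sequence[SiteFit]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "column": f.column,
                "slope": f.slope,
                "intercept": f.intercept,
                "se_slope": f.se_slope,
                "t_stat": f.t_stat,
                "p_value": f.p_value,
                "n_used": f.n_used,
                "status": f.status,
            }
            for f in fits
        ]
    )


def site_screen(
    res: RESMatrix,
    traits: TraitTable,
    V: BMCovariance,
    alpha_screen: float = 0.05,
    trait_column: str = "L_avg",
    correction: str | None = None,
) -> tuple[list[SiteFit], pd.DataFrame]:
    """PGLS on every alignment column; RPLARs are the columns with p < alpha.

    With ``correction='bh'`` the screen uses Benjamini-Hochberg adjusted
    p-values instead of raw ones (the default screen is uncorrected).
    Returns (all per-site fits, RPLAR table sorted by column).
    """
    if set(res.ids) != set(V.taxa):
        raise PGLSError("RES matrix and covariance cover different taxa")
    if res.ids != list(V.taxa):  # align covariance rows to RES row order
        perm = [V.taxa.index(t) for t in res.ids]
        V = BMCovariance(list(res.ids), V.V[np.ix_(perm, perm)], V.lam)
    life = traits.lifespan(trait_column)
    missing = [t for t in res.ids if t not in life.index]
    if missing:
        raise PGLSError(f"traits missing for: {missing}")
    y = life.loc[res.ids].to_numpy(float)
    n, L_cols = res.scores.shape

    # whiten once; every column then reduces to an OLS on transformed data
    Lc = _whiten(V.V)
    yw = linalg.solve_triangular(Lc, y, lower=True)
    ones_w = linalg.solve_triangular(Lc, np.ones(n), lower=True)
    Xw_all = linalg.solve_triangular(Lc, res.scores, lower=True)

    fits: list[SiteFit] = []
    for jx in range(L_cols):
        col = int(res.columns[jx])
        x = res.scores[:, jx]
        if np.ptp(x) == 0:
            fits.append(SiteFit(col, None, None, None, None, None, n,
                                status="constant_predictor"))
            continue
        fits.append(_fast_fit(ones_w, Xw_all[:, jx], yw, n, col))
    frame = site_fits_frame(fits)
    ok = frame["status"] == "ok"
    pvals = frame.loc[ok, "p_value"].to_numpy(float)
    if correction == "bh":
        frame.loc[ok, "p_adj"] = _benjamini_hochberg(pvals)
        sig = ok & (frame["p_adj"] < alpha_screen)
    elif correction is None:
        sig = ok & (frame["p_value"] < alpha_screen)
    else:
        raise PGLSError(f"unknown correction: {correction}")
    rplars = frame[sig].reset_index(drop=True)
    logger.info(
        "screen: %d columns, %d ok fits, %d RPLARs at alpha=%g%s",
        L_cols, int(ok.sum()), len(rplars), alpha_screen,
        " (BH)" if correction == "bh" else "",
    )
    return fits, rplars


def _fast_fit(ones_w, xw, yw, n: int, column: int) -> SiteFit:
    Xw = np.column_stack([ones_w, xw])
    G = Xw.T @ Xw
    det = G[0, 0] * G[1, 1] - G[0, 1] ** 2
    if det <= 0 or not np.isfinite(det):
        return SiteFit(column, None, None, None, None, None, n,
                       status="constant_predictor")
    b = Xw.T @ yw
    beta = np.array(
        [(G[1, 1] * b[0] - G[0, 1] * b[1]) / det,
         (G[0, 0] * b[1] - G[0, 1] * b[0]) / det]
    )
    resid = yw - Xw @ beta
    rss = float(resid @ resid)
    sigma2 = rss / (n - 2)
    se = float(np.sqrt(max(sigma2 * G[0, 0] / det, 0.0)))
    scale = float(yw @ yw) if float(yw @ yw) > 0 else 1.0
    if rss / scale < _RESID_TOL or se == 0.0:
        t = 0.0 if abs(beta[1]) < np.sqrt(_RESID_TOL) else np.inf
        p = 1.0 if t == 0.0 else 0.0
    else:
        t = float(beta[1] / se)
        p = float(2 * stats.t.sf(abs(t), df=n - 2))
    return SiteFit(column, float(beta[1]), float(beta[0]), se, t, p, n, "ok")


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        running = min(running, p[idx] * m / rank)
        adj[idx] = running
    return adj


def joint_model_fit(
    res: RESMatrix,
    traits: TraitTable,
    V: BMCovariance,
    columns: Sequence[int],
    trait_column: str = "L_avg",
) -> ModelFitSummary:
    """Single GLS of lifespan on the RES of all selected columns jointly.

    The log-likelihood is full ML (sigma^2 = RSS/n) under
    y ~ N(X beta, sigma^2 V); k counts the regression coefficients plus
    sigma^2, and AIC = 2k - 2 logLik.
    """
    columns = [int(c) for c in columns]
    if not columns:
        raise PGLSError("joint model needs at least one column")
    col_list = res.columns.tolist()
    missing = [c for c in columns if c not in col_list]
    if missing:
        raise PGLSError(f"unknown columns: {missing}")
    if set(res.ids) != set(V.taxa):
        raise PGLSError("RES matrix and covariance cover different taxa")
    if res.ids != list(V.taxa):
        perm = [V.taxa.index(t) for t in res.ids]
        V = BMCovariance(list(res.ids), V.V[np.ix_(perm, perm)], V.lam)
    y = traits.lifespan(trait_column).loc[res.ids].to_numpy(float)
    n = len(y)
    if n <= len(columns) + 2:
        raise PGLSError(
            f"{n} taxa cannot support {len(columns)} predictors"
        )
    idx = [col_list.index(c) for c in columns]
    X = np.column_stack([np.ones(n), res.scores[:, idx]])
    Lc = _whiten(V.V)
    Xw = linalg.solve_triangular(Lc, X, lower=True)
    yw = linalg.solve_triangular(Lc, y, lower=True)
    rank = np.linalg.matrix_rank(Xw)
    if rank < X.shape[1]:
        collinear = _collinear_columns(Xw, columns)
        raise PGLSError(f"rank-deficient design; collinear columns: {collinear}")
    beta, _, _, _ = np.linalg.lstsq(Xw, yw, rcond=None)
    resid = yw - Xw @ beta
    rss = float(resid @ resid)
    sigma2 = rss / n
    if sigma2 <= 0:
        raise PGLSError("exact fit: ML sigma^2 is zero, logLik unbounded")
    logdet = 2 * np.log(np.diag(Lc)).sum()
    loglik = -0.5 * (n * np.log(2 * np.pi * sigma2) + n + logdet)
    k = len(columns) + 2
    return ModelFitSummary(
        aic=float(2 * k - 2 * loglik),
        loglik=float(loglik),
        k=k,
        predictors=tuple(columns),
    )


def _collinear_columns(Xw: np.ndarray, columns: Sequence[int]) -> list[int]:
    _, R = np.linalg.qr(Xw)
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(Xw.shape) * np.finfo(float).eps
    bad = np.flatnonzero(diag < tol)
    return [columns[i - 1] for i in bad if i >= 1]


def map_to_reference(
    rplars: pd.DataFrame, alignment: Alignment, reference_id: str
) -> pd.DataFrame:
    """Attach reference residue numbers (1-based, ungapped) to RPLAR rows.

    Columns where the reference carries a gap get an empty ref_residue.
    """
    if reference_id not in alignment.ids:
        raise PGLSError(f"reference id '{reference_id}' not in alignment")
    row = alignment.rows[alignment.ids.index(reference_id)]
    nongap = row != "-"
    residue_no = np.cumsum(nongap)  # residue count through each column
    out = rplars.copy()
    ref_res: list[float] = []
    ref_sym: list[str] = []
    for col in out["column"].astype(int):
        j = col - 1
        if nongap[j]:
            ref_res.append(int(residue_no[j]))
            ref_sym.append(str(row[j]))
        else:
            ref_res.append(np.nan)
            ref_sym.append("-")
    out["ref_residue"] = pd.array(ref_res, dtype="Int64")
    out["ref_symbol"] = ref_sym
    return out
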