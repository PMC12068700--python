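"""Lifespan normalization.

Average lifespan is missing for many species while maximum lifespan is widely
recorded.  A simple linear regression ``L_avg = alpha * L_max + beta`` is fit
on the species with both values, used to impute the missing averages, and a
normalized lifespan

    L_norm = L_avg_est + (L_max - L_avg_est) * alpha

pulls the estimate part-way toward the maximum, weighted by the regression
slope.  Species with an observed average keep it as ``L_avg_est`` (no
re-prediction); normalization is intended for broad multi-order datasets and
is optional for order-specific analyses, where raw averages are used.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .seqio import TraitTable

logger = logging.getLogger("resphylo")


class LifespanError(ValueError):
    pass


@dataclass(frozen=True)
class LifespanModel:
    """OLS fit of average on maximum lifespan.

    alpha: slope (dimensionless); beta: intercept (years); n_train: number of
    species with both lifespans used in the fit.
    """

    alpha: float
    beta: float
    n_train: int


def fit_lifespan_regression(traits: TraitTable) -> LifespanModel:
    """Fit ``L_avg = alpha * L_max + beta`` by ordinary least squares."""
    df = traits.data
    both = df[df["L_avg"].notna() & df["L_max"].notna()]
    if len(both) < 2:
        raise LifespanError(
            f"need >=2 species with both L_avg and L_max, got {len(both)}"
        )
    x = both["L_max"].to_numpy(float)
    y = both["L_avg"].to_numpy(float)
    if np.ptp(x) == 0:
        raise LifespanError("all L_max values equal: regression is degenerate")
    fit = stats.linregress(x, y)
    logger.info(
        "lifespan regression: alpha=%.4f beta=%.4f (n=%d, r=%.3f)",
        fit.slope, fit.intercept, len(both), fit.rvalue,
    )
    return LifespanModel(float(fit.slope), float(fit.intercept), len(both))


def normalize_lifespans(traits: TraitTable, model: LifespanModel) -> TraitTable:
    """Add ``L_avg_est``, ``L_norm`` and ``source`` columns.

    ``L_avg_est`` is the observed average when present, otherwise
    ``alpha * L_max + beta``.  ``L_norm`` applies the slope-weighted
    correction toward ``L_max``; when ``L_max`` is missing the correction
    term is unavailable and ``L_norm = L_avg_est``.
    """
    df = traits.data.copy()
    observed = df["L_avg"].notna()
    est = np.where(
        observed, df["L_avg"], model.alpha * df["L_max"] + model.beta
    )
    nonpos = est <= 0
    if nonpos.any():
        dropped = sorted(df.loc[nonpos, "species"])
        logger.warning(
            "normalize: dropping %d species with non-positive estimated "
            "average lifespan: %s", len(dropped), dropped
        )
        df = df[~nonpos].reset_index(drop=True)
        observed = df["L_avg"].notna()
        est = est[~nonpos]
    df["L_avg_est"] = est
    lmax = df["L_max"].to_numpy(float)
    lnorm = est + (lmax - est) * model.alpha
    df["L_norm"] = np.where(np.isnan(lmax), est, lnorm)
    df["source"] = np.where(observed, "observed", "estimated")
    n_est = int((~observed).sum())
    if n_est:
        logger.info("normalize: estimated L_avg for %d species", n_est)
    return TraitTable(df)
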