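"""Relative Evolutionary Score (RES).

Each alignment column gets a position-specific symbol distribution with an
additive pseudocount; the whole alignment gets a background distribution over
the same 21-symbol alphabet (20 amino acids + gap).  The RES of sequence i at
column j is the log-odds of the column probability of the residue that
sequence carries there versus its background probability:

    score(i, j) = log( p(a_ij, j) / q(a_ij) )

Gaps are counted and scored like any residue.  With pseudocount kappa the
column probabilities are (c(a,j) + kappa) / (n + kappa*|S|) and the
background is (C(a) + kappa) / (n*L + kappa*|S|), so every probability is
strictly positive and a single-column alignment scores exactly zero
everywhere (column counts coincide with global counts).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .seqio import ALPHABET, SYMBOL_INDEX, Alignment, TraitTable

logger = logging.getLogger("resphylo")

N_SYMBOLS = len(ALPHABET)  # 21


class ScoringError(ValueError):
    pass


@dataclass
class PWMModel:
    """Position weight matrix with pseudocounts plus background frequencies.

    probs: ``(21, L)`` column-wise symbol probabilities; background: length-21
    vector; both include the same additive pseudocount.
    """

    probs: np.ndarray
    background: np.ndarray
    pseudocount: float
    log_base: float

    def __post_init__(self) -> None:
        col_sums = self.probs.sum(axis=0)
        if not np.allclose(col_sums, 1.0, atol=1e-12):
            raise ScoringError("PWM columns do not sum to 1")
        if not np.isclose(self.background.sum(), 1.0, atol=1e-12):
            raise ScoringError("background does not sum to 1")
        if (self.probs <= 0).any() or (self.background <= 0).any():
            raise ScoringError("probabilities must be strictly positive")


@dataclass
class RESMatrix:
    """Per-sequence, per-column evolutionary scores (n x L), finite everywhere.

    ``columns`` are 1-based alignment column numbers.
    """

    scores: np.ndarray
    ids: list[str]
    columns: np.ndarray

    def __post_init__(self) -> None:
        if not np.isfinite(self.scores).all():
            raise ScoringError("RES matrix contains non-finite scores")

    @property
    def n(self) -> int:
        return self.scores.shape[0]

    @property
    def length(self) -> int:
        return self.scores.shape[1]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.scores, columns=[f"pos{j}" for j in self.columns]
        )
        df.insert(0, "id", self.ids)
        return df

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def build_pwm(
    alignment: Alignment, pseudocount: float = 1.0, log_base: float = 2.0
) -> PWMModel:
    """Count symbols per column and overall, with additive pseudocount."""
    if pseudocount <= 0:
        raise ScoringError(f"pseudocount must be > 0, got {pseudocount}")
    if log_base not in (2.0, np.e):
        raise ScoringError("log_base must be 2 or e")
    n, L = alignment.rows.shape
    idx = _symbol_indices(alignment)
    counts = np.zeros((N_SYMBOLS, L))
    for a in range(N_SYMBOLS):
        counts[a] = (idx == a).sum(axis=0)
    probs = (counts + pseudocount) / (n + pseudocount * N_SYMBOLS)
    total = counts.sum(axis=1)
    background = (total + pseudocount) / (n * L + pseudocount * N_SYMBOLS)
    return PWMModel(probs, background, float(pseudocount), float(log_base))


def score_alignment(alignment: Alignment, pwm: PWMModel) -> RESMatrix:
    """Log-odds score of every residue against the background."""
    if pwm.probs.shape[1] != alignment.length:
        raise ScoringError(
            f"PWM has {pwm.probs.shape[1]} columns but alignment has "
            f"{alignment.length}"
        )
    idx = _symbol_indices(alignment)
    cols = np.arange(alignment.length)
    log_ratio = np.log(pwm.probs[idx, cols]) - np.log(pwm.background[idx])
    scores = log_ratio / np.log(pwm.log_base)
    return RESMatrix(scores, list(alignment.ids), np.arange(1, alignment.length + 1))


def compute_res(
    alignment: Alignment, pseudocount: float = 1.0, log_base: float = 2.0
) -> RESMatrix:
    """Convenience: build the PWM and score the same alignment."""
    return score_alignment(alignment, build_pwm(alignment, pseudocount, log_base))


def export_res_heatmap(
    res: RESMatrix,
    traits: TraitTable,
    site_subset,
    path: str | Path,
    trait_column: str = "L_avg",
    image_path: str | Path | None = None,
) -> pd.DataFrame:
    """Write RES at selected columns, rows ordered by descending lifespan.

    Ties in lifespan fall back to species id order (stable).  ``site_subset``
    holds 1-based column numbers; an empty subset yields a header-only table.
    Returns the written frame.
    """
    site_subset = [int(j) for j in site_subset]
    known = set(res.columns.tolist())
    unknown = [j for j in site_subset if j not in known]
    if unknown:
        raise ScoringError(f"unknown alignment columns: {unknown}")
    life = traits.lifespan(trait_column)
    missing = [i for i in res.ids if i not in life.index]
    if missing:
        raise ScoringError(f"traits missing for sequences: {missing}")
    order = sorted(res.ids, key=lambda s: (-life[s], s))
    row_idx = [res.ids.index(s) for s in order]
    col_idx = [int(np.where(res.columns == j)[0][0]) for j in site_subset]
    sub = res.scores[np.ix_(row_idx, col_idx)] if site_subset else \
        np.empty((len(order), 0))
    df = pd.DataFrame(sub, columns=[f"pos{j}" for j in site_subset])
    df.insert(0, trait_column, [life[s] for s in order])
    df.insert(0, "id", order)
    df.to_csv(path, sep="\t", index=False)
    if image_path is not None and site_subset:
        _render_heatmap(df, site_subset, image_path)
    return df


def _render_heatmap(df: pd.DataFrame, site_subset, image_path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    mat = df[[f"pos{j}" for j in site_subset]].to_numpy(float)
    fig, ax = plt.subplots(
        figsize=(max(4, 0.3 * len(site_subset)), max(3, 0.12 * len(df)))
    )
    im = ax.imshow(mat, aspect="auto", cmap="coolwarm")
    ax.set_xticks(range(len(site_subset)), [str(j) for j in site_subset],
                  rotation=90, fontsize=6)
    ax.set_yticks(range(len(df)), df["id"], fontsize=5)
    ax.set_xlabel("alignment column")
    fig.colorbar(im, ax=ax, label="RES")
    fig.tight_layout()
    fig.savefig(image_path, dpi=150)
    plt.close(fig)


def _symbol_indices(alignment: Alignment) -> np.ndarray:
    lut = np.zeros(128, dtype=np.int64)
    for sym, i in SYMBOL_INDEX.items():
        lut[ord(sym)] = i
    codes = alignment.rows.view(np.uint32).reshape(alignment.rows.shape)
    return lut[codes]
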