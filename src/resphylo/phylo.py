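"""Tree construction and the Brownian-motion trait covariance.

When no tree is supplied the workflow builds one from the alignment:
p-distances (mismatch fraction over pairwise non-gap columns), neighbor
joining (Saitou-Nei), negative branch-length clamping, and midpoint rooting.
NJ recovers any additive distance matrix exactly, which makes the whole
pipeline auditable against path-length oracles.

The Brownian-motion covariance V has V(i,j) equal to the branch length shared
between the root and the most recent common ancestor of taxa i and j, and
V(i,i) the root-to-tip length.  Pagel's lambda scales the off-diagonals:
lambda=1 is pure Brownian motion, lambda=0 removes all phylogenetic
covariance.  ``estimate_lambda`` maximizes the multivariate-normal likelihood
of a continuous trait over (mu, sigma^2, lambda) with mu and sigma^2 profiled
in closed form and lambda found by bounded 1-D search on [0, 1].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import dendropy
import numpy as np
from scipy import linalg, optimize

from .seqio import Alignment, PhyloTree

logger = logging.getLogger("resphylo")


class PhyloError(ValueError):
    pass


@dataclass
class DistanceMatrix:
    """Symmetric non-negative distances with zero diagonal."""

    taxa: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.d, dtype=float)
        n = len(self.taxa)
        if d.shape != (n, n):
            raise PhyloError(f"distance matrix shape {d.shape} != ({n},{n})")
        if not np.allclose(d, d.T, atol=1e-12):
            raise PhyloError("distance matrix is not symmetric")
        if np.abs(np.diag(d)).max() > 1e-12:
            raise PhyloError("distance matrix diagonal is not zero")
        if (d < 0).any():
            raise PhyloError("negative distances")
        self.d = d


@dataclass
class BMCovariance:
    """Shared-path-length covariance with a Pagel's lambda multiplier."""

    taxa: list[str]
    V: np.ndarray
    lam: float = 1.0

    def __post_init__(self) -> None:
        V = np.asarray(self.V, dtype=float)
        if not np.allclose(V, V.T, atol=1e-10):
            raise PhyloError("covariance is not symmetric")
        self.V = V

    @property
    def n(self) -> int:
        return len(self.taxa)


@dataclass(frozen=True)
class SignalEstimate:
    """ML estimate of Pagel's lambda for one trait on one tree."""

    lambda_hat: float
    sigma2_hat: float
    loglik: float
    loglik_star: float  # log-likelihood at lambda = 0 (no signal)
    at_zero_boundary: bool


# ---------------------------------------------------------------------------
# distances


def pdistance(alignment: Alignment) -> DistanceMatrix:
    """Pairwise mismatch fraction over columns where neither row has a gap."""
    if alignment.n < 3:
        raise PhyloError("p-distance tree building needs >= 3 sequences")
    rows = alignment.rows
    gaps = rows == "-"
    n = alignment.n
    d = np.zeros((n, n))
    for i in range(n):
        comparable = ~gaps[i] & ~gaps
        n_comp = comparable.sum(axis=1)
        zero = np.flatnonzero(n_comp == 0)
        zero = zero[zero != i]
        if zero.size:
            j = int(zero[0])
            raise PhyloError(
                "no comparable (gap-free in both) columns between "
                f"'{alignment.ids[i]}' and '{alignment.ids[j]}'"
            )
        mism = ((rows != rows[i]) & comparable).sum(axis=1)
        with np.errstate(invalid="ignore"):
            d[i] = mism / n_comp
        d[i, i] = 0.0
    d = (d + d.T) / 2  # exact symmetry against float noise
    return DistanceMatrix(list(alignment.ids), d)


# ---------------------------------------------------------------------------
# neighbor joining


def neighbor_joining(dm: DistanceMatrix) -> PhyloTree:
    """Saitou-Nei agglomeration; clamps negative branch lengths to zero and
    midpoint-roots the resulting unrooted tree.

    Ties in the Q matrix are broken by the smallest (row, column) index pair
    so construction is deterministic.
    """
    n = len(dm.taxa)
    if n < 3:
        raise PhyloError("neighbor joining needs >= 3 taxa")
    D = dm.d.copy()
    # newick fragments and the pending edge length under each active node
    nodes = [f"'{t}'" if _needs_quotes(t) else t for t in dm.taxa]
    active = list(range(n))
    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        Q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        flat = int(np.argmin(Q))  # argmin returns first minimum: deterministic
        ai, aj = divmod(flat, m)
        if ai > aj:
            ai, aj = aj, ai
        dij = sub[ai, aj]
        li = 0.5 * dij + (r[ai] - r[aj]) / (2 * (m - 2))
        lj = dij - li
        li, lj = max(li, 0.0), max(lj, 0.0)
        i, j = active[ai], active[aj]
        # distances from the new internal node to every other active node
        new = 0.5 * (D[i, active] + D[j, active] - dij)
        D = np.pad(D, ((0, 1), (0, 1)))
        k = D.shape[0] - 1
        D[k, active] = new
        D[active, k] = new
        D[k, k] = 0.0
        nodes.append(f"({nodes[i]}:{_fmt(li)},{nodes[j]}:{_fmt(lj)})")
        active = [a for a in active if a not in (i, j)] + [k]
    i, j, k = active
    li = 0.5 * (D[i, j] + D[i, k] - D[j, k])
    lj = 0.5 * (D[i, j] + D[j, k] - D[i, k])
    lk = 0.5 * (D[i, k] + D[j, k] - D[i, j])
    li, lj, lk = (max(v, 0.0) for v in (li, lj, lk))
    newick = (
        f"({nodes[i]}:{_fmt(li)},{nodes[j]}:{_fmt(lj)},{nodes[k]}:{_fmt(lk)});"
    )
    tree = dendropy.Tree.get(
        data=newick, schema="newick", preserve_underscores=True,
        suppress_internal_node_taxa=True,
    )
    tree.reroot_at_midpoint(update_bipartitions=False)
    if tree.seed_node.edge.length:
        tree.seed_node.edge.length = None
    return PhyloTree(tree)


def _needs_quotes(label: str) -> bool:
    return any(c in label for c in "(),:;[] '")


def _fmt(x: float) -> str:
    return format(float(x), ".17g")


def path_length_matrix(tree: PhyloTree) -> tuple[list[str], np.ndarray]:
    """Leaf-to-leaf path lengths; the oracle for additive recovery."""
    taxa, V = _shared_path_matrix(tree.tree)
    depth = np.diag(V)
    d = depth[:, None] + depth[None, :] - 2 * V
    np.fill_diagonal(d, 0.0)
    return taxa, d


# ---------------------------------------------------------------------------
# Brownian-motion covariance


def _shared_path_matrix(tree: dendropy.Tree) -> tuple[list[str], np.ndarray]:
    leaves = list(tree.leaf_node_iter())
    taxa = [lf.taxon.label for lf in leaves]
    index = {id(lf): i for i, lf in enumerate(leaves)}
    n = len(leaves)
    depth: dict[int, float] = {id(tree.seed_node): 0.0}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        depth[id(node)] = depth[id(node.parent_node)] + (node.edge.length or 0.0)
    V = np.zeros((n, n))
    below: dict[int, list[int]] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            i = index[id(node)]
            below[id(node)] = [i]
            V[i, i] = depth[id(node)]
            continue
        groups = [below.pop(id(c)) for c in node.child_nodes()]
        d = depth[id(node)]
        for gi in range(len(groups)):
            for gj in range(gi + 1, len(groups)):
                for a in groups[gi]:
                    V[a, groups[gj]] = d
                    V[groups[gj], a] = d
        below[id(node)] = [x for g in groups for x in g]
    return taxa, V


def bm_covariance(tree: PhyloTree) -> BMCovariance:
    """Root-to-MRCA shared branch lengths for every taxon pair (lambda = 1)."""
    taxa, V = _shared_path_matrix(tree.tree)
    return BMCovariance(taxa, V, lam=1.0)


def lambda_transform(cov: BMCovariance, lam: float) -> BMCovariance:
    """Multiply off-diagonal covariances by lambda, keep diagonals."""
    if not 0.0 <= lam <= 1.0:
        raise PhyloError(f"lambda must be in [0, 1], got {lam}")
    V = cov.V * lam
    np.fill_diagonal(V, np.diag(cov.V))
    return BMCovariance(list(cov.taxa), V, lam=lam)


# ---------------------------------------------------------------------------
# Pagel's lambda ML


def _profiled_loglik(V: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """(loglik, mu_hat, sigma2_hat) for y ~ N(mu 1, sigma^2 V), mu/sigma^2 ML."""
    n = len(y)
    try:
        cho = linalg.cho_factor(V, lower=True)
    except linalg.LinAlgError as exc:
        raise PhyloError(
            "singular covariance (condition number "
            f"{np.linalg.cond(V):.3g})"
        ) from exc
    one = np.ones(n)
    Vi1 = linalg.cho_solve(cho, one)
    Viy = linalg.cho_solve(cho, y)
    mu = (one @ Viy) / (one @ Vi1)
    r = y - mu
    sigma2 = (r @ linalg.cho_solve(cho, r)) / n
    if sigma2 <= 0:
        raise PhyloError("degenerate trait: zero residual variance")
    logdet = 2 * np.log(np.diag(cho[0])).sum()
    ll = -0.5 * (n * np.log(2 * np.pi * sigma2) + n + logdet)
    return float(ll), float(mu), float(sigma2)


def estimate_lambda(
    tree: PhyloTree,
    trait,
    grid_points: int = 11,
    xatol: float = 1e-6,
) -> SignalEstimate:
    """Maximum-likelihood Pagel's lambda for a continuous trait.

    ``trait`` maps taxon label to value (mapping or pandas Series).  The
    likelihood is profiled over mu and sigma^2 and optimized over lambda on
    [0, 1], seeded from the best of a coarse grid to cope with boundary
    multimodality.
    """
    cov = bm_covariance(tree)
    if cov.n < 4:
        raise PhyloError("lambda estimation needs >= 4 taxa")
    y = np.array([float(trait[t]) for t in cov.taxa])
    if np.ptp(y) == 0:
        raise PhyloError("constant trait: lambda is unidentifiable")

    def ll(lam: float) -> float:
        return _profiled_loglik(lambda_transform(cov, lam).V, y)[0]

    grid = np.linspace(0.0, 1.0, grid_points)
    grid_ll = np.array([ll(g) for g in grid])
    best = int(np.argmax(grid_ll))
    lo = grid[max(best - 1, 0)]
    hi = grid[min(best + 1, grid_points - 1)]
    res = optimize.minimize_scalar(
        lambda lam: -ll(lam), bounds=(lo, hi), method="bounded",
        options={"xatol": xatol},
    )
    lam_hat = float(np.clip(res.x, 0.0, 1.0))
    candidates = [lam_hat, float(grid[best])]
    lam_hat = max(candidates, key=ll)
    loglik, _, sigma2 = _profiled_loglik(lambda_transform(cov, lam_hat).V, y)
    loglik_star = ll(0.0)
    if loglik < loglik_star:  # lambda = 0 never beaten by a worse interior fit
        lam_hat, loglik = 0.0, loglik_star
        sigma2 = _profiled_loglik(lambda_transform(cov, 0.0).V, y)[2]
    return SignalEstimate(
        lambda_hat=lam_hat,
        sigma2_hat=sigma2,
        loglik=loglik,
        loglik_star=loglik_star,
        at_zero_boundary=lam_hat < 1e-4,
    )
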