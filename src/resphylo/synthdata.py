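"""Synthetic trees, traits, and alignments with known ground truth.

The generator mirrors the statistical structure the screen assumes: a Yule
pure-birth phylogeny, a lifespan-like trait evolved by Brownian motion with a
chosen Pagel's lambda, and an alignment whose columns are either neutral
(symmetric 20-state substitution process run down the tree) or linked to the
trait (long-lived taxa carry one residue, short-lived another, with
configurable misassignment noise).  Known linked-column labels make
sensitivity and false-positive accounting exact.

Every draw flows from a single numpy Generator, so a fixed seed reproduces
the whole bundle bit for bit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

from .phylo import bm_covariance, lambda_transform
from .seqio import Alignment, PhyloTree, TraitTable

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"  # neutral process never emits gaps
LONG_RESIDUE, SHORT_RESIDUE = "K", "E"


class SynthError(ValueError):
    pass


@dataclass
class SimConfig:
    """Study conditions for one synthetic dataset.

    Defaults match the screen's standard evaluation setting: 60 taxa,
    120 columns of which 6 are trait-linked at effect 0.95, Brownian trait
    with unit rate and full phylogenetic signal.
    """

    n_taxa: int = 60
    birth_rate: float = 1.0
    L_total: int = 120
    linked_columns: tuple[int, ...] = (10, 30, 50, 70, 90, 110)
    effect: float = 0.95
    neutral_rate: float = 0.5
    sigma2: float = 1.0
    lambda_true: float = 1.0
    root_value: float = 30.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.linked_columns = tuple(int(c) for c in self.linked_columns)
        if any(not 1 <= c <= self.L_total for c in self.linked_columns):
            raise SynthError(
                f"linked columns {self.linked_columns} outside 1..{self.L_total}"
            )
        if not 0.5 <= self.effect <= 1.0:
            raise SynthError(f"effect must be in [0.5, 1], got {self.effect}")
        if self.birth_rate <= 0 or self.neutral_rate < 0 or self.sigma2 < 0:
            raise SynthError("rates must be positive")
        if not 0.0 <= self.lambda_true <= 1.0:
            raise SynthError(f"lambda_true must be in [0, 1]")


def _rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def simulate_yule_tree(
    n_taxa: int, birth_rate: float = 1.0, seed=0
) -> PhyloTree:
    """Pure-birth ultrametric tree.

    Starting from two lineages, while k lineages exist the next split waits
    Exp(k * birth_rate); after the n-th lineage appears one further waiting
    period elapses before the present, so expected depth is
    sum_{k=2..n} 1/(k * birth_rate).
    """
    if n_taxa < 3:
        raise SynthError("need >= 3 taxa")
    rng = _rng(seed)
    taxon_ns = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxon_ns)
    root = tree.seed_node
    tips = []
    for _ in range(2):
        child = dendropy.Node(edge_length=0.0)
        root.add_child(child)
        tips.append(child)
    k = 2
    while True:
        dt = rng.exponential(1.0 / (birth_rate * k))
        for tip in tips:
            tip.edge.length += dt
        if k == n_taxa:
            break
        split = tips.pop(int(rng.integers(len(tips))))
        for _ in range(2):
            child = dendropy.Node(edge_length=0.0)
            split.add_child(child)
            tips.append(child)
        k += 1
    width = len(str(n_taxa))
    for i, tip in enumerate(tips, start=1):
        tip.taxon = taxon_ns.new_taxon(f"T{i:0{width}d}")
    return PhyloTree(tree)


def simulate_bm_trait(
    tree: PhyloTree,
    sigma2: float = 1.0,
    lambda_true: float = 1.0,
    root_value: float = 0.0,
    seed=0,
) -> pd.Series:
    """Draw one trait from N(root_value * 1, sigma2 * V(lambda))."""
    rng = _rng(seed)
    cov = lambda_transform(bm_covariance(tree), lambda_true)
    V = sigma2 * cov.V
    eigmin = float(np.linalg.eigvalsh(V).min())
    if eigmin < -1e-9 * max(1.0, float(np.abs(V).max())):
        raise SynthError(f"covariance not PSD (min eigenvalue {eigmin:.3g})")
    if sigma2 == 0:
        values = np.full(cov.n, float(root_value))
    else:
        L = np.linalg.cholesky(V + 1e-12 * np.eye(cov.n))
        values = root_value + L @ rng.standard_normal(cov.n)
    return pd.Series(values, index=cov.taxa, name="trait")


def _evolve_neutral_column(
    tree: dendropy.Tree, rate: float, rng: np.random.Generator
) -> dict[str, str]:
    """Symmetric 20-state process: change prob 1 - exp(-rate * length) per
    branch; on change, a uniform draw among the other 19 residues."""
    states: dict[int, int] = {id(tree.seed_node): int(rng.integers(20))}
    out: dict[str, str] = {}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        parent_state = states[id(node.parent_node)]
        blen = node.edge.length or 0.0
        if rng.random() < 1.0 - np.exp(-rate * blen):
            shift = 1 + int(rng.integers(19))
            state = (parent_state + shift) % 20
        else:
            state = parent_state
        states[id(node)] = state
        if node.is_leaf():
            out[node.taxon.label] = AMINO_ACIDS[state]
    return out


def simulate_linked_alignment(
    tree: PhyloTree, trait: pd.Series, config: SimConfig, seed=None
) -> Alignment:
    """Alignment with known trait-linked columns among a neutral background.

    Linked columns give the "long-lived" residue K to taxa with trait
    strictly above the median and E otherwise, then flip each assignment
    independently with probability 1 - effect.  Neutral columns evolve down
    the tree.  Taxa are ordered by taxon id.
    """
    rng = _rng(config.seed if seed is None else seed)
    taxa = sorted(tree.taxa)
    missing = [t for t in taxa if t not in trait.index]
    if missing:
        raise SynthError(f"trait missing for taxa: {missing}")
    linked = set(config.linked_columns)
    median = float(np.median(trait.loc[taxa]))
    rows = np.empty((len(taxa), config.L_total), dtype="<U1")
    for j in range(1, config.L_total + 1):
        if j in linked:
            for i, t in enumerate(taxa):
                long_lived = float(trait[t]) > median
                if rng.random() < 1.0 - config.effect:
                    long_lived = not long_lived
                rows[i, j - 1] = LONG_RESIDUE if long_lived else SHORT_RESIDUE
        else:
            col = _evolve_neutral_column(tree.tree, config.neutral_rate, rng)
            for i, t in enumerate(taxa):
                rows[i, j - 1] = col[t]
    return Alignment(
        list(taxa), rows,
        provenance={"simulated": True, "linked_columns": sorted(linked)},
    )


def enumerate_unrooted_trees(n_taxa: int) -> list[list[tuple[int, int]]]:
    """All labeled unrooted binary topologies on leaves 0..n-1 as edge lists.

    Built by stepwise leaf insertion (every tree arises exactly once), so the
    count follows (2k-5)!! — 3, 15, 105, 945, 10395 for 4..8 leaves.
    Internal nodes are numbered from ``n_taxa`` upward.
    """
    if n_taxa < 3:
        raise SynthError("need >= 3 leaves")
    trees: list[list[tuple[int, int]]] = [[(0, 1)]]
    for k in range(2, n_taxa):
        internal = n_taxa + k - 2
        grown: list[list[tuple[int, int]]] = []
        for edges in trees:
            for i, (u, v) in enumerate(edges):
                grown.append(
                    edges[:i] + edges[i + 1:]
                    + [(u, internal), (internal, v), (internal, k)]
                )
        trees = grown
    return trees


def additive_distance_matrix(
    edges: list[tuple[int, int]], n_taxa: int, rng=None
) -> np.ndarray:
    """Leaf-to-leaf path lengths of an edge-list tree with random edge
    lengths in [0.5, 3); the ground truth for additive-recovery checks."""
    rng = _rng(0 if rng is None else rng)
    lengths = {
        tuple(sorted(e)): float(x)
        for e, x in zip(edges, rng.uniform(0.5, 3.0, len(edges)))
    }
    adj: dict[int, list[int]] = {}
    for u, v in edges:
        adj.setdefault(u, []).append(v)
        adj.setdefault(v, []).append(u)
    d = np.zeros((n_taxa, n_taxa))
    for s in range(n_taxa):
        dist = {s: 0.0}
        stack = [s]
        while stack:
            x = stack.pop()
            for y in adj[x]:
                if y not in dist:
                    dist[y] = dist[x] + lengths[tuple(sorted((x, y)))]
                    stack.append(y)
        for t in range(n_taxa):
            d[s, t] = dist[t]
    return (d + d.T) / 2  # exact symmetry against float path-sum noise


@dataclass
class SyntheticBundle:
    tree: PhyloTree
    traits: TraitTable
    alignment: Alignment
    truth: dict = field(default_factory=dict)


def make_dataset(config: SimConfig) -> SyntheticBundle:
    """Full reproducible bundle: tree, lifespan-like traits, alignment, truth."""
    rng = np.random.default_rng(config.seed)
    tree = simulate_yule_tree(config.n_taxa, config.birth_rate, rng)
    trait = simulate_bm_trait(
        tree, config.sigma2, config.lambda_true, config.root_value, rng
    )
    alignment = simulate_linked_alignment(tree, trait, config, rng)
    traits = TraitTable(pd.DataFrame({
        "species": alignment.ids,
        "L_avg": trait.loc[alignment.ids].to_numpy(),
        "L_max": np.nan,
    }))
    truth = {
        "linked_columns": sorted(config.linked_columns),
        "effect": config.effect,
        "lambda_true": config.lambda_true,
        "seed": config.seed,
    }
    return SyntheticBundle(tree, traits, alignment, truth)


def write_dataset(bundle: SyntheticBundle, out_prefix: str | Path) -> dict:
    """Write aln.fasta / tree.nwk / traits.tsv / truth.json under a prefix."""
    from . import seqio

    out = Path(out_prefix)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "alignment": out / "aln.fasta",
        "tree": out / "tree.nwk",
        "traits": out / "traits.tsv",
        "truth": out / "truth.json",
    }
    seqio.write_alignment(bundle.alignment, paths["alignment"])
    seqio.write_tree(bundle.tree, paths["tree"])
    seqio.write_traits(bundle.traits, paths["traits"])
    with open(paths["truth"], "w", encoding="utf-8") as fh:
        json.dump(bundle.truth, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return {k: str(v) for k, v in paths.items()}
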