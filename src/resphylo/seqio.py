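"""Input/output for the formats the workflow touches.

Aligned protein FASTA, newick trees with branch lengths, and TSV/CSV trait
tables, plus the cross-file harmonization step that restricts all three to a
common taxon set before any statistics are run.

The residue alphabet is fixed at the 20 canonical amino acids plus the gap
symbol ``-``.  Non-canonical letters (B, Z, X, U, O, J, ``*``, ``.``) are
mapped to the gap with a logged warning so every downstream count runs over
exactly 21 symbols.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import dendropy
import numpy as np
import pandas as pd
from Bio import SeqIO

logger = logging.getLogger("resphylo")

#: 20 canonical amino acids followed by the gap symbol.
ALPHABET: str = "ACDEFGHIKLMNPQRSTVWY-"
GAP: str = "-"
SYMBOL_INDEX: dict[str, int] = {a: i for i, a in enumerate(ALPHABET)}
#: Letters outside the canonical alphabet that are collapsed onto the gap.
NON_CANONICAL: frozenset[str] = frozenset("BZXUOJ*.")


class SeqIOError(ValueError):
    """Raised for malformed or inconsistent input files."""


@dataclass
class Alignment:
    """Rectangular protein alignment: ``n`` sequences by ``L`` columns.

    ``rows`` is an ``(n, L)`` array of single characters drawn from
    :data:`ALPHABET`.  Columns are 1-based in every report the package writes.
    """

    ids: list[str]
    rows: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.rows = np.asarray(self.rows, dtype="<U1")
        if self.rows.ndim != 2:
            raise SeqIOError("alignment rows must form a 2-D matrix")
        n, L = self.rows.shape
        if n < 2:
            raise SeqIOError(f"alignment needs at least 2 sequences, got {n}")
        if L < 1:
            raise SeqIOError("alignment has zero columns")
        if len(self.ids) != n:
            raise SeqIOError("number of ids does not match number of rows")
        if len(set(self.ids)) != n:
            dupes = sorted({i for i in self.ids if self.ids.count(i) > 1})
            raise SeqIOError(f"duplicate sequence ids: {dupes}")
        bad = set(np.unique(self.rows)) - set(ALPHABET)
        if bad:
            raise SeqIOError(f"symbols outside alphabet: {sorted(bad)}")

    @property
    def n(self) -> int:
        return self.rows.shape[0]

    @property
    def length(self) -> int:
        return self.rows.shape[1]

    def sequence(self, seq_id: str) -> str:
        return "".join(self.rows[self.ids.index(seq_id)])

    def subset(self, ids: Sequence[str]) -> "Alignment":
        """Return the alignment restricted to ``ids`` in the given order."""
        idx = [self.ids.index(i) for i in ids]
        return Alignment(list(ids), self.rows[idx], dict(self.provenance))


@dataclass
class PhyloTree:
    """Rooted tree with branch lengths over the aligned taxa.

    A thin wrapper around a :class:`dendropy.Tree`; all branch lengths are
    non-negative and every non-root edge carries a length (required by the
    Brownian-motion covariance).
    """

    tree: dendropy.Tree

    def __post_init__(self) -> None:
        seed = self.tree.seed_node
        if seed is None or not seed.child_nodes():
            raise SeqIOError("tree has no taxa")
        labels = self.taxa
        if len(labels) != len(set(labels)):
            raise SeqIOError("duplicate leaf labels in tree")
        for edge in self.tree.preorder_edge_iter():
            if edge.tail_node is None:  # root edge
                continue
            if edge.length is None:
                node = edge.head_node
                name = node.taxon.label if node.taxon else "<internal>"
                raise SeqIOError(f"missing branch length above node '{name}'")
            if edge.length < 0:
                raise SeqIOError(f"negative branch length {edge.length}")

    @property
    def taxa(self) -> list[str]:
        return [lf.taxon.label for lf in self.tree.leaf_node_iter()]

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    def prune_to(self, labels: Iterable[str]) -> "PhyloTree":
        """Return a copy restricted to ``labels`` (suppressing unifurcations)."""
        keep = set(labels)
        clone = self.tree.clone(depth=1)
        clone.retain_taxa_with_labels(sorted(keep))
        clone.purge_taxon_namespace()
        return PhyloTree(clone)

    def as_newick(self) -> str:
        return (
            self.tree.as_string(schema="newick", suppress_rooting=True).strip()
        )


@dataclass
class TraitTable:
    """Species lifespan table.

    Columns: ``species``, ``L_avg`` (observed average lifespan, years),
    ``L_max`` (observed maximum lifespan, years), and, once normalization has
    run, ``L_avg_est``, ``L_norm`` and ``source``.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        if "species" not in df.columns:
            raise SeqIOError("trait table needs a 'species' column")
        for col in ("L_avg", "L_max"):
            if col not in df.columns:
                df[col] = np.nan
            df[col] = pd.to_numeric(df[col], errors="coerce")
        df["species"] = df["species"].astype(str).map(normalize_label)
        if df["species"].duplicated().any():
            dupes = sorted(df.loc[df["species"].duplicated(), "species"])
            raise SeqIOError(f"duplicate species in trait table: {dupes}")
        neither = df["L_avg"].isna() & df["L_max"].isna()
        if neither.any():
            raise SeqIOError(
                "species with neither L_avg nor L_max: "
                f"{sorted(df.loc[neither, 'species'])}"
            )
        nonpos = ((df["L_avg"] <= 0) & df["L_avg"].notna()) | (
            (df["L_max"] <= 0) & df["L_max"].notna()
        )
        if nonpos.any():
            raise SeqIOError(
                f"non-positive lifespans for: {sorted(df.loc[nonpos, 'species'])}"
            )
        self.data = df.reset_index(drop=True)

    @property
    def species(self) -> list[str]:
        return list(self.data["species"])

    def subset(self, species: Sequence[str]) -> "TraitTable":
        df = self.data.set_index("species").loc[list(species)].reset_index()
        return TraitTable(df)

    def lifespan(self, column: str = "L_avg") -> pd.Series:
        """Per-species lifespan values from ``column``, indexed by species."""
        if column not in self.data.columns:
            raise SeqIOError(f"trait table has no column '{column}'")
        s = self.data.set_index("species")[column]
        if s.isna().any():
            raise SeqIOError(
                f"missing {column} for: {sorted(s.index[s.isna()])}"
            )
        return s.astype(float)


def normalize_label(label: str) -> str:
    """Exact-match normalization shared by FASTA, newick and trait tables.

    Whitespace runs become single underscores; surrounding quotes (a newick
    convention) are stripped.
    """
    return "_".join(label.strip().strip("'\"").split())


def _sanitize_residues(seq: str, seq_id: str) -> str:
    seq = seq.upper()
    bad = sorted(set(seq) & NON_CANONICAL)
    if bad:
        logger.warning(
            "sequence %s: mapping non-canonical symbols %s to gap", seq_id, bad
        )
        seq = seq.translate(str.maketrans({c: GAP for c in bad}))
    unknown = set(seq) - set(ALPHABET)
    if unknown:
        raise SeqIOError(
            f"sequence {seq_id}: unrecognized symbols {sorted(unknown)}"
        )
    return seq


def read_alignment(path: str | Path, format: str = "fasta") -> Alignment:
    """Read an aligned FASTA file into a validated :class:`Alignment`."""
    if format != "fasta":
        raise SeqIOError(f"unsupported alignment format: {format}")
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise SeqIOError(f"no sequences found in {path}")
    ids: list[str] = []
    seqs: list[str] = []
    length = None
    for rec in records:
        seq_id = normalize_label(rec.id)
        seq = _sanitize_residues(str(rec.seq), seq_id)
        if length is None:
            length = len(seq)
        elif len(seq) != length:
            raise SeqIOError(
                f"length mismatch: sequence '{seq_id}' has length "
                f"{len(seq)}, expected {length}"
            )
        ids.append(seq_id)
        seqs.append(seq)
    rows = np.array([list(s) for s in seqs], dtype="<U1")
    aln = Alignment(ids, rows, provenance={"source": str(path)})
    logger.info("read alignment %s: n=%d, L=%d", path, aln.n, aln.length)
    return aln


def write_alignment(alignment: Alignment, path: str | Path) -> None:
    """Write an alignment as canonical FASTA (one line per sequence)."""
    with open(path, "w", encoding="utf-8") as fh:
        for seq_id, row in zip(alignment.ids, alignment.rows):
            fh.write(f">{seq_id}\n{''.join(row)}\n")


def read_tree(path: str | Path) -> PhyloTree:
    """Read a rooted newick tree with branch lengths.

    Trees whose root has more than two children are rejected as unrooted:
    the Brownian-motion covariance needs an explicit root.
    """
    path = Path(path)
    tree = dendropy.Tree.get(
        path=str(path),
        schema="newick",
        preserve_underscores=True,
        suppress_internal_node_taxa=True,
    )
    for leaf in tree.leaf_node_iter():
        leaf.taxon.label = normalize_label(leaf.taxon.label)
    root_children = tree.seed_node.child_nodes()
    if len(root_children) > 2:
        raise SeqIOError(
            f"tree in {path} is unrooted (root has {len(root_children)} "
            "children); root it (e.g. midpoint) before use"
        )
    return PhyloTree(tree)


def write_tree(tree: PhyloTree, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(tree.as_newick() + "\n")


def read_traits(path: str | Path) -> TraitTable:
    """Read a TSV/CSV trait table (``species``, ``L_avg``, ``L_max``)."""
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep)
    df.columns = [c.strip() for c in df.columns]
    return TraitTable(df)


def write_traits(traits: TraitTable, path: str | Path) -> None:
    traits.data.to_csv(path, sep="\t", index=False)


def harmonize(
    alignment: Alignment, tree: PhyloTree, traits: TraitTable
) -> tuple[Alignment, PhyloTree, TraitTable]:
    """Restrict alignment, tree and traits to their common taxa.

    Canonical order is the alignment's order filtered to the intersection.
    Dropped taxa are logged.  Fails if fewer than 3 taxa remain (PGLS needs
    residual degrees of freedom).
    """
    common = set(alignment.ids) & set(tree.taxa) & set(traits.species)
    if len(common) < 3:
        raise SeqIOError(
            f"only {len(common)} taxa shared across alignment/tree/traits; "
            "need at least 3"
        )
    order = [t for t in alignment.ids if t in common]
    for name, have in (
        ("alignment", alignment.ids),
        ("tree", tree.taxa),
        ("traits", traits.species),
    ):
        dropped = sorted(set(have) - common)
        if dropped:
            logger.warning("harmonize: dropping %d taxa from %s: %s",
                           len(dropped), name, dropped)
    return alignment.subset(order), tree.prune_to(order), traits.subset(order)
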