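"""Rooted phylogenies and the Brownian-motion covariance consumed by PGLS.

A tree with branch lengths in arbitrary time units induces the standard
Brownian trait covariance among its tips: ``V[i, j]`` is the path length
shared by tips *i* and *j* from the root to their most recent common
ancestor, and ``V[i, i]`` is the root-to-tip distance.  Pagel's lambda
rescales the off-diagonal entries by a factor in [0, 1], interpolating
between phylogenetic independence (0) and full Brownian structure (1).

Parsing and pruning are delegated to :mod:`dendropy`; this module owns
label normalisation, validation and the covariance construction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import dendropy
import numpy as np

from .errors import MissingTaxaError, NewickParseError

logger = logging.getLogger(__name__)

__all__ = [
    "PhyloTree",
    "PhyloCovariance",
    "parse_newick",
    "prune_to_taxa",
    "covariance_from_tree",
    "normalize_label",
]


def normalize_label(label: str) -> str:
    """Canonical taxon-name form: trimmed, underscores unified to spaces.

    Newick dialects disagree on whether ``Tursiops_truncatus`` and
    ``Tursiops truncatus`` are the same label; after normalisation they are.
    """
    return " ".join(str(label).replace("_", " ").split())


@dataclass(frozen=True)
class PhyloCovariance:
    """Brownian covariance among an ordered list of tips.

    Attributes
    ----------
    taxa
        Tip labels, in the row/column order of ``matrix``.
    matrix
        Symmetric positive semi-definite matrix of shared path lengths.
    lam
        The Pagel's lambda that was applied to the off-diagonal.
    """

    taxa: tuple[str, ...]
    matrix: np.ndarray
    lam: float = 1.0

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.taxa), len(self.taxa)):
            raise ValueError("covariance matrix shape does not match taxa")
        object.__setattr__(self, "matrix", m)

    def subset(self, taxa: list[str]) -> "PhyloCovariance":
        """Row/column subset in the requested order."""
        want = [normalize_label(t) for t in taxa]
        index = {t: i for i, t in enumerate(self.taxa)}
        missing = [t for t in want if t not in index]
        if missing:
            raise MissingTaxaError(f"taxa absent from covariance: {missing}")
        idx = np.array([index[t] for t in want])
        return PhyloCovariance(tuple(want), self.matrix[np.ix_(idx, idx)], self.lam)


class PhyloTree:
    """A rooted, branch-length-bearing tree with uniquely labelled tips.

    Thin wrapper over a :class:`dendropy.Tree` enforcing the invariants the
    comparative analysis needs: unique tip labels, non-negative branch
    lengths, and pruning that preserves root-to-tip distances.
    """

    def __init__(self, tree: dendropy.Tree):
        self._tree = tree
        self._validate()

    # -- construction -------------------------------------------------

    @classmethod
    def from_newick(cls, text: str) -> "PhyloTree":
        try:
            tree = dendropy.Tree.get(
                data=text,
                schema="newick",
                preserve_underscores=True,
                suppress_internal_node_taxa=True,
            )
        except Exception as exc:  # dendropy raises several parse error types
            raise NewickParseError(f"malformed Newick: {exc}") from exc
        return cls(tree)

    def _validate(self) -> None:
        seen: dict[str, int] = {}
        for leaf in self._tree.leaf_node_iter():
            if leaf.taxon is None or leaf.taxon.label is None:
                raise NewickParseError("unlabelled tip in tree")
            label = normalize_label(leaf.taxon.label)
            leaf.taxon.label = label
            seen[label] = seen.get(label, 0) + 1
        dupes = sorted(t for t, n in seen.items() if n > 1)
        if dupes:
            raise NewickParseError(f"duplicate tip labels: {dupes}")
        if len(seen) < 1:
            raise NewickParseError("tree has no tips")
        for edge in self._tree.preorder_edge_iter():
            if edge.head_node is self._tree.seed_node:
                continue  # root edge length is irrelevant; missing is fine
            if edge.length is None:
                raise NewickParseError(
                    f"missing branch length above node "
                    f"{edge.head_node.taxon.label if edge.head_node.taxon else '<internal>'}"
                )
            if edge.length < 0:
                raise NewickParseError(
                    f"negative branch length {edge.length} above node "
                    f"{edge.head_node.taxon.label if edge.head_node.taxon else '<internal>'}"
                )
            if edge.length == 0 and edge.head_node.is_leaf():
                logger.warning(
                    "zero-length terminal branch at tip %s",
                    edge.head_node.taxon.label,
                )

    # -- basic queries -------------------------------------------------

    @property
    def tip_labels(self) -> list[str]:
        return [leaf.taxon.label for leaf in self._tree.leaf_node_iter()]

    @property
    def n_tips(self) -> int:
        return len(self._tree.leaf_nodes())

    def tip_depths(self) -> dict[str, float]:
        """Root-to-tip path length per tip."""
        depths: dict[str, float] = {}
        for node in self._tree.preorder_node_iter():
            parent_depth = 0.0 if node.parent_node is None else node.parent_node._wb_depth
            node._wb_depth = parent_depth + (node.edge.length or 0.0)
            if node.is_leaf():
                depths[node.taxon.label] = node._wb_depth
        return depths

    def is_ultrametric(self, rel_tol: float = 1e-8) -> bool:
        d = np.array(list(self.tip_depths().values()))
        return bool(np.ptp(d) <= rel_tol * max(d.max(), 1.0))

    def to_newick(self) -> str:
        return self._tree.as_string(schema="newick", suppress_rooting=True).strip()

    # -- manipulation --------------------------------------------------

    def prune(self, taxa) -> "PhyloTree":
        """New tree retaining only ``taxa``; root-to-tip distances preserved,
        degree-2 internal nodes collapsed by summing branch lengths."""
        want = {normalize_label(t) for t in taxa}
        if not want:
            raise MissingTaxaError("cannot prune to an empty taxon set")
        have = set(self.tip_labels)
        missing = sorted(want - have)
        if missing:
            raise MissingTaxaError(f"taxa absent from tree: {missing}")
        clone = dendropy.Tree(self._tree)
        clone.retain_taxa_with_labels(sorted(want))
        # dendropy leaves a dangling root unifurcation in some topologies
        clone.suppress_unifurcations()
        return PhyloTree(clone)

    # -- covariance ----------------------------------------------------

    def covariance(self, lam: float = 1.0) -> PhyloCovariance:
        """Brownian covariance with Pagel's lambda applied off-diagonal."""
        if not (0.0 <= lam <= 1.0):
            raise ValueError(f"lambda must lie in [0, 1], got {lam}")
        if self.n_tips < 2:
            raise ValueError("covariance requires at least 2 tips")
        depths = self.tip_depths()
        labels = self.tip_labels
        pdm = self._tree.phylogenetic_distance_matrix()
        taxa_by_label = {t.label: t for t in self._tree.taxon_namespace if t.label in depths}
        n = len(labels)
        V = np.zeros((n, n))
        for i, a in enumerate(labels):
            V[i, i] = depths[a]
            for j in range(i + 1, n):
                b = labels[j]
                d = pdm.patristic_distance(taxa_by_label[a], taxa_by_label[b])
                shared = 0.5 * (depths[a] + depths[b] - d)
                # clip tiny negative float noise
                shared = max(shared, 0.0)
                V[i, j] = V[j, i] = lam * shared
        return PhyloCovariance(tuple(labels), V, lam)


# -- functional facade (the operation names used throughout the package) --


def parse_newick(text: str) -> PhyloTree:
    """Parse a Newick string (branch lengths required, trailing semicolon)."""
    return PhyloTree.from_newick(text)


def prune_to_taxa(tree: PhyloTree, taxa) -> PhyloTree:
    return tree.prune(taxa)


def covariance_from_tree(tree: PhyloTree, lam: float = 1.0) -> PhyloCovariance:
    return tree.covariance(lam)
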