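"""Time-calibrated phylogenies: I/O, clade stem ages, exemplar pruning, Brownian covariance.

Trees are rooted, with branch lengths in millions of years (Myr). Ages run
backward from the present: extant tips sit at age 0 and the root is the
oldest node. Trees are expected to be ultrametric up to numerical noise; a
tree whose tip depths differ by more than ``ULTRAMETRIC_RTOL`` times its
depth triggers a warning but is still usable (ages are then measured from
the deepest tip).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np

logger = logging.getLogger("cladediv")

#: relative tolerance (fraction of tree depth) for the ultrametricity check
ULTRAMETRIC_RTOL = 1e-6


class TreeError(ValueError):
    """Invalid tree structure or tree query."""


class PolytomyError(TreeError):
    """Operation requires a strictly bifurcating tree."""


@dataclass(frozen=True)
class CladeAgeRecord:
    """Stem (and, for clades with >=2 tips, crown) age of one clade, in Myr."""

    clade_id: str
    stem_age: float
    crown_age: float | None = None

    def __post_init__(self):
        if self.stem_age <= 0:
            raise TreeError(f"stem_age must be > 0, got {self.stem_age}")
        if self.crown_age is not None and self.stem_age < self.crown_age - 1e-12:
            raise TreeError(
                f"stem_age ({self.stem_age}) < crown_age ({self.crown_age})"
            )


@dataclass
class PhyloCovariance:
    """Brownian-motion trait covariance implied by a tree.

    ``matrix[i, j]`` is the shared root-to-MRCA path length (Myr) of taxa
    ``taxa[i]`` and ``taxa[j]``; the diagonal holds root-to-tip path lengths.
    ``lambda_applied`` is "raw" for the untransformed matrix, else the
    Pagel's lambda value that scaled the off-diagonal entries.
    """

    taxa: tuple[str, ...]
    matrix: np.ndarray
    lambda_applied: float | str = "raw"

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.taxa)
        if self.matrix.shape != (n, n):
            raise TreeError(
                f"covariance shape {self.matrix.shape} does not match {n} taxa"
            )

    def reordered(self, taxa: Sequence[str]) -> "PhyloCovariance":
        """Return a copy with rows/columns permuted into the given taxon order."""
        idx = [self.taxa.index(t) for t in taxa]
        return PhyloCovariance(
            tuple(taxa), self.matrix[np.ix_(idx, idx)], self.lambda_applied
        )


class TimeTree:
    """A rooted, time-calibrated tree wrapping a :class:`dendropy.Tree`.

    Validates on construction: unique tip labels, branch lengths present and
    non-negative on every non-root edge. Polytomies are tolerated here but
    rejected by covariance construction (:func:`vcv_matrix`).
    """

    def __init__(self, tree: dendropy.Tree):
        self._tree = tree
        self._tree.is_rooted = True
        self._validate()
        self._index_ages()

    # -- construction ------------------------------------------------------

    @classmethod
    def read(cls, path: str | Path, schema: str = "newick") -> "TimeTree":
        """Read a tree from a Newick or NEXUS file.

        NEXUS TREES blocks with TRANSLATE tables are handled; square-bracket
        comments are ignored (dendropy semantics).
        """
        try:
            tree = dendropy.Tree.get(
                path=str(path), schema=schema, preserve_underscores=True
            )
        except Exception as exc:
            raise TreeError(f"cannot parse {schema} tree {path}: {exc}") from exc
        out = cls(tree)
        logger.info(
            "read %s tree %s: %d tips, depth %.6g Myr",
            schema, path, out.n_tips, out.depth,
        )
        return out

    @classmethod
    def from_string(cls, data: str, schema: str = "newick") -> "TimeTree":
        try:
            tree = dendropy.Tree.get(
                data=data, schema=schema, preserve_underscores=True
            )
        except Exception as exc:
            raise TreeError(f"cannot parse {schema} tree: {exc}") from exc
        return cls(tree)

    def write(self, path: str | Path, schema: str = "newick") -> None:
        self._tree.write(
            path=str(path), schema=schema, suppress_rooting=(schema == "newick")
        )

    def as_string(self, schema: str = "newick") -> str:
        return self._tree.as_string(
            schema=schema, suppress_rooting=(schema == "newick")
        )

    # -- validation and indexing ------------------------------------------

    def _validate(self) -> None:
        labels = [leaf.taxon.label for leaf in self._tree.leaf_node_iter()]
        dupes = {l for l in labels if labels.count(l) > 1}
        if dupes:
            raise TreeError(f"duplicate tip labels: {sorted(dupes)}")
        for node in self._tree.preorder_node_iter():
            if node.parent_node is None:
                continue
            if node.edge.length is None:
                raise TreeError(
                    "missing branch length on edge above "
                    f"{_node_name(node)}"
                )
            if node.edge.length < 0:
                raise TreeError(
                    f"negative branch length ({node.edge.length}) above "
                    f"{_node_name(node)}"
                )

    def _index_ages(self) -> None:
        # root distance per node; present = deepest tip
        self._root_dist: dict[dendropy.Node, float] = {}
        for node in self._tree.preorder_node_iter():
            if node.parent_node is None:
                self._root_dist[node] = 0.0
            else:
                self._root_dist[node] = (
                    self._root_dist[node.parent_node] + node.edge.length
                )
        tip_depths = [
            self._root_dist[leaf] for leaf in self._tree.leaf_node_iter()
        ]
        self._depth = max(tip_depths)
        if self._depth > 0:
            spread = (max(tip_depths) - min(tip_depths)) / self._depth
            self._ultrametric = spread <= ULTRAMETRIC_RTOL
            if not self._ultrametric:
                logger.warning(
                    "tree is not ultrametric: tip depth spread is %.3g of "
                    "depth (tolerance %.0e); ages measured from deepest tip",
                    spread, ULTRAMETRIC_RTOL,
                )
        else:
            self._ultrametric = True

    # -- basic queries -----------------------------------------------------

    @property
    def dendropy_tree(self) -> dendropy.Tree:
        return self._tree

    @property
    def tip_labels(self) -> tuple[str, ...]:
        return tuple(
            leaf.taxon.label for leaf in self._tree.leaf_node_iter()
        )

    @property
    def n_tips(self) -> int:
        return len(self.tip_labels)

    @property
    def depth(self) -> float:
        """Root-to-deepest-tip path length, Myr."""
        return self._depth

    @property
    def is_ultrametric(self) -> bool:
        return self._ultrametric

    @property
    def is_binary(self) -> bool:
        return all(
            len(n.child_nodes()) == 2
            for n in self._tree.preorder_internal_node_iter()
        )

    def node_age(self, node: dendropy.Node) -> float:
        """Age of a node, Myr before present (present = deepest tip)."""
        return self._depth - self._root_dist[node]

    def mrca(self, tip_labels: Iterable[str]) -> dendropy.Node:
        labels = list(tip_labels)
        missing = set(labels) - set(self.tip_labels)
        if missing:
            raise TreeError(f"tips not in tree: {sorted(missing)}")
        return self._tree.mrca(taxon_labels=labels)

    def leaf_labels_under(self, node: dendropy.Node) -> set[str]:
        return {leaf.taxon.label for leaf in node.leaf_iter()}


def _node_name(node: dendropy.Node) -> str:
    if node.is_leaf() and node.taxon is not None:
        return f"tip '{node.taxon.label}'"
    tips = sorted(l.taxon.label for l in node.leaf_iter())
    head = ",".join(tips[:3]) + ("..." if len(tips) > 3 else "")
    return f"internal node ({head})"


# ---------------------------------------------------------------------------
# stem / crown ages
# ---------------------------------------------------------------------------

def stem_age(tree: TimeTree, tip_set: Iterable[str],
             clade_id: str | None = None) -> CladeAgeRecord:
    """Stem (and crown) age of the clade spanned by ``tip_set``.

    The stem age is the time back to the start of the clade's stem branch,
    i.e. the clade's split from its sister lineage: MRCA age plus the stem
    branch length. The crown age (MRCA age) is reported for clades with at
    least two tips.

    Raises :class:`TreeError` if ``tip_set`` is not monophyletic (listing the
    intruding tips) or if the clade is the whole tree (no stem branch).
    """
    tips = sorted(set(tip_set))
    if not tips:
        raise TreeError("empty tip set")
    if len(tips) == 1:
        leaf = next(
            l for l in tree.dendropy_tree.leaf_node_iter()
            if l.taxon.label == tips[0]
        ) if tips[0] in tree.tip_labels else None
        if leaf is None:
            raise TreeError(f"tips not in tree: {tips}")
        node = leaf
    else:
        node = tree.mrca(tips)
        spanned = tree.leaf_labels_under(node)
        intruders = spanned - set(tips)
        if intruders:
            raise TreeError(
                f"tip set {tips} is not monophyletic; MRCA also spans "
                f"{sorted(intruders)}"
            )
    if node.parent_node is None:
        raise TreeError("clade spans the whole tree: no stem branch")
    stem = tree.node_age(node) + node.edge.length
    crown = tree.node_age(node) if len(tips) >= 2 else None
    return CladeAgeRecord(
        clade_id=clade_id or "+".join(tips), stem_age=stem, crown_age=crown
    )


# ---------------------------------------------------------------------------
# pruning to one exemplar per clade
# ---------------------------------------------------------------------------

def prune_to_exemplars(
    tree: TimeTree, clade_map: Mapping[str, Iterable[str]]
) -> TimeTree:
    """Reduce the tree to one tip per clade, relabelled by clade id.

    For each clade the lexicographically first member tip is retained (any
    member gives the same stem age on an ultrametric tree; the first is kept
    for determinism). Tips not covered by ``clade_map`` are retained under
    their own label. Collapsed unifurcations have their branch lengths
    summed, so all pairwise tip path lengths are preserved exactly.
    """
    assignment: dict[str, str] = {}
    for clade_id, tips in clade_map.items():
        for t in tips:
            if t in assignment:
                raise TreeError(
                    f"clades overlap: tip '{t}' in both "
                    f"'{assignment[t]}' and '{clade_id}'"
                )
            assignment[t] = clade_id
    missing = set(assignment) - set(tree.tip_labels)
    if missing:
        raise TreeError(f"clade_map tips not in tree: {sorted(missing)}")

    exemplars: dict[str, str] = {}  # retained tip label -> new label
    for clade_id, tips in clade_map.items():
        tips = sorted(tips)
        if not tips:
            raise TreeError(f"clade '{clade_id}' has no tips")
        exemplars[tips[0]] = clade_id
    for t in tree.tip_labels:
        if t not in assignment:
            exemplars[t] = t

    sub = tree.dendropy_tree.extract_tree_with_taxa_labels(
        labels=list(exemplars)
    )
    # extracted trees share Taxon objects with the source; move the subtree
    # onto a fresh namespace before relabelling so the input tree is untouched
    tns = dendropy.TaxonNamespace()
    for leaf in sub.leaf_node_iter():
        leaf.taxon = tns.new_taxon(label=exemplars[leaf.taxon.label])
    sub.taxon_namespace = tns
    return TimeTree(sub)


def restrict_to_tips(tree: TimeTree, tip_labels: Iterable[str]) -> TimeTree:
    """Induced subtree on the given tips (path lengths preserved)."""
    labels = sorted(set(tip_labels))
    missing = set(labels) - set(tree.tip_labels)
    if missing:
        raise TreeError(f"tips not in tree: {sorted(missing)}")
    sub = tree.dendropy_tree.extract_tree_with_taxa_labels(labels=labels)
    tns = dendropy.TaxonNamespace()
    for leaf in sub.leaf_node_iter():
        leaf.taxon = tns.new_taxon(label=leaf.taxon.label)
    sub.taxon_namespace = tns
    return TimeTree(sub)


def read_clade_map(path: str | Path) -> dict[str, set[str]]:
    """Read a two-column delimited (whitespace or tab) tip->clade table."""
    clades: dict[str, set[str]] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t") if "\t" in line else line.split()
        if len(parts) != 2:
            raise TreeError(f"clade map line not two columns: {line!r}")
        tip, clade = parts
        clades.setdefault(clade, set()).add(tip)
    return clades


# ---------------------------------------------------------------------------
# phylogenetic covariance
# ---------------------------------------------------------------------------

def vcv_matrix(tree: TimeTree, resolve_polytomies: bool = False) -> PhyloCovariance:
    """Brownian-motion variance-covariance matrix of the tips.

    Entry (i, j) is the path length from the root to the MRCA of tips i and
    j; the diagonal holds full root-to-tip path lengths. Polytomies are
    rejected unless ``resolve_polytomies`` is set, in which case they are
    resolved arbitrarily with zero-length branches (which leaves the
    covariance unchanged) and a warning is logged.
    """
    work = tree
    if not tree.is_binary:
        if not resolve_polytomies:
            raise PolytomyError(
                "tree contains polytomies; pass resolve_polytomies=True to "
                "resolve them with zero-length branches"
            )
        t = tree.dendropy_tree.clone(depth=1)
        t.resolve_polytomies()
        for node in t.preorder_node_iter():
            if node.parent_node is not None and node.edge.length is None:
                node.edge.length = 0.0
        logger.warning("polytomies resolved arbitrarily with zero-length branches")
        work = TimeTree(t)

    dt = work.dendropy_tree
    leaves = list(dt.leaf_node_iter())
    taxa = tuple(l.taxon.label for l in leaves)
    index = {l: i for i, l in enumerate(leaves)}
    n = len(leaves)
    C = np.zeros((n, n))

    # root distance per node, then fill each tip pair at its MRCA
    rdist: dict[dendropy.Node, float] = {}
    below: dict[dendropy.Node, list[int]] = {}
    for node in dt.preorder_node_iter():
        rdist[node] = (
            0.0 if node.parent_node is None
            else rdist[node.parent_node] + node.edge.length
        )
    for node in dt.postorder_node_iter():
        if node.is_leaf():
            i = index[node]
            below[node] = [i]
            C[i, i] = rdist[node]
        else:
            kids = node.child_nodes()
            for a in range(len(kids)):
                for b in range(a + 1, len(kids)):
                    for i in below[kids[a]]:
                        for j in below[kids[b]]:
                            C[i, j] = C[j, i] = rdist[node]
            below[node] = [i for k in kids for i in below[k]]
    return PhyloCovariance(taxa=taxa, matrix=C, lambda_applied="raw")


def apply_lambda(C: PhyloCovariance, lam: float) -> PhyloCovariance:
    """Pagel's lambda transform: scale off-diagonal covariances by ``lam``.

    lambda = 0 gives a star phylogeny (diagonal matrix); lambda = 1 returns
    the matrix unchanged. The result is positive semi-definite for
    lambda in [0, 1] on ultrametric trees.
    """
    if not (0.0 <= lam <= 1.0):
        raise ValueError(f"lambda must be in [0, 1], got {lam}")
    M = C.matrix * lam
    np.fill_diagonal(M, np.diag(C.matrix))
    return PhyloCovariance(taxa=C.taxa, matrix=M, lambda_applied=lam)
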