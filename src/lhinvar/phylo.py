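"""Phylogeny handling for phylogenetic regression.

Wraps dendropy for Newick parsing and pruning, and builds the Brownian-motion
variance–covariance structure used by PGLS: V[i, j] is the shared root-to-tip
path length of tips i and j (the depth of their most recent common ancestor),
and the diagonal holds each tip's own root-to-tip depth.  Trees need not be
ultrametric; unequal depths are exactly what the fixed variance weights in
the GLS correct for.

Pagel's λ rescales the off-diagonal (shared-history) part of V, sliding the
model between a star phylogeny (λ = 0, independent tips) and pure Brownian
motion (λ = 1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import dendropy
import numpy as np

log = logging.getLogger(__name__)


@dataclass
class PhyloTree:
    """A rooted tree with branch lengths and uniquely named tips."""

    tree: dendropy.Tree

    def __post_init__(self):
        labels = self.tip_labels
        if len(set(labels)) != len(labels):
            raise ValueError("tip names are not unique")
        lengths = [e.length for e in self.tree.preorder_edge_iter()
                   if e.head_node.parent_node is not None]
        if any(l is not None and l < 0 for l in lengths):
            raise ValueError("negative branch length")
        if not any(l for l in lengths if l):
            raise ValueError("tree has no positive branch length")

    @property
    def tip_labels(self) -> list[str]:
        return [lf.taxon.label for lf in self.tree.leaf_node_iter()]

    @property
    def n_tips(self) -> int:
        return len(self.tree.leaf_nodes())

    def as_newick(self) -> str:
        return self.tree.as_string(schema="newick").strip()


def read_newick(path=None, *, data: str | None = None) -> PhyloTree:
    """Parse a Newick tree from a file path or a raw string.

    Branch lengths are required on every non-root edge; a missing trailing
    semicolon is tolerated with a warning (a common dialect).
    """
    if data is None:
        with open(path) as fh:
            data = fh.read()
    text = data.strip()
    if not text.endswith(";"):
        log.warning("newick string lacks a trailing ';'; appended")
        text += ";"
    try:
        tree = dendropy.Tree.get(
            data=text, schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises schema-specific errors
        raise ValueError(f"newick parse error: {exc}") from exc
    for edge in tree.preorder_edge_iter():
        node = edge.head_node
        if node.parent_node is None:
            continue
        if edge.length is None:
            name = node.taxon.label if node.taxon else "<internal>"
            raise ValueError(f"missing branch length on edge above {name!r}")
    return PhyloTree(tree)


def prune_to_taxa(tree: PhyloTree, taxa) -> tuple[PhyloTree, list[str]]:
    """Restrict the tree to ``taxa``; pairwise tip path lengths are kept.

    Returns the pruned tree and the sorted list of requested names absent
    from the tree.  Fewer than two retained tips is an error.
    """
    want = {str(t) for t in taxa}
    have = set(tree.tip_labels)
    keep = want & have
    dropped = sorted(want - have)
    if dropped:
        log.warning("prune: %d requested taxa not in tree", len(dropped))
    if len(keep) < 2:
        raise ValueError(f"pruning would retain {len(keep)} tip(s); need >= 2")
    sub = tree.tree.extract_tree_with_taxa_labels(
        labels=keep, suppress_unifurcations=True
    )
    return PhyloTree(sub), dropped


@dataclass
class PhyloCov:
    """Brownian-motion covariance structure over an ordered tip set."""

    taxa: list[str]
    V: np.ndarray
    depths: np.ndarray = field(default=None)

    def __post_init__(self):
        if self.depths is None:
            self.depths = np.diag(self.V).copy()
        V = self.V
        if not np.allclose(V, V.T, atol=1e-12):
            raise ValueError("covariance matrix not symmetric")
        check_psd(V)

    def restrict(self, taxa) -> "PhyloCov":
        """Sub-matrix for ``taxa`` (in the given order)."""
        pos = {t: i for i, t in enumerate(self.taxa)}
        idx = np.array([pos[t] for t in taxa])
        return PhyloCov(list(taxa), self.V[np.ix_(idx, idx)],
                        self.depths[idx].copy())


def check_psd(V: np.ndarray, rtol: float = 1e-8) -> None:
    """Raise if V is not positive semi-definite (eigenvalue tolerance)."""
    lo = np.linalg.eigvalsh(V)[0]
    if lo < -rtol * max(np.trace(V), 1.0):
        raise ValueError(f"matrix not PSD (min eigenvalue {lo:.3g})")


def bm_covariance(tree: PhyloTree, jitter_singular: bool = True) -> PhyloCov:
    """Shared root-to-tip path lengths for all tip pairs.

    A length on the root (seed) edge counts as shared history of all tips:
    trees pruned out of a larger phylogeny carry the stem back to the
    original root there, which makes pruning commute exactly with taking
    the covariance sub-block.  Polytomies are fine.  If a zero-length terminal branch makes V singular, the offending
    diagonal entries are perturbed by 1e-8 × tree depth so the GLS stays
    invertible — well below reporting precision.
    """
    t = tree.tree
    tips = list(t.leaf_node_iter())
    labels = [lf.taxon.label for lf in tips]
    index = {id(lf): i for i, lf in enumerate(tips)}
    n = len(tips)
    V = np.zeros((n, n))

    depth: dict[int, float] = {}
    for node in t.preorder_node_iter():
        if node.parent_node is None:
            depth[id(node)] = node.edge.length or 0.0
        else:
            depth[id(node)] = depth[id(node.parent_node)] + (node.edge.length or 0.0)

    # postorder: pairs of tips split across children of a node share depth(node)
    tipsets: dict[int, list[int]] = {}
    for node in t.postorder_node_iter():
        if node.is_leaf():
            i = index[id(node)]
            V[i, i] = depth[id(node)]
            tipsets[id(node)] = [i]
        else:
            groups = [tipsets.pop(id(c)) for c in node.child_nodes()]
            d = depth[id(node)]
            for gi in range(len(groups)):
                for gj in range(gi + 1, len(groups)):
                    ii = np.array(groups[gi])
                    jj = np.array(groups[gj])
                    V[np.ix_(ii, jj)] = d
                    V[np.ix_(jj, ii)] = d
            tipsets[id(node)] = [i for g in groups for i in g]

    if jitter_singular:
        maxd = float(np.max(np.diag(V)))
        zero_term = np.array([not (lf.edge.length or 0.0) for lf in tips])
        if zero_term.any() and maxd > 0:
            # zero-length terminal branch duplicates its parent's row
            V[np.diag_indices(n)] += np.where(zero_term, 1e-8 * maxd, 0.0)
            log.debug("%d zero-length terminal branch(es) perturbed by "
                      "1e-8 x tree depth", int(zero_term.sum()))
    return PhyloCov(labels, V)


def pagel_transform(cov: PhyloCov, lam: float) -> PhyloCov:
    """Multiply off-diagonal covariances by λ, keeping diagonals.

    λ = 0 removes the phylogeny (independent tips), λ = 1 is unchanged
    Brownian motion.  λ may exceed 1 up to the PSD limit; a non-PSD result
    is an error.
    """
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    V = cov.V * lam
    np.fill_diagonal(V, np.diag(cov.V))
    check_psd(V)  # raises for lambda beyond the PSD bound
    return PhyloCov(list(cov.taxa), V, cov.depths.copy())


def to_correlation(cov: PhyloCov) -> np.ndarray:
    """Correlation matrix R with R_ij = V_ij / sqrt(V_ii V_jj)."""
    d = np.sqrt(np.diag(cov.V))
    if np.any(d <= 0):
        raise ValueError("zero tip depth; cannot form correlation matrix")
    return cov.V / np.outer(d, d)
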