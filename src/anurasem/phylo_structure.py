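"""Phylogeny-weighted composition (P matrix), PCPS, and PUT insertion.

The P matrix smooths a presence/absence community matrix by pairwise
phylogenetic similarity among species, so that each site's row describes
how its occurrences are spread across the phylogeny.  A principal
coordinates analysis of between-site dissimilarities of P rows (PCPS)
yields orthogonal axes of phylogenetic composition; the first axis
captures the deepest splits in the tree.

Phylogenetically uncertain taxa (PUTs) absent from the reference tree are
inserted at their most derived consensus clade (MDCC): the new tip is
attached at the crown node of the named clade with a branch equal to the
clade's height, keeping the clade ultrametric.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from anurasem.data_io import CommunityMatrix

EIG_TOL = 1e-10  # relative cutoff separating "positive" from numerically-zero eigenvalues


@dataclass
class PcoaResult:
    """Principal-coordinates decomposition of a dissimilarity matrix.

    ``axis_scores`` has one column per retained positive eigenvalue,
    scaled by sqrt(eigenvalue); ``fraction_of_variation`` divides each
    positive eigenvalue by the sum of positive eigenvalues (negative
    eigenvalues are reported but excluded from the denominator).
    """

    eigenvalues: np.ndarray  # all eigenvalues, descending
    axis_scores: np.ndarray  # objects × retained positive axes
    fraction_of_variation: np.ndarray
    negative_eigenvalues: np.ndarray

    @property
    def n_axes(self) -> int:
        return self.axis_scores.shape[1]

    def cumulative_fraction(self) -> np.ndarray:
        return np.cumsum(self.fraction_of_variation)

    def axis_frame(self, ids: list[str], prefix: str = "axis") -> pd.DataFrame:
        return pd.DataFrame(
            self.axis_scores,
            index=pd.Index(ids, name="id"),
            columns=[f"{prefix}{i + 1}" for i in range(self.n_axes)],
        )

    def eigen_frame(self) -> pd.DataFrame:
        lam = self.eigenvalues
        frac = np.full(lam.size, np.nan)
        frac[: self.fraction_of_variation.size] = self.fraction_of_variation
        return pd.DataFrame({"eigenvalue": lam, "fraction_of_variation": frac})


def pcoa(dissimilarity: np.ndarray) -> PcoaResult:
    """Classical (Gower) principal coordinates analysis.

    Double-centers the squared dissimilarities, B = −½·J·D²·J, and
    eigendecomposes B.  No Cailliez/Lingoes correction is applied:
    negative eigenvalues are reported as-is and excluded from the
    fraction-of-variation denominator, matching the convention of the
    standard PCPS implementation.
    """
    d = np.asarray(dissimilarity, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("dissimilarity must be a square matrix")
    n = d.shape[0]
    d2 = d**2
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ d2 @ j
    lam, vec = np.linalg.eigh((b + b.T) / 2)
    order = np.argsort(lam)[::-1]
    lam, vec = lam[order], vec[:, order]
    tol = EIG_TOL * max(abs(lam[0]), 1.0)
    pos = lam > tol
    if not pos.any():
        raise ValueError("no positive eigenvalues: all objects coincide")
    scores = vec[:, pos] * np.sqrt(lam[pos])
    frac = lam[pos] / lam[pos].sum()
    return PcoaResult(
        eigenvalues=lam,
        axis_scores=scores,
        fraction_of_variation=frac,
        negative_eigenvalues=lam[lam < -tol],
    )


# ---------------------------------------------------------------------------
# trees


def tip_labels(tree: dendropy.Tree) -> list[str]:
    return [leaf.taxon.label for leaf in tree.leaf_node_iter()]


def shared_branch_length_matrix(tree: dendropy.Tree) -> pd.DataFrame:
    """C matrix: root-to-MRCA depth for each tip pair (tip depth on diagonal).

    Built in one postorder sweep: leaves under different children of a
    node have that node as their MRCA.
    """
    tree.calc_node_root_distances(return_leaf_distances_only=False)
    leaves = sorted(tree.leaf_node_iter(), key=lambda n: n.taxon.label)
    labels = [n.taxon.label for n in leaves]
    idx = {id(n): i for i, n in enumerate(leaves)}
    n = len(leaves)
    c = np.zeros((n, n))
    for i, leaf in enumerate(leaves):
        c[i, i] = leaf.root_distance
    leafsets: dict[int, list[int]] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            leafsets[id(node)] = [idx[id(node)]]
            continue
        groups = [leafsets.pop(id(ch)) for ch in node.child_nodes()]
        depth = node.root_distance
        for gi in range(len(groups)):
            for gj in range(gi + 1, len(groups)):
                for a in groups[gi]:
                    c[a, groups[gj]] = depth
                    c[np.array(groups[gj]), a] = depth
        leafsets[id(node)] = [x for g in groups for x in g]
    return pd.DataFrame(c, index=labels, columns=labels)


def cophenetic_matrix(tree: dendropy.Tree) -> pd.DataFrame:
    """Patristic (branch-length path) distances among all tips.

    d(i, j) = depth(i) + depth(j) − 2·depth(mrca(i, j)).
    """
    c = shared_branch_length_matrix(tree)
    depth = np.diag(c.to_numpy())
    d = depth[:, None] + depth[None, :] - 2 * c.to_numpy()
    np.fill_diagonal(d, 0.0)
    return pd.DataFrame(d, index=c.index, columns=c.columns)


def phylo_weighted_composition(
    cm: CommunityMatrix, tree: dendropy.Tree, coph: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Phylogeny-weighted species composition (P matrix).

    Species similarity S = 1 − D/max(D) with unit diagonal; each site row
    is incidence × S renormalized to sum to 1.
    """
    if coph is None:
        coph = cophenetic_matrix(tree)
    coph = coph.loc[cm.species_ids, cm.species_ids]
    d = coph.to_numpy()
    dmax = d.max()
    if dmax <= 0:
        raise ValueError("degenerate tree: all patristic distances are zero")
    s = 1.0 - d / dmax
    raw = cm.incidence.to_numpy(dtype=float) @ s
    p = raw / raw.sum(axis=1, keepdims=True)
    return pd.DataFrame(p, index=cm.incidence.index, columns=cm.incidence.columns)


def pcps(p_matrix: pd.DataFrame) -> PcoaResult:
    """Principal coordinates of phylogenetic structure.

    Square-root Bray–Curtis dissimilarities among P-matrix rows followed
    by classical PCoA.  Requires at least 3 sites.
    """
    if p_matrix.shape[0] < 3:
        raise ValueError("PCPS requires at least 3 sites")
    d = np.sqrt(squareform(pdist(p_matrix.to_numpy(), metric="braycurtis")))
    return pcoa(d)


def _clade_height(node: dendropy.Node) -> float:
    """Mean root-to-tip distance within the clade (exact if ultrametric)."""
    depths = []
    for leaf in node.leaf_iter():
        dist, cur = 0.0, leaf
        while cur is not node:
            dist += cur.edge.length or 0.0
            cur = cur.parent_node
        depths.append(dist)
    return float(np.mean(depths))


def add_taxon_at_mdcc(
    tree: dendropy.Tree, taxon: str, mdcc_tips: list[str]
) -> dendropy.Tree:
    """Attach ``taxon`` at the crown node of the clade spanned by ``mdcc_tips``.

    The named tip set must be exactly the leaf set of its most recent
    common ancestor (monophyly); the new branch length equals the clade
    height so the insertion is ultrametric within the clade.  Existing
    path lengths are untouched, so pruning the new tip recovers the
    original tree exactly.
    """
    present = {t.label for t in tree.taxon_namespace}
    if taxon in present:
        raise ValueError(f"taxon {taxon!r} already present in tree")
    missing = [t for t in mdcc_tips if t not in present]
    if missing:
        raise ValueError(f"MDCC tips not in tree: {missing}")
    tree = tree.clone(depth=1)
    mrca = tree.mrca(taxon_labels=mdcc_tips)
    clade_leaves = {leaf.taxon.label for leaf in mrca.leaf_iter()}
    extra = clade_leaves - set(mdcc_tips)
    if extra:
        raise ValueError(
            f"tip set {sorted(mdcc_tips)} is not monophyletic: its MRCA also "
            f"contains {sorted(extra)}"
        )
    height = _clade_height(mrca)
    new_taxon = tree.taxon_namespace.new_taxon(label=taxon)
    mrca.new_child(taxon=new_taxon, edge_length=height)
    tree.update_bipartitions(suppress_unifurcations=False)
    return tree
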