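"""Functional-trait space: PVR, BM trait imputation, dendrogram FD, SES.FD.

Trait variation among related species partly reflects shared ancestry.
Phylogenetic eigenvector regression (PVR) ordinates the species
cophenetic-distance matrix and regresses traits on the leading axes; the
residuals carry the phylogeny-free trait signal.  Missing continuous
traits are imputed under a multivariate Brownian-motion model (traits
co-evolving along the tree) by EM maximum likelihood.  Functional
diversity per site is the total branch length of the UPGMA functional
dendrogram spanning the site's species (root-inclusive, after Petchey &
Gaston), standardized against a tip-label-shuffling null model.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from anurasem.data_io import (
    CATEGORICAL_TRAITS,
    CONTINUOUS_TRAITS,
    CommunityMatrix,
    TraitTable,
)
from anurasem.null_models import SesResult, ses_from_null
from anurasem.phylo_structure import (
    cophenetic_matrix,
    pcoa,
    shared_branch_length_matrix,
)

__all__ = [
    "pvr_eigenvectors",
    "shared_branch_length_matrix",
    "impute_traits_bm",
    "trait_feature_matrix",
    "trait_pvr_residuals",
    "Dendrogram",
    "functional_dendrogram",
    "fd_petchey_gaston",
    "ses_fd",
]

# ---------------------------------------------------------------------------
# phylogenetic eigenvector regression


def pvr_eigenvectors(
    tree: dendropy.Tree,
    variance_fraction: float = 0.95,
    coph: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Leading PCoA axes of the cophenetic-distance matrix.

    Returns the smallest number of axes whose cumulative share of the
    positive eigenvalues reaches ``variance_fraction``.
    """
    if not 0 < variance_fraction <= 1:
        raise ValueError("variance_fraction must be in (0, 1]")
    if coph is None:
        coph = cophenetic_matrix(tree)
    res = pcoa(coph.to_numpy())
    cum = res.cumulative_fraction()
    k = int(np.searchsorted(cum, variance_fraction - 1e-12) + 1)
    k = min(k, res.n_axes)
    return pd.DataFrame(
        res.axis_scores[:, :k],
        index=pd.Index(coph.index, name="species"),
        columns=[f"pvr{i + 1}" for i in range(k)],
    )


# ---------------------------------------------------------------------------
# Brownian-motion imputation


def impute_traits_bm(
    tree: dendropy.Tree,
    tt: TraitTable,
    tol: float = 1e-6,
    max_iter: int = 500,
) -> pd.DataFrame:
    """Fill missing continuous traits by multivariate-BM maximum likelihood.

    Traits evolve as correlated Brownian motions along the tree, so the
    stacked trait vector is multivariate normal with covariance C ⊗ R
    (C = shared branch lengths, R = evolutionary trait covariance).  Root
    means and R are estimated by EM over the missing entries; missing
    values are replaced by their conditional expectations.  Observed
    entries are returned unchanged; categorical traits are never imputed.
    """
    cols = [c for c in CONTINUOUS_TRAITS if c in tt.data.columns]
    out = tt.data.copy()
    if not cols:
        return out
    cmat = shared_branch_length_matrix(tree)
    species = [s for s in tt.species_ids if s in cmat.index]
    if set(tt.species_ids) - set(species):
        raise ValueError(
            f"species missing from tree: {sorted(set(tt.species_ids) - set(species))}"
        )
    c = cmat.loc[species, species].to_numpy()
    y = tt.data.loc[species, cols].to_numpy(dtype=float)
    n, p = y.shape
    miss = np.isnan(y)
    if (~miss).sum(axis=0).min() < 1:
        raise ValueError("each continuous trait needs at least one observed value")
    if not miss.any():
        return out

    try:
        np.linalg.cholesky(c + 1e-12 * np.eye(n))
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            "shared-branch-length matrix is not positive definite (duplicate "
            "zero-length tips?); resolve or jitter the tree before imputing"
        ) from exc

    cinv = np.linalg.inv(c)
    ones = np.ones(n)
    w = cinv @ ones / (ones @ cinv @ ones)  # GLS mean weights

    # init from observed marginals
    mu = np.nanmean(y, axis=0)
    complete = ~miss.any(axis=1)
    if complete.sum() >= p + 2:
        yc = y[complete] - mu
        r = yc.T @ yc / complete.sum()
    else:
        r = np.diag(np.nanvar(y, axis=0))
    r += 1e-8 * np.eye(p)

    flat_miss = miss.ravel()  # species-major stacking: index i*p + a
    obs_idx = np.where(~flat_miss)[0]
    mis_idx = np.where(flat_miss)[0]
    yflat = y.ravel()
    ll_prev = -np.inf
    for _ in range(max_iter):
        sigma = np.kron(c, r)
        m = np.tile(mu, n)
        soo = sigma[np.ix_(obs_idx, obs_idx)]
        som = sigma[np.ix_(obs_idx, mis_idx)]
        smm = sigma[np.ix_(mis_idx, mis_idx)]
        lo = np.linalg.cholesky(soo + 1e-10 * np.eye(obs_idx.size))
        resid_o = yflat[obs_idx] - m[obs_idx]
        alpha = np.linalg.solve(lo.T, np.linalg.solve(lo, resid_o))
        cond_mean = m[mis_idx] + som.T @ alpha
        half = np.linalg.solve(lo, som)
        cond_cov = smm - half.T @ half

        ll = -0.5 * (
            resid_o @ alpha
            + 2 * np.log(np.diag(lo)).sum()
            + obs_idx.size * np.log(2 * np.pi)
        )

        yhat = yflat.copy()
        yhat[mis_idx] = cond_mean
        yh = yhat.reshape(n, p)
        mu = w @ yh
        yc = yh - mu
        corr = np.zeros((p, p))
        # E[Yᵀ C⁻¹ Y] correction from conditional covariance of missing cells
        mi_sp, mi_tr = mis_idx // p, mis_idx % p
        cinv_blk = cinv[np.ix_(mi_sp, mi_sp)] * cond_cov
        for a in range(p):
            sel_a = mi_tr == a
            for b in range(p):
                corr[a, b] = cinv_blk[np.ix_(sel_a, mi_tr == b)].sum()
        r = (yc.T @ cinv @ yc + corr) / n
        r = (r + r.T) / 2 + 1e-10 * np.eye(p)

        if ll - ll_prev < tol * (abs(ll_prev) + 1.0) and np.isfinite(ll_prev):
            break
        ll_prev = ll
    else:
        raise RuntimeError(
            f"BM imputation EM did not converge in {max_iter} iterations "
            f"(last log-likelihood {ll:.6g})"
        )

    filled = pd.DataFrame(yh, index=species, columns=cols)
    for col in cols:
        out.loc[species, col] = out.loc[species, col].fillna(filled[col])
    return out


# ---------------------------------------------------------------------------
# feature matrix and PVR residuals


def trait_feature_matrix(
    traits: pd.DataFrame, include_development: bool = True
) -> pd.DataFrame:
    """Numeric species × feature matrix for functional distances.

    Continuous traits are z-scored; categorical traits are one-hot
    encoded (already unit range).  ``include_development=False`` drops
    the development-type trait, for checking that FD results are not
    driven circularly by the response trait.
    """
    parts = []
    for col in CONTINUOUS_TRAITS:
        if col in traits.columns:
            v = traits[col].astype(float)
            parts.append(((v - v.mean()) / v.std(ddof=1)).rename(col))
    for col in CATEGORICAL_TRAITS:
        if col not in traits.columns:
            continue
        if col == "development_type" and not include_development:
            continue
        dummies = pd.get_dummies(traits[col], prefix=col).astype(float)
        parts.append(dummies)
    feats = pd.concat(parts, axis=1)
    if feats.isna().any().any():
        raise ValueError("feature matrix contains NaN; impute continuous traits first")
    return feats


def trait_pvr_residuals(features: pd.DataFrame, pvr_axes: pd.DataFrame) -> pd.DataFrame:
    """Residuals of each feature on the retained phylogenetic eigenvectors."""
    if set(features.index) != set(pvr_axes.index):
        raise ValueError("features and PVR axes cover different species")
    x = pvr_axes.loc[features.index].to_numpy()
    n, k = x.shape
    if k + 1 >= n:
        raise ValueError(f"saturated regression: {k} eigenvectors for {n} species")
    design = np.column_stack([np.ones(n), x])
    y = features.to_numpy(dtype=float)
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta
    return pd.DataFrame(resid, index=features.index, columns=features.columns)


# ---------------------------------------------------------------------------
# functional dendrogram and FD


@dataclass
class Dendrogram:
    """UPGMA tree over species with branch lengths in trait-distance units.

    Internally the 2n−2 edges of the rooted merge tree are stored with a
    tips × edges descent indicator, so the Petchey–Gaston FD of any
    species set is a single sparse sum.  Cophenetic distance between two
    tips equals their merge height (node depths are merge height / 2).
    """

    labels: list[str]
    linkage: np.ndarray
    edge_lengths: np.ndarray  # one per non-root node
    below: np.ndarray  # tips × edges bool: tip descends from edge's child node

    @property
    def n_tips(self) -> int:
        return len(self.labels)

    @property
    def total_length(self) -> float:
        return float(self.edge_lengths.sum())

    def cophenetic(self) -> pd.DataFrame:
        from scipy.spatial.distance import squareform

        d = squareform(hierarchy.cophenet(self.linkage))
        return pd.DataFrame(d, index=self.labels, columns=self.labels)

    def to_newick(self) -> str:
        tree = hierarchy.to_tree(self.linkage)

        def rec(node, parent_height):
            length = (parent_height - node.dist) / 2
            if node.is_leaf():
                return f"{self.labels[node.id]}:{length:.10g}"
            inner = ",".join(rec(ch, node.dist) for ch in (node.left, node.right))
            return f"({inner}):{length:.10g}"

        root = tree
        inner = ",".join(rec(ch, root.dist) for ch in (root.left, root.right))
        return f"({inner}):0;"


def functional_dendrogram(
    features: pd.DataFrame, distance: str = "euclidean", linkage: str = "upgma"
) -> Dendrogram:
    """Cluster species into an ultrametric functional dendrogram (UPGMA)."""
    if features.shape[0] < 2:
        raise ValueError("need at least 2 species")
    if features.isna().any().any():
        raise ValueError("features contain NaN; impute first")
    method = {"upgma": "average"}.get(linkage, linkage)
    z = hierarchy.linkage(pdist(features.to_numpy(), metric=distance), method=method)
    n = features.shape[0]
    heights = np.concatenate([np.zeros(n), z[:, 2]])
    parent = np.full(2 * n - 1, -1)
    for k in range(n - 1):
        parent[int(z[k, 0])] = n + k
        parent[int(z[k, 1])] = n + k
    nodes = np.arange(2 * n - 2)  # all but root
    edge_lengths = (heights[parent[nodes]] - heights[nodes]) / 2
    if (edge_lengths < -1e-8).any():
        raise ValueError("non-monotone merge heights; dendrogram not ultrametric")
    edge_lengths = np.clip(edge_lengths, 0, None)
    below = np.zeros((n, 2 * n - 2), dtype=bool)
    below[np.arange(n), np.arange(n)] = True
    for k in range(n - 2):  # accumulate tip sets bottom-up (root excluded)
        node = n + k
        left, right = int(z[k, 0]), int(z[k, 1])
        below[:, node] = below[:, left] | below[:, right]
    return Dendrogram(
        labels=list(features.index),
        linkage=z,
        edge_lengths=edge_lengths,
        below=below,
    )


def _site_edge_presence(dend: Dendrogram, cm: CommunityMatrix, row_order: np.ndarray):
    inc = cm.incidence.to_numpy(dtype=np.float32)
    sub = dend.below[row_order].astype(np.float32)
    return (inc @ sub) > 0


def _tip_order(dend: Dendrogram, cm: CommunityMatrix) -> np.ndarray:
    pos = {lab: i for i, lab in enumerate(dend.labels)}
    missing = [s for s in cm.species_ids if s not in pos]
    if missing:
        raise ValueError(f"species absent from dendrogram: {missing}")
    return np.array([pos[s] for s in cm.species_ids])


def fd_petchey_gaston(dend: Dendrogram, cm: CommunityMatrix) -> pd.DataFrame:
    """Root-inclusive functional diversity: summed branch lengths per site.

    fd(site) is the total length of dendrogram edges on the union of
    tip-to-root paths over the site's species; a single-species site
    scores its tip-to-root path length, and the full pool scores the
    whole tree length.
    """
    if (cm.incidence.sum(axis=1) < 1).any():
        raise ValueError("empty site")
    order = _tip_order(dend, cm)
    presence = _site_edge_presence(dend, cm, order)
    fd = presence @ dend.edge_lengths
    return pd.DataFrame(
        {"fd": fd, "richness": cm.incidence.sum(axis=1).to_numpy()},
        index=cm.incidence.index,
    )


def ses_fd(
    dend: Dendrogram, cm: CommunityMatrix, n_null: int = 999, seed: int = 0
) -> SesResult:
    """SES of FD under tip-label permutation (taxa-labels null).

    Each replicate permutes species across all dendrogram tips and
    recomputes every site's FD.  Negative SES = functional clustering,
    positive = overdispersion; sites whose FD is invariant under
    relabelling (e.g. the full pool) are flagged undefined.
    """
    if n_null < 1:
        raise ValueError("n_null must be >= 1")
    order = _tip_order(dend, cm)
    observed = (_site_edge_presence(dend, cm, order)) @ dend.edge_lengths
    rng = np.random.default_rng(seed)
    inc = cm.incidence.to_numpy(dtype=np.float32)
    lengths = dend.edge_lengths
    null = np.empty((n_null, inc.shape[0]))
    n_tips = dend.n_tips
    for r in range(n_null):
        perm = rng.permutation(n_tips)
        sub = dend.below[perm[order]].astype(np.float32)
        null[r] = ((inc @ sub) > 0) @ lengths
    return ses_from_null(cm.site_ids, observed, null, n_null, seed)
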