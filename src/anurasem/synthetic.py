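"""Synthetic study systems with known ground truth.

Two generators back the test suite and the acceptance runs:

* a mechanistic one — birth–death phylogeny, a direct-development trait
  concentrated in a few clades, correlated Brownian-motion morphometrics
  with missing values, spatially autocorrelated environmental gradients,
  and logistic-Gaussian-niche community assembly — which reproduces the
  *qualitative* causal structure (abiotic → biotic → %DD) end to end;

* a linear-Gaussian one (``simulate_sem_dataset``) whose declared
  standardized path coefficients are exact population values, used to
  check SEM parameter recovery quantitatively.

Default parameters are the study conditions of the motivating system:
766 communities, a regional pool of 464 species of which ~10.6% (49)
develop directly in 3 concentrated lineages, and missing morphometrics
for 139/464 (head width) and 146/464 (tibia length) species.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd
from dendropy.simulate import treesim
from scipy.spatial.distance import pdist, squareform

from anurasem.data_io import CommunityMatrix, EnvTable, TraitTable
from anurasem.trait_space import shared_branch_length_matrix

#: exact-coefficient path structure used for SEM recovery; coefficients on
#: z-scored variables (see docs/methods.md for the choice of values)
DEFAULT_PATHS: dict[str, dict[str, float]] = {
    "PCPS1": {"BIO4": 0.25, "BIO12": -0.20, "ET0": 0.20, "slope": 0.15},
    "SES.FD": {"BIO4": -0.15, "BIO12": 0.20, "ET0": -0.20, "slope": 0.10},
    "%DD": {
        "BIO4": -0.305,
        "BIO12": 0.05,
        "ET0": -0.451,
        "slope": 0.10,
        "PCPS1": 0.15,
        "SES.FD": 0.231,
    },
}

EXOGENOUS = ["BIO4", "BIO12", "ET0", "slope"]

#: modest collinearity among climate gradients; slope independent
DEFAULT_EXOG_CORR = np.array(
    [
        [1.0, 0.2, 0.2, 0.0],
        [0.2, 1.0, 0.2, 0.0],
        [0.2, 0.2, 1.0, 0.0],
        [0.0, 0.0, 0.0, 1.0],
    ]
)


@dataclass
class ScenarioConfig:
    """Parameters of a synthetic study system (defaults = study conditions)."""

    n_species: int = 464
    n_sites: int = 766
    birth_rate: float = 1.0
    death_rate: float = 0.5
    dd_fraction: float = 49 / 464
    dd_clade_count: int = 3
    trait_means: tuple[float, ...] = (45.0, 15.0, 20.0)  # mm
    trait_sds: tuple[float, ...] = (12.0, 4.0, 6.0)
    trait_corr: float = 0.8
    missing_fraction: dict = field(
        default_factory=lambda: {"head_width": 139 / 464, "tibia_length": 146 / 464}
    )
    env_range: float = 3.0  # degrees, exponential GP range
    dd_env_effect: float = 1.5  # strength of the env → %DD filter at assembly
    dd_rarity: float = 2.0  # occupancy penalty keeping direct developers rare
    paths: dict = field(default_factory=lambda: DEFAULT_PATHS)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.dd_fraction < 1:
            raise ValueError("dd_fraction must be in (0, 1)")
        if self.birth_rate <= 0 or self.death_rate < 0:
            raise ValueError("rates must be positive")


# ---------------------------------------------------------------------------
# phylogeny and traits


def simulate_tree(
    n_species: int, birth_rate: float = 1.0, death_rate: float = 0.5, seed: int = 0
) -> dendropy.Tree:
    """Birth–death tree conditioned on the number of extant tips.

    Extinct lineages are pruned, so the tree is ultrametric.  Tips are
    relabelled sp0001..spNNNN; reproducible from the seed.
    """
    if n_species < 3:
        raise ValueError("need at least 3 species")
    rng = random.Random(seed)
    tree = treesim.birth_death_tree(
        birth_rate=birth_rate,
        death_rate=death_rate,
        num_extant_tips=n_species,
        rng=rng,
        repeat_until_success=True,
    )
    tree.suppress_unifurcations()  # drop the originating root branch
    tree.seed_node.edge.length = None  # no stem above the root
    # the simulator stops at the event creating the n-th tip, leaving that
    # cherry with zero-length branches; run the clock a little further
    # (uniformly on every pendant edge, preserving ultrametricity)
    depth = max(leaf.distance_from_root() for leaf in tree.leaf_node_iter())
    for leaf in tree.leaf_node_iter():
        leaf.edge.length = (leaf.edge.length or 0.0) + 1e-3 * depth
    for i, leaf in enumerate(tree.leaf_node_iter()):
        leaf.taxon.label = f"sp{i + 1:04d}"
    tree.is_rooted = True
    return tree


def assign_direct_development(
    tree: dendropy.Tree,
    dd_fraction: float = 49 / 464,
    dd_clade_count: int = 3,
    seed: int = 0,
    max_attempts: int = 500,
) -> pd.Series:
    """Mark whole clades as direct-developing, totalling ≈ dd_fraction of tips.

    Picks ``dd_clade_count`` disjoint monophyletic clades whose combined
    tip count is as close as possible to the target; errors if no
    combination lands within ±50% of it.
    """
    labels = sorted(leaf.taxon.label for leaf in tree.leaf_node_iter())
    n = len(labels)
    target = max(1, round(dd_fraction * n))
    clades = []
    for node in tree.preorder_internal_node_iter():
        tips = frozenset(leaf.taxon.label for leaf in node.leaf_iter())
        if 1 <= len(tips) <= target:
            clades.append(tips)
    rng = np.random.default_rng(seed)
    best, best_err = None, np.inf
    for _ in range(max_attempts):
        chosen: list[frozenset] = []
        used: set[str] = set()
        remaining = target
        for k in range(dd_clade_count, 0, -1):
            want = max(1, round(remaining / k))
            options = [c for c in clades if not (c & used)]
            if not options:
                break
            sizes = np.array([len(c) for c in options])
            weights = 1.0 / (1.0 + (sizes - want) ** 2)
            pick = options[rng.choice(len(options), p=weights / weights.sum())]
            chosen.append(pick)
            used |= pick
            remaining -= len(pick)
        if len(chosen) != dd_clade_count:
            continue
        err = abs(sum(len(c) for c in chosen) - target)
        if err < best_err:
            best, best_err = chosen, err
        if err == 0:
            break
    if best is None or best_err > 0.5 * target:
        raise ValueError(
            f"no {dd_clade_count}-clade combination within ±50% of {target} tips"
        )
    marked = set().union(*best)
    dev = pd.Series(
        [1 if s in marked else 0 for s in labels],
        index=pd.Index(labels, name="species"),
        name="direct",
    )
    dev.attrs["clades"] = [sorted(c) for c in best]
    dev.attrs["realized_fraction"] = len(marked) / n
    return dev


def simulate_bm_traits(
    tree: dendropy.Tree,
    means: tuple[float, ...] = (45.0, 15.0, 20.0),
    sds: tuple[float, ...] = (12.0, 4.0, 6.0),
    corr: float = 0.8,
    seed: int = 0,
) -> pd.DataFrame:
    """Correlated Brownian-motion morphometrics (mm) along the tree.

    The tip covariance is R ⊗ C with C normalized to unit depth, so the
    stated SDs are tip-level marginal SDs.  Values are floored at 0.5 mm
    (negative excursions are vanishingly rare at the default scales).
    """
    cmat = shared_branch_length_matrix(tree)
    c = cmat.to_numpy()
    c = c / c.diagonal().max()
    p = len(means)
    r = np.full((p, p), corr)
    np.fill_diagonal(r, 1.0)
    r = r * np.outer(sds, sds)
    rng = np.random.default_rng(seed)
    lc = np.linalg.cholesky(c + 1e-10 * np.eye(c.shape[0]))
    lr = np.linalg.cholesky(r)
    y = np.asarray(means) + lc @ rng.standard_normal((c.shape[0], p)) @ lr.T
    y = np.clip(y, 0.5, None)
    return pd.DataFrame(
        y, index=cmat.index, columns=["body_length", "head_width", "tibia_length"]
    )


def _bm_latent(tree: dendropy.Tree, seed: int) -> pd.Series:
    cmat = shared_branch_length_matrix(tree)
    c = cmat.to_numpy() / cmat.to_numpy().diagonal().max()
    rng = np.random.default_rng(seed)
    z = np.linalg.cholesky(c + 1e-10 * np.eye(c.shape[0])) @ rng.standard_normal(
        c.shape[0]
    )
    return pd.Series(z, index=cmat.index)


def build_trait_table(
    tree: dendropy.Tree,
    dev: pd.Series,
    morpho: pd.DataFrame,
    missing_fraction: dict | None = None,
    seed: int = 0,
) -> TraitTable:
    """Assemble a full trait table with clade-structured categorical traits.

    Direct developers get terrestrial oviposition/juvenile habitat and
    ground oviposition sites; the rest follow latent-BM thresholds so the
    categories carry phylogenetic signal.  Continuous traits are masked
    completely at random per ``missing_fraction``.
    """
    rng = np.random.default_rng(seed)
    species = list(dev.index)
    lat1 = _bm_latent(tree, seed + 11).loc[species]
    lat2 = _bm_latent(tree, seed + 12).loc[species]
    direct = dev.loc[species].astype(bool)

    ovi_type = np.where(direct | (lat1 > lat1.quantile(0.8)), "terrestrial", "aquatic")
    juv = np.where(
        direct,
        "terrestrial",
        np.where(lat2 > lat2.quantile(0.7), "semiterrestrial", "aquatic"),
    )
    site_levels = ["water", "bubble_nest", "foam_nest", "female_back", "arboreal", "carried"]
    qs = np.clip(lat2.rank(pct=True).to_numpy(), 0, 0.999)
    ovi_site = np.where(
        direct, "ground", np.asarray(site_levels)[(qs * len(site_levels)).astype(int)]
    )
    df = pd.DataFrame(
        {
            "oviposition_type": ovi_type,
            "development_type": np.where(direct, "direct", "larval"),
            "juvenile_habitat": juv,
            "oviposition_site": ovi_site,
        },
        index=pd.Index(species, name="species"),
    ).join(morpho.loc[species])
    for col, frac in (missing_fraction or {}).items():
        n_mask = round(frac * len(species))
        idx = rng.choice(len(species), size=n_mask, replace=False)
        df.iloc[idx, df.columns.get_loc(col)] = np.nan
    return TraitTable(data=df)


# ---------------------------------------------------------------------------
# environment


def _gp_samples(coords: np.ndarray, rho: float, n_vars: int, rng) -> np.ndarray:
    d = squareform(pdist(coords))
    v = np.exp(-d / rho) + 1e-8 * np.eye(coords.shape[0])
    lo = np.linalg.cholesky(v)
    return lo @ rng.standard_normal((coords.shape[0], n_vars))


def simulate_env(
    n_sites: int,
    env_range: float = 3.0,
    seed: int = 0,
    exog_corr: np.ndarray = DEFAULT_EXOG_CORR,
    extent: tuple[float, float, float, float] = (-55.0, -35.0, -30.0, -5.0),
) -> tuple[EnvTable, pd.DataFrame]:
    """Spatially autocorrelated environmental gradients on random coordinates.

    Each variable is a unit-variance Gaussian process with exponential
    covariance exp(−d/range) over planar lon/lat distances, mixed to the
    requested cross-correlation, then put on realistic raw scales.
    """
    if n_sites < 10:
        raise ValueError("need at least 10 sites")
    rng = np.random.default_rng(seed)
    lon0, lon1, lat0, lat1 = extent
    coords = np.column_stack(
        [rng.uniform(lon0, lon1, n_sites), rng.uniform(lat0, lat1, n_sites)]
    )
    z = _gp_samples(coords, env_range, 4, rng) @ np.linalg.cholesky(exog_corr).T
    sites = [f"site{i + 1:04d}" for i in range(n_sites)]
    data = pd.DataFrame(
        {
            "BIO4": 250 + 80 * z[:, 0],
            "BIO12": 1400 + 500 * z[:, 1],
            "ET0": 1200 + 250 * z[:, 2],
            "slope": 8 + 5 * z[:, 3],
        },
        index=pd.Index(sites, name="site"),
    )
    coords_df = pd.DataFrame(
        coords, columns=["longitude", "latitude"], index=data.index
    )
    return EnvTable(data=data, standardized=False), coords_df


# ---------------------------------------------------------------------------
# community assembly (mechanistic)


def assemble_communities(
    tree: dendropy.Tree,
    dev: pd.Series,
    env: EnvTable,
    coords: pd.DataFrame,
    dd_env_effect: float = 1.5,
    dd_rarity: float = 2.0,
    mean_richness: float = 13.5,
    seed: int = 0,
    max_redraws: int = 100,
) -> CommunityMatrix:
    """Assemble communities from a logistic Gaussian-niche occurrence model.

    Species niche optima follow Brownian motion on the tree along two
    latent gradients tied to the climate variables, so composition is
    clade-structured (PCPS axes are meaningful).  Direct developers get
    an extra logit term −dd_env_effect·(z_ET0 + z_BIO4 − z_slope)/√3,
    implanting the abiotic → %DD causal link.  Sites ending with fewer
    than two species are redrawn.
    """
    species = sorted(dev.index)
    envz = (env.data - env.data.mean()) / env.data.std(ddof=1)
    g1 = (envz["BIO4"] + envz["ET0"]).to_numpy() / np.sqrt(2)
    g2 = (envz["BIO12"] + envz["slope"]).to_numpy() / np.sqrt(2)
    opt1 = _bm_latent(tree, seed + 21).loc[species].to_numpy() * 1.2
    opt2 = _bm_latent(tree, seed + 22).loc[species].to_numpy() * 1.2
    direct = dev.loc[species].to_numpy().astype(float)
    filt = (
        -(envz["ET0"] + envz["BIO4"] - envz["slope"]).to_numpy() / np.sqrt(3)
    )

    n_sites, n_sp = len(env.site_ids), len(species)
    logit = (
        -((g1[:, None] - opt1[None, :]) ** 2) / 2.0
        - ((g2[:, None] - opt2[None, :]) ** 2) / 2.0
        + dd_env_effect * filt[:, None] * direct[None, :]
        - dd_rarity * direct[None, :]  # direct developers are range-restricted
    )
    # intercept calibrated so the expected site richness hits the target;
    # sites left with expected richness < 3 get a suitability boost so the
    # >=2-species filter terminates
    base = np.log(mean_richness / n_sp) - np.log(np.exp(logit).mean())
    prob = 1.0 / (1.0 + np.exp(-(base + logit)))
    expected = prob.sum(axis=1)
    boost = np.log(np.maximum(1.0, 3.0 / np.maximum(expected, 1e-9)))
    prob = 1.0 / (1.0 + np.exp(-(base + boost[:, None] + logit)))
    rng = np.random.default_rng(seed)
    inc = (rng.random((n_sites, n_sp)) < prob).astype(np.int8)
    for _ in range(max_redraws):
        thin = inc.sum(axis=1) < 2
        if not thin.any():
            break
        inc[thin] = (rng.random((thin.sum(), n_sp)) < prob[thin]).astype(np.int8)
    else:
        raise RuntimeError("could not assemble >=2 species at every site")
    return CommunityMatrix(
        incidence=pd.DataFrame(
            inc,
            index=pd.Index(env.site_ids, name="site"),
            columns=pd.Index(species, name="species"),
        ),
        coordinates=coords.loc[env.site_ids],
    )


# ---------------------------------------------------------------------------
# linear-Gaussian SEM scenario (exact path coefficients)


def simulate_sem_dataset(
    n_sites: int = 766,
    paths: dict[str, dict[str, float]] | None = None,
    exog_corr: np.ndarray = DEFAULT_EXOG_CORR,
    env_range: float = 3.0,
    error_range: float = 1.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, np.ndarray, dict]:
    """Site table whose standardized path coefficients are known exactly.

    Exogenous variables are unit-variance spatial GPs with the given
    cross-correlation; each endogenous variable is its parents' linear
    combination plus noise scaled so its population variance is 1 — the
    declared coefficients are then the true standardized paths.
    Residuals are themselves exponential-correlated fields with range
    ``error_range`` — exactly the error family the GLS stage fits (which
    has no nugget), so its inference is exercised under a correctly
    specified model.  Returns (data, coords, ground truth).
    """
    paths = paths or DEFAULT_PATHS
    rng = np.random.default_rng(seed)
    lon = rng.uniform(-55, -35, n_sites)
    lat = rng.uniform(-30, -5, n_sites)
    coords = np.column_stack([lon, lat])
    z = _gp_samples(coords, env_range, len(EXOGENOUS), rng) @ np.linalg.cholesky(
        exog_corr
    ).T
    data = pd.DataFrame(z, columns=EXOGENOUS)
    cov = pd.DataFrame(exog_corr, index=EXOGENOUS, columns=EXOGENOUS)

    for node, coefs in paths.items():
        parents = list(coefs)
        b = np.array([coefs[p] for p in parents])
        sig_par = cov.loc[parents, parents].to_numpy()
        explained = float(b @ sig_par @ b)
        if explained >= 1:
            raise ValueError(f"paths into {node} explain variance >= 1")
        resid_var = 1.0 - explained
        noise = np.sqrt(resid_var) * _gp_samples(coords, error_range, 1, rng)[:, 0]
        data[node] = data[parents].to_numpy() @ b + noise
        # extend the population covariance with the new variable
        cross = cov.loc[:, parents].to_numpy() @ b
        cov[node] = cross
        cov.loc[node] = np.append(cross, 1.0)
        cov.loc[node, node] = 1.0

    truth = {
        "paths": paths,
        "r2": {
            node: float(
                np.array(list(c.values()))
                @ cov.loc[list(c), list(c)].to_numpy()
                @ np.array(list(c.values()))
            )
            for node, c in paths.items()
        },
        "seed": seed,
    }
    return data, coords, truth


# ---------------------------------------------------------------------------
# whole-scenario driver


@dataclass
class Scenario:
    """A fully generated study system plus its ground truth."""

    config: ScenarioConfig
    tree: dendropy.Tree
    dev: pd.Series
    traits: TraitTable
    env: EnvTable
    coords: pd.DataFrame
    community: CommunityMatrix

    @property
    def truth(self) -> dict:
        return {
            "n_species": len(self.dev),
            "n_direct": int(self.dev.sum()),
            "realized_dd_fraction": float(self.dev.mean()),
            "dd_clades": self.dev.attrs.get("clades"),
            "n_sites": len(self.community.site_ids),
            "paths": self.config.paths,
        }


def make_scenario(config: ScenarioConfig | None = None) -> Scenario:
    """Generate tree, traits, environment, and communities from one seed."""
    cfg = config or ScenarioConfig()
    tree = simulate_tree(cfg.n_species, cfg.birth_rate, cfg.death_rate, cfg.seed)
    dev = assign_direct_development(
        tree, cfg.dd_fraction, cfg.dd_clade_count, seed=cfg.seed + 1
    )
    morpho = simulate_bm_traits(
        tree, cfg.trait_means, cfg.trait_sds, cfg.trait_corr, seed=cfg.seed + 2
    )
    traits = build_trait_table(
        tree, dev, morpho, missing_fraction=cfg.missing_fraction, seed=cfg.seed + 3
    )
    env, coords = simulate_env(cfg.n_sites, cfg.env_range, seed=cfg.seed + 4)
    community = assemble_communities(
        tree,
        dev,
        env,
        coords,
        dd_env_effect=cfg.dd_env_effect,
        dd_rarity=cfg.dd_rarity,
        seed=cfg.seed + 5,
    )
    return Scenario(
        config=cfg,
        tree=tree,
        dev=dev,
        traits=traits,
        env=env,
        coords=coords,
        community=community,
    )


def write_scenario(scn: Scenario, out_dir: str | Path) -> dict:
    """Write the four standard input files + ground-truth JSON; return paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    comm = scn.coords.join(scn.community.incidence)
    comm.index.name = "site"
    comm.to_csv(out / "community.csv")
    scn.traits.data.to_csv(out / "traits.csv")
    env = scn.env.data.copy()
    env.to_csv(out / "env.csv")
    scn.tree.write(path=str(out / "tree.nwk"), schema="newick")
    (out / "truth.json").write_text(json.dumps(scn.truth, indent=2))
    return {
        "community": str(out / "community.csv"),
        "traits": str(out / "traits.csv"),
        "env": str(out / "env.csv"),
        "tree": str(out / "tree.nwk"),
        "truth": str(out / "truth.json"),
    }
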