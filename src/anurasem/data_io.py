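"""Input readers, validated in-memory containers, and the end-to-end driver.

The analysis consumes four inputs: a sites × species incidence table with
site coordinates, a species trait table, a rooted branch-lengthed
phylogeny, and a site × environment table.  Everything is carried
internally as pandas objects keyed by canonical site/species names
(whitespace trimmed, spaces replaced by underscores — the Newick tip
convention), so the four sources can be aligned by exact name match.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("anurasem")

CATEGORICAL_TRAITS = {
    "oviposition_type": {"aquatic", "terrestrial"},
    "development_type": {"larval", "direct"},
    "juvenile_habitat": {"terrestrial", "aquatic", "semiterrestrial"},
    "oviposition_site": {
        "water",
        "bubble_nest",
        "foam_nest",
        "female_back",
        "ground",
        "arboreal",
        "carried",
    },
}
CONTINUOUS_TRAITS = ["body_length", "head_width", "tibia_length"]
ENV_VARIABLES = ["BIO4", "BIO12", "ET0", "slope"]


def canonical_name(name: str) -> str:
    """Trim whitespace and replace internal spaces with underscores."""
    return "_".join(str(name).strip().split())


class FormatError(ValueError):
    """The file lacks required structure (columns, branch lengths, ...)."""


class ValidationError(ValueError):
    """The file parsed but its contents violate an invariant."""


# ---------------------------------------------------------------------------
# containers


@dataclass
class CommunityMatrix:
    """Sites × species presence/absence with per-site coordinates.

    ``incidence`` is a 0/1 DataFrame (index = site ids, columns = species
    ids); ``coordinates`` holds ``longitude``/``latitude`` in decimal
    degrees with the same index.  After construction every retained site
    has at least two species and finite, in-range coordinates.
    """

    incidence: pd.DataFrame
    coordinates: pd.DataFrame
    n_dropped_sites: int = 0

    def __post_init__(self) -> None:
        inc = self.incidence
        if inc.index.duplicated().any():
            dups = inc.index[inc.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate site ids: {dups}")
        if inc.columns.duplicated().any():
            dups = inc.columns[inc.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate species ids: {dups}")
        vals = inc.to_numpy()
        if not np.isin(vals, (0, 1)).all():
            raise ValidationError("incidence entries must be 0 or 1")
        if not inc.index.equals(self.coordinates.index):
            raise ValidationError("coordinate index does not match incidence index")
        if not np.isfinite(self.coordinates[["longitude", "latitude"]].to_numpy()).all():
            raise ValidationError("non-finite coordinates")
        if (inc.sum(axis=1) < 2).any():
            bad = inc.index[inc.sum(axis=1) < 2].tolist()
            raise ValidationError(f"sites with fewer than two species: {bad}")

    @property
    def site_ids(self) -> list[str]:
        return list(self.incidence.index)

    @property
    def species_ids(self) -> list[str]:
        return list(self.incidence.columns)

    @property
    def richness(self) -> pd.Series:
        return self.incidence.sum(axis=1)


@dataclass
class TraitTable:
    """Species trait table: four categorical + three continuous traits.

    Continuous morphometrics (mm) may be missing (NaN); ``development_type``
    never is.  Categorical levels are restricted to fixed vocabularies.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        if df.index.duplicated().any():
            raise ValidationError("duplicate species in trait table")
        if "development_type" not in df.columns:
            raise FormatError("trait table lacks development_type")
        if df["development_type"].isna().any():
            bad = df.index[df["development_type"].isna()].tolist()
            raise ValidationError(f"missing development_type for: {bad}")
        for col, levels in CATEGORICAL_TRAITS.items():
            if col not in df.columns:
                continue
            seen = set(df[col].dropna().unique())
            if not seen <= levels:
                raise ValidationError(f"unknown {col} levels: {sorted(seen - levels)}")
        for col in CONTINUOUS_TRAITS:
            if col in df.columns and (df[col].dropna() <= 0).any():
                raise ValidationError(f"non-positive values in {col}")

    @property
    def species_ids(self) -> list[str]:
        return list(self.data.index)

    def development_vector(self) -> pd.Series:
        """1 for direct developers, 0 for larval development."""
        return (self.data["development_type"] == "direct").astype(int)


@dataclass
class EnvTable:
    """Per-site abiotic predictors: BIO4, BIO12, ET0, terrain slope."""

    data: pd.DataFrame
    standardized: bool = False

    def __post_init__(self) -> None:
        missing = [c for c in ENV_VARIABLES if c not in self.data.columns]
        if missing:
            raise FormatError(f"environment table lacks columns: {missing}")
        if not np.isfinite(self.data[ENV_VARIABLES].to_numpy()).all():
            raise ValidationError("non-finite environment values")

    @property
    def site_ids(self) -> list[str]:
        return list(self.data.index)


@dataclass
class AlignedData:
    """The four inputs restricted to common sites/species, in shared order."""

    community: CommunityMatrix
    traits: TraitTable
    tree: dendropy.Tree
    env: EnvTable
    dropped_species: dict[str, list[str]] = field(default_factory=dict)
    dropped_sites: dict[str, list[str]] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# readers


def _read_table(path: str | Path, fmt: str | None = None) -> pd.DataFrame:
    path = Path(path)
    if fmt is None:
        fmt = "xlsx" if path.suffix.lower() in (".xlsx", ".xls") else "csv"
    if fmt == "xlsx":
        return pd.read_excel(path)
    return pd.read_csv(path)


def _coord_ok(lon: float, lat: float) -> bool:
    return (
        np.isfinite(lon)
        and np.isfinite(lat)
        and -180.0 < lon < 180.0
        and -90.0 < lat < 90.0
    )


def read_community_table(path: str | Path, fmt: str | None = None) -> CommunityMatrix:
    """Read a community incidence table (wide or long, CSV or XLSX).

    Wide layout: one row per site with ``site``, ``longitude``,
    ``latitude`` columns and one 0/1 column per species.  Long layout:
    one row per occurrence with ``site``, ``species``, ``longitude``,
    ``latitude`` columns.  Sites with out-of-range/missing coordinates or
    fewer than two species are dropped; the count is reported on the
    returned object and logged.
    """
    df = _read_table(path, fmt)
    df.columns = [canonical_name(c) for c in df.columns]
    lower = {c.lower(): c for c in df.columns}
    for required in ("longitude", "latitude"):
        if required not in lower:
            raise FormatError(f"community table lacks a {required} column")
    if "site" not in lower:
        raise FormatError("community table lacks a site column")
    site_c, lon_c, lat_c = lower["site"], lower["longitude"], lower["latitude"]

    if "species" in lower:  # long layout
        sp_c = lower["species"]
        recs = df[[site_c, sp_c]].apply(lambda s: s.map(canonical_name))
        dup = recs.duplicated()
        if dup.any():
            offenders = recs[dup].to_records(index=False).tolist()
            raise ValidationError(f"duplicate (site, species) records: {offenders}")
        df = df.assign(**{site_c: recs[site_c], sp_c: recs[sp_c]})
        incidence = (
            pd.crosstab(df[site_c], df[sp_c]).clip(upper=1).astype(np.int8)
        )
        coords = df.groupby(site_c)[[lon_c, lat_c]].first()
    else:  # wide layout
        df[site_c] = df[site_c].map(canonical_name)
        df = df.set_index(site_c)
        coords = df[[lon_c, lat_c]]
        sp_cols = [c for c in df.columns if c not in (lon_c, lat_c)]
        incidence = df[sp_cols].fillna(0).astype(np.int8)
        incidence.columns = [canonical_name(c) for c in incidence.columns]

    coords = coords.rename(columns={lon_c: "longitude", lat_c: "latitude"}).astype(float)
    ok_coord = coords.apply(lambda r: _coord_ok(r["longitude"], r["latitude"]), axis=1)
    ok_rich = incidence.sum(axis=1) >= 2
    keep = ok_coord & ok_rich
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("dropped %d sites (coordinates or single-species filter)", n_dropped)
    incidence = incidence.loc[keep]
    incidence.index.name = "site"
    incidence.columns.name = "species"
    return CommunityMatrix(
        incidence=incidence, coordinates=coords.loc[keep], n_dropped_sites=n_dropped
    )


def read_trait_table(path: str | Path, fmt: str | None = None) -> TraitTable:
    df = _read_table(path, fmt)
    df.columns = [canonical_name(c).lower() for c in df.columns]
    if "species" not in df.columns:
        raise FormatError("trait table lacks a species column")
    df["species"] = df["species"].map(canonical_name)
    df = df.set_index("species")
    return TraitTable(data=df)


def read_env_table(path: str | Path, fmt: str | None = None, standardized: bool = False) -> EnvTable:
    df = _read_table(path, fmt)
    df.columns = [canonical_name(c) for c in df.columns]
    lower = {c.lower(): c for c in df.columns}
    if "site" not in lower:
        raise FormatError("environment table lacks a site column")
    df[lower["site"]] = df[lower["site"]].map(canonical_name)
    df = df.set_index(lower["site"])
    df.index.name = "site"
    return EnvTable(data=df, standardized=standardized)


def read_tree(path: str | Path) -> dendropy.Tree:
    """Read a rooted Newick tree with branch lengths.

    Polytomies are preserved.  A tree with any missing branch length, or
    with an unrooted (trifurcating, unflagged) basal structure, is refused.
    """
    tree = dendropy.Tree.get(
        path=str(path), schema="newick", preserve_underscores=True
    )
    for edge in tree.preorder_edge_iter():
        if edge.head_node is tree.seed_node:
            continue
        if edge.length is None:
            raise FormatError(
                f"branch leading to {edge.head_node.taxon or 'an internal node'} "
                "has no length; a branch-lengthed tree is required"
            )
    nchild = len(tree.seed_node.child_nodes())
    if nchild > 2 and not tree.is_rooted:
        raise FormatError(
            f"tree is unrooted (basal polytomy of {nchild} without rooting flag)"
        )
    tree.is_rooted = True
    labels = [t.label for t in tree.taxon_namespace]
    if len(labels) != len(set(labels)):
        raise ValidationError("duplicate tip labels in tree")
    return tree


# ---------------------------------------------------------------------------
# alignment


def align_inputs(
    cm: CommunityMatrix,
    tt: TraitTable,
    tree: dendropy.Tree,
    env: EnvTable,
    on_missing_from_tree: str = "error",
) -> AlignedData:
    """Restrict all four inputs to shared sites/species with consistent order.

    Species are restricted to the intersection of the community matrix,
    the trait table, and the tree tips; sites to the intersection of the
    community matrix and the environment table.  Dropped names are
    returned per source.  A species known to both the community and the
    trait table but absent from the tree is an error by default (insert
    it at its MDCC first, see ``add_taxon_at_mdcc``); pass
    ``on_missing_from_tree="drop"`` to discard such species instead.
    """
    tips = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    sp_cm, sp_tt = set(cm.species_ids), set(tt.species_ids)
    absent = sorted((sp_cm & sp_tt) - tips)
    if absent and on_missing_from_tree == "error":
        raise ValidationError(
            f"species missing from tree: {absent}; insert them at their MDCC "
            "or pass on_missing_from_tree='drop'"
        )
    species = sorted(sp_cm & sp_tt & tips)
    sites = sorted(set(cm.site_ids) & set(env.site_ids))
    if not species or not sites:
        raise ValidationError("empty site or species intersection after alignment")

    dropped_species = {
        "community": sorted(sp_cm - set(species)),
        "traits": sorted(sp_tt - set(species)),
        "tree": sorted(tips - set(species)),
    }
    dropped_sites = {
        "community": sorted(set(cm.site_ids) - set(sites)),
        "env": sorted(set(env.site_ids) - set(sites)),
    }

    inc = cm.incidence.loc[sites, species]
    keep = inc.sum(axis=1) >= 2  # restriction may re-create thin sites
    if (~keep).any():
        dropped_sites["community"] += sorted(inc.index[~keep])
        inc = inc.loc[keep]
        sites = list(inc.index)
    cm2 = CommunityMatrix(
        incidence=inc,
        coordinates=cm.coordinates.loc[sites],
        n_dropped_sites=cm.n_dropped_sites + len(dropped_sites["community"]),
    )
    tt2 = TraitTable(data=tt.data.loc[species])
    env2 = EnvTable(data=env.data.loc[sites], standardized=env.standardized)

    tree2 = tree.clone(depth=1)
    tree2.retain_taxa_with_labels(species)
    return AlignedData(
        community=cm2,
        traits=tt2,
        tree=tree2,
        env=env2,
        dropped_species=dropped_species,
        dropped_sites=dropped_sites,
    )


# ---------------------------------------------------------------------------
# result writing


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write a result table with enough precision for lossless round-trip."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, float_format="%.17g")


# ---------------------------------------------------------------------------
# end-to-end driver


def run_pipeline(config: str | Path | dict, out_dir: str | Path | None = None) -> dict:
    """Run the full analysis from a YAML config (or dict) and write results.

    The config names the four input files, the null-model replicate
    count, the master seed, the PVR variance fraction, and the SEM DAG
    (edge list).  Writes per-stage CSVs plus a JSON log of decisions and
    seeds, and returns the in-memory results.
    """
    from anurasem import null_models, phylo_structure, sem, spatial_gls, trait_space

    if not isinstance(config, dict):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    cfg = dict(config)
    out = Path(out_dir or cfg.get("out_dir", "results/pipeline"))
    out.mkdir(parents=True, exist_ok=True)

    n_null = int(cfg.get("n_null", 999))
    if n_null < 1:
        raise ValueError("n_null must be >= 1 (null models undefined otherwise)")
    seed = int(cfg.get("seed", 0))
    variance_fraction = float(cfg.get("variance_fraction", 0.95))

    def stage(name):
        logger.info("stage: %s", name)

    try:
        stage("read inputs")
        cm = read_community_table(cfg["community"])
        tt = read_trait_table(cfg["traits"])
        tree = read_tree(cfg["tree"])
        env = read_env_table(cfg["env"], standardized=cfg.get("env_standardized", False))
        for taxon, tip_set in (cfg.get("put_insertions") or {}).items():
            tree = phylo_structure.add_taxon_at_mdcc(tree, taxon, tip_set)
        bundle = align_inputs(cm, tt, tree, env)
    except Exception as exc:  # noqa: BLE001 - re-raise with stage context
        raise RuntimeError(f"pipeline failed at stage 'inputs': {exc}") from exc

    cm, tt, tree, env = bundle.community, bundle.traits, bundle.tree, bundle.env
    dev = tt.development_vector().loc[cm.species_ids]

    stage("ses of direct-development proportion")
    ses_dd = null_models.ses_dd_proportion(cm, dev, n_null=n_null, seed=seed)
    write_table(ses_dd.to_frame(), out / "ses_dd.csv")

    stage("phylogenetic composition (P matrix, PCPS)")
    pmat = phylo_structure.phylo_weighted_composition(cm, tree)
    pcps_res = phylo_structure.pcps(pmat)
    write_table(pcps_res.axis_frame(cm.site_ids, "pcps"), out / "pcps_scores.csv")
    write_table(pcps_res.eigen_frame(), out / "pcps_eigen.csv")

    stage("trait imputation, PVR, functional diversity")
    pvr = trait_space.pvr_eigenvectors(tree, variance_fraction=variance_fraction)
    traits_full = trait_space.impute_traits_bm(tree, tt)
    features = trait_space.trait_feature_matrix(
        traits_full, include_development=cfg.get("include_development_traits", True)
    )
    resid = trait_space.trait_pvr_residuals(features, pvr)
    dend = trait_space.functional_dendrogram(resid)
    ses_fd_res = trait_space.ses_fd(dend, cm, n_null=n_null, seed=seed + 1)
    write_table(ses_fd_res.to_frame(), out / "ses_fd.csv")

    stage("site table and spatial models")
    site_table = pd.DataFrame(
        {
            "BIO4": env.data["BIO4"],
            "BIO12": env.data["BIO12"],
            "ET0": env.data["ET0"],
            "slope": env.data["slope"],
            "PCPS1": pcps_res.axis_scores[:, 0],
            "SES.FD": ses_fd_res.ses,
            "%DD": (
                ses_dd.ses
                if cfg.get("dd_response", "ses") == "ses"
                else ses_dd.observed
            ),
        },
        index=pd.Index(cm.site_ids, name="site"),
    )
    if not env.standardized:
        site_table[["BIO4", "BIO12", "ET0", "slope"]] = spatial_gls.standardize(
            site_table[["BIO4", "BIO12", "ET0", "slope"]]
        )
    write_table(site_table, out / "site_table.csv")

    stage("piecewise SEM")
    edges = [tuple(e) for e in cfg.get("dag", sem.FIG1_DAG_EDGES)]
    pm = sem.PathModel.from_edges(edges)
    coords = cm.coordinates[["longitude", "latitude"]].to_numpy()
    sem_res = sem.fit_piecewise_sem(pm, site_table, coords)
    write_table(sem_res.paths_frame(), out / "sem_paths.csv")
    (out / "sem_report.txt").write_text(sem_res.report())
    (out / "sem_report.json").write_text(json.dumps(sem_res.to_dict(), indent=2))

    log = {
        "seed": seed,
        "n_null": n_null,
        "variance_fraction": variance_fraction,
        "n_sites": len(cm.site_ids),
        "n_species": len(cm.species_ids),
        "n_dropped_sites": cm.n_dropped_sites,
        "dropped_species": bundle.dropped_species,
        "pvr_axes": int(pvr.shape[1]),
        "dag": [list(e) for e in edges],
        "dd_response": cfg.get("dd_response", "ses"),
    }
    (out / "run_log.json").write_text(json.dumps(log, indent=2))
    return {
        "ses_dd": ses_dd,
        "pcps": pcps_res,
        "ses_fd": ses_fd_res,
        "site_table": site_table,
        "sem": sem_res,
        "log": log,
    }
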