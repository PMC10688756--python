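"""Composition-controlled null model for the direct-development proportion.

The observed per-site proportion of direct developers (%DD) confounds the
trait of interest with species composition: species-rich sites drawn from
a pool with few direct developers will show low proportions regardless of
any ecological filtering.  Shuffling the species → development-type map
over the whole regional pool (a D-matrix randomization: species identity
is permuted, incidence held fixed) yields a null distribution of the
proportion at each site, and the standardized effect size

    SES = (observed − null mean) / null SD

measures the composition-free excess or deficit of direct developers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from anurasem.data_io import CommunityMatrix


@dataclass
class SesResult:
    """Per-site observed statistic with its null mean/SD and SES.

    ``defined`` is False where the null SD is zero; there SES is NaN
    rather than a fabricated 0.
    """

    site_ids: list[str]
    observed: np.ndarray
    null_mean: np.ndarray
    null_sd: np.ndarray
    n_replicates: int
    seed: int

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        self.observed = np.asarray(self.observed, dtype=float)
        self.null_mean = np.asarray(self.null_mean, dtype=float)
        self.null_sd = np.asarray(self.null_sd, dtype=float)
        if (self.null_sd < 0).any():
            raise ValueError("negative null SD")

    @property
    def defined(self) -> np.ndarray:
        # scale-aware zero test: a null SD at rounding level of the mean is
        # a relabelling-invariant statistic, not real null variation
        tol = 1e-10 * np.maximum(np.abs(self.null_mean), 1.0)
        return self.null_sd > tol

    @property
    def ses(self) -> np.ndarray:
        out = np.full_like(self.observed, np.nan)
        d = self.defined
        out[d] = (self.observed[d] - self.null_mean[d]) / self.null_sd[d]
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "observed": self.observed,
                "null_mean": self.null_mean,
                "null_sd": self.null_sd,
                "ses": self.ses,
                "defined": self.defined,
            },
            index=pd.Index(self.site_ids, name="site"),
        )


def _aligned_dev(cm: CommunityMatrix, dev) -> np.ndarray:
    """Coerce the development vector to the community species order."""
    if isinstance(dev, pd.Series):
        if set(dev.index) != set(cm.species_ids):
            raise ValueError("development vector index does not match community species")
        dev = dev.loc[cm.species_ids]
    dev = np.asarray(dev, dtype=float)
    if dev.shape != (len(cm.species_ids),):
        raise ValueError(
            f"development vector length {dev.shape} does not match "
            f"{len(cm.species_ids)} species"
        )
    if not np.isin(dev, (0, 1)).all():
        raise ValueError("development vector must be binary (1 = direct)")
    return dev


def observed_dd_proportion(cm: CommunityMatrix, dev) -> pd.Series:
    """Proportion of present species that are direct developers, per site."""
    dev = _aligned_dev(cm, dev)
    inc = cm.incidence.to_numpy(dtype=float)
    richness = inc.sum(axis=1)
    prop = inc @ dev / richness
    return pd.Series(prop, index=pd.Index(cm.site_ids, name="site"), name="prop_dd")


def ses_dd_proportion(
    cm: CommunityMatrix, dev, n_null: int = 999, seed: int = 0
) -> SesResult:
    """Standardized effect size of %DD under pool-wide label shuffling.

    Each of ``n_null`` replicates permutes the species → development map
    across the entire regional pool and recomputes every site proportion;
    a single seeded RNG stream drives all replicates, so results are
    bit-reproducible.  Species are processed in their canonical (sorted)
    order before permutations are drawn, making the result invariant to
    the column order of the input matrix.
    """
    if n_null < 1:
        raise ValueError("n_null must be >= 1")
    dev = _aligned_dev(cm, dev)

    order = np.argsort(np.asarray(cm.species_ids))
    inc = cm.incidence.to_numpy(dtype=float)[:, order]
    dev_sorted = dev[order]
    richness = inc.sum(axis=1)
    observed = inc @ dev_sorted / richness

    rng = np.random.default_rng(seed)
    n_sp = dev_sorted.size
    null = np.empty((n_null, len(cm.site_ids)))
    for r in range(n_null):
        perm = rng.permutation(n_sp)
        null[r] = inc @ dev_sorted[perm] / richness
    return SesResult(
        site_ids=cm.site_ids,
        observed=observed,
        null_mean=null.mean(axis=0),
        null_sd=null.std(axis=0, ddof=0),
        n_replicates=n_null,
        seed=seed,
    )


def ses_from_null(
    site_ids: list[str],
    observed: np.ndarray,
    null_matrix: np.ndarray,
    n_replicates: int,
    seed: int,
) -> SesResult:
    """Assemble a SesResult from an (n_replicates × n_sites) null matrix."""
    return SesResult(
        site_ids=site_ids,
        observed=np.asarray(observed, dtype=float),
        null_mean=null_matrix.mean(axis=0),
        null_sd=null_matrix.std(axis=0, ddof=0),
        n_replicates=n_replicates,
        seed=seed,
    )
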