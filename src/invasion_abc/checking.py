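"""Posterior-predictive model checking with tail-area ppp-values.

Datasets are simulated from the fitted scenario with parameter values drawn
with replacement from the posterior sample; for each held-out test
statistic q the cumulative probability p = Prob(q_sim < q_obs) is computed
over the simulations (ties counted as half), and the posterior predictive
p-value is the tail area: ppp = p when p <= 0.5, else 1 - p, hence always
in [0, 0.5]. Test quantities must be disjoint from the statistics used for
parameter estimation. Because many, often dependent, statistics are tested
at once, a Benjamini–Hochberg step-up procedure controls the false
discovery rate. A principal-component projection of the simulated
statistic vectors, with the observed point mapped through the same
transform, gives a visual/depth check of model adequacy.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import false_discovery_control
from sklearn.decomposition import PCA

from .demography import Scenario
from .estimation import PosteriorSample
from .genotype_data import GenotypeDataset
from .simulator import GSMModel, drop_mutations, simulate_genealogies
from .sumstats import StatVector, catalog_names, full_catalog

logger = logging.getLogger(__name__)


@dataclass
class PPCReport:
    test_stat_names: list[str]
    ppp: np.ndarray                  # (S,), in [0, 0.5]
    n_ppc: int
    n_below_005: int
    n_below_0001: int
    fdr_flags: np.ndarray            # adjusted significance at fdr_level
    fdr_level: float
    resolution: float                # 1 / (n_ppc + 1)
    pca_sim_coords: np.ndarray | None = None   # (n_ppc, 2)
    pca_obs_coords: np.ndarray | None = None   # (2,)
    obs_depth_rank: float | None = None        # fraction of sims less extreme
    extras: dict = field(default_factory=dict)


def ppp_values(sim_stats: np.ndarray, obs: np.ndarray) -> np.ndarray:
    """Tail-area posterior predictive p-values, column-wise.

    ``sim_stats`` has one row per posterior-predictive simulation and one
    column per test statistic; ties between simulated and observed values
    count one half.
    """
    sim_stats = np.asarray(sim_stats, dtype=float)
    obs = np.asarray(obs, dtype=float)
    if sim_stats.ndim != 2 or sim_stats.shape[1] != len(obs):
        raise ValueError("sim_stats must be (n_sim, n_stats) matching obs")
    n = sim_stats.shape[0]
    p = ((sim_stats < obs).sum(axis=0) + 0.5 * (sim_stats == obs).sum(axis=0)) / n
    return np.minimum(p, 1.0 - p)


def test_statistic_complement(
    pops: list[str],
    estimation_names: Sequence[str],
    triplets: str | list = "all",
) -> list[str]:
    """Full-catalog names minus the estimation subset, order-stable."""
    names, _ = catalog_names(pops, triplets)
    catalog = set(names)
    outside = [n for n in estimation_names if n not in catalog]
    if outside:
        raise ValueError(
            f"estimation subset not contained in the catalog: {outside[:5]}"
        )
    drop = set(estimation_names)
    return [n for n in names if n not in drop]


def pca_projection_check(
    sim_stats: np.ndarray,
    obs: np.ndarray,
    n_components: int = 5,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Project simulations and the observed vector on principal components.

    Components are fitted on the simulated vectors (constant columns are
    dropped, columns standardized); returns the simulations' first-two-axes
    coordinates, the observed coordinates, and the observed point's depth
    rank — the fraction of simulations whose variance-scaled squared
    distance from the center is smaller than the observed one (1.0 = most
    extreme point).
    """
    sim_stats = np.asarray(sim_stats, dtype=float)
    if sim_stats.shape[0] < 3:
        raise ValueError("need at least 3 simulated vectors")
    sd = sim_stats.std(axis=0)
    keep = sd > 0
    if not np.all(keep):
        logger.info("dropping %d constant statistics before PCA", (~keep).sum())
    Xs = (sim_stats[:, keep] - sim_stats[:, keep].mean(axis=0)) / sd[keep]
    x_obs = (np.asarray(obs, dtype=float)[keep] - sim_stats[:, keep].mean(axis=0)) / sd[keep]
    k = min(n_components, Xs.shape[1], Xs.shape[0] - 1)
    pca = PCA(n_components=k)
    scores = pca.fit_transform(Xs)
    obs_scores = pca.transform(x_obs[None, :])[0]
    lam = np.maximum(pca.explained_variance_, 1e-12)
    depth_sim = (scores**2 / lam).sum(axis=1)
    depth_obs = float((obs_scores**2 / lam).sum())
    rank = float(np.mean(depth_sim < depth_obs))
    coords2 = scores[:, :2] if k >= 2 else np.pad(scores, ((0, 0), (0, 2 - k)))
    obs2 = obs_scores[:2] if k >= 2 else np.pad(obs_scores, (0, 2 - k))
    return coords2, obs2, rank


def posterior_predictive_check(
    scenario: Scenario,
    posterior: PosteriorSample,
    observed_dataset: GenotypeDataset,
    n_ppc: int,
    test_stats: Sequence[str],
    estimation_names: Sequence[str],
    rng_seed: int = 0,
    sample_config: Mapping[str, int] | None = None,
    fixed_params: Mapping[str, float] | None = None,
    fdr_level: float = 0.05,
    model: GSMModel | None = None,
) -> PPCReport:
    """Simulate from the scenario-posterior combination and score the fit.

    ``test_stats`` must be disjoint from ``estimation_names`` (the
    statistics the posterior was fitted on); overlap is an error, not a
    warning. Parameter vectors are drawn with replacement from the
    posterior draws, weighted by the posterior weights.
    """
    if n_ppc < 100:
        raise ValueError("n_ppc must be >= 100 for a usable tail resolution")
    overlap = set(test_stats) & set(estimation_names)
    if overlap:
        raise ValueError(
            f"test statistics overlap the estimation set: {sorted(overlap)[:5]}"
        )
    rng = np.random.default_rng(rng_seed)
    fixed_params = dict(fixed_params or {})
    if sample_config is None:
        sample_config = observed_dataset.sample_sizes()
    n_loci = observed_dataset.n_loci

    w = posterior.weights / posterior.weights.sum()
    pick = rng.choice(len(posterior.draws), size=n_ppc, replace=True, p=w)

    sim_matrix = np.empty((n_ppc, len(test_stats)))
    import warnings as _warnings

    for i, row in enumerate(pick):
        params = dict(fixed_params)
        params.update(posterior.draws.iloc[row].to_dict())
        seed_i = np.random.SeedSequence([rng_seed, i])
        s_trees, s_muts = seed_i.spawn(2)
        gen = simulate_genealogies(
            scenario, params, np.random.default_rng(s_trees),
            sample_config=sample_config, n_loci=n_loci,
        )
        row_model = model
        if row_model is None:
            kwargs = {}
            if "mu" in params:
                kwargs["mu"] = params["mu"]
            if "p_geom" in params:
                kwargs["p_geom"] = params["p_geom"]
            row_model = GSMModel(**kwargs)
        ds = drop_mutations(gen, row_model, np.random.default_rng(s_muts))
        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore")
            sv = full_catalog(ds)
        sim_matrix[i] = sv.subset(list(test_stats)).values

    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore")
        obs_sv = full_catalog(observed_dataset).subset(list(test_stats))
    ppp = ppp_values(sim_matrix, obs_sv.values)

    resolution = 1.0 / (n_ppc + 1)
    # BH on the two-sided equivalents, floored at the Monte-Carlo resolution
    raw = np.clip(2.0 * ppp, resolution, 1.0)
    adjusted = false_discovery_control(raw, method="bh")
    flags = adjusted <= fdr_level
    coords, obs_coords, depth = pca_projection_check(sim_matrix, obs_sv.values)
    return PPCReport(
        test_stat_names=list(test_stats),
        ppp=ppp,
        n_ppc=n_ppc,
        n_below_005=int((ppp < 0.05).sum()),
        n_below_0001=int((ppp < 0.001).sum()),
        fdr_flags=flags,
        fdr_level=fdr_level,
        resolution=resolution,
        pca_sim_coords=coords,
        pca_obs_coords=obs_coords,
        obs_depth_rank=depth,
        extras={"adjusted_p": adjusted},
    )
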