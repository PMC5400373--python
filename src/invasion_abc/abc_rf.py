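"""ABC model choice by random forest (ABC-RF).

A classification forest is trained on the reference table (summary
statistics plus linear-discriminant axes appended as extra covariates) to
predict the scenario label. Applied to the observed statistic vector, each
tree casts one vote; the scenario with most votes is selected. The forest's
out-of-bag (OOB) misclassification fraction over the table is the prior
error rate — the probability of choosing a wrong scenario when scenario and
parameters are drawn from their priors. The posterior probability of the
selected scenario comes from a secondary regression forest fitted to the
OOB misclassification indicator: 1 minus its predicted local error at the
observed point, clipped to [0, 1].
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor

from .reftable import ReferenceTable
from .sumstats import StatVector

logger = logging.getLogger(__name__)

LDA_PREFIX = "LDA"


@dataclass
class ModelChoiceResult:
    """Votes, winner, posterior probability and prior error rate."""

    scenario_names: list[str]
    votes: np.ndarray                 # (K,) summed over trees, first replicate
    best_scenario: str
    posterior_probability: float      # mean over replicates
    prior_error_rate: float           # mean over replicates
    n_trees: int
    n_replicates: int = 1
    replicate_posteriors: np.ndarray | None = None
    replicate_errors: np.ndarray | None = None
    forest_params: dict = field(default_factory=dict)

    @property
    def posterior_sd(self) -> float:
        if self.replicate_posteriors is None or len(self.replicate_posteriors) < 2:
            return 0.0
        return float(np.std(self.replicate_posteriors, ddof=1))

    @property
    def prior_error_sd(self) -> float:
        if self.replicate_errors is None or len(self.replicate_errors) < 2:
            return 0.0
        return float(np.std(self.replicate_errors, ddof=1))


def append_lda_axes(table: ReferenceTable) -> ReferenceTable:
    """Fit discriminant axes on the table and append them as extra columns.

    Adds min(K-1, d) projection columns for K scenarios and d statistics;
    the fitted projector is stored on the returned table so an observed
    vector is projected with the identical transform. A singular
    within-class scatter falls back to the SVD solver's implicit
    regularization with a logged warning.
    """
    if len(table.scenario_names) < 2:
        raise ValueError("discriminant axes need at least 2 scenarios")
    if any(c.startswith(LDA_PREFIX) for c in table.stat_names):
        return table
    X = table.stats.to_numpy()
    y = table.scenario_idx
    lda = LinearDiscriminantAnalysis(solver="svd")
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        axes = lda.fit_transform(X, y)
    for w in caught:
        if "collinear" in str(w.message).lower():
            logger.warning(
                "within-class scatter is singular; discriminant axes rely on "
                "the SVD solver's implicit regularization"
            )
    import pandas as pd

    stats = table.stats.copy()
    for k in range(axes.shape[1]):
        stats[f"{LDA_PREFIX}{k + 1}"] = axes[:, k]
    out = ReferenceTable(
        scenario_names=list(table.scenario_names),
        scenario_idx=table.scenario_idx.copy(),
        params=table.params.copy(),
        stats=stats,
        prior_set=table.prior_set,
        root_seed=table.root_seed,
        seed_ledger=table.seed_ledger,
        stat_arity=list(table.stat_arity) + [0] * axes.shape[1],
    )
    out.lda = (lda, list(table.stat_names))
    return out


def _observed_matrix(table: ReferenceTable, observed: StatVector) -> np.ndarray:
    """Observed vector aligned with the table's columns, with discriminant
    axes appended through the stored projector when present."""
    cols = table.stat_names
    axis_cols = [c for c in cols if c.startswith(LDA_PREFIX)]
    base_cols = [c for c in cols if not c.startswith(LDA_PREFIX)]
    obs_map = dict(zip(observed.names, observed.values))
    missing = [c for c in base_cols if c not in obs_map]
    if missing:
        raise KeyError(
            f"observed statistics missing table columns (first few): {missing[:5]}"
        )
    base = np.array([obs_map[c] for c in base_cols])
    if not axis_cols:
        return base[None, :]
    if table.lda is None:
        raise ValueError("table has axis columns but no stored projector")
    lda, fit_cols = table.lda
    proj_in = np.array([obs_map[c] for c in fit_cols])[None, :]
    axes = lda.transform(proj_in)
    full = np.concatenate([base, axes.ravel()])
    return full[None, :]


def _fit_forest(
    table: ReferenceTable, n_trees: int, seed: int
) -> RandomForestClassifier:
    forest = RandomForestClassifier(
        n_estimators=n_trees,
        oob_score=True,
        random_state=int(seed) & 0x7FFFFFFF,
        n_jobs=1,
    )
    with warnings.catch_warnings():
        # few-tree forests legitimately leave some rows never OOB
        warnings.simplefilter("ignore")
        forest.fit(table.stats.to_numpy(), table.scenario_idx)
    return forest


def _oob_error_indicator(
    forest: RandomForestClassifier, y: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Per-row OOB misclassification indicator and a validity mask."""
    proba = forest.oob_decision_function_
    valid = ~np.isnan(proba).any(axis=1) & (proba.sum(axis=1) > 0)
    pred = np.full(len(y), -1, dtype=np.int64)
    pred[valid] = forest.classes_[np.argmax(proba[valid], axis=1)]
    return (pred != y).astype(float), valid


def prior_error_rate_rf(
    table: ReferenceTable,
    n_trees: int = 500,
    rng_seed: int = 0,
    method: str = "oob",
) -> float:
    """Prior error rate of the classification forest.

    ``method="oob"`` (default): out-of-bag misclassification fraction over
    the reference table. ``method="holdout"``: error on a 20% held-out split.
    """
    table = append_lda_axes(table)
    if method == "oob":
        forest = _fit_forest(table, n_trees, rng_seed)
        err, valid = _oob_error_indicator(forest, table.scenario_idx)
        return float(err[valid].mean())
    if method == "holdout":
        rng = np.random.default_rng(rng_seed)
        n = table.n_rows
        perm = rng.permutation(n)
        cut = max(1, n // 5)
        test, train = perm[:cut], perm[cut:]
        forest = RandomForestClassifier(
            n_estimators=n_trees, random_state=rng_seed & 0x7FFFFFFF, n_jobs=1
        )
        X = table.stats.to_numpy()
        forest.fit(X[train], table.scenario_idx[train])
        pred = forest.predict(X[test])
        return float(np.mean(pred != table.scenario_idx[test]))
    raise ValueError(f"unknown method {method!r}")


def posterior_probability_best(
    table: ReferenceTable,
    forest: RandomForestClassifier,
    observed: StatVector | np.ndarray,
    n_trees: int | None = None,
    rng_seed: int = 0,
) -> float:
    """Posterior probability of the forest's selected scenario via the
    secondary regression forest on the OOB misclassification indicator."""
    X = table.stats.to_numpy()
    x_obs = (
        observed
        if isinstance(observed, np.ndarray)
        else _observed_matrix(table, observed)
    )
    err, valid = _oob_error_indicator(forest, table.scenario_idx)
    reg = RandomForestRegressor(
        n_estimators=n_trees or forest.n_estimators,
        random_state=rng_seed & 0x7FFFFFFF,
        min_samples_leaf=5,  # smooths the local error surface
        n_jobs=1,
    )
    reg.fit(X[valid], err[valid])
    local_error = float(reg.predict(np.atleast_2d(x_obs))[0])
    return float(np.clip(1.0 - local_error, 0.0, 1.0))


def rf_model_choice(
    table: ReferenceTable,
    observed: StatVector,
    n_trees: int = 500,
    rng_seed: int = 0,
    n_replicates: int = 1,
) -> ModelChoiceResult:
    """Select the best scenario for an observed dataset by classification
    votes, and estimate its posterior probability and the prior error rate.

    Replicate runs retrain the forests on the same table with different
    forest seeds (mirroring replicate analyses of a fixed reference table);
    means and standard deviations across replicates are reported.
    """
    if len(table.scenario_names) < 2:
        raise ValueError("model choice needs at least 2 scenarios")
    table = append_lda_axes(table)
    x_obs = _observed_matrix(table, observed)
    K = len(table.scenario_names)

    ss = np.random.SeedSequence(rng_seed)
    rep_seeds = [int(s.generate_state(1)[0]) & 0x7FFFFFFF for s in ss.spawn(n_replicates)]

    votes_first: np.ndarray | None = None
    all_votes = np.zeros((n_replicates, K))
    posteriors = np.empty(n_replicates)
    errors = np.empty(n_replicates)
    for r, seed in enumerate(rep_seeds):
        forest = _fit_forest(table, n_trees, seed)
        tree_preds = np.array(
            [t.predict(x_obs.astype(np.float32))[0] for t in forest.estimators_],
            dtype=np.int64,
        )
        # tree leaves are indexed in forest.classes_ space
        votes = np.bincount(
            forest.classes_[tree_preds].astype(np.int64), minlength=K
        )
        all_votes[r] = votes
        if votes_first is None:
            votes_first = votes
        err, valid = _oob_error_indicator(forest, table.scenario_idx)
        errors[r] = float(err[valid].mean())
        posteriors[r] = posterior_probability_best(
            table, forest, x_obs, rng_seed=seed
        )

    mean_votes = all_votes.mean(axis=0)
    order = np.argsort(-mean_votes)
    best_idx = int(order[0])
    ties = np.flatnonzero(mean_votes == mean_votes[best_idx])
    if len(ties) > 1:
        best_idx = int(ties.min())
        logger.warning(
            "vote tie between scenarios %s; choosing lowest index",
            [table.scenario_names[i] for i in ties],
        )
    return ModelChoiceResult(
        scenario_names=list(table.scenario_names),
        votes=votes_first,
        best_scenario=table.scenario_names[best_idx],
        posterior_probability=float(posteriors.mean()),
        prior_error_rate=float(errors.mean()),
        n_trees=n_trees,
        n_replicates=n_replicates,
        replicate_posteriors=posteriors,
        replicate_errors=errors,
        forest_params={
            "max_features": "sqrt",
            "max_depth": None,
            "n_trees": n_trees,
        },
    )
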