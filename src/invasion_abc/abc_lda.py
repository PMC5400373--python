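"""Standard ABC model choice: rejection plus polychotomous logistic
regression on linear-discriminant axes (ABC-LDA).

Statistics are standardized by their table-wide median absolute deviation,
the simulated datasets closest (Euclidean) to the observed one are kept
(default: the closest 1%), and a multinomial logistic regression of the
scenario label on the discriminant axes over the accepted rows yields the
posterior probability of each scenario at the observed point. The prior
error rate is the fraction of held-out pseudo-observed datasets whose
highest-probability scenario differs from their generating scenario.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.linear_model import LogisticRegression

from .abc_rf import LDA_PREFIX
from .reftable import ReferenceTable
from .sumstats import StatVector

logger = logging.getLogger(__name__)


@dataclass
class LDAChoiceResult:
    scenario_names: list[str]
    probabilities: np.ndarray        # (K,), sums to 1
    best_scenario: str
    tolerance: float
    n_accepted: int
    best_ci: tuple[float, float] | None = None  # approximate 95% interval

    def probability_of(self, name: str) -> float:
        return float(self.probabilities[self.scenario_names.index(name)])


def mad_scale(X: np.ndarray) -> np.ndarray:
    """Per-column median absolute deviation, falling back to the standard
    deviation and then to 1 for degenerate columns."""
    med = np.median(X, axis=0)
    mad = np.median(np.abs(X - med), axis=0)
    sd = X.std(axis=0)
    scale = np.where(mad > 0, mad, sd)
    return np.where(scale > 0, scale, 1.0)


def _base_columns(table: ReferenceTable) -> list[str]:
    return [c for c in table.stat_names if not c.startswith(LDA_PREFIX)]


def _observed_vector(observed: StatVector | np.ndarray, cols: list[str]) -> np.ndarray:
    if isinstance(observed, np.ndarray):
        if len(observed) != len(cols):
            raise ValueError("observed array length mismatch")
        return observed
    obs_map = dict(zip(observed.names, observed.values))
    missing = [c for c in cols if c not in obs_map]
    if missing:
        raise KeyError(f"observed statistics missing: {missing[:5]}")
    return np.array([obs_map[c] for c in cols])


class _LDAEngine:
    """Reusable fitted pieces: scale, discriminant axes, label layout."""

    def __init__(self, X: np.ndarray, y: np.ndarray, n_classes: int):
        self.scale = mad_scale(X)
        self.Xs = X / self.scale
        self.y = y
        self.n_classes = n_classes
        self.lda = LinearDiscriminantAnalysis(solver="svd")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            self.axes = self.lda.fit_transform(self.Xs, y)

    def project(self, x: np.ndarray) -> np.ndarray:
        return self.lda.transform(np.atleast_2d(x / self.scale))

    def choose(
        self, x_obs: np.ndarray, tolerance: float, with_ci: bool = False
    ) -> tuple[np.ndarray, int, tuple[float, float] | None]:
        xs = x_obs / self.scale
        d = np.linalg.norm(self.Xs - xs, axis=1)
        m = max(2, math.ceil(tolerance * len(d)))
        idx = np.argpartition(d, m - 1)[:m]
        Z = self.axes[idx]
        y_acc = self.y[idx]
        z_obs = self.project(x_obs)
        probs = np.zeros(self.n_classes)
        present = np.unique(y_acc)
        if len(present) == 1:
            probs[present[0]] = 1.0
            logger.debug(
                "only one scenario present among accepted rows; "
                "remaining probabilities reported as 0"
            )
            return probs, m, (1.0, 1.0) if with_ci else None
        if len(present) < self.n_classes:
            logger.debug(
                "%d of %d scenarios absent from the accepted set; their "
                "probabilities are reported as 0",
                self.n_classes - len(present), self.n_classes,
            )
        clf = LogisticRegression(max_iter=2000, C=1e4)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # ridge guard against separation
            clf.fit(Z, y_acc)
        p = clf.predict_proba(z_obs)[0]
        for cls, pv in zip(clf.classes_, p):
            probs[cls] = pv
        ci = None
        if with_ci:
            ci = _best_prob_ci(clf, Z, z_obs, probs)
        return probs, m, ci


def _best_prob_ci(
    clf: LogisticRegression,
    Z: np.ndarray,
    z_obs: np.ndarray,
    probs: np.ndarray,
) -> tuple[float, float]:
    """Approximate 95% interval for the best scenario's probability via the
    multinomial regression's asymptotic (Fisher-information) covariance and
    the delta method. Labeled approximate: the ridge guard and the accepted
    subsample both perturb the asymptotics."""
    P = clf.predict_proba(Z)                      # (m, K)
    Zb = np.hstack([Z, np.ones((len(Z), 1))])     # bias term
    K, D = P.shape[1], Zb.shape[1]
    n_par = K * D
    info = np.zeros((n_par, n_par))
    for i in range(len(Zb)):
        W = np.diag(P[i]) - np.outer(P[i], P[i])
        info += np.kron(W, np.outer(Zb[i], Zb[i]))
    info += 1e-8 * np.eye(n_par)
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        return (float("nan"), float("nan"))
    zb = np.append(z_obs.ravel(), 1.0)
    p_obs = clf.predict_proba(z_obs)[0]
    best = int(np.argmax(p_obs))
    # gradient of p_best wrt the stacked coefficients
    grad = np.zeros(n_par)
    for k in range(K):
        coef = p_obs[best] * ((1.0 if k == best else 0.0) - p_obs[k])
        grad[k * D : (k + 1) * D] = coef * zb
    var = float(grad @ cov @ grad)
    half = 1.96 * math.sqrt(max(var, 0.0))
    pb = float(probs.max())
    return (max(0.0, pb - half), min(1.0, pb + half))


def lda_model_choice(
    table: ReferenceTable,
    observed: StatVector | np.ndarray,
    tolerance: float = 0.01,
    rng_seed: int = 0,
    with_ci: bool = True,
) -> LDAChoiceResult:
    """Posterior scenario probabilities by rejection + logistic regression."""
    if not 0.0 < tolerance <= 1.0:
        raise ValueError("tolerance must lie in (0, 1]")
    if len(table.scenario_names) < 2:
        raise ValueError("model choice needs at least 2 scenarios")
    cols = _base_columns(table)
    X = table.stats[cols].to_numpy()
    engine = _LDAEngine(X, table.scenario_idx, len(table.scenario_names))
    x_obs = _observed_vector(observed, cols)
    probs, m, ci = engine.choose(x_obs, tolerance, with_ci=with_ci)
    if np.any(probs == 0.0):
        warnings.warn(
            "some scenarios are absent from the accepted set; their "
            "probabilities are reported as 0",
            stacklevel=2,
        )
    best = int(np.argmax(probs))
    return LDAChoiceResult(
        scenario_names=list(table.scenario_names),
        probabilities=probs,
        best_scenario=table.scenario_names[best],
        tolerance=tolerance,
        n_accepted=m,
        best_ci=ci,
    )


def prior_error_rate_lda(
    table: ReferenceTable,
    tolerance: float = 0.01,
    n_pseudo: int = 500,
    rng_seed: int = 0,
) -> float:
    """Fraction of pseudo-observed datasets assigned to a wrong scenario.

    ``n_pseudo`` rows are drawn from the table, held out, and classified
    against the remaining rows with the same rejection + regression rule.
    """
    if n_pseudo < 1:
        raise ValueError("n_pseudo must be >= 1")
    n = table.n_rows
    if n_pseudo >= n:
        raise ValueError("n_pseudo must be smaller than the table")
    rng = np.random.default_rng(rng_seed)
    pseudo = rng.choice(n, size=n_pseudo, replace=False)
    mask = np.ones(n, dtype=bool)
    mask[pseudo] = False
    cols = _base_columns(table)
    X = table.stats[cols].to_numpy()
    engine = _LDAEngine(X[mask], table.scenario_idx[mask], len(table.scenario_names))
    wrong = 0
    for i in pseudo:
        probs, _, _ = engine.choose(X[i], tolerance, with_ci=False)
        if int(np.argmax(probs)) != table.scenario_idx[i]:
            wrong += 1
    return wrong / n_pseudo
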