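"""Cross-validated logistic regression over predictor subsets.

The model is a plain multivariate logistic regression for estimated concern:

    logit EC_ij = a0 + sum_k a_k x_kij

fitted by maximum likelihood (Newton/IRLS, no regularisation), evaluated by
K-fold cross-validation with the ROC score (area under the ROC curve) on
pooled out-of-fold predictions, and by AIC (2k - 2 ln L) from the full-data
fit.  Folds are drawn at notification level: the same child can appear in
both training and test folds, which is stated behaviour (each notification
is a distinct decision point); a child-grouped mode is available.

The best-subset search enumerates all models of the form {age + 3 other
predictors} from a variable pool, ranks them by ROC score, and also reports
the full-pool model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score, roc_curve

from .features import EVENT_FEATURES, FEATURE_NAMES, RECORDED_FEATURES, WHOLE_LIFE_FEATURES

logger = logging.getLogger("kinrisk")

VARIABLE_POOLS = {
    "events_only": EVENT_FEATURES,
    "events_plus_recorded": EVENT_FEATURES + RECORDED_FEATURES,
    "all": EVENT_FEATURES + RECORDED_FEATURES + WHOLE_LIFE_FEATURES,
}

SUBSAMPLES = ("all", "first", "subsequent")


class FitError(RuntimeError):
    """Maximum-likelihood fit failed."""


class ConvergenceError(FitError):
    pass


class SeparationError(FitError):
    pass


@dataclass(frozen=True)
class ModelSpec:
    """Which predictors enter the regression, from which pool, on which
    subsample.  Age is always permitted; first-notification specs must not
    contain event-based features (they are all zero there)."""

    predictor_names: tuple[str, ...]
    variable_pool: str = "all"
    subsample: str = "all"

    def __post_init__(self):
        unknown = set(self.predictor_names) - set(FEATURE_NAMES)
        if unknown:
            raise ValueError(f"unknown predictors: {sorted(unknown)}")
        if self.variable_pool not in VARIABLE_POOLS:
            raise ValueError(f"unknown variable_pool {self.variable_pool!r}")
        if self.subsample not in SUBSAMPLES:
            raise ValueError(f"unknown subsample {self.subsample!r}")
        if self.subsample == "first":
            bad = set(self.predictor_names) & set(EVENT_FEATURES)
            if bad:
                raise ValueError(
                    f"event-based predictors {sorted(bad)} are not allowed in "
                    "first-notification models (all zero at the first notification)"
                )
        pool = set(VARIABLE_POOLS[self.variable_pool]) | {"age"}
        outside = set(self.predictor_names) - pool
        if outside:
            raise ValueError(
                f"predictors {sorted(outside)} outside pool {self.variable_pool!r}"
            )

    @property
    def m(self) -> int:
        return len(self.predictor_names)


@dataclass
class ModelResult:
    """Fitted coefficients, out-of-fold scores and model-quality metrics."""

    spec: ModelSpec
    alpha0: float
    alphas: dict[str, float]
    std_errors: dict[str, float]  # includes "(intercept)"
    oof_scores: np.ndarray
    roc_score: float
    aic: float
    loglik: float
    n: int
    K: int
    seed: int
    fold_ids: np.ndarray = field(repr=False, default=None)
    fold_coefs: list = field(repr=False, default=None)

    def to_dict(self) -> dict:
        return {
            "predictors": list(self.spec.predictor_names),
            "variable_pool": self.spec.variable_pool,
            "subsample": self.spec.subsample,
            "alpha0": self.alpha0,
            "alphas": self.alphas,
            "std_errors": self.std_errors,
            "roc_score": self.roc_score,
            "aic": self.aic,
            "loglik": self.loglik,
            "n": self.n,
            "K": self.K,
            "seed": self.seed,
        }


# ---------------------------------------------------------------------------
# Maximum likelihood core
# ---------------------------------------------------------------------------


def logistic_mle(
    X: np.ndarray,
    y: np.ndarray,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> tuple[np.ndarray, float, np.ndarray]:
    """Newton/IRLS fit of a logistic regression with intercept.

    ``X`` is (n, p) *without* an intercept column.  Returns
    ``(beta, loglik, cov)`` where ``beta[0]`` is the intercept and ``cov``
    is the inverse observed information.  Convergence is declared when the
    largest coefficient change drops below ``tol``.
    """
    y = np.asarray(y, dtype=float)
    if y.min() == y.max():
        raise FitError("response has a single class")
    Xd = np.column_stack([np.ones(len(y)), np.asarray(X, dtype=float)])
    p = Xd.shape[1]
    beta = np.zeros(p)
    pbar = y.mean()
    beta[0] = np.log(pbar / (1.0 - pbar))
    for _ in range(max_iter):
        eta = Xd @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1.0 - mu)
        grad = Xd.T @ (y - mu)
        H = (Xd * w[:, None]).T @ Xd
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            # rank-deficient information (collinear/constant columns): the
            # likelihood optimum is still well-defined in the identified
            # subspace; take the minimum-norm Newton step
            logger.debug("singular information matrix; using pseudoinverse step")
            step = np.linalg.pinv(H) @ grad
        if not np.all(np.isfinite(step)):
            raise SeparationError(
                "non-finite Newton step (separating predictors?); "
                "consider penalised estimation — none is applied by default"
            )
        # dampen huge steps for stability
        norm = np.max(np.abs(step))
        if norm > 10.0:
            step *= 10.0 / norm
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            eta = Xd @ beta
            loglik = float(np.sum(y * eta - np.logaddexp(0.0, eta)))
            mu = 1.0 / (1.0 + np.exp(-eta))
            w = mu * (1.0 - mu)
            H = (Xd * w[:, None]).T @ Xd
            try:
                cov = np.linalg.inv(H)
            except np.linalg.LinAlgError:
                cov = np.linalg.pinv(H)
            return beta, loglik, cov
    if np.max(np.abs(beta)) > 30.0:
        raise SeparationError(
            "coefficients diverging: data look completely separated; "
            "consider penalised estimation — none is applied by default"
        )
    raise ConvergenceError(f"IRLS did not converge in {max_iter} iterations")


def aic(loglik: float, n_params: int) -> float:
    """Akaike information criterion 2k - 2 ln L; ``n_params`` counts the
    intercept plus the m predictor coefficients."""
    return 2.0 * n_params - 2.0 * loglik


def roc_score(labels, scores) -> tuple[float, pd.DataFrame]:
    """Area under the ROC curve plus curve points.

    Equals the probability that a random positive case outscores a random
    negative one, with ties counting half.  0.5 is coin-toss performance;
    1.0 is perfect separation.
    """
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    if labels.min() == labels.max():
        raise ValueError("ROC undefined: labels contain a single class")
    auc = float(roc_auc_score(labels, scores))
    fpr, tpr, thr = roc_curve(labels, scores)
    curve = pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})
    return auc, curve


# ---------------------------------------------------------------------------
# Cross-validated fitting
# ---------------------------------------------------------------------------


def make_folds(n: int, K: int, seed: int, groups=None) -> np.ndarray:
    """Random fold assignment with sizes differing by at most one; with
    ``groups`` given, whole groups (children) share a fold."""
    rng = np.random.default_rng(seed)
    if groups is None:
        fold = np.empty(n, dtype=int)
        fold[rng.permutation(n)] = np.arange(n) % K
        return fold
    groups = np.asarray(groups)
    uniq = np.unique(groups)
    gfold = np.empty(len(uniq), dtype=int)
    gfold[rng.permutation(len(uniq))] = np.arange(len(uniq)) % K
    mapping = dict(zip(uniq, gfold))
    return np.array([mapping[g] for g in groups])


def fit_logistic_cv(
    table: pd.DataFrame,
    spec: ModelSpec,
    K: int = 10,
    seed: int = 0,
    grouped: bool = False,
) -> ModelResult:
    """Fit ``spec`` on ``table`` with K-fold cross-validation.

    Out-of-fold predicted probabilities come from per-fold fits; reported
    coefficients, standard errors and AIC come from the full-data fit; the
    ROC score is computed on the pooled out-of-fold predictions.
    """
    cols = list(spec.predictor_names)
    missing = [c for c in cols if c not in table.columns]
    if missing:
        raise ValueError(f"feature matrix lacks columns {missing}")
    X = table[cols].to_numpy(dtype=float)
    y = table["ec"].to_numpy(dtype=float)
    n = len(y)
    if n < 2 * K:
        raise FitError(f"too few cases ({n}) for K={K} cross-validation")

    groups = table["child_id"].to_numpy() if grouped else None
    fold_ids = make_folds(n, K, seed, groups)

    oof = np.empty(n)
    fold_coefs = []
    for k in range(K):
        test = fold_ids == k
        try:
            beta_k, _, _ = logistic_mle(X[~test], y[~test])
        except FitError as exc:
            raise type(exc)(f"fold {k} of spec {cols}: {exc}") from exc
        fold_coefs.append(beta_k)
        eta = beta_k[0] + X[test] @ beta_k[1:]
        oof[test] = 1.0 / (1.0 + np.exp(-eta))

    try:
        beta, loglik, cov = logistic_mle(X, y)
    except FitError as exc:
        raise type(exc)(f"full-data fit of spec {cols}: {exc}") from exc
    se = np.sqrt(np.diag(cov))
    auc, _ = roc_score(y, oof)
    return ModelResult(
        spec=spec,
        alpha0=float(beta[0]),
        alphas={c: float(b) for c, b in zip(cols, beta[1:])},
        std_errors={"(intercept)": float(se[0]), **{c: float(s) for c, s in zip(cols, se[1:])}},
        oof_scores=oof,
        roc_score=auc,
        aic=aic(loglik, len(beta)),
        loglik=loglik,
        n=n,
        K=K,
        seed=seed,
        fold_ids=fold_ids,
        fold_coefs=fold_coefs,
    )


# ---------------------------------------------------------------------------
# Best-subset search
# ---------------------------------------------------------------------------


def select_subsample(table: pd.DataFrame, subsample: str) -> pd.DataFrame:
    if subsample == "all":
        return table
    if subsample == "first":
        return table[table["seq"] == 1].reset_index(drop=True)
    if subsample == "subsequent":
        return table[table["seq"] > 1].reset_index(drop=True)
    raise ValueError(f"unknown subsample {subsample!r}")


def pool_predictors(pool: str, subsample: str) -> list[str]:
    """Non-age candidate predictors for a pool, after subsample rules."""
    preds = list(VARIABLE_POOLS[pool])
    if subsample == "first":
        preds = [p for p in preds if p not in EVENT_FEATURES]
    return preds


def best_subset_search(
    table: pd.DataFrame,
    pool: str = "all",
    subsample: str = "all",
    size_limit: int = 4,
    K: int = 10,
    seed: int = 0,
) -> list[ModelResult]:
    """Exhaustive search over {age + (size_limit-1) others} from ``pool``,
    ranked by ROC score (descending; AIC reported alongside).  The full-pool
    model is appended as the final candidate regardless of rank position of
    the subsets, then the whole list is re-ranked.

    For the first-notifications subsample the event-based features are
    removed from every pool.
    """
    sub = select_subsample(table, subsample)
    candidates = pool_predictors(pool, subsample)
    if not candidates:
        raise ValueError(f"empty predictor pool {pool!r} for subsample {subsample!r}")
    n_other = min(size_limit - 1, len(candidates))
    results: list[ModelResult] = []
    seen: set[tuple] = set()
    for combo in combinations(sorted(candidates), n_other):
        names = ("age",) + combo
        if names in seen:
            continue
        seen.add(names)
        spec = ModelSpec(names, variable_pool=pool, subsample=subsample)
        results.append(fit_logistic_cv(sub, spec, K=K, seed=seed))
    full_names = ("age",) + tuple(sorted(candidates))
    if full_names not in seen:
        spec = ModelSpec(full_names, variable_pool=pool, subsample=subsample)
        results.append(fit_logistic_cv(sub, spec, K=K, seed=seed))
    results.sort(key=lambda r: (-r.roc_score, r.spec.predictor_names))
    return results


def whole_life_comparison(
    table: pd.DataFrame,
    subsample: str,
    size_limit: int = 4,
    K: int = 10,
    seed: int = 0,
) -> dict[str, ModelResult]:
    """Best four-variable model containing at least one whole-life feature
    versus the best containing none (the headline model comparison), plus
    the full model; all from one exhaustive search over the full pool."""
    ranked = best_subset_search(table, "all", subsample, size_limit=size_limit, K=K, seed=seed)
    wl = set(WHOLE_LIFE_FEATURES)
    four_var = [r for r in ranked if r.spec.m <= size_limit]
    with_wl = next(r for r in four_var if wl & set(r.spec.predictor_names))
    without_wl = next(r for r in four_var if not (wl & set(r.spec.predictor_names)))
    full = max((r for r in ranked if r.spec.m > size_limit), default=ranked[0],
               key=lambda r: r.roc_score)
    return {"best_whole_life": with_wl, "best_without_whole_life": without_wl, "full": full}
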