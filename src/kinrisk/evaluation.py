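"""Predictive-bias audit: calibration and error-rate parity across groups.

Gender and ethnicity are never model inputs (the feature matrix has no such
columns, by construction); they are joined back onto the scored cases here,
after fitting, to check that the model is *statistically calibrated* (its
predicted probabilities match observed incidence across the score range) and
that error rates at a common operating threshold are similar across groups.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger("kinrisk")


@dataclass
class AuditReport:
    calibration_bins: pd.DataFrame
    group_metrics: dict[str, pd.DataFrame]
    threshold: float

    def to_dict(self) -> dict:
        return {
            "threshold": self.threshold,
            "calibration_bins": self.calibration_bins.to_dict(orient="records"),
            "group_metrics": {
                attr: df.to_dict(orient="records") for attr, df in self.group_metrics.items()
            },
        }


def _clopper_pearson(k: int, n: int, alpha: float = 0.05) -> tuple[float, float]:
    lo = 0.0 if k == 0 else float(stats.beta.ppf(alpha / 2, k, n - k + 1))
    hi = 1.0 if k == n else float(stats.beta.ppf(1 - alpha / 2, k + 1, n - k))
    return lo, hi


def calibration_table(labels, scores, n_bins: int = 10) -> pd.DataFrame:
    """Equal-frequency calibration bins with exact binomial intervals.

    Columns: ``bin`` index, score range, ``n``, ``mean_predicted``,
    ``observed`` incidence and its 95% Clopper–Pearson interval, and
    ``covered`` — whether the interval contains the mean prediction.  When
    tied scores make fewer than ``n_bins`` distinct quantile edges, bins are
    merged with a warning.
    """
    labels = np.asarray(labels, dtype=float)
    scores = np.asarray(scores, dtype=float)
    if scores.min() < 0.0 or scores.max() > 1.0:
        raise ValueError("scores must be probabilities in [0, 1]")
    binned = pd.qcut(scores, q=n_bins, duplicates="drop")
    if binned.categories.size < n_bins:
        warnings.warn(
            f"only {binned.categories.size} distinct score bins formed "
            f"(requested {n_bins}); tied scores merged",
            stacklevel=2,
        )
    rows = []
    frame = pd.DataFrame({"y": labels, "s": scores, "bin": binned.codes})
    for code, grp in frame.groupby("bin"):
        n = len(grp)
        k = int(grp["y"].sum())
        lo, hi = _clopper_pearson(k, n)
        mean_pred = float(grp["s"].mean())
        rows.append(
            {
                "bin": int(code),
                "score_min": float(grp["s"].min()),
                "score_max": float(grp["s"].max()),
                "n": n,
                "mean_predicted": mean_pred,
                "observed": k / n,
                "ci_low": lo,
                "ci_high": hi,
                "covered": bool(lo <= mean_pred <= hi),
            }
        )
    return pd.DataFrame(rows)


def calibration_in_the_large(labels, scores) -> float:
    """Observed incidence minus mean predicted probability (0 when the model
    is calibrated on average; negative when scores overshoot)."""
    return float(np.mean(labels) - np.mean(scores))


def default_threshold(labels, scores) -> float:
    """Operating point: the score quantile matching the cohort's positive
    rate, so the flagged fraction equals the observed incidence."""
    return float(np.quantile(np.asarray(scores, dtype=float), 1.0 - float(np.mean(labels))))


def _proportion_variance(x: np.ndarray, clusters: np.ndarray | None) -> float:
    """Variance of a sample proportion; with ``clusters`` given, the
    cluster-robust (linearised) variance Σ_c (t_c - n_c p̂)² / n², which
    accounts for correlated outcomes within families/children."""
    n = len(x)
    if n == 0:
        return np.nan
    p = float(x.mean())
    if clusters is None:
        return p * (1 - p) / n
    df = pd.DataFrame({"x": x.astype(float), "c": clusters})
    agg = df.groupby("c")["x"].agg(["sum", "size"])
    resid = agg["sum"] - agg["size"] * p
    return float((resid**2).sum() / n**2)


def group_error_rates(
    labels,
    scores,
    groups,
    threshold: float | None = None,
    alpha: float = 0.05,
    clusters=None,
) -> pd.DataFrame:
    """Per-group ROC score, FPR and FNR at a shared operating threshold.

    Predicted positive means score strictly above the threshold.  For each
    group the difference of its FPR/FNR from the rest of the sample is
    reported with a normal-approximation interval; when ``clusters`` (e.g.
    child or family identifiers) are supplied, cluster-robust variances are
    used, since notifications of related children are correlated.  Groups
    containing a single outcome class have their undefined metrics flagged
    (``defined = False``) and set to NaN.
    """
    labels = np.asarray(labels, dtype=float)
    scores = np.asarray(scores, dtype=float)
    groups = np.asarray(groups)
    clusters = None if clusters is None else np.asarray(clusters)
    if threshold is None:
        threshold = default_threshold(labels, scores)
    pred = scores > threshold
    zcrit = float(stats.norm.ppf(1 - alpha / 2))

    from sklearn.metrics import roc_auc_score

    def rates(y, p, cl):
        neg, pos = y == 0, y == 1
        fpr = float(p[neg].mean()) if neg.any() else np.nan
        fnr = float((~p[pos]).mean()) if pos.any() else np.nan
        var_fpr = _proportion_variance(p[neg], None if cl is None else cl[neg])
        var_fnr = _proportion_variance(~p[pos], None if cl is None else cl[pos])
        return fpr, fnr, int(neg.sum()), int(pos.sum()), var_fpr, var_fnr

    rows = []
    for g in pd.unique(groups):
        sel = groups == g
        y, p, s = labels[sel], pred[sel], scores[sel]
        cl = None if clusters is None else clusters[sel]
        cl_r = None if clusters is None else clusters[~sel]
        defined = y.min() != y.max() if len(y) else False
        fpr, fnr, n_neg, n_pos, v_fpr, v_fnr = rates(y, p, cl)
        roc = float(roc_auc_score(y, s)) if defined else np.nan
        fpr_r, fnr_r, n_neg_r, n_pos_r, v_fpr_r, v_fnr_r = rates(
            labels[~sel], pred[~sel], cl_r
        )
        row = {
            "group": g,
            "n": int(sel.sum()),
            "n_pos": n_pos,
            "n_neg": n_neg,
            "defined": bool(defined),
            "roc_score": roc,
            "fpr": fpr,
            "fnr": fnr,
            "calibration_in_the_large": calibration_in_the_large(y, s),
        }
        for name, a, na, va, b, nb, vb in [
            ("fpr", fpr, n_neg, v_fpr, fpr_r, n_neg_r, v_fpr_r),
            ("fnr", fnr, n_pos, v_fnr, fnr_r, n_pos_r, v_fnr_r),
        ]:
            if np.isnan(a) or np.isnan(b) or na == 0 or nb == 0:
                row[f"{name}_diff"] = np.nan
                row[f"{name}_diff_ci_low"] = np.nan
                row[f"{name}_diff_ci_high"] = np.nan
            else:
                diff = a - b
                se = float(np.sqrt(va + vb))
                row[f"{name}_diff"] = diff
                row[f"{name}_diff_ci_low"] = diff - zcrit * se
                row[f"{name}_diff_ci_high"] = diff + zcrit * se
        rows.append(row)
    out = pd.DataFrame(rows).sort_values("group").reset_index(drop=True)
    n_defined = int(out["defined"].sum())
    if n_defined < 2:
        raise ValueError("need at least two groups with both outcome classes")
    return out


def fairness_audit(
    scored_cases: pd.DataFrame,
    persons: pd.DataFrame,
    attributes: tuple[str, ...] = ("gender", "ethnicity_group"),
    n_bins: int = 10,
    threshold: float | None = None,
) -> AuditReport:
    """Full audit of scored cases: calibration plus per-attribute group
    error rates.  ``scored_cases`` needs ``child_id``, ``ec`` and ``score``
    columns; group labels are joined from the persons table (they are not in
    the feature matrix)."""
    labels = scored_cases["ec"].to_numpy(dtype=float)
    scores = scored_cases["score"].to_numpy(dtype=float)
    if threshold is None:
        threshold = default_threshold(labels, scores)
    lookup = persons.set_index("person_id")
    clusters = scored_cases["child_id"].to_numpy()
    metrics = {}
    for attr in attributes:
        g = scored_cases["child_id"].map(lookup[attr]).fillna("(unknown)").to_numpy()
        metrics[attr] = group_error_rates(
            labels, scores, g, threshold=threshold, clusters=clusters
        )
    return AuditReport(
        calibration_bins=calibration_table(labels, scores, n_bins=n_bins),
        group_metrics=metrics,
        threshold=threshold,
    )
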