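"""Single-split classification trees (depth 1) per predictor.

Fitting a depth-1 tree is finding a threshold for one predictor: cases
strictly above it form the high-risk group, the rest the low-risk group.
The threshold maximises the Gini impurity decrease over candidate midpoints
of sorted unique values (ties broken toward the smaller threshold).  The
follow-up analysis reports, per age bracket, the incidence of high estimated
concern in the high-risk group (the positive predictive value, PPV) and in
the low-risk group (the false omission rate, FOR) — the quantities that show
whether a single network variable usefully separates risk groups, and how
much more so under whole-life than recorded semantics.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .models import make_folds

logger = logging.getLogger("kinrisk")


@dataclass(frozen=True)
class AgeBracketIncidence:
    bracket: tuple[int, int]  # inclusive completed-years range
    n_high: int
    n_low: int
    ppv: float | None  # None when the high-risk group is empty
    false_omission_rate: float | None

    def to_dict(self) -> dict:
        return {
            "bracket": list(self.bracket),
            "n_high": self.n_high,
            "n_low": self.n_low,
            "ppv": self.ppv,
            "false_omission_rate": self.false_omission_rate,
        }


@dataclass(frozen=True)
class StumpResult:
    predictor_name: str
    threshold: float
    gini_decrease: float
    high_risk_proportion: float
    fold_thresholds: tuple[float, ...] = ()
    per_age_bracket: tuple[AgeBracketIncidence, ...] | None = None

    def to_dict(self) -> dict:
        return {
            "predictor": self.predictor_name,
            "threshold": self.threshold,
            "gini_decrease": self.gini_decrease,
            "high_risk_proportion": self.high_risk_proportion,
            "fold_thresholds": list(self.fold_thresholds),
            "per_age_bracket": None
            if self.per_age_bracket is None
            else [b.to_dict() for b in self.per_age_bracket],
        }


def gini_split(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Best single split of ``x`` by Gini impurity decrease.

    Candidates are midpoints of consecutive sorted unique values; the
    high-risk side is strictly above the threshold.  Returns
    ``(threshold, impurity_decrease)``; ties go to the smaller threshold.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    order = np.argsort(x, kind="mergesort")
    xs, ys = x[order], y[order]
    # boundaries between runs of equal values
    change = np.nonzero(np.diff(xs))[0]  # split after index i: left = xs[:i+1]
    if len(change) == 0:
        raise ValueError("constant predictor: no split candidates")
    n = len(xs)
    cum_pos = np.cumsum(ys)
    n_left = change + 1
    pos_left = cum_pos[change]
    n_right = n - n_left
    pos_right = cum_pos[-1] - pos_left
    p_l = pos_left / n_left
    p_r = pos_right / n_right
    gini_l = 2.0 * p_l * (1.0 - p_l)
    gini_r = 2.0 * p_r * (1.0 - p_r)
    p = cum_pos[-1] / n
    parent = 2.0 * p * (1.0 - p)
    decrease = parent - (n_left * gini_l + n_right * gini_r) / n
    best = int(np.argmax(decrease))  # first maximum -> smallest threshold
    threshold = (xs[change[best]] + xs[change[best] + 1]) / 2.0
    return float(threshold), float(decrease[best])


def fit_stump(
    table: pd.DataFrame,
    predictor: str,
    K: int = 10,
    seed: int = 0,
) -> StumpResult:
    """Fit a depth-1 tree on one predictor with estimated concern as the
    response.  Also refits on each of K training folds; with large samples
    all folds normally produce the identical threshold — any disagreement is
    reported as a warning and retained in ``fold_thresholds``."""
    if predictor not in table.columns:
        raise ValueError(f"feature matrix lacks column {predictor!r}")
    x = table[predictor].to_numpy(dtype=float)
    y = table["ec"].to_numpy(dtype=float)
    if len(np.unique(x)) < 2:
        raise ValueError(f"constant predictor {predictor!r}")
    threshold, decrease = gini_split(x, y)

    fold_thresholds = []
    if K > 1 and len(x) >= 2 * K:
        fold_ids = make_folds(len(x), K, seed)
        for k in range(K):
            train = fold_ids != k
            try:
                t_k, _ = gini_split(x[train], y[train])
            except ValueError:
                t_k = float("nan")
            fold_thresholds.append(t_k)
        distinct = {t for t in fold_thresholds if not np.isnan(t)}
        if len(distinct) > 1 or (distinct and distinct != {threshold}):
            warnings.warn(
                f"stump for {predictor!r}: cross-validated thresholds disagree "
                f"({sorted(distinct)}); full-data threshold {threshold} used",
                stacklevel=2,
            )

    return StumpResult(
        predictor_name=predictor,
        threshold=threshold,
        gini_decrease=decrease,
        high_risk_proportion=float((x > threshold).mean()),
        fold_thresholds=tuple(fold_thresholds),
    )


def default_age_brackets(max_age: int = 16) -> list[tuple[int, int]]:
    """Single completed years 0..max_age-1 (bracket edges are a config
    input; single years are the default)."""
    return [(a, a) for a in range(max_age)]


def risk_group_incidence(
    table: pd.DataFrame,
    stump: StumpResult,
    age_brackets: list[tuple[int, int]] | None = None,
) -> StumpResult:
    """Fill ``per_age_bracket``: incidence of high estimated concern in the
    high-risk (PPV) and low-risk (FOR) groups within each age bracket.
    Empty brackets/groups are emitted with size 0 and incidence ``None``."""
    if age_brackets is None:
        age_brackets = default_age_brackets()
    x = table[stump.predictor_name].to_numpy(dtype=float)
    y = table["ec"].to_numpy(dtype=float)
    age = table["age"].to_numpy(dtype=float)
    high = x > stump.threshold
    out = []
    for lo, hi in age_brackets:
        sel = (age >= lo) & (age <= hi)
        h = sel & high
        l = sel & ~high
        n_h, n_l = int(h.sum()), int(l.sum())
        out.append(
            AgeBracketIncidence(
                bracket=(lo, hi),
                n_high=n_h,
                n_low=n_l,
                ppv=float(y[h].mean()) if n_h else None,
                false_omission_rate=float(y[l].mean()) if n_l else None,
            )
        )
    return replace(
        stump,
        per_age_bracket=tuple(out),
        high_risk_proportion=float(high.mean()),
    )
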