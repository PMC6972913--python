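"""Validation metrics and method comparison.

Prediction accuracy is the Pearson correlation between true and predicted
breeding values of validation animals; bias is the slope of the regression
of true on predicted values (1 = unbiased); prediction-error variance
(PEV) is the per-animal variance of posterior breeding-value samples.
Methods are compared with two-sided paired t-tests across replicates,
Bonferroni-corrected within each comparison family, with compact letter
grouping.
"""

from __future__ import annotations

from itertools import combinations
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "accuracy",
    "bias_slope",
    "pev_from_chain",
    "compare_methods",
    "aggregate_results",
]


def _paired(tbv, gebv):
    tbv = np.asarray(tbv, dtype=float)
    gebv = np.asarray(gebv, dtype=float)
    if tbv.shape != gebv.shape or tbv.ndim != 1:
        raise ValueError("tbv and gebv must be 1-D vectors of equal length")
    if tbv.size < 3:
        raise ValueError("need at least 3 validation animals")
    return tbv, gebv


def accuracy(tbv, gebv) -> float:
    """Pearson correlation between true and predicted breeding values."""
    tbv, gebv = _paired(tbv, gebv)
    if tbv.std() == 0 or gebv.std() == 0:
        raise ValueError("zero variance in tbv or gebv")
    return float(np.corrcoef(tbv, gebv)[0, 1])


def bias_slope(tbv, gebv) -> float:
    """Slope of the regression of TBV on GEBV (cov / var of predictions)."""
    tbv, gebv = _paired(tbv, gebv)
    v = gebv.var(ddof=1)
    if v == 0:
        raise ValueError("zero variance in gebv")
    c = np.cov(tbv, gebv, ddof=1)[0, 1]
    return float(c / v)


def pev_from_chain(gebv_samples: np.ndarray) -> np.ndarray:
    """Per-animal prediction-error variance from posterior GEBV draws.

    ``gebv_samples`` is (n_samples, n_animals); the sample variance uses
    the n-1 denominator. Summarize with ``.mean()`` over animals.
    """
    g = np.asarray(gebv_samples, dtype=float)
    if g.ndim != 2 or g.shape[0] < 2:
        raise ValueError("need at least 2 posterior samples per animal")
    return g.var(axis=0, ddof=1)


def _letter_groups(labels, sig: np.ndarray) -> dict:
    """Greedy compact-letter display: walk methods in order, reuse a letter
    when not significantly different from every current member."""
    groups = []  # list of sets of label indices
    m = len(labels)
    for i in range(m):
        placed = False
        for g in groups:
            if all(not sig[i, j] for j in g):
                g.add(i)
                placed = True
        if not placed:
            groups.append({i})
    letters = {lab: "" for lab in labels}
    for gi, g in enumerate(groups):
        ch = chr(ord("a") + gi)
        for i in sorted(g):
            letters[labels[i]] += ch
    return letters


def compare_methods(results: pd.DataFrame, alpha: float = 0.05,
                    value: str = "accuracy",
                    family: tuple = ("trait", "group")) -> pd.DataFrame:
    """All pairwise two-sided paired t-tests between methods.

    ``results`` is tidy with columns ``replicate``, ``method``, ``trait``,
    ``group`` (animal subset) and the metric column ``value``. Within each
    comparison family (default: one per trait x animal-group) every method
    pair is tested with accuracies paired by replicate, and the Bonferroni
    threshold is ``alpha / n_pairs`` for that family. The returned frame
    has one row per pair plus per-method letter groups.
    """
    req = {"replicate", "method", value} | set(family)
    missing = req - set(results.columns)
    if missing:
        raise ValueError(f"results frame lacks columns {sorted(missing)}")
    rows = []
    for key, sub in results.groupby(list(family)):
        methods = sorted(sub["method"].unique())
        pairs = list(combinations(methods, 2))
        if not pairs:
            continue
        thr = alpha / len(pairs)
        wide = sub.pivot_table(index="replicate", columns="method",
                               values=value)
        if wide.isna().any().any():
            raise ValueError(f"unpaired replicates in family {key}")
        if len(wide) < 2:
            raise ValueError("need at least 2 replicates for paired tests")
        m = len(methods)
        sig = np.zeros((m, m), dtype=bool)
        stats_rows = []
        for (a, b) in pairs:
            d = wide[a] - wide[b]
            if np.allclose(d, 0):
                t, p = 0.0, 1.0
            else:
                t, p = stats.ttest_rel(wide[a], wide[b])
            s = p < thr
            ia, ib = methods.index(a), methods.index(b)
            sig[ia, ib] = sig[ib, ia] = s
            stats_rows.append((a, b, float(wide[a].mean()),
                               float(wide[b].mean()), float(t), float(p),
                               thr, bool(s)))
        letters = _letter_groups(methods, sig)
        for (a, b, ma, mb, t, p, th, s) in stats_rows:
            rec = dict(zip(family, key if isinstance(key, tuple) else (key,)))
            rec.update(method_a=a, method_b=b, mean_a=ma, mean_b=mb,
                       t_stat=t, p_value=p, threshold=th, significant=s,
                       letters_a=letters[a], letters_b=letters[b])
            rows.append(rec)
    return pd.DataFrame(rows)


def aggregate_results(results: pd.DataFrame,
                      value: str = "accuracy") -> pd.DataFrame:
    """Mean and standard error of a metric over replicates, per
    method/trait/animal-group cell."""
    g = results.groupby(["method", "trait", "group"])[value]
    out = g.agg(mean="mean", sd="std", n="count").reset_index()
    out["se"] = out["sd"] / np.sqrt(out["n"])
    return out
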