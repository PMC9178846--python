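"""Negative-binomial Wald differential expression for replicate groups.

A transparent two-group NB Wald test: per-gene dispersion by a pooled
method-of-moments estimate, log2 fold change on pseudo-counted normalized
group means, a delta-method standard error from the NB variance function
``Var = mu + alpha mu^2``, a Student-t reference for the Wald statistic,
Benjamini–Hochberg adjustment and the calling
thresholds FDR < 0.05 and \\|log2FC\\| > 1 (strict, as published). No
dispersion or fold-change shrinkage and no independent filtering, so the
whole path is auditable; externally produced DE tables with the same
columns can be substituted anywhere downstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .expression import compute_size_factors, filter_expressed

DISPERSION_FLOOR = 1e-8
_LN2 = np.log(2.0)


@dataclass
class Contrast:
    """Two disjoint sample groups; fold changes are group_a over group_b."""

    group_a: Sequence[str]
    group_b: Sequence[str]
    label: str = ""

    def validate(self) -> None:
        if len(self.group_a) < 2 or len(self.group_b) < 2:
            raise ValueError("each contrast group needs >= 2 replicates")
        if set(self.group_a) & set(self.group_b):
            raise ValueError("contrast groups must be disjoint")


def estimate_dispersion(groups: Sequence[np.ndarray], floor: float = DISPERSION_FLOOR) -> float:
    """Pooled method-of-moments NB dispersion for one gene.

    Within-group variances (ddof=1) are pooled by their degrees of
    freedom, the mean is the replicate-weighted mean of group means, and
    ``alpha = max(floor, (s2 - m) / m^2)``; under-dispersed genes clamp to
    the floor.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    ns = np.array([len(g) for g in groups])
    if (ns < 2).any():
        raise ValueError("each group needs >= 2 replicates")
    means = np.array([g.mean() for g in groups])
    variances = np.array([g.var(ddof=1) for g in groups])
    s2 = np.sum((ns - 1) * variances) / np.sum(ns - 1)
    m = np.sum(ns * means) / np.sum(ns)
    if m <= 0:
        raise ValueError("zero mean in all groups: gene is untestable")
    return float(max(floor, (s2 - m) / m**2))


def _nb_wald_core(
    Xa: np.ndarray,
    Xb: np.ndarray,
    pseudocount: float = 0.5,
    floor: float = DISPERSION_FLOOR,
) -> pd.DataFrame:
    """Vectorized NB Wald test: rows of Xa/Xb are replicates, columns genes.

    The Wald statistic is referred to a Student t distribution on
    n_a + n_b - 2 degrees of freedom rather than a normal: the standard
    error is a plug-in estimate from few replicates, and the t reference
    keeps the type-I error at its nominal level (the normal reference is
    measurably anticonservative at n <= 10 per group).
    """
    na, nb = Xa.shape[0], Xb.shape[0]
    ma, mb = Xa.mean(axis=0), Xb.mean(axis=0)
    s2a, s2b = Xa.var(axis=0, ddof=1), Xb.var(axis=0, ddof=1)
    s2 = ((na - 1) * s2a + (nb - 1) * s2b) / (na + nb - 2)
    m = (na * ma + nb * mb) / (na + nb)
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = np.where(m > 0, np.maximum((s2 - m) / np.maximum(m, 1e-300) ** 2, floor), floor)
    c = pseudocount
    lfc = np.log2((ma + c) / (mb + c))
    var_ma = (ma + alpha * ma**2) / na
    var_mb = (mb + alpha * mb**2) / nb
    se = np.sqrt(var_ma / (ma + c) ** 2 + var_mb / (mb + c) ** 2) / _LN2
    untestable = (ma == 0) & (mb == 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, lfc / se, 0.0)
    p = 2.0 * stats.t.sf(np.abs(z), df=na + nb - 2)
    lfc = np.where(untestable, 0.0, lfc)
    se = np.where(untestable, np.inf, se)
    p = np.where(untestable, 1.0, p)
    return pd.DataFrame({"log2fc": lfc, "se": se, "p": p})


def adjust_bh(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values with monotone enforcement.

    Ties are handled stably; NaN p-values propagate to NaN q-values (with
    a warning giving their count) and do not enter the adjustment.
    """
    p = np.asarray(p_values, dtype=float)
    finite = ~np.isnan(p)
    if ((p[finite] < 0) | (p[finite] > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    q = np.full(p.shape, np.nan)
    m = int(finite.sum())
    if m:
        pm = p[finite]
        order = np.argsort(pm, kind="stable")
        ranked = pm[order] * m / np.arange(1, m + 1)
        qs = np.minimum(np.minimum.accumulate(ranked[::-1])[::-1], 1.0)
        out = np.empty(m)
        out[order] = qs
        q[finite] = out
    n_nan = int((~finite).sum())
    if n_nan:
        warnings.warn(f"adjust_bh: {n_nan} NaN p-values propagated", RuntimeWarning)
    return q


def call_degs(result: pd.DataFrame, alpha: float = 0.05, lfc_min: float = 1.0) -> pd.Series:
    """Up/down/ns calls at FDR < alpha and |log2FC| > lfc_min (both strict)."""
    q = result["q"].to_numpy(dtype=float)
    lfc = result["log2fc"].to_numpy(dtype=float)
    calls = np.full(len(result), "ns", dtype=object)
    with np.errstate(invalid="ignore"):
        sig = q < alpha
        calls[sig & (lfc > lfc_min)] = "up"
        calls[sig & (lfc < -lfc_min)] = "down"
    return pd.Series(calls, index=result.index, name="call")


class NBWaldDE(BaseEstimator):
    """Two-group negative-binomial Wald differential expression test.

    scikit-learn style estimator. ``fit(X, y)`` takes a samples × genes
    matrix of *normalized* counts (DataFrame or array) and a length-n_samples
    group label vector with exactly two levels; fold changes are the first
    label encountered over the second unless ``groups`` fixes the order.

    Attributes (after fit): ``results_`` — per-gene DataFrame with columns
    ``log2fc, se, p, q, call``.
    """

    def __init__(
        self,
        alpha: float = 0.05,
        lfc_min: float = 1.0,
        pseudocount: float = 0.5,
        dispersion_floor: float = DISPERSION_FLOOR,
        groups: tuple | None = None,
    ):
        self.alpha = alpha
        self.lfc_min = lfc_min
        self.pseudocount = pseudocount
        self.dispersion_floor = dispersion_floor
        self.groups = groups

    def fit(self, X, y):
        if isinstance(X, pd.DataFrame):
            genes = X.columns
            Xv = X.to_numpy(dtype=float)
        else:
            Xv = np.asarray(X, dtype=float)
            genes = pd.RangeIndex(Xv.shape[1])
        y = np.asarray(y)
        if len(y) != Xv.shape[0]:
            raise ValueError("y must have one label per sample (row of X)")
        levels = list(dict.fromkeys(y)) if self.groups is None else list(self.groups)
        if len(levels) != 2 or not set(levels) == set(np.unique(y)):
            raise ValueError("y must contain exactly the two group labels")
        a, b = levels
        res = _nb_wald_core(
            Xv[y == a], Xv[y == b], self.pseudocount, self.dispersion_floor
        )
        res.index = genes
        res["q"] = adjust_bh(res["p"].to_numpy())
        res["call"] = call_degs(res, self.alpha, self.lfc_min)
        self.results_ = res
        self.n_features_in_ = Xv.shape[1]
        self.group_labels_ = (a, b)
        return self


def wald_test_contrast(
    counts: pd.DataFrame,
    contrast: Contrast,
    size_factors: pd.Series,
    alpha: float = 0.05,
    lfc_min: float = 1.0,
) -> pd.DataFrame:
    """Run the NB Wald test for one contrast of a genes × samples count matrix."""
    contrast.validate()
    missing = (set(contrast.group_a) | set(contrast.group_b)) - set(counts.columns)
    if missing:
        raise KeyError(f"samples not in count matrix: {sorted(missing)}")
    norm = counts / size_factors.reindex(counts.columns)
    samples = list(contrast.group_a) + list(contrast.group_b)
    y = np.array(["a"] * len(contrast.group_a) + ["b"] * len(contrast.group_b))
    est = NBWaldDE(alpha=alpha, lfc_min=lfc_min, groups=("a", "b"))
    est.fit(norm[samples].T, y)
    res = est.results_
    res.index = counts.index
    res.index.name = "gene_id"
    return res


def run_cross_contrasts(
    counts: pd.DataFrame,
    sheet: pd.DataFrame,
    cross: str,
    timepoint: str,
    alpha: float = 0.05,
    lfc_min: float = 1.0,
    expressed_threshold: int = 30,
) -> dict[str, pd.DataFrame]:
    """The three triplet contrasts (H vs F, H vs M, F vs M) for one cross/timepoint.

    Size factors and the expressed-gene filter are computed on the triplet's
    own samples; results are returned over the expressed-gene set, keyed
    ``"HvsF", "HvsM", "FvsM"``.
    """
    sel = sheet[(sheet["cross"] == cross) & (sheet["timepoint"] == timepoint)]
    by_role = {role: list(grp["sample_id"]) for role, grp in sel.groupby("role")}
    for role in ("female_parent", "male_parent", "hybrid"):
        if role not in by_role:
            raise ValueError(f"cross {cross!r} at {timepoint!r} is missing role {role!r}")
    samples = [s for role in by_role for s in by_role[role]]
    sub = counts[[s for s in counts.columns if s in set(samples)]]
    size_factors = compute_size_factors(sub)
    expressed = filter_expressed(sub, sel, threshold=expressed_threshold)
    sub = sub.loc[expressed]
    F, M, H = by_role["female_parent"], by_role["male_parent"], by_role["hybrid"]
    contrasts = {
        "HvsF": Contrast(H, F, "HvsF"),
        "HvsM": Contrast(H, M, "HvsM"),
        "FvsM": Contrast(F, M, "FvsM"),
    }
    return {
        label: wald_test_contrast(sub, con, size_factors, alpha, lfc_min)
        for label, con in contrasts.items()
    }


def deg_counts(results: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Up/down DEG counts per contrast (the bar-chart analogue)."""
    rows = [
        {
            "contrast": label,
            "up": int((res["call"] == "up").sum()),
            "down": int((res["call"] == "down").sum()),
        }
        for label, res in results.items()
    ]
    return pd.DataFrame(rows).set_index("contrast")


def read_de_table(path) -> pd.DataFrame:
    """Import an externally produced DE table (gene_id, log2fc, p and/or q).

    Missing q-values are BH-adjusted from p; calls are (re)derived with the
    default thresholds if absent.
    """
    df = pd.read_csv(path, sep="\t").set_index("gene_id")
    if "q" not in df.columns:
        df["q"] = adjust_bh(df["p"].to_numpy())
    if "call" not in df.columns:
        df["call"] = call_degs(df)
    return df
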