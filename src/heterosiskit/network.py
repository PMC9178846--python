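"""Weighted co-expression network: soft threshold, adjacency, topological
overlap, module detection, eigengenes, module–trait correlation and
KME-based hub genes.

The workflow mirrors the standard weighted-correlation-network recipe:
raise absolute (or signed) Pearson correlations to a soft-threshold power
chosen for approximate scale-free topology, convert to a topological
overlap measure (TOM), cluster genes by average-linkage on 1 - TOM with a
static cut, merge modules whose eigengenes are highly correlated, and
summarize each module by its eigengene (first principal component).
Module membership (KME) is the correlation of a gene's profile with its
own module eigengene, with a Student-t p-value on n - 2 degrees of
freedom.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.base import BaseEstimator


def _as_expr(expr) -> tuple[np.ndarray, pd.Index, pd.Index]:
    """Coerce samples × genes input to (array, sample index, gene index)."""
    if isinstance(expr, pd.DataFrame):
        return expr.to_numpy(dtype=float), expr.index, expr.columns
    X = np.asarray(expr, dtype=float)
    return X, pd.RangeIndex(X.shape[0]), pd.RangeIndex(X.shape[1])


def _cor_pvalue(r: np.ndarray, n: int) -> np.ndarray:
    """Two-sided Student p for a Pearson correlation on n - 2 df."""
    r = np.clip(np.asarray(r, dtype=float), -1.0, 1.0)
    df = n - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt(df / np.maximum(1.0 - r**2, 1e-300))
    return 2.0 * stats.t.sf(np.abs(t), df)


def _scale_free_fit(k: np.ndarray, n_bins: int = 10) -> float:
    """R^2 of log10(frequency) vs log10(connectivity) over linear bins.

    The fit index is 0 when the slope is non-negative (a scale-free degree
    distribution must decay).
    """
    k = k[k > 0]
    if len(k) < n_bins:
        return 0.0
    edges = np.linspace(k.min(), k.max() + 1e-12, n_bins + 1)
    which = np.clip(np.digitize(k, edges) - 1, 0, n_bins - 1)
    log_k, log_f = [], []
    for b in range(n_bins):
        mask = which == b
        if mask.sum() == 0:
            continue
        log_k.append(np.log10(k[mask].mean()))
        log_f.append(np.log10(mask.sum() / len(k)))
    if len(log_k) < 3:
        return 0.0
    slope, _, r, _, _ = stats.linregress(log_k, log_f)
    return float(r**2) if slope < 0 else 0.0


def _corrcoef_genes(expr) -> tuple[np.ndarray, pd.Index]:
    X, _, genes = _as_expr(expr)
    sd = X.std(axis=0)
    keep = sd > 0
    if not keep.all():
        warnings.warn(
            f"dropping {int((~keep).sum())} constant-expression genes", RuntimeWarning
        )
        X, genes = X[:, keep], genes[keep]
    return np.corrcoef(X.T), genes


def pick_soft_threshold(
    expr,
    candidates: Sequence[int] = range(1, 21),
    rsq_target: float = 0.8,
    n_bins: int = 10,
) -> int:
    """Smallest power giving scale-free fit R^2 >= target, else the argmax.

    Connectivity at power beta is ``k_i = sum_j |cor_ij|^beta`` (diagonal
    excluded); the fit regresses log10 bin frequency on log10 mean bin
    connectivity over ``n_bins`` linear bins.
    """
    X, _, _ = _as_expr(expr)
    if X.shape[1] < 20 or X.shape[0] < 4:
        raise ValueError("need >= 20 genes and >= 4 samples to pick a soft threshold")
    C, _ = _corrcoef_genes(expr)
    A0 = np.abs(C)
    fits = {}
    for beta in candidates:
        k = (A0**beta).sum(axis=0) - 1.0
        fits[beta] = _scale_free_fit(k, n_bins)
        if fits[beta] >= rsq_target:
            return int(beta)
    return int(max(fits, key=fits.get))


def build_adjacency(expr, beta: float, signed: bool = False) -> pd.DataFrame:
    """Soft-thresholded adjacency ``|cor|^beta`` (or ``((1+cor)/2)^beta`` signed)."""
    if beta < 1:
        raise ValueError("beta must be >= 1")
    X, _, genes = _as_expr(expr)
    sd = X.std(axis=0)
    if (sd == 0).any():
        bad = list(genes[sd == 0][:10])
        raise ValueError(f"zero-variance genes: {bad}")
    C = np.corrcoef(X.T)
    A = ((1.0 + C) / 2.0) ** beta if signed else np.abs(C) ** beta
    np.fill_diagonal(A, 1.0)
    return pd.DataFrame(A, index=genes, columns=genes)


def compute_tom(adjacency) -> np.ndarray:
    """Topological overlap matrix.

    ``TOM_ij = (sum_{u != i,j} a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij)``
    with connectivity k excluding the diagonal; TOM_ii = 1.
    """
    A = np.asarray(adjacency, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("adjacency must be square")
    if not np.allclose(A, A.T, atol=1e-10):
        raise ValueError("adjacency must be symmetric")
    if not np.allclose(np.diag(A), 1.0):
        raise ValueError("adjacency diagonal must be 1")
    k = A.sum(axis=0) - 1.0
    numerator = A @ A - A  # = sum_{u != i,j} a_iu a_uj + a_ij   (diag 1)
    denominator = np.minimum.outer(k, k) + 1.0 - A
    with np.errstate(divide="ignore", invalid="ignore"):
        tom = np.where(denominator > 0, numerator / denominator, 0.0)
    np.fill_diagonal(tom, 1.0)
    return tom


def _relabel_by_size(labels: np.ndarray, min_module_size: int) -> np.ndarray:
    """Drop undersized clusters to 0 and relabel survivors 1..k by size."""
    out = np.zeros(len(labels), dtype=int)
    uniq, counts = np.unique(labels[labels > 0], return_counts=True)
    keep = [(c, u) for u, c in zip(uniq, counts) if c >= min_module_size]
    for new, (_, old) in enumerate(sorted(keep, reverse=True), start=1):
        out[labels == old] = new
    return out


def detect_modules(
    tom: np.ndarray,
    min_module_size: int = 30,
    cut_height_fraction: float = 0.99,
    merge_cor: float = 0.75,
    expr=None,
) -> np.ndarray:
    """Average-linkage modules on 1 - TOM with a static cut.

    The tree is cut at ``cut_height_fraction x`` the maximum merge height;
    clusters below ``min_module_size`` become unassigned (label 0). When
    ``expr`` (samples × genes, same gene order as the TOM) is given,
    modules whose eigengenes correlate above ``merge_cor`` are merged
    iteratively. Returns integer labels, 0 = unassigned.
    """
    tom = np.asarray(tom, dtype=float)
    n = tom.shape[0]
    if n < min_module_size:
        warnings.warn("fewer genes than min_module_size: all unassigned", RuntimeWarning)
        return np.zeros(n, dtype=int)
    D = 1.0 - (tom + tom.T) / 2.0
    np.fill_diagonal(D, 0.0)
    D = np.clip(D, 0.0, None)
    Z = linkage(squareform(D, checks=False), method="average")
    cut = cut_height_fraction * Z[:, 2].max()
    raw = fcluster(Z, t=cut, criterion="distance")
    labels = _relabel_by_size(raw, min_module_size)
    if expr is not None:
        labels = _merge_close_modules(expr, labels, merge_cor)
        labels = _relabel_by_size(labels, min_module_size)
    return labels


def _merge_close_modules(expr, labels: np.ndarray, merge_cor: float) -> np.ndarray:
    """Iteratively merge the most correlated eigengene pair above the cutoff."""
    labels = labels.copy()
    while True:
        me = module_eigengenes(expr, labels)
        if me.shape[1] < 2:
            return labels
        cm = np.corrcoef(me.to_numpy().T)
        np.fill_diagonal(cm, -np.inf)
        i, j = np.unravel_index(np.argmax(cm), cm.shape)
        if cm[i, j] <= merge_cor:
            return labels
        mod_i = int(me.columns[i].removeprefix("ME"))
        mod_j = int(me.columns[j].removeprefix("ME"))
        labels[labels == mod_j] = mod_i


def module_eigengenes(expr, labels: np.ndarray) -> pd.DataFrame:
    """Unit-norm first principal component of each module's standardized profiles.

    Columns are named ``ME<label>``; the sign is fixed so each eigengene
    correlates positively with the module's mean expression profile. A
    single-gene module's eigengene is its standardized (unit-norm) profile.
    """
    X, samples, _ = _as_expr(expr)
    labels = np.asarray(labels, dtype=int)
    if len(labels) != X.shape[1]:
        raise ValueError("labels must have one entry per gene (column of expr)")
    cols = {}
    for mod in sorted(set(labels) - {0}):
        sub = X[:, labels == mod]
        mu, sd = sub.mean(axis=0), sub.std(axis=0)
        Zs = (sub - mu) / np.where(sd > 0, sd, 1.0)
        U, S, _ = np.linalg.svd(Zs, full_matrices=False)
        e = U[:, 0]
        profile = sub.mean(axis=1)
        if profile.std() > 0:
            r = np.corrcoef(e, profile)[0, 1]
            if r < 0:
                e = -e
        cols[f"ME{mod}"] = e
    return pd.DataFrame(cols, index=samples)


def module_membership(expr, labels: np.ndarray, eigengenes: pd.DataFrame) -> pd.DataFrame:
    """KME (gene vs own-module eigengene correlation) with its p-value.

    Unassigned genes (label 0) are excluded.
    """
    X, _, genes = _as_expr(expr)
    labels = np.asarray(labels, dtype=int)
    n = X.shape[0]
    rows = []
    for g in range(X.shape[1]):
        mod = labels[g]
        if mod == 0:
            continue
        e = eigengenes[f"ME{mod}"].to_numpy()
        x = X[:, g]
        if x.std() == 0 or e.std() == 0:
            kme, p = np.nan, np.nan
        else:
            kme = float(np.corrcoef(x, e)[0, 1])
            p = float(_cor_pvalue(np.array([kme]), n)[0])
        rows.append({"gene": genes[g], "module": mod, "kme": kme, "p": p})
    return pd.DataFrame(rows).set_index("gene")


def module_trait_correlation(eigengenes: pd.DataFrame, trait) -> pd.DataFrame:
    """Pearson r (with Student p on n - 2 df) of each eigengene vs a trait."""
    t = np.asarray(trait, dtype=float)
    n = len(t)
    if n != len(eigengenes):
        raise ValueError("trait must align with the eigengene samples")
    if n < 4:
        raise ValueError("need >= 4 samples")
    rows = []
    for col in eigengenes.columns:
        e = eigengenes[col].to_numpy()
        if t.std() == 0 or e.std() == 0:
            r, p = np.nan, np.nan
        else:
            r = float(np.corrcoef(e, t)[0, 1])
            p = float(_cor_pvalue(np.array([r]), n)[0])
        rows.append({"module": col, "r": r, "p": p})
    return pd.DataFrame(rows).set_index("module")


def hub_genes(
    expr,
    labels: np.ndarray,
    eigengenes: pd.DataFrame,
    kme_min: float = 0.90,
    p_max: float = 1e-6,
) -> pd.DataFrame:
    """Hub genes: KME > kme_min and p < p_max (both strict)."""
    kme = module_membership(expr, labels, eigengenes)
    return kme[(kme["kme"] > kme_min) & (kme["p"] < p_max)]


class CoexpressionNetwork(BaseEstimator):
    """End-to-end weighted co-expression network estimator.

    ``fit(X)`` takes a samples × genes expression frame (typically
    log2(TPM + 1) of differentially expressed genes), drops
    constant-expression genes, picks the soft threshold when ``beta`` is
    None, builds adjacency and TOM, detects and merges modules and
    computes eigengenes and module membership.

    Attributes (after fit): ``genes_``, ``beta_``, ``adjacency_``,
    ``tom_``, ``labels_`` (Series gene → module id, 0 = unassigned),
    ``eigengenes_`` (samples × ME columns) and ``kme_``.
    """

    def __init__(
        self,
        beta: int | None = None,
        signed: bool = False,
        min_module_size: int = 30,
        cut_height_fraction: float = 0.99,
        merge_cor: float = 0.75,
    ):
        self.beta = beta
        self.signed = signed
        self.min_module_size = min_module_size
        self.cut_height_fraction = cut_height_fraction
        self.merge_cor = merge_cor

    def fit(self, X, y=None):
        Xv, samples, genes = _as_expr(X)
        sd = Xv.std(axis=0)
        keep = sd > 0
        if not keep.all():
            warnings.warn(
                f"dropping {int((~keep).sum())} constant-expression genes",
                RuntimeWarning,
            )
        Xv, genes = Xv[:, keep], genes[keep]
        expr = pd.DataFrame(Xv, index=samples, columns=genes)
        self.beta_ = (
            int(self.beta) if self.beta is not None else pick_soft_threshold(expr)
        )
        self.adjacency_ = build_adjacency(expr, self.beta_, self.signed)
        self.tom_ = compute_tom(self.adjacency_.to_numpy())
        labels = detect_modules(
            self.tom_,
            self.min_module_size,
            self.cut_height_fraction,
            self.merge_cor,
            expr=expr,
        )
        self.genes_ = genes
        self.labels_ = pd.Series(labels, index=genes, name="module")
        self.eigengenes_ = module_eigengenes(expr, labels)
        self.kme_ = module_membership(expr, labels, self.eigengenes_)
        self._expr = expr
        return self

    @property
    def n_modules_(self) -> int:
        return int(self.labels_.max()) if len(self.labels_) else 0

    def trait_correlation(self, trait) -> pd.DataFrame:
        return module_trait_correlation(self.eigengenes_, trait)

    def hub_genes(self, kme_min: float = 0.90, p_max: float = 1e-6) -> pd.DataFrame:
        kme = self.kme_
        return kme[(kme["kme"] > kme_min) & (kme["p"] < p_max)]
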