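"""Count-matrix bookkeeping: normalization, TPM, expressed-gene filter,
replicate correlation and the qPCR 2^-ddCT utility.

Conventions: a count matrix is a genes × samples :class:`pandas.DataFrame`
of non-negative integers with unique gene/sample identifiers; a sample
sheet maps every sample to (cross, role, timepoint, replicate).
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def _check_counts(counts: pd.DataFrame) -> None:
    if counts.index.has_duplicates:
        raise ValueError("duplicate gene identifiers in count matrix")
    if counts.columns.has_duplicates:
        raise ValueError("duplicate sample identifiers in count matrix")
    if (counts.to_numpy() < 0).any():
        raise ValueError("counts must be non-negative")


def compute_size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios library-size factors.

    The reference is the per-gene geometric mean over samples, restricted
    to genes with non-zero counts in every sample; each sample's factor is
    the median of its count/reference ratios over those genes.
    """
    _check_counts(counts)
    X = counts.to_numpy(dtype=float)
    all_nonzero = (X > 0).all(axis=1)
    if not all_nonzero.any():
        raise ValueError(
            "no gene has non-zero counts in every sample; size factors are "
            "undefined — filter samples or supply factors explicitly"
        )
    Xn = X[all_nonzero]
    log_ref = np.log(Xn).mean(axis=1)
    factors = np.exp(np.median(np.log(Xn) - log_ref[:, None], axis=0))
    return pd.Series(factors, index=counts.columns, name="size_factor")


def compute_tpm(counts: pd.DataFrame, lengths: pd.Series) -> pd.DataFrame:
    """Transcripts per million: length-normalized rates rescaled to 1e6.

    ``TPM_g = 1e6 * (c_g / L_g) / sum_h (c_h / L_h)`` per sample; an
    all-zero sample yields all-zero TPM.
    """
    _check_counts(counts)
    missing = counts.index.difference(lengths.index)
    if len(missing) > 0:
        raise KeyError(f"missing gene lengths for: {list(missing[:10])}"
                       + ("..." if len(missing) > 10 else ""))
    L = lengths.reindex(counts.index).to_numpy(dtype=float)
    if (L <= 0).any():
        raise ValueError("gene lengths must be > 0")
    rates = counts.to_numpy(dtype=float) / L[:, None]
    totals = rates.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        tpm = np.where(totals > 0, 1e6 * rates / totals, 0.0)
    return pd.DataFrame(tpm, index=counts.index, columns=counts.columns)


def filter_expressed(
    counts: pd.DataFrame, sheet: pd.DataFrame, threshold: int = 30
) -> pd.Index:
    """Expressed genes: replicate-group sum strictly above ``threshold``.

    Replicates are grouped by (cross, role, timepoint); a gene is expressed
    if in *at least one* group the summed counts exceed the threshold.
    This keeps genes expressed in only a single genotype, which the
    dominance classes require.
    """
    _check_counts(counts)
    missing = set(counts.columns) - set(sheet["sample_id"])
    if missing:
        raise ValueError(f"sample sheet is missing samples: {sorted(missing)[:5]}")
    expressed = pd.Series(False, index=counts.index)
    for _, grp in sheet.groupby(["cross", "role", "timepoint"], sort=False):
        samples = [s for s in grp["sample_id"] if s in counts.columns]
        if not samples:
            raise ValueError("replicate group with zero samples in count matrix")
        expressed |= counts[samples].sum(axis=1) > threshold
    return counts.index[expressed]


def sample_correlation_matrix(
    tpm: pd.DataFrame, expressed: pd.Index | None = None
) -> pd.DataFrame:
    """Pairwise Pearson correlation between samples over expressed genes.

    Zero-variance samples produce NaN off-diagonal entries (the
    "undefined" flag); the diagonal is 1 by convention.
    """
    sub = tpm.loc[expressed] if expressed is not None else tpm
    if len(sub) < 2:
        raise ValueError("need at least 2 expressed genes")
    corr = sub.corr(method="pearson")
    np.fill_diagonal(corr.values, 1.0)
    return corr


def qpcr_relative_expression(
    target_ct: pd.Series, reference_ct: pd.Series, calibrator: str
) -> pd.Series:
    """Relative expression by the 2^-ddCT method.

    ``dCT = CT_target - CT_reference`` per sample; ``ddCT`` subtracts the
    calibrator's dCT, so the calibrator's relative expression is exactly 1.
    """
    if calibrator not in target_ct.index or calibrator not in reference_ct.index:
        raise KeyError(f"calibrator sample {calibrator!r} missing from CT tables")
    dct = target_ct - reference_ct.reindex(target_ct.index)
    if dct.isna().any():
        bad = list(dct.index[dct.isna()])
        raise KeyError(f"missing reference CT for samples: {bad}")
    ddct = dct - dct.loc[calibrator]
    return pd.Series(2.0 ** (-ddct), index=target_ct.index, name="relative_expression")
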