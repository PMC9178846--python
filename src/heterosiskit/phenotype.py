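"""Phenotype heterosis statistics.

Mid-parent heterosis ``MPH = (F1 - MP) / MP x 100%`` and high-parent
heterosis ``HPH = (F1 - HP) / HP x 100%``, where MP is the mean of the
two parents' trait means and HP the better parent's mean; significance of
the hybrid against the mid-parent value by an unpaired two-sample t-test
(Student by default, Welch optional) on replicate-index-paired mid-parent
pseudo-samples; and a multiplicative log decomposition of the leaf-area
gain into leaf-length and leaf-width contributions.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats


def mid_parent_value(female_mean: float, male_mean: float) -> float:
    """Arithmetic mean of the two parental trait means."""
    if female_mean is None or male_mean is None or np.isnan(female_mean) or np.isnan(male_mean):
        raise ValueError("both parental means are required")
    return (float(female_mean) + float(male_mean)) / 2.0


def compute_mph(f1_mean: float, mpv: float) -> float:
    """Mid-parent heterosis in percent (83.77 means +83.77%)."""
    if mpv <= 0:
        raise ValueError("mid-parent value must be > 0")
    return (float(f1_mean) - float(mpv)) / float(mpv) * 100.0


def compute_hph(f1_mean: float, hp: float) -> float:
    """High-parent heterosis in percent relative to the best parent."""
    if hp <= 0:
        raise ValueError("high-parent value must be > 0")
    return (float(f1_mean) - float(hp)) / float(hp) * 100.0


def significance_stars(p: float) -> str:
    """Star annotation: * p<0.05, ** p<0.01, *** p<0.001, else 'ns'."""
    if np.isnan(p):
        return "ns"
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def hybrid_vs_mpv_test(
    hybrid_reps,
    female_reps,
    male_reps,
    equal_var: bool = True,
) -> tuple[float, float, str]:
    """Unpaired t-test of hybrid replicates against mid-parent pseudo-samples.

    Mid-parent pseudo-samples are built by replicate-index pairing of the
    parents (unequal replicate counts pair up to the shorter, with a
    warning). ``equal_var=False`` switches to Welch's test.
    Returns ``(t, p, stars)``.
    """
    h = np.asarray(hybrid_reps, dtype=float)
    f = np.asarray(female_reps, dtype=float)
    m = np.asarray(male_reps, dtype=float)
    if len(f) != len(m):
        warnings.warn(
            "unequal parent replicate counts; pairing up to the shorter",
            RuntimeWarning,
        )
    k = min(len(f), len(m))
    if len(h) < 2 or k < 2:
        raise ValueError("need >= 2 replicates per group")
    mpv = (f[:k] + m[:k]) / 2.0
    if h.var(ddof=1) == 0 and mpv.var(ddof=1) == 0:
        # degenerate: both samples constant
        t, p = (0.0, 1.0) if h.mean() == mpv.mean() else (np.inf, 0.0)
    else:
        t, p = stats.ttest_ind(h, mpv, equal_var=equal_var)
    return float(t), float(p), significance_stars(float(p))


def leaf_contribution(
    hybrid_length: float,
    mpv_length: float,
    hybrid_width: float,
    mpv_width: float,
) -> tuple[float, float]:
    """Percent contribution of leaf length vs width to the leaf-area gain.

    Treats area as proportional to length x width, so the log area gain
    decomposes additively: ``contribution_L = dlogL / (dlogL + dlogW) x 100``
    with ``dlogX = log(X_hybrid) - log(X_MPV)``. Returns (length_pct,
    width_pct); ``(nan, nan)`` when the total log gain is zero.
    """
    for v in (hybrid_length, mpv_length, hybrid_width, mpv_width):
        if v <= 0:
            raise ValueError("all means must be > 0")
    dl = np.log(hybrid_length) - np.log(mpv_length)
    dw = np.log(hybrid_width) - np.log(mpv_width)
    total = dl + dw
    if total == 0:
        return (float("nan"), float("nan"))
    return (100.0 * dl / total, 100.0 * dw / total)


def heterosis_table(
    phenotypes: pd.DataFrame, equal_var: bool = True
) -> pd.DataFrame:
    """Per (cross, trait, timepoint) heterosis summary from a replicate table.

    Expects rows (cross, role, timepoint, replicate, trait, value) with
    roles female_parent / male_parent / hybrid. Emits MPV, HP, MPH%, HPH%,
    and the hybrid-vs-MPV t-test with significance stars. Groups with
    fewer than 3 replicates are kept but flagged with a warning.
    """
    required = {"cross", "role", "timepoint", "replicate", "trait", "value"}
    if not required <= set(phenotypes.columns):
        raise ValueError(f"phenotype table needs columns {sorted(required)}")
    rows = []
    for (cross, trait, tp), grp in phenotypes.groupby(
        ["cross", "trait", "timepoint"], sort=False
    ):
        reps = {
            role: sub.sort_values("replicate")["value"].to_numpy(dtype=float)
            for role, sub in grp.groupby("role")
        }
        for role in ("female_parent", "male_parent", "hybrid"):
            if role not in reps:
                raise ValueError(
                    f"{cross}/{trait}/{tp}: missing role {role!r} in phenotype table"
                )
            if len(reps[role]) < 3:
                warnings.warn(
                    f"{cross}/{trait}/{tp}: fewer than 3 replicates for {role}",
                    RuntimeWarning,
                )
        fm, mm = reps["female_parent"].mean(), reps["male_parent"].mean()
        f1 = reps["hybrid"].mean()
        mpv = mid_parent_value(fm, mm)
        hp = max(fm, mm)
        t, p, star = hybrid_vs_mpv_test(
            reps["hybrid"], reps["female_parent"], reps["male_parent"], equal_var
        )
        rows.append(
            {
                "cross": cross,
                "trait": trait,
                "timepoint": tp,
                "female_mean": fm,
                "male_mean": mm,
                "f1_mean": f1,
                "MPV": mpv,
                "HP": hp,
                "MPH_pct": compute_mph(f1, mpv),
                "HPH_pct": compute_hph(f1, hp),
                "t": t,
                "p": p,
                "stars": star,
            }
        )
    return pd.DataFrame(rows)
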