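"""Synthetic parent/parent/hybrid RNA-seq triplets with planted truth.

The study design emulated here: two inbred parents (female, male) and
their F1 hybrid, three biological replicates per genotype, sampled at two
timepoints, gene-level negative-binomial counts. Every gene is planted
into one of the 13 truth labels (the 12 inheritance classes of
:mod:`heterosiskit.eld` plus ``NC``) and its per-genotype true means are
derived deterministically from the label, so downstream stages can be
scored against an exact ground truth.

Truth construction (class → means): draw a log-normal baseline ``b``;
"equal" genotypes share a mean, a "greater" genotype multiplies it by
``effect_fold`` f. Additive truth puts the hybrid exactly at the
mid-parent of a f-fold parent pair; transgressive truth puts the hybrid
at ``f × max(parents)`` (up) or ``min(parents) / f`` (down), which makes
the expected classification unambiguous.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .eld import CLASS_PATTERNS

ROLES = ("female_parent", "male_parent", "hybrid")
_ROLE_SHORT = {"female_parent": "F", "male_parent": "M", "hybrid": "H"}

#: Default planted class mix, mirroring the published composition at the
#: first sampling point: most differential genes show expression-level
#: dominance (parental-ELD ~85% of classified genes, ~58% of ELD toward
#: the higher parent), while additive and transgressive genes are rare.
DEFAULT_CLASS_PROPORTIONS: dict[str, float] = {
    "NC": 0.40,
    "II": 0.1479, "IV": 0.1479,   # high-parent ELD bins
    "XI": 0.1071, "IX": 0.1071,   # low-parent ELD bins
    "I": 0.005, "XII": 0.005,     # additive
    "V": 0.04 / 3, "VI": 0.04 / 3, "VIII": 0.04 / 3,   # transgressive up
    "III": 0.04 / 3, "VII": 0.04 / 3, "X": 0.04 / 3,   # transgressive down
}


def class_means(label: str, baseline: float, effect_fold: float) -> tuple[float, float, float]:
    """True (mu_female, mu_male, mu_hybrid) for a truth label."""
    b, f = float(baseline), float(effect_fold)
    mapping = {
        "NC": (b, b, b),
        "I": (f * b, b, (f + 1) / 2 * b),
        "XII": (b, f * b, (f + 1) / 2 * b),
        "II": (b, f * b, f * b),
        "XI": (f * b, b, b),
        "IV": (f * b, b, f * b),
        "IX": (b, f * b, b),
        "V": (f * b, b, f * f * b),
        "VI": (b, b, f * b),
        "VIII": (b, f * b, f * f * b),
        "III": (f * b, b, b / f),
        "VII": (b, b, b / f),
        "X": (b, f * b, b / f),
    }
    try:
        return mapping[label]
    except KeyError:
        raise ValueError(f"unknown truth label {label!r}") from None


@dataclass
class SimulationConfig:
    """Parameters of the triplet count simulation.

    Parameters
    ----------
    n_genes : number of simulated genes.
    n_replicates : biological replicates per genotype and timepoint (>= 2).
    class_proportions : fraction of genes planted into each of the 13
        truth labels; must be non-negative and sum to 1 (within 1e-9).
    baseline_mean : scale of the log-normal baseline expression mean.
    baseline_sigma : log-scale spread of baselines across genes.
    effect_fold : fold change separating "different" genotype means (> 1).
    dispersion : NB dispersion alpha >= 0 (Var = mu + alpha mu^2); 0 gives
        Poisson counts.
    depth_factors : per-sample library-size multipliers; drawn
        log-normal(0, 0.1) when omitted.
    timepoints : sampling timepoint labels (default two, as in a
        21/24-days-after-sowing design).
    cross : cross label written to the sample sheet.
    seed : integer seed driving one reproducible stream.
    """

    n_genes: int = 2000
    n_replicates: int = 3
    class_proportions: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_PROPORTIONS)
    )
    baseline_mean: float = 200.0
    baseline_sigma: float = 0.5
    effect_fold: float = 4.0
    dispersion: float = 0.05
    depth_factors: Sequence[float] | None = None
    timepoints: Sequence[str] = ("T1", "T2")
    cross: str = "SIM"
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes < 0:
            raise ValueError("n_genes must be >= 0")
        if self.n_replicates < 2:
            raise ValueError("n_replicates must be >= 2")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if self.effect_fold <= 1:
            raise ValueError("effect_fold must be > 1")
        if self.baseline_mean <= 0:
            raise ValueError("baseline_mean must be > 0")
        props = dict(self.class_proportions)
        unknown = set(props) - set(CLASS_PATTERNS)
        if unknown:
            raise ValueError(f"unknown truth labels in class_proportions: {sorted(unknown)}")
        vals = np.array(list(props.values()), dtype=float)
        if (vals < 0).any():
            raise ValueError("class_proportions must be >= 0")
        if abs(vals.sum() - 1.0) > 1e-9:
            raise ValueError(f"class_proportions must sum to 1, got {vals.sum():.12f}")
        n_samples = len(self.timepoints) * len(ROLES) * self.n_replicates
        if self.depth_factors is not None:
            df = np.asarray(self.depth_factors, dtype=float)
            if df.shape != (n_samples,):
                raise ValueError(
                    f"depth_factors must have length {n_samples} (one per sample)"
                )
            if (df <= 0).any():
                raise ValueError("depth_factors must be > 0")


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """NB(mean, Var = mu + alpha mu^2) counts via the gamma–Poisson mixture."""
    mean = np.asarray(mean, dtype=float)
    if dispersion == 0:
        return rng.poisson(mean)
    lam = rng.gamma(shape=1.0 / dispersion, scale=dispersion * mean)
    return rng.poisson(lam)


def simulate_triplet_counts(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate a parent/parent/hybrid count matrix with planted truth.

    Returns ``(counts, sample_sheet, truth)``: a genes × samples integer
    count frame, a sample sheet (sample_id, cross, role, timepoint,
    replicate) and a truth table (true_class plus the true per-genotype
    means on the undepth-scaled scale). Identical config (including seed)
    yields identical output.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    gene_ids = [f"g{i:05d}" for i in range(config.n_genes)]

    sheet_rows = []
    for tp in config.timepoints:
        for role in ROLES:
            for rep in range(1, config.n_replicates + 1):
                sheet_rows.append(
                    {
                        "sample_id": f"{config.cross}_{_ROLE_SHORT[role]}_{tp}_r{rep}",
                        "cross": config.cross,
                        "role": role,
                        "timepoint": tp,
                        "replicate": rep,
                    }
                )
    sheet = pd.DataFrame(
        sheet_rows, columns=["sample_id", "cross", "role", "timepoint", "replicate"]
    )

    if config.n_genes == 0:
        counts = pd.DataFrame(
            np.empty((0, len(sheet)), dtype=np.int64),
            index=pd.Index([], name="gene_id"),
            columns=sheet["sample_id"],
        )
        truth = pd.DataFrame(
            columns=["true_class", "mu_female", "mu_male", "mu_hybrid"],
            index=pd.Index([], name="gene_id"),
        )
        return counts, sheet, truth

    props = dict(config.class_proportions)
    labels = rng.choice(list(props), size=config.n_genes, p=list(props.values()))
    baselines = config.baseline_mean * rng.lognormal(
        0.0, config.baseline_sigma, config.n_genes
    )
    mus = np.array(
        [class_means(lab, b, config.effect_fold) for lab, b in zip(labels, baselines)]
    )  # (n_genes, 3) in ROLES order F, M, H

    if config.depth_factors is None:
        depth = rng.lognormal(0.0, 0.1, len(sheet))
    else:
        depth = np.asarray(config.depth_factors, dtype=float)

    role_col = {role: i for i, role in enumerate(ROLES)}
    cols = np.empty((config.n_genes, len(sheet)), dtype=np.int64)
    for j, row in enumerate(sheet.itertuples(index=False)):
        mu = mus[:, role_col[row.role]] * depth[j]
        cols[:, j] = _nb_draw(rng, mu, config.dispersion)

    counts = pd.DataFrame(
        cols, index=pd.Index(gene_ids, name="gene_id"), columns=sheet["sample_id"]
    )
    truth = pd.DataFrame(
        {
            "true_class": labels,
            "mu_female": mus[:, 0],
            "mu_male": mus[:, 1],
            "mu_hybrid": mus[:, 2],
        },
        index=pd.Index(gene_ids, name="gene_id"),
    )
    return counts, sheet, truth


def simulate_gene_lengths(gene_ids: Sequence[str], seed: int = 0) -> pd.Series:
    """Log-normal gene lengths (median ~1.5 kb, floor 200 b) for TPM."""
    rng = np.random.default_rng(seed)
    lengths = np.maximum(
        200, np.round(rng.lognormal(np.log(1500.0), 0.6, len(gene_ids)))
    ).astype(int)
    return pd.Series(lengths, index=pd.Index(gene_ids, name="gene_id"), name="length")


def simulate_phenotypes(
    n_reps: int,
    female_mean: float,
    male_mean: float,
    mph_target: float,
    cv: float,
    seed: int = 0,
    cross: str = "SIM",
    trait: str = "dry_weight",
    timepoint: str = "T1",
) -> pd.DataFrame:
    """Simulate a phenotype replicate table with a planted mid-parent heterosis.

    Hybrid replicates are drawn around ``MP × (1 + mph_target/100)`` where
    MP is the mid-parent value; parents around their own means; all values
    normal with coefficient of variation ``cv`` (``cv=0`` gives the exact
    means). Returns rows (cross, role, timepoint, replicate, trait, value).
    """
    if n_reps < 2:
        raise ValueError("n_reps must be >= 2")
    if female_mean <= 0 or male_mean <= 0:
        raise ValueError("parent means must be > 0")
    if cv < 0:
        raise ValueError("cv must be >= 0")
    rng = np.random.default_rng(seed)
    mp = (female_mean + male_mean) / 2.0
    hybrid_mean = mp * (1.0 + mph_target / 100.0)
    rows = []
    for role, mean in (
        ("female_parent", female_mean),
        ("male_parent", male_mean),
        ("hybrid", hybrid_mean),
    ):
        values = mean * (1.0 + cv * rng.standard_normal(n_reps)) if cv > 0 else np.full(n_reps, mean)
        for rep, v in enumerate(values, start=1):
            rows.append(
                {
                    "cross": cross,
                    "role": role,
                    "timepoint": timepoint,
                    "replicate": rep,
                    "trait": trait,
                    "value": float(v),
                }
            )
    return pd.DataFrame(rows)
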