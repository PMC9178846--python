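"""Expression-inheritance (ELD) classification of hybrid/parent gene triplets.

Each gene of an F1/parent triplet carries three signed significance codes,
one per differential-expression contrast:

* ``s_HF`` — hybrid vs female parent,
* ``s_HM`` — hybrid vs male parent,
* ``s_FM`` — female parent vs male parent,

where ``+1`` means the first genotype is significantly *higher*, ``-1``
significantly lower and ``0`` no significant difference. The 27 possible
sign patterns partition into

* 1 no-change pattern (``NC``),
* 12 consistent expression classes (Roman numerals I–XII) covering five
  biological categories — additive (hybrid between two differing parents),
  expression-level dominance toward the female (ELD-F) or male (ELD-M)
  parent, transgressive up-regulation (OD, hybrid above both parents) and
  transgressive down-regulation (UD, hybrid below both parents),
* 14 internally inconsistent patterns that the 12-class scheme cannot
  express (e.g. parents differ but the hybrid matches neither); these are
  kept as an explicit residual class ``AMB`` rather than forced into the
  nearest bin.

The numeral convention is fixed so that {II, XI} are the ELD-M bins,
{IV, IX} the ELD-F bins (hence parental-ELD = II + XI + IV + IX),
{I, XII} additive, {V, VI, VIII} OD and {III, VII, X} UD. Within each
category the bins are ordered by the sign of the parental contrast.
"""

from __future__ import annotations

import itertools
import logging
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

logger = logging.getLogger(__name__)

#: sign pattern (s_HF, s_HM, s_FM) for each of the 12 classes + NC.
CLASS_PATTERNS: dict[str, tuple[int, int, int]] = {
    # additive: hybrid strictly between two differing parents
    "I": (-1, +1, +1),   # F > H > M
    "XII": (+1, -1, -1),  # M > H > F
    # ELD-M: hybrid indistinguishable from the male parent
    "II": (+1, 0, -1),   # M high parent
    "XI": (-1, 0, +1),   # M low parent
    # ELD-F: hybrid indistinguishable from the female parent
    "IV": (0, +1, +1),   # F high parent
    "IX": (0, -1, -1),   # F low parent
    # OD (transgressive up): hybrid above both parents, split by s_FM
    "V": (+1, +1, +1),
    "VI": (+1, +1, 0),
    "VIII": (+1, +1, -1),
    # UD (transgressive down): hybrid below both parents, split by s_FM
    "III": (-1, -1, +1),
    "VII": (-1, -1, 0),
    "X": (-1, -1, -1),
    # no change anywhere
    "NC": (0, 0, 0),
}

PATTERN_TO_CLASS: dict[tuple[int, int, int], str] = {
    v: k for k, v in CLASS_PATTERNS.items()
}

CLASS_CATEGORY: dict[str, str] = {
    "I": "additive", "XII": "additive",
    "II": "ELD-M", "XI": "ELD-M",
    "IV": "ELD-F", "IX": "ELD-F",
    "V": "OD", "VI": "OD", "VIII": "OD",
    "III": "UD", "VII": "UD", "X": "UD",
    "NC": "NC",
    "AMB": "AMB",
}

#: the four expression-level-dominance bins ("parental ELD").
PARENTAL_ELD_CLASSES = frozenset({"II", "XI", "IV", "IX"})
#: ELD bins whose matched parent is the significantly higher one.
HIGH_PARENT_CLASSES = frozenset({"II", "IV"})

_VALID_CODES = (-1, 0, 1)


def classify_gene(s_hf: int, s_hm: int, s_fm: int) -> dict:
    """Classify one gene from its three signed significance codes.

    Returns a dict with ``class_label`` (I–XII, NC or AMB), ``category``,
    ``parental_eld`` and ``high_parent_eld`` flags.
    """
    for code in (s_hf, s_hm, s_fm):
        if code not in _VALID_CODES:
            raise ValueError(f"sign codes must be in {{-1, 0, +1}}, got {code!r}")
    label = PATTERN_TO_CLASS.get((int(s_hf), int(s_hm), int(s_fm)), "AMB")
    return {
        "class_label": label,
        "category": CLASS_CATEGORY[label],
        "parental_eld": label in PARENTAL_ELD_CLASSES,
        "high_parent_eld": label in HIGH_PARENT_CLASSES,
    }


class InheritanceClassifier(BaseEstimator):
    """Deterministic mapper from sign triplets to inheritance classes.

    A stateless scikit-learn style estimator: :meth:`fit` only validates
    input shape, :meth:`predict` maps an ``(n_genes, 3)`` array of sign
    codes (columns ``s_HF, s_HM, s_FM``) to class labels.
    """

    def fit(self, X, y=None):
        X = np.asarray(X)
        if X.ndim != 2 or X.shape[1] != 3:
            raise ValueError("expected an (n_genes, 3) array of sign codes")
        self.n_features_in_ = 3
        return self

    def predict(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=int)
        if X.ndim != 2 or X.shape[1] != 3:
            raise ValueError("expected an (n_genes, 3) array of sign codes")
        if not np.isin(X, _VALID_CODES).all():
            raise ValueError("sign codes must be in {-1, 0, +1}")
        return np.array(
            [PATTERN_TO_CLASS.get(tuple(row), "AMB") for row in X], dtype=object
        )


def encode_calls(hf: pd.DataFrame, hm: pd.DataFrame, fm: pd.DataFrame) -> pd.DataFrame:
    """Turn three DE result tables into one sign-code table.

    Each input is a per-gene frame with a ``call`` column in
    {``up``, ``down``, ``ns``} (``up`` meaning the first genotype of the
    contrast is higher). Genes absent from any table are dropped; the
    number dropped is logged.
    """
    sign = {"up": 1, "down": -1, "ns": 0}
    common = hf.index.intersection(hm.index).intersection(fm.index)
    if len(common) == 0:
        raise ValueError("the three DE tables share no genes")
    n_dropped = len(hf.index.union(hm.index).union(fm.index)) - len(common)
    if n_dropped:
        logger.warning("encode_calls: dropped %d genes missing from some table", n_dropped)
    out = pd.DataFrame(
        {
            "s_HF": hf.loc[common, "call"].map(sign),
            "s_HM": hm.loc[common, "call"].map(sign),
            "s_FM": fm.loc[common, "call"].map(sign),
        },
        index=common,
    )
    if out.isna().any().any():
        raise ValueError("DE calls must be one of 'up', 'down', 'ns'")
    return out.astype(int)


def classify_table(triplet_calls: pd.DataFrame) -> pd.DataFrame:
    """Classify every gene of a sign-code table (columns s_HF, s_HM, s_FM)."""
    clf = InheritanceClassifier().fit(triplet_calls[["s_HF", "s_HM", "s_FM"]])
    labels = clf.predict(triplet_calls[["s_HF", "s_HM", "s_FM"]].to_numpy())
    out = triplet_calls.copy()
    out["class_label"] = labels
    out["category"] = [CLASS_CATEGORY[c] for c in labels]
    out["parental_eld"] = [c in PARENTAL_ELD_CLASSES for c in labels]
    out["high_parent_eld"] = [c in HIGH_PARENT_CLASSES for c in labels]
    return out


def summarize_classes(assignments: pd.DataFrame) -> dict:
    """Count/percentage summary of an assignment table.

    Percentages are over all assigned genes (including NC and AMB).
    ``parental_eld_share_pct`` is the share of the four ELD bins among all
    genes falling in one of the 12 classes; ``high_parent_eld_share_pct``
    is the share of high-parent bins among ELD genes. Both are ``None``
    when their denominator is empty.
    """
    if len(assignments) == 0:
        raise ValueError("assignments is empty")
    labels = assignments["class_label"]
    n = len(labels)
    class_counts = labels.value_counts().to_dict()
    cat_counts = assignments["category"].value_counts().to_dict()
    classified = labels[labels.isin(CLASS_PATTERNS.keys()) & (labels != "NC")]
    n_classified = len(classified)
    n_parental = int(classified.isin(PARENTAL_ELD_CLASSES).sum())
    n_high = int(classified.isin(HIGH_PARENT_CLASSES).sum())
    return {
        "n_genes": n,
        "class_counts": class_counts,
        "class_pct": {k: 100.0 * v / n for k, v in class_counts.items()},
        "category_counts": cat_counts,
        "category_pct": {k: 100.0 * v / n for k, v in cat_counts.items()},
        "n_classified": n_classified,
        "parental_eld_share_pct": (
            100.0 * n_parental / n_classified if n_classified else None
        ),
        "high_parent_eld_share_pct": (
            100.0 * n_high / n_parental if n_parental else None
        ),
    }


def overlap_sets(named_gene_sets: Mapping[str, Iterable]) -> dict[str, int]:
    """Venn-region cardinalities for 2–3 named gene sets.

    Returns a dict keyed by ``"A"``, ``"A&B"``, … (sorted names joined by
    ``&``) giving the number of elements exactly in that combination of
    sets and no other.
    """
    sets = {name: set(s) for name, s in named_gene_sets.items()}
    if len(sets) < 2:
        raise ValueError("need at least 2 sets")
    names = list(sets)
    regions: dict[str, int] = {}
    for r in range(1, len(names) + 1):
        for members in itertools.combinations(names, r):
            inside = set.intersection(*(sets[m] for m in members))
            outside = set.union(set(), *(sets[m] for m in names if m not in members))
            regions["&".join(sorted(members))] = len(inside - outside)
    return regions
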