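"""Multi-rater categorical agreement and consensus item classification.

Seven judges independently sorted each anxiety item into cognitive worry,
physiological arousal, both, or neither/unclear.  Fleiss' kappa quantifies
chance-corrected agreement; the consensus rule accepts items with near-
unanimous judgments, flags a middle band for adjudication, and forces
low-agreement items to neither/unclear.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CATEGORIES",
    "validate_ratings",
    "fleiss_kappa",
    "consensus_classify",
    "classification_from_consensus",
]

CATEGORIES = (
    "cognitive_worry",
    "physiological_arousal",
    "both",
    "neither_unclear",
)


def validate_ratings(ratings: pd.DataFrame) -> pd.DataFrame:
    """Check the items-by-raters matrix: every cell filled, >= 2 raters and
    >= 2 items."""
    if ratings.shape[0] < 2 or ratings.shape[1] < 2:
        raise ValueError("need at least 2 items and 2 raters")
    if ratings.isna().any().any():
        raise ValueError("rating matrix has empty cells")
    return ratings


def _count_matrix(ratings: pd.DataFrame, categories: Sequence[str] | None):
    if categories is None:
        categories = sorted(set(np.asarray(ratings).ravel().tolist()))
    counts = np.zeros((len(ratings), len(categories)), dtype=int)
    arr = np.asarray(ratings)
    for k, cat in enumerate(categories):
        counts[:, k] = (arr == cat).sum(axis=1)
    if counts.sum() != ratings.size:
        raise ValueError("ratings contain categories outside the given set")
    return counts, list(categories)


def fleiss_kappa(
    ratings: pd.DataFrame, categories: Sequence[str] | None = None
) -> float:
    """Fleiss' kappa for m raters and k categories.

    kappa = (Pbar - Pbar_e) / (1 - Pbar_e), where the per-item agreement is
    P_i = [sum_k n_ik^2 - m] / [m (m - 1)] and Pbar_e = sum_k p_k^2 from the
    pooled category proportions.  Requires the same rater count per item.
    When every rating falls in one category Pbar_e = 1 and kappa is
    undefined; perfect agreement returns 1, anything else is an error.
    """
    validate_ratings(ratings)
    counts, _ = _count_matrix(ratings, categories)
    m = counts.sum(axis=1)
    if len(set(m.tolist())) != 1:
        raise ValueError("unequal rater counts across items")
    m = int(m[0])
    if m < 2:
        raise ValueError("need at least 2 raters")
    P_i = ((counts**2).sum(axis=1) - m) / (m * (m - 1))
    P_bar = float(P_i.mean())
    p_k = counts.sum(axis=0) / counts.sum()
    P_e = float((p_k**2).sum())
    if P_e >= 1.0:
        if P_bar >= 1.0:
            return 1.0
        raise ValueError("kappa undefined: all ratings in a single category")
    return (P_bar - P_e) / (1 - P_e)


def consensus_classify(
    ratings: pd.DataFrame,
    accept_threshold: float = 6 / 7,
    review_threshold: float = 5 / 7,
    categories: Sequence[str] | None = None,
    unclear_category: str = "neither_unclear",
) -> pd.DataFrame:
    """Per-item consensus category, agreement fraction, and status.

    agreement = modal count / raters.  agreement >= accept -> ``accepted``;
    review <= agreement < accept -> ``adjudicate`` (modal category is
    provisional, to be resolved manually); agreement < review, or a modal
    tie -> forced to the unclear category with status ``unclear``.
    """
    if not (0 < review_threshold <= accept_threshold <= 1):
        raise ValueError("need 0 < review_threshold <= accept_threshold <= 1")
    validate_ratings(ratings)
    counts, cats = _count_matrix(ratings, categories)
    m = counts.sum(axis=1)
    rows = []
    for i, item in enumerate(ratings.index):
        c = counts[i]
        top = c.max()
        agreement = top / m[i]
        tie = (c == top).sum() > 1
        if tie or agreement < review_threshold:
            cat, status = unclear_category, "unclear"
        else:
            cat = cats[int(np.argmax(c))]
            status = "accepted" if agreement >= accept_threshold else "adjudicate"
        rows.append(
            {"item": item, "category": cat, "agreement": float(agreement),
             "status": status}
        )
    return pd.DataFrame(rows).set_index("item")


def classification_from_consensus(
    consensus: pd.DataFrame,
    overrides: Mapping[str, str] | None = None,
    unclear_category: str = "neither_unclear",
) -> dict[str, str]:
    """Final item -> category map for composite scoring.

    Accepted items keep their modal category; adjudicated items take the
    manual override when provided (else their provisional modal category);
    unclear items go to the unclear category.
    """
    overrides = dict(overrides or {})
    out = {}
    for item, row in consensus.iterrows():
        if item in overrides:
            out[item] = overrides[item]
        elif row["status"] == "unclear":
            out[item] = unclear_category
        else:
            out[item] = row["category"]
    return out
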