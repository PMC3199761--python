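"""Scoring method output against simulation truth.

Three evaluations mirror the benchmark protocol: ROC/AUC for ranking
the differentially regulated genes (DRGs), DRL-enrichment fractions for
a DCL set against its link universe, and an empirical significance test
of those fractions against uniformly resampled link sets.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve


def ranked_scores(
    score_table: pd.DataFrame,
    all_genes,
    score_col: str = "dC",
    ascending: bool = False,
) -> pd.Series:
    """Scores over the full gene universe, rankable for ROC analysis.

    Genes absent from ``score_table`` (no filtered links, so no defined
    statistic) and genes with NaN scores share one score strictly below
    the minimum defined score, placing them jointly last; dropping them
    instead would bias sensitivity.  ``ascending=True`` negates the
    score column first (for p-value-like scores where small means
    differential).
    """
    s = score_table.set_index("gene")[score_col].astype(float)
    if ascending:
        s = -s
    s = s.reindex(all_genes)
    defined = s.dropna()
    floor = (defined.min() - 1.0) if len(defined) else 0.0
    return s.fillna(floor)


def roc_points(scores: pd.Series, truth: set) -> tuple[np.ndarray, np.ndarray, float]:
    """ROC curve (fpr, tpr) and its AUC for a scored gene list.

    Higher scores should indicate truth membership; ties follow the
    midrank (Mann-Whitney) convention via trapezoidal integration.
    Raises on single-class truth.
    """
    labels = np.array([g in truth for g in scores.index], dtype=int)
    if labels.all() or not labels.any():
        raise ValueError("truth labels must contain both classes")
    fpr, tpr, _ = roc_curve(labels, scores.to_numpy())
    return fpr, tpr, float(_trapezoid_auc(fpr, tpr))


def roc_auc(scores: pd.Series, truth: set) -> float:
    """AUC alone (see :func:`roc_points`)."""
    return roc_points(scores, truth)[2]


def extended_truth(drls: set, universe: set) -> set:
    """Extend planted DRLs by one-step adjacency within a link universe.

    A universe link is an extended DRL when it shares a gene with some
    DRL (or is one).  Coexpression changes spread from a perturbed
    regulation to the links around it, so method output is also scored
    against this softer truth set.
    """
    drgs = {g for pair in drls for g in pair}
    return set(drls) | {
        (i, j) for (i, j) in universe if i in drgs or j in drgs
    }


def drl_enrichment(
    dcls: set,
    truth: set,
    universe: set,
) -> dict:
    """Fractions of truth links among the DCL set vs. the whole universe.

    Returns ``background_fraction`` = |truth ∩ universe| / |universe|
    and ``dcl_fraction`` = |truth ∩ dcls| / |dcls| (None when the DCL
    set is empty).  Pass ``extended_drls`` as ``truth`` for the
    extended-DRL variant.
    """
    if not dcls <= universe:
        raise ValueError("DCL set must be a subset of the link universe")
    if len(universe) == 0:
        raise ValueError("empty link universe")
    background = len(truth & universe) / len(universe)
    dcl_fraction = len(truth & dcls) / len(dcls) if dcls else None
    return {
        "background_fraction": background,
        "dcl_fraction": dcl_fraction,
        "n_universe": len(universe),
        "n_dcls": len(dcls),
    }


def random_link_significance(
    dcl_size: int,
    observed_fraction: float,
    truth: set,
    universe: set,
    n_draws: int = 1000,
    seed: int | None = None,
) -> dict:
    """Empirical p-value of a DCL set's truth fraction under random sampling.

    Draws ``n_draws`` uniform link subsets of size ``dcl_size`` from the
    universe and compares their truth fractions with the observed one:
    ``p = (1 + #{draw >= observed}) / (1 + n_draws)``.
    """
    if n_draws < 100:
        raise ValueError("n_draws must be >= 100")
    universe_list = sorted(universe)
    if dcl_size > len(universe_list):
        raise ValueError("dcl_size exceeds the universe")
    rng = np.random.default_rng(seed)
    is_truth = np.array([link in truth for link in universe_list])
    draws = np.empty(n_draws)
    for k in range(n_draws):
        idx = rng.choice(len(universe_list), size=dcl_size, replace=False)
        draws[k] = is_truth[idx].mean()
    p = (1.0 + int((draws >= observed_fraction).sum())) / (1.0 + n_draws)
    return {
        "empirical_p": p,
        "null_mean": float(draws.mean()),
        "observed_fraction": observed_fraction,
    }
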