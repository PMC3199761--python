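"""All-pairs Pearson correlation and the half-thresholding link filter.

Two expression matrices (one per condition, identical gene universe) are
encoded into a set of paired correlations ``{(x_ij, y_ij)}`` over all gene
pairs.  The *half-thresholding* filter then keeps a pair in **both**
condition networks if at least one of the two correlations passes the
cutoff — either a per-condition BH q-value below ``q_th`` or an absolute
correlation of at least ``rho``.  Pairs failing on both sides carry no
usable coexpression signal in either condition and are discarded; the
survivors form a single shared link universe ("two coexpression networks
with identical structure but different link weights") on which every
downstream differential-coexpression statistic operates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

LINK_COLUMNS = [
    "gene_i", "gene_j", "pcc_x", "pcc_y", "p_x", "p_y", "q_x", "q_y",
]


def check_expression_matrix(df: pd.DataFrame, name: str = "matrix") -> None:
    """Validate a genes × samples expression matrix.

    Requires unique gene identifiers, at least 4 samples (the correlation
    p-value needs ``df = n_samples - 2 >= 2``), and a complete numeric
    table — missing entries are rejected rather than handled by pairwise
    deletion, which would silently change the degrees of freedom per pair.
    """
    if df.index.has_duplicates:
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"{name}: duplicate gene ids: {dupes}")
    if df.shape[1] < 4:
        raise ValueError(
            f"{name}: at least 4 samples required, got {df.shape[1]}"
        )
    values = df.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        raise ValueError(f"{name}: non-numeric values present")
    if np.isnan(values).any():
        rows = df.index[np.isnan(values).any(axis=1)].tolist()
        raise ValueError(f"{name}: missing values in rows {rows}")


@dataclass
class ExpressionPair:
    """A pair of genes × samples expression matrices, one per condition.

    Both matrices share an identical, identically ordered gene index;
    sample counts may differ between conditions.
    """

    cond_x: pd.DataFrame
    cond_y: pd.DataFrame

    def __post_init__(self) -> None:
        check_expression_matrix(self.cond_x, "cond_x")
        check_expression_matrix(self.cond_y, "cond_y")
        if not self.cond_x.index.equals(self.cond_y.index):
            raise ValueError(
                "condition matrices must share an identical gene index"
            )

    @property
    def gene_ids(self) -> pd.Index:
        return self.cond_x.index

    @property
    def n_genes(self) -> int:
        return len(self.cond_x.index)


@dataclass
class FilteredLinkSet:
    """The half-thresholded link universe.

    ``links`` holds one row per kept unordered gene pair with both
    condition correlations and their p/q-values; ``params`` records the
    cutoff used.  ``n_links`` is the link-universe size N.
    """

    links: pd.DataFrame
    params: dict = field(default_factory=dict)

    @property
    def n_links(self) -> int:
        return len(self.links)


def pearson_pvalue(r: np.ndarray, n_samples: int) -> np.ndarray:
    """Two-sided p-value of a Pearson correlation via the t-transform.

    ``t = r * sqrt((n-2) / (1 - r^2))`` against a t-distribution with
    ``n - 2`` degrees of freedom; ``|r| = 1`` maps to ``p = 0``.
    """
    r = np.asarray(r, dtype=float)
    if n_samples < 4:
        raise ValueError("need at least 4 samples for a correlation p-value")
    df = n_samples - 2
    p = np.zeros_like(r, dtype=float)
    interior = np.abs(r) < 1.0
    t = np.abs(r[interior]) * np.sqrt(df / (1.0 - r[interior] ** 2))
    p[interior] = 2.0 * stats.t.sf(t, df)
    return p


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values (same order as input)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _condition_correlations(values: np.ndarray):
    """Full correlation matrix plus a per-gene nonzero-variance mask."""
    sd = values.std(axis=1)
    valid = sd > 0
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(values)
    r = np.atleast_2d(r)
    np.clip(r, -1.0, 1.0, out=r)
    return r, valid


def allpairs_correlations(vx: np.ndarray, vy: np.ndarray):
    """Array-level all-pairs correlation core shared with the permutation test.

    Returns ``(idx_i, idx_j, x, y, p_x, p_y, q_x, q_y)`` over the valid
    unordered pairs (self-pairs excluded, each pair once, i < j in row
    order).  Pairs touching a gene with zero variance in either condition
    are excluded; BH adjustment is applied per condition over the
    remaining pairs (each condition is its own family of tests).
    """
    n_genes = vx.shape[0]
    rx, valid_x = _condition_correlations(vx)
    ry, valid_y = _condition_correlations(vy)
    valid = valid_x & valid_y
    if not valid.all():
        logger.warning(
            "excluding %d zero-variance gene(s) from the link universe",
            int((~valid).sum()),
        )
    iu_i, iu_j = np.triu_indices(n_genes, k=1)
    keep = valid[iu_i] & valid[iu_j]
    iu_i, iu_j = iu_i[keep], iu_j[keep]
    x = rx[iu_i, iu_j]
    y = ry[iu_i, iu_j]
    p_x = pearson_pvalue(x, vx.shape[1])
    p_y = pearson_pvalue(y, vy.shape[1])
    q_x = bh_adjust(p_x)
    q_y = bh_adjust(p_y)
    return iu_i, iu_j, x, y, p_x, p_y, q_x, q_y


def compute_pcc(pair: ExpressionPair) -> pd.DataFrame:
    """All-pairs correlation link table for an expression pair.

    One row per unordered gene pair with the two condition correlations
    ``pcc_x``/``pcc_y``, their two-sided p-values and per-condition BH
    q-values.  Links of zero-variance (constant) genes are excluded with
    a logged warning.
    """
    vx = pair.cond_x.to_numpy(dtype=float)
    vy = pair.cond_y.to_numpy(dtype=float)
    iu_i, iu_j, x, y, p_x, p_y, q_x, q_y = allpairs_correlations(vx, vy)
    genes = pair.gene_ids.to_numpy()
    return pd.DataFrame(
        {
            "gene_i": genes[iu_i],
            "gene_j": genes[iu_j],
            "pcc_x": x,
            "pcc_y": y,
            "p_x": p_x,
            "p_y": p_y,
            "q_x": q_x,
            "q_y": q_y,
        }
    )


def half_threshold_mask(
    q_x: np.ndarray,
    q_y: np.ndarray,
    x: np.ndarray,
    y: np.ndarray,
    q_th: float | None = None,
    rho: float | None = None,
) -> np.ndarray:
    """Boolean keep-mask of the half-thresholding rule (array core)."""
    if (q_th is None) == (rho is None):
        raise ValueError("specify exactly one of q_th or rho")
    if q_th is not None:
        return np.minimum(q_x, q_y) < q_th
    return np.maximum(np.abs(x), np.abs(y)) >= rho


def half_threshold_filter(
    links: pd.DataFrame,
    q_th: float | None = None,
    rho: float | None = None,
) -> FilteredLinkSet:
    """Apply the half-thresholding rule to an all-pairs link table.

    A pair is kept iff ``min(q_x, q_y) < q_th`` (q-mode) or
    ``max(|x|, |y|) >= rho`` (rho-mode).  Exactly one mode must be given;
    the default downstream convention is q-mode with ``q_th = 0.25``.
    """
    if len(links) == 0:
        if (q_th is None) == (rho is None):
            raise ValueError("specify exactly one of q_th or rho")
        empty = pd.DataFrame(columns=LINK_COLUMNS)
        return FilteredLinkSet(empty, params={"q_th": q_th, "rho": rho})
    mask = half_threshold_mask(
        links["q_x"].to_numpy(), links["q_y"].to_numpy(),
        links["pcc_x"].to_numpy(), links["pcc_y"].to_numpy(),
        q_th=q_th, rho=rho,
    )
    kept = links.loc[mask].reset_index(drop=True)
    return FilteredLinkSet(kept, params={"q_th": q_th, "rho": rho})
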