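"""DCe: differentially coexpressed links via the limit-fold-change model,
then differentially coexpressed genes via binomial enrichment.

Each filtered link is summarized by its maximum absolute correlation
``max_corr = max(|x|, |y|)`` and its log absolute correlation ratio
``lfc = |log((|x| + eps) / (|y| + eps))|``.  Links split into three
classes:

* **reversed** — opposite-signed correlations, both strong (passing the
  ``rho`` or ``q_th`` cutoff): taken as DCLs outright.  These are the
  correlation-reversal pairs that connectivity-based measures miss.
* **same-signed** — screened by the LFC model with ``max_corr`` as
  predictor and ``lfc`` as response: a large fold change at a given
  coexpression strength marks a DCL.
* **diff-signed** (opposite signs, not both strong) — screened with the
  roles flipped (``lfc`` predictor, ``max_corr`` response).

The LFC model bins links along the predictor, selects the top fraction
``delta`` of each bin by response as outliers, takes per bin the outlier
with the lowest response as that bin's boundary point, fits
``y = a + b/x`` to the boundary points by least squares, and flags every
link strictly above the curve.

With N filtered links of which K are DCLs, a gene with n_i links of which
k_i are DCLs gets the upper-tail binomial p-value P(X >= k_i),
X ~ Bin(n_i, K/N) — a small p marks a DCL-enriched, differentially
coexpressed gene.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .corr import FilteredLinkSet, bh_adjust

logger = logging.getLogger(__name__)

#: additive guard so that a zero correlation yields a finite log ratio
LOG_RATIO_EPS = 1e-4

SAME_SIGNED = "same-signed"
DIFF_SIGNED = "diff-signed"
REVERSED = "reversed"


@dataclass
class LFCFit:
    """Fitted boundary curve ``y = a + b/x`` of one LFC screening pass."""

    a: float
    b: float
    bin_edges: np.ndarray
    boundary_points: np.ndarray  # (n_bins_used, 2) array of (x, y)
    delta: float
    fallback: bool = False  # True when < 2 distinct boundary points

    def curve(self, x) -> np.ndarray:
        x = np.maximum(np.asarray(x, dtype=float), LOG_RATIO_EPS)
        return self.a + self.b / x


def link_features(links: pd.DataFrame) -> pd.DataFrame:
    """Attach ``max_corr`` and ``lfc`` columns to a link table."""
    x = links["pcc_x"].to_numpy(dtype=float)
    y = links["pcc_y"].to_numpy(dtype=float)
    out = links.copy()
    out["max_corr"] = np.maximum(np.abs(x), np.abs(y))
    out["lfc"] = np.abs(
        np.log((np.abs(x) + LOG_RATIO_EPS) / (np.abs(y) + LOG_RATIO_EPS))
    )
    return out


def classify_links(
    fls: FilteredLinkSet,
    rho: float | None = 0.8,
    q_th: float | None = None,
) -> pd.DataFrame:
    """Partition filtered links into same-signed / diff-signed / reversed.

    Zero correlations evidence no reversal, so a link with ``x*y >= 0``
    is same-signed.  Opposite-signed links where both conditions pass the
    cutoff (``|r| >= rho`` in both, or ``q < q_th`` in both) are reversed
    and immediately DCLs; the remaining opposite-signed links go to the
    flipped LFC screen.
    """
    if (rho is None) == (q_th is None):
        raise ValueError("specify exactly one of rho or q_th")
    links = link_features(fls.links)
    x = links["pcc_x"].to_numpy(dtype=float)
    y = links["pcc_y"].to_numpy(dtype=float)
    opposite = x * y < 0
    if rho is not None:
        strong = (np.abs(x) >= rho) & (np.abs(y) >= rho)
    else:
        strong = (links["q_x"].to_numpy() < q_th) & (
            links["q_y"].to_numpy() < q_th
        )
    cls = np.where(opposite, DIFF_SIGNED, SAME_SIGNED)
    cls[opposite & strong] = REVERSED
    links["cls"] = cls
    links["is_dcl"] = cls == REVERSED
    return links


def _bin_outliers(links: pd.DataFrame, predictor: str, response: str,
                  n_bins: int, delta: float):
    """Per-bin top-delta outlier rows plus each bin's boundary row index.

    Equal-width bins over the predictor's observed range; ties in the
    response broken by larger ``max_corr``, then lexicographic gene pair.
    Returns (outlier_index, boundary_points) where boundary_points is a
    list of (x, y) of the lowest-response outlier per nonempty bin.
    """
    pred = links[predictor].to_numpy(dtype=float)
    lo, hi = pred.min(), pred.max()
    if hi == lo:
        edges = np.array([lo, lo + 1.0])
    else:
        edges = np.linspace(lo, hi, n_bins + 1)
    bin_of = np.clip(np.searchsorted(edges, pred, side="right") - 1,
                     0, len(edges) - 2)
    ordered = links.assign(_bin=bin_of).sort_values(
        [response, "max_corr", "gene_i", "gene_j"],
        ascending=[False, False, True, True],
        kind="mergesort",
    )
    outlier_idx = []
    boundary = []
    for _, grp in ordered.groupby("_bin", sort=True):
        take = math.ceil(delta * len(grp))
        top = grp.iloc[:take]
        outlier_idx.append(top.index.to_numpy())
        last = top.iloc[-1]  # lowest response among the bin's outliers
        boundary.append((float(last[predictor]), float(last[response])))
    return np.concatenate(outlier_idx), np.asarray(boundary, dtype=float), edges


def lfc_select(
    links: pd.DataFrame,
    predictor: str,
    response: str,
    n_bins: int = 20,
    delta: float = 0.1,
    boundary_mode: str = "min-outlier",
) -> tuple[np.ndarray, LFCFit | None]:
    """Flag outlying links under the limit-fold-change model.

    Fits ``response = a + b / predictor`` by least squares over the
    boundary points (``min-outlier``: the lowest-response outlier per
    bin; ``all-outliers``: every per-bin outlier) and flags links with
    response strictly above the curve.  With fewer than 2 distinct
    boundary points no curve is identifiable and exactly the per-bin
    outliers are flagged instead.

    Returns a boolean flag array aligned with ``links`` and the fit.
    """
    if not 0 < delta < 1:
        raise ValueError("delta must lie in (0, 1)")
    if boundary_mode not in ("min-outlier", "all-outliers"):
        raise ValueError(f"unknown boundary mode {boundary_mode!r}")
    if len(links) == 0:
        return np.zeros(0, dtype=bool), None
    links = links.reset_index(drop=True)
    outlier_idx, boundary, edges = _bin_outliers(
        links, predictor, response, n_bins, delta
    )
    if boundary_mode == "all-outliers":
        pts = links.loc[outlier_idx, [predictor, response]].to_numpy(float)
    else:
        pts = boundary
    distinct = np.unique(pts, axis=0)
    if len(distinct) < 2 or np.ptp(pts[:, 1]) == 0:
        # a constant response admits no boundary curve either
        logger.warning(
            "LFC fit: degenerate boundary points; "
            "flagging per-bin outliers without a curve"
        )
        flags = np.zeros(len(links), dtype=bool)
        flags[outlier_idx] = True
        fit = LFCFit(
            a=float("nan"), b=float("nan"), bin_edges=edges,
            boundary_points=boundary, delta=delta, fallback=True,
        )
        return flags, fit
    px = np.maximum(pts[:, 0], LOG_RATIO_EPS)
    design = np.column_stack([np.ones_like(px), 1.0 / px])
    coef, *_ = np.linalg.lstsq(design, pts[:, 1], rcond=None)
    fit = LFCFit(
        a=float(coef[0]), b=float(coef[1]), bin_edges=edges,
        boundary_points=boundary, delta=delta,
    )
    resp = links[response].to_numpy(dtype=float)
    flags = resp > fit.curve(links[predictor].to_numpy(dtype=float))
    return flags, fit


def binomial_enrich(n_i, k_i, K: int, N: int) -> np.ndarray:
    """Upper-tail binomial p-value(s) for DCL enrichment of a gene.

    ``p = P(X >= k_i)`` with ``X ~ Binomial(n_i, K/N)``.  Degenerate
    rates are handled naturally: K = 0 gives p = 1 at k_i = 0, and
    K = N gives p = 1 for any k_i.
    """
    n_i = np.asarray(n_i, dtype=int)
    k_i = np.asarray(k_i, dtype=int)
    if N <= 0:
        raise ValueError("N must be positive")
    if np.any(k_i > n_i) or np.any(k_i < 0) or np.any(n_i > N):
        raise ValueError("require 0 <= k_i <= n_i <= N")
    if not 0 <= K <= N:
        raise ValueError("require 0 <= K <= N")
    return stats.binom.sf(k_i - 1, n_i, K / N)


def dce_run(
    fls: FilteredLinkSet,
    rho: float | None = 0.8,
    q_th: float | None = None,
    delta: float = 0.1,
    n_bins: int = 20,
    boundary_mode: str = "min-outlier",
    restrict_to_genes=None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full DCe pass: classify links, LFC-screen both classes, enrich genes.

    Returns ``(dcl_table, dcg_table)``.  The DCL table carries every
    filtered link with its class, features and ``is_dcl`` flag; the DCG
    table has per-gene link counts, DCL counts, the binomial p-value and
    BH q across genes, sorted by p.  ``restrict_to_genes`` optionally
    narrows the *reported* DCLs to those touching the given genes
    (post-hoc; the enrichment itself always uses the full link universe).
    """
    links = classify_links(fls, rho=rho, q_th=q_th)
    for cls, pred, resp in (
        (SAME_SIGNED, "max_corr", "lfc"),
        (DIFF_SIGNED, "lfc", "max_corr"),
    ):
        sub = links[links["cls"] == cls]
        if len(sub) == 0:
            continue
        flags, _ = lfc_select(
            sub, pred, resp, n_bins=n_bins, delta=delta,
            boundary_mode=boundary_mode,
        )
        links.loc[sub.index, "is_dcl"] = flags

    N = len(links)
    K = int(links["is_dcl"].sum())
    logger.info("DCe: N = %d filtered links, K = %d DCLs", N, K)

    genes = pd.unique(
        np.concatenate([links["gene_i"].to_numpy(), links["gene_j"].to_numpy()])
    )
    ends = pd.concat(
        [
            links[["gene_i", "is_dcl"]].set_axis(["gene", "is_dcl"], axis=1),
            links[["gene_j", "is_dcl"]].set_axis(["gene", "is_dcl"], axis=1),
        ],
        ignore_index=True,
    )
    counts = ends.groupby("gene", sort=False).agg(
        n_links=("is_dcl", "size"), n_dcl=("is_dcl", "sum")
    ).reindex(genes)
    p = binomial_enrich(
        counts["n_links"].to_numpy(), counts["n_dcl"].to_numpy(), K, N
    )
    dcg = pd.DataFrame(
        {
            "gene": genes,
            "n_links": counts["n_links"].to_numpy(),
            "n_dcl": counts["n_dcl"].to_numpy(),
            "p": p,
            "q": bh_adjust(p),
        }
    ).sort_values(["p", "gene"], kind="mergesort").reset_index(drop=True)

    if restrict_to_genes is not None:
        wanted = set(restrict_to_genes)
        touching = links["gene_i"].isin(wanted) | links["gene_j"].isin(wanted)
        links = links[~links["is_dcl"] | touching].copy()

    return links.reset_index(drop=True), dcg
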