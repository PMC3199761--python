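"""DCp: differential coexpression profiles.

For gene *i* with *n* neighbors in the half-thresholded link universe, the
correlations to those neighbors under the two conditions form vectors
X = (x_i1..x_in) and Y = (y_i1..y_in) — the gene's coexpression profiles.
The DCp statistic is the root-mean-square profile change

    dC_i = sqrt( sum_j (x_ij - y_ij)^2 / n )

which lies in [0, 2]; a single link reversing from +1 to -1 saturates the
bound.  Significance comes from a condition-label permutation test: the
pooled samples are reshuffled into two pseudo-conditions of the original
sizes, the whole pipeline (correlation → BH → half-threshold filter → dC)
is re-run, and all permutation dC values are pooled across genes and
rounds into one empirical null.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .corr import (
    ExpressionPair,
    FilteredLinkSet,
    allpairs_correlations,
    bh_adjust,
    half_threshold_mask,
)

logger = logging.getLogger(__name__)


def dcp_score(x, y) -> float:
    """RMS difference between a gene's two coexpression profiles."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("profiles must have equal length")
    if x.size == 0:
        raise ValueError("dC is undefined for a gene with no kept links")
    return float(np.sqrt(np.mean((x - y) ** 2)))


def coexpression_profiles(fls: FilteredLinkSet) -> dict[object, pd.DataFrame]:
    """Per-gene neighbor table with both condition correlations.

    Every gene incident to at least one kept link maps to a frame with
    columns ``neighbor``, ``x``, ``y``; isolated genes are absent.
    """
    links = fls.links
    if len(links) == 0:
        return {}
    # each undirected link contributes to both endpoint profiles
    fwd = links[["gene_i", "gene_j", "pcc_x", "pcc_y"]].set_axis(
        ["gene", "neighbor", "x", "y"], axis=1
    )
    rev = links[["gene_j", "gene_i", "pcc_x", "pcc_y"]].set_axis(
        ["gene", "neighbor", "x", "y"], axis=1
    )
    both = pd.concat([fwd, rev], ignore_index=True)
    return {
        gene: grp[["neighbor", "x", "y"]].reset_index(drop=True)
        for gene, grp in both.groupby("gene", sort=False)
    }


def _dc_arrays(idx_i, idx_j, x, y, n_genes):
    """Vectorized per-gene dC over an index-coded link set.

    Returns (dC, n_links) arrays of length n_genes; genes with no links
    get dC = NaN and n_links = 0.
    """
    d2 = (x - y) ** 2
    n = (
        np.bincount(idx_i, minlength=n_genes)
        + np.bincount(idx_j, minlength=n_genes)
    )
    s = (
        np.bincount(idx_i, weights=d2, minlength=n_genes)
        + np.bincount(idx_j, weights=d2, minlength=n_genes)
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        dc = np.sqrt(s / n)
    dc[n == 0] = np.nan
    return dc, n


def gene_dc_table(pair: ExpressionPair, fls: FilteredLinkSet) -> pd.DataFrame:
    """Observed dC per gene (columns gene, dC, n_links), dC descending."""
    gene_pos = {g: k for k, g in enumerate(pair.gene_ids)}
    links = fls.links
    idx_i = links["gene_i"].map(gene_pos).to_numpy(dtype=int)
    idx_j = links["gene_j"].map(gene_pos).to_numpy(dtype=int)
    dc, n = _dc_arrays(
        idx_i, idx_j,
        links["pcc_x"].to_numpy(dtype=float),
        links["pcc_y"].to_numpy(dtype=float),
        pair.n_genes,
    )
    out = pd.DataFrame({"gene": pair.gene_ids, "dC": dc, "n_links": n})
    return out.sort_values("dC", ascending=False, kind="mergesort").reset_index(
        drop=True
    )


def _pipeline_dc(vx, vy, q_th, rho, n_genes):
    """correlation → BH → half-threshold → dC, on raw arrays."""
    idx_i, idx_j, x, y, _, _, q_x, q_y = allpairs_correlations(vx, vy)
    mask = half_threshold_mask(q_x, q_y, x, y, q_th=q_th, rho=rho)
    dc, n = _dc_arrays(idx_i[mask], idx_j[mask], x[mask], y[mask], n_genes)
    return dc, n


def dcp_permutation_test(
    pair: ExpressionPair,
    n_perm: int = 1000,
    seed: int | None = None,
    q_th: float | None = 0.25,
    rho: float | None = None,
) -> pd.DataFrame:
    """DCp with permutation significance.

    Condition labels are shuffled over the pooled samples preserving the
    two group sizes; for each of ``n_perm`` rounds the full pipeline is
    re-run (the link universe is re-derived from the permuted data) and
    the resulting dC values, across all genes and rounds, form one pooled
    empirical null.  Per gene, ``p = (1 + #{null >= observed}) / (1 + #null)``
    (add-one estimator, never zero); BH across genes gives q.

    Returns a frame (gene, dC, p, q, n_links) sorted by dC descending;
    genes with no kept links in the observed data have dC = NaN and are
    assigned p = q = NaN.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if n_perm < 20:
        logger.warning(
            "n_perm = %d gives a coarse p-value resolution", n_perm
        )
    rng = np.random.default_rng(seed)
    vx = pair.cond_x.to_numpy(dtype=float)
    vy = pair.cond_y.to_numpy(dtype=float)
    n_genes = pair.n_genes
    nx = vx.shape[1]
    pooled = np.concatenate([vx, vy], axis=1)

    obs_dc, obs_n = _pipeline_dc(vx, vy, q_th, rho, n_genes)

    null_chunks = []
    for _ in range(n_perm):
        order = rng.permutation(pooled.shape[1])
        px = pooled[:, order[:nx]]
        py = pooled[:, order[nx:]]
        dc, _ = _pipeline_dc(px, py, q_th, rho, n_genes)
        null_chunks.append(dc[~np.isnan(dc)])
    null = np.concatenate(null_chunks) if null_chunks else np.empty(0)
    null.sort()

    p = np.full(n_genes, np.nan)
    defined = ~np.isnan(obs_dc)
    if null.size:
        # count of null values >= observed, via sorted search
        ge = null.size - np.searchsorted(null, obs_dc[defined], side="left")
        p[defined] = (1.0 + ge) / (1.0 + null.size)
    else:
        p[defined] = 1.0

    q = np.full(n_genes, np.nan)
    q[defined] = bh_adjust(p[defined])

    out = pd.DataFrame(
        {
            "gene": pair.gene_ids,
            "dC": obs_dc,
            "p": p,
            "q": q,
            "n_links": obs_n,
        }
    )
    return out.sort_values("dC", ascending=False, kind="mergesort").reset_index(
        drop=True
    )
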