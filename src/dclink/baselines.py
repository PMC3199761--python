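"""Connectivity-based comparator measures: LRC, ASC and WGCNA-style dC.

These are the gene-connectivity measures the link-based statistics are
evaluated against.  LRC and ASC operate on hard-thresholded binary
networks (a link exists in a condition iff ``|r| >= rho`` there); WGCNA
soft-thresholds, keeping every pair with its correlation raised to a
power ``beta``.  All three summarize a gene's neighborhood into one
number per condition and compare the two numbers, which is why none of
them can see a correlation that stays strong but flips sign.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

DEFAULT_RHO = 0.8
DEFAULT_BETA = 12


def hard_threshold_masks(links: pd.DataFrame, rho: float):
    """Per-condition binary presence masks over an all-pairs link table."""
    if not 0 < rho < 1:
        raise ValueError("rho must lie in (0, 1)")
    in_x = np.abs(links["pcc_x"].to_numpy(dtype=float)) >= rho
    in_y = np.abs(links["pcc_y"].to_numpy(dtype=float)) >= rho
    return in_x, in_y


def _per_gene_count(links: pd.DataFrame, mask: np.ndarray, genes) -> np.ndarray:
    ends = pd.concat(
        [links.loc[mask, "gene_i"], links.loc[mask, "gene_j"]],
        ignore_index=True,
    )
    return ends.value_counts().reindex(genes, fill_value=0).to_numpy()


def lrc_score(k_x, k_y) -> np.ndarray:
    """Absolute log10 ratio of connectivities, pseudo-count 1 guarding zeros."""
    k_x = np.asarray(k_x, dtype=float)
    k_y = np.asarray(k_y, dtype=float)
    if np.any(k_x < 0) or np.any(k_y < 0):
        raise ValueError("connectivities must be nonnegative")
    return np.abs(np.log10((k_x + 1.0) / (k_y + 1.0)))


def asc_score(specific_x, specific_y) -> np.ndarray:
    """Average count of condition-specific connections of a gene."""
    specific_x = np.asarray(specific_x, dtype=float)
    specific_y = np.asarray(specific_y, dtype=float)
    if np.any(specific_x < 0) or np.any(specific_y < 0):
        raise ValueError("counts must be nonnegative")
    return (specific_x + specific_y) / 2.0


def soft_adjacency(r: np.ndarray, beta: float, mode: str) -> np.ndarray:
    """WGCNA soft-threshold adjacency: |r|^beta or ((1+r)/2)^beta."""
    if beta < 1:
        raise ValueError("beta must be >= 1")
    r = np.asarray(r, dtype=float)
    if mode == "unsigned":
        return np.abs(r) ** beta
    if mode == "signed":
        return ((1.0 + r) / 2.0) ** beta
    raise ValueError(f"unknown WGCNA mode {mode!r}")


def lrc(links: pd.DataFrame, genes, rho: float = DEFAULT_RHO) -> pd.DataFrame:
    """LRC table (gene, dC) over the hard-thresholded networks."""
    in_x, in_y = hard_threshold_masks(links, rho)
    k_x = _per_gene_count(links, in_x, genes)
    k_y = _per_gene_count(links, in_y, genes)
    out = pd.DataFrame({"gene": genes, "dC": lrc_score(k_x, k_y)})
    return out.sort_values("dC", ascending=False, kind="mergesort").reset_index(
        drop=True
    )


def asc(links: pd.DataFrame, genes, rho: float = DEFAULT_RHO) -> pd.DataFrame:
    """ASC table (gene, dC): mean count of links present in only one network."""
    in_x, in_y = hard_threshold_masks(links, rho)
    only_x = in_x & ~in_y
    only_y = in_y & ~in_x
    sx = _per_gene_count(links, only_x, genes)
    sy = _per_gene_count(links, only_y, genes)
    out = pd.DataFrame({"gene": genes, "dC": asc_score(sx, sy)})
    return out.sort_values("dC", ascending=False, kind="mergesort").reset_index(
        drop=True
    )


def wgcna(
    links: pd.DataFrame,
    genes,
    beta: float = DEFAULT_BETA,
    mode: str = "signed",
    normalized: bool = False,
) -> pd.DataFrame:
    """WGCNA-style differential weighted connectivity (gene, dC).

    Soft-thresholding keeps all pairs, so ``links`` should be the full
    all-pairs table, not a filtered one.  Per gene,
    ``wk_c = sum_j a_c(i, j)`` with the signed or unsigned adjacency, and
    ``dC = |wk_x - wk_y|`` (optionally normalized by ``max(wk_x, wk_y)``).
    """
    a_x = soft_adjacency(links["pcc_x"].to_numpy(dtype=float), beta, mode)
    a_y = soft_adjacency(links["pcc_y"].to_numpy(dtype=float), beta, mode)
    gi = links["gene_i"].to_numpy()
    gj = links["gene_j"].to_numpy()
    wk_x = (
        pd.Series(a_x, index=gi).groupby(level=0).sum()
        .add(pd.Series(a_x, index=gj).groupby(level=0).sum(), fill_value=0.0)
        .reindex(genes, fill_value=0.0)
        .to_numpy()
    )
    wk_y = (
        pd.Series(a_y, index=gi).groupby(level=0).sum()
        .add(pd.Series(a_y, index=gj).groupby(level=0).sum(), fill_value=0.0)
        .reindex(genes, fill_value=0.0)
        .to_numpy()
    )
    dc = np.abs(wk_x - wk_y)
    if normalized:
        denom = np.maximum(np.maximum(wk_x, wk_y), np.finfo(float).tiny)
        dc = dc / denom
    out = pd.DataFrame({"gene": genes, "dC": dc})
    return out.sort_values("dC", ascending=False, kind="mergesort").reset_index(
        drop=True
    )
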