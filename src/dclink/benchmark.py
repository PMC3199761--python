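"""Replicate benchmark protocol: simulate, run every method, score.

One replicate = one simulated two-condition dataset with planted
perturbations; each method ranks genes, the ranking is scored by ROC
AUC against the planted DRGs, and the DCe DCL set is scored by DRL /
extended-DRL enrichment against the filtered link universe.  AUCs are
averaged arithmetically across replicates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import baselines
from .corr import ExpressionPair, compute_pcc, half_threshold_filter
from .dce import dce_run
from .dcp import gene_dc_table
from .evaluate import drl_enrichment, extended_truth, ranked_scores, roc_auc
from .simulate import _pair as _canon
from .simulate import simulate_pair


@dataclass
class ReplicateResult:
    """Per-replicate AUCs and DCe link-level enrichment."""

    aucs: dict[str, float]
    drl: dict
    extended: dict
    n_links: int
    n_dcls: int


@dataclass
class BenchmarkResult:
    replicates: list[ReplicateResult] = field(default_factory=list)

    def mean_auc(self, method: str) -> float:
        return float(np.mean([r.aucs[method] for r in self.replicates]))

    def auc_table(self) -> pd.DataFrame:
        rows = [r.aucs for r in self.replicates]
        return pd.DataFrame(rows)


def run_replicate(
    seed: int,
    n_genes: int = 200,
    rate: float = 0.1,
    mode: str = "switch",
    n_samples: int = 10,
    q_th: float = 0.25,
    wgcna_betas=(12,),
    delta: float = 0.1,
    dce_rho: float = 0.8,
) -> ReplicateResult:
    """Simulate one dataset pair and score all methods on it.

    DCp and the baselines rank genes by their dC scores; DCe ranks by
    its binomial enrichment p-value (small = differential).  WGCNA runs
    once per requested ``beta``, signed and unsigned.
    """
    cond_x, cond_y, truth, _ = simulate_pair(
        n_genes=n_genes, rate=rate, mode=mode, n_samples=n_samples, seed=seed
    )
    pair = ExpressionPair(cond_x, cond_y)
    links = compute_pcc(pair)
    fls = half_threshold_filter(links, q_th=q_th)
    genes = pair.gene_ids
    drgs = truth.drgs

    aucs: dict[str, float] = {}
    dcp_tbl = gene_dc_table(pair, fls)
    aucs["dcp"] = roc_auc(ranked_scores(dcp_tbl, genes), drgs)

    dcl_tbl, dcg_tbl = dce_run(fls, rho=dce_rho, delta=delta)
    aucs["dce"] = roc_auc(
        ranked_scores(dcg_tbl, genes, score_col="p", ascending=True), drgs
    )

    for beta in wgcna_betas:
        for wmode in ("signed", "unsigned"):
            tbl = baselines.wgcna(links, genes, beta=beta, mode=wmode)
            aucs[f"wgcna_{wmode}_beta{beta}"] = roc_auc(
                ranked_scores(tbl, genes), drgs
            )
    aucs["asc"] = roc_auc(ranked_scores(baselines.asc(links, genes), genes), drgs)
    aucs["lrc"] = roc_auc(ranked_scores(baselines.lrc(links, genes), genes), drgs)

    universe = {
        _canon(i, j)
        for i, j in zip(fls.links["gene_i"], fls.links["gene_j"])
    }
    dcl_mask = dcl_tbl["is_dcl"].to_numpy()
    dcls = {
        _canon(i, j)
        for i, j in zip(
            dcl_tbl.loc[dcl_mask, "gene_i"], dcl_tbl.loc[dcl_mask, "gene_j"]
        )
    }
    drl_set = set(truth.drls)
    drl = drl_enrichment(dcls, drl_set, universe)
    extended = drl_enrichment(dcls, extended_truth(drl_set, universe), universe)
    return ReplicateResult(
        aucs=aucs, drl=drl, extended=extended,
        n_links=len(universe), n_dcls=len(dcls),
    )


def wgcna_beta_contrast(
    n_replicates: int = 300,
    seed: int = 0,
    betas=(6, 12),
    **sim_kwargs,
) -> pd.DataFrame:
    """Paired signed-vs-unsigned WGCNA AUC contrast on fresh replicates.

    The signed-minus-unsigned AUC difference on switch perturbations is
    a small paired effect, so it is estimated on many more replicates
    than the headline five-replicate comparison.  Returns one row per
    replicate with columns ``signed_beta{b}`` / ``unsigned_beta{b}``.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for _ in range(n_replicates):
        cond_x, cond_y, truth, _ = simulate_pair(
            seed=int(rng.integers(0, 2**31)), **sim_kwargs
        )
        pair = ExpressionPair(cond_x, cond_y)
        links = compute_pcc(pair)
        genes = pair.gene_ids
        row = {}
        for beta in betas:
            for wmode in ("signed", "unsigned"):
                tbl = baselines.wgcna(links, genes, beta=beta, mode=wmode)
                row[f"{wmode}_beta{beta}"] = roc_auc(
                    ranked_scores(tbl, genes), truth.drgs
                )
        rows.append(row)
    return pd.DataFrame(rows)


def run_benchmark(
    n_replicates: int = 5,
    seed: int = 0,
    **replicate_kwargs,
) -> BenchmarkResult:
    """Run ``n_replicates`` independent replicates seeded from ``seed``."""
    rng = np.random.default_rng(seed)
    rep_seeds = rng.integers(0, 2**31, size=n_replicates)
    result = BenchmarkResult()
    for s in rep_seeds:
        result.replicates.append(run_replicate(int(s), **replicate_kwargs))
    return result
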