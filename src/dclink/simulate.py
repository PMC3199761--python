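"""Ground-truth benchmark generator: regulatory networks, planted
perturbations, and paired expression data.

The benchmark builds a signed, weighted, directed regulatory network,
perturbs a fixed fraction of its edges — *regulation-elimination*
(remove the edge) or *regulation-switch* (flip activation/repression) —
and simulates one expression matrix from the original network and one
from the perturbed network.  The perturbed edges are the differentially
regulated links (DRLs), their endpoint genes the DRGs, and DRLs plus all
links sharing a gene with a DRL the "extended DRLs"; these truth sets
are what the evaluation module scores method output against.

Expression is generated per sample: root genes (no regulators) draw
independent standard-normal baselines and every downstream gene takes a
tanh-squashed signed weighted sum of its regulators' levels plus
Gaussian noise, evaluated in topological order.  Activation therefore
yields positive parent-child expression correlation and repression
negative, in expectation — so a switched edge flips the sign of that
correlation between conditions while roughly preserving magnitude, and
an eliminated edge drives it toward zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

ELIMINATED = "eliminated"
SWITCHED = "switched"


def _pair(u: str, v: str) -> tuple[str, str]:
    """Canonical unordered gene pair."""
    return (u, v) if u <= v else (v, u)


@dataclass
class PerturbationTruth:
    """Planted perturbations and the derived truth sets for evaluation."""

    drls: dict[tuple[str, str], str]  # unordered pair -> perturbation type
    drgs: set[str] = field(init=False)
    extended_drls: set[tuple[str, str]] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.drgs = {g for pair in self.drls for g in pair}


def generate_network(
    n_genes: int,
    mean_degree: float = 2.0,
    activation_fraction: float = 0.7,
    seed: int | None = None,
    root_fraction: float = 0.15,
) -> nx.DiGraph:
    """Random directed regulatory network with hub-biased wiring.

    The first ``root_fraction`` of genes are regulatory inputs with no
    parents (a transcriptional network is driven by many independent
    signals, not a single master regulator).  Remaining genes are added
    one at a time, each receiving regulators drawn from existing genes
    with probability proportional to their current out-degree plus one
    (preferential attachment, giving the heavy-tailed out-degree
    profile of transcriptional networks).  Edges carry ``sign`` (+1
    activation with probability ``activation_fraction``, else -1
    repression) and ``weight`` drawn uniformly from [0.5, 1].  The
    construction is acyclic by design.
    """
    if n_genes < 10:
        raise ValueError("n_genes must be >= 10")
    if mean_degree < 1:
        raise ValueError("mean_degree must be >= 1")
    if mean_degree >= n_genes:
        raise ValueError("mean_degree must be smaller than n_genes")
    if not 0 < root_fraction < 1:
        raise ValueError("root_fraction must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    width = len(str(n_genes - 1))
    names = [f"G{i:0{width}d}" for i in range(n_genes)]
    net = nx.DiGraph()
    net.add_nodes_from(names)
    n_roots = max(1, round(root_fraction * n_genes))
    # target edges = mean_degree * n_genes / 2 (mean_degree counts both ends);
    # a cumulative quota keeps the realized count within rounding of target
    target_edges = mean_degree * n_genes / 2.0
    per_node = target_edges / (n_genes - n_roots)
    out_deg = np.zeros(n_genes)
    quota = 0
    for child in range(n_roots, n_genes):
        k = round(per_node * (child - n_roots + 1)) - quota
        quota += k
        k = min(child, k)
        probs = out_deg[:child] + 1.0
        probs /= probs.sum()
        parents = rng.choice(child, size=k, replace=False, p=probs)
        for parent in parents:
            sign = 1 if rng.random() < activation_fraction else -1
            weight = rng.uniform(0.5, 1.0)
            net.add_edge(names[parent], names[child], sign=sign, weight=weight)
            out_deg[parent] += 1
    return net


def perturb_network(
    net: nx.DiGraph,
    rate: float,
    mode: str = "switch",
    seed: int | None = None,
) -> tuple[nx.DiGraph, PerturbationTruth]:
    """Plant perturbations on ``round(rate * |edges|)`` uniformly chosen edges.

    ``mode`` is ``eliminate`` (remove the regulation), ``switch`` (flip
    its sign) or ``mixed`` (half each; an odd count gives elimination
    the extra edge).  Returns the perturbed copy and the truth record,
    including extended DRLs computed from the original adjacency.
    """
    if not 0 < rate < 1:
        raise ValueError("rate must lie in (0, 1)")
    if mode not in ("eliminate", "switch", "mixed"):
        raise ValueError(f"unknown perturbation mode {mode!r}")
    edges = list(net.edges())
    n_perturb = round(rate * len(edges))
    if n_perturb == 0:
        raise ValueError("rate too small: no edges would be perturbed")
    rng = np.random.default_rng(seed)
    chosen = [edges[i] for i in rng.choice(len(edges), n_perturb, replace=False)]
    if mode == "eliminate":
        kinds = [ELIMINATED] * n_perturb
    elif mode == "switch":
        kinds = [SWITCHED] * n_perturb
    else:
        n_elim = (n_perturb + 1) // 2
        kinds = [ELIMINATED] * n_elim + [SWITCHED] * (n_perturb - n_elim)

    perturbed = net.copy()
    drls: dict[tuple[str, str], str] = {}
    for (u, v), kind in zip(chosen, kinds):
        if kind == ELIMINATED:
            perturbed.remove_edge(u, v)
        else:
            perturbed[u][v]["sign"] *= -1
        drls[_pair(u, v)] = kind

    truth = PerturbationTruth(drls=drls)
    all_pairs = {_pair(u, v) for u, v in net.edges()}
    extended = set(drls)
    for pair in all_pairs:
        if pair[0] in truth.drgs or pair[1] in truth.drgs:
            extended.add(pair)
    truth.extended_drls = extended
    return perturbed, truth


def simulate_expression(
    net: nx.DiGraph,
    n_samples: int = 10,
    noise_sd: float = 0.25,
    seed: int | None = None,
    max_cycle_iter: int = 5,
) -> pd.DataFrame:
    """Simulate a genes × samples expression matrix from a regulatory network.

    Root genes draw independent N(0, 1) baselines per sample; each
    regulated gene's level is ``tanh(sum_p sign_p * weight_p * level_p)``
    plus N(0, noise_sd) noise, evaluated in topological order.  Cyclic
    networks are resolved by ``max_cycle_iter`` fixed-point sweeps over
    an arbitrary order.  Row order is the network's node order.
    """
    if n_samples < 4:
        raise ValueError("n_samples must be >= 4")
    rng = np.random.default_rng(seed)
    nodes = list(net.nodes())
    pos = {g: k for k, g in enumerate(nodes)}
    levels = np.zeros((len(nodes), n_samples))
    try:
        order = list(nx.topological_sort(net))
        sweeps = 1
    except nx.NetworkXUnfeasible:
        order = nodes
        sweeps = max_cycle_iter
    # baselines for every gene first, so the draw sequence (hence the
    # matrix under a fixed seed) does not depend on topology details
    baseline = rng.standard_normal((len(nodes), n_samples))
    noise = rng.normal(0.0, noise_sd, size=(len(nodes), n_samples)) \
        if noise_sd > 0 else np.zeros((len(nodes), n_samples))
    levels[:] = baseline
    for _ in range(sweeps):
        for gene in order:
            parents = list(net.predecessors(gene))
            if not parents:
                continue
            total = np.zeros(n_samples)
            for parent in parents:
                edge = net[parent][gene]
                total += edge["sign"] * edge["weight"] * levels[pos[parent]]
            levels[pos[gene]] = np.tanh(total) + noise[pos[gene]]
    return pd.DataFrame(levels, index=nodes)


def simulate_pair(
    n_genes: int = 200,
    mean_degree: float = 2.0,
    rate: float = 0.1,
    mode: str = "switch",
    n_samples: int = 10,
    noise_sd: float = 0.25,
    activation_fraction: float = 0.7,
    seed: int | None = None,
):
    """One full benchmark instance: original/perturbed nets, data, truth.

    Returns ``(cond_x, cond_y, truth, net)`` where ``cond_x`` is
    simulated from the original network and ``cond_y`` from the
    perturbed one, with independent samples.  All randomness flows from
    ``seed`` through one generator.
    """
    rng = np.random.default_rng(seed)
    sub = [int(s) for s in rng.integers(0, 2**31, size=4)]
    net = generate_network(
        n_genes, mean_degree, activation_fraction, seed=sub[0]
    )
    perturbed, truth = perturb_network(net, rate, mode, seed=sub[1])
    cond_x = simulate_expression(net, n_samples, noise_sd, seed=sub[2])
    cond_y = simulate_expression(perturbed, n_samples, noise_sd, seed=sub[3])
    cond_x.columns = [f"X{k}" for k in range(n_samples)]
    cond_y.columns = [f"Y{k}" for k in range(n_samples)]
    return cond_x, cond_y, truth, net
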