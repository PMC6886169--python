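"""Weighted lncRNA functional network and random walk with restart (RWR).

The network is undirected, weighted in (0, 1], with zero-weight pairs absent.
RWR iterates p <- (1-r) W p + r p0 on the column-normalized weighted
adjacency W, seeded uniformly on a disease's known lncRNAs; the fixed point
scores every node's proximity to the seeds and ranks candidates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy import sparse

from .io import AssociationTable
from .lncrna_similarity import LncPairScore

logger = logging.getLogger(__name__)


@dataclass
class RwrConfig:
    """Walk parameters: restart probability, convergence tolerance, iteration cap."""

    restart_prob: float = 0.7
    tol: float = 1e-10
    max_iter: int = 1000

    def __post_init__(self) -> None:
        if not (0.0 < self.restart_prob < 1.0):
            raise ValueError("restart_prob must lie in (0, 1)")
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")


def assemble_network(
    pair_scores: list[LncPairScore],
    min_weight: float = 0.0,
    nodes: set[str] | None = None,
) -> nx.Graph:
    """Build the undirected weighted network from pair scores.

    Edges keep weights strictly above ``max(0, min_weight)``; lncRNAs passed
    via ``nodes`` are retained even when isolated.
    """
    net = nx.Graph()
    if nodes:
        net.add_nodes_from(nodes)
    threshold = max(0.0, min_weight)
    for s in pair_scores:
        if s.lncrna_a == s.lncrna_b:
            continue
        if s.weight > threshold:
            net.add_edge(s.lncrna_a, s.lncrna_b, weight=s.weight, cr=s.cr, mr=s.mr)
    if net.number_of_edges() == 0:
        logger.warning("network has no edges; RWR will return the seed distribution")
    return net


def _column_normalized(net: nx.Graph, order: list[str]) -> sparse.csr_matrix:
    adj = nx.to_scipy_sparse_array(net, nodelist=order, weight="weight", format="csc")
    col_sums = np.asarray(adj.sum(axis=0)).ravel()
    scale = np.divide(1.0, col_sums, out=np.zeros_like(col_sums, dtype=float), where=col_sums > 0)
    return (adj @ sparse.diags(scale)).tocsr(), col_sums == 0


def rwr(net: nx.Graph, seeds: set[str], cfg: RwrConfig | None = None) -> dict[str, float]:
    """Stationary RWR probabilities over all network nodes.

    The walker restarts to a uniform distribution over the seeds with
    probability ``restart_prob``; dangling (isolated) node columns are
    replaced by the restart vector so probability mass is conserved. Stops
    when the L1 change drops below ``tol`` or at ``max_iter``.
    """
    cfg = cfg or RwrConfig()
    if not seeds:
        raise ValueError("no known lncRNAs for disease: empty seed set")
    order = sorted(net.nodes)
    missing = seeds - set(order)
    if missing:
        raise ValueError(f"seeds not in network: {sorted(missing)}")
    idx = {n: i for i, n in enumerate(order)}
    n = len(order)
    p0 = np.zeros(n)
    for s in seeds:
        p0[idx[s]] = 1.0 / len(seeds)
    W, dangling = _column_normalized(net, order)
    r = cfg.restart_prob
    p = p0.copy()
    for _ in range(cfg.max_iter):
        # dangling columns redirect their mass to the restart vector
        p_new = (1.0 - r) * (W @ p + p[dangling].sum() * p0) + r * p0
        if np.abs(p_new - p).sum() < cfg.tol:
            p = p_new
            break
        p = p_new
    return {node: float(p[idx[node]]) for node in order}


def rwr_dense_solve(net: nx.Graph, seeds: set[str], restart_prob: float = 0.7) -> dict[str, float]:
    """Closed-form RWR via the dense linear system (I - (1-r) W) p = r p0.

    Exact fixed point for cross-checking the power iteration; intended for
    small networks.
    """
    order = sorted(net.nodes)
    idx = {n: i for i, n in enumerate(order)}
    n = len(order)
    p0 = np.zeros(n)
    for s in seeds:
        p0[idx[s]] = 1.0 / len(seeds)
    W, dangling = _column_normalized(net, order)
    W = W.toarray()
    W[:, dangling] = p0[:, None]  # dangling columns restart
    p = np.linalg.solve(np.eye(n) - (1.0 - restart_prob) * W, restart_prob * p0)
    return {node: float(p[idx[node]]) for node in order}


@dataclass
class RankedList:
    """RWR ranking of candidate lncRNAs for one disease.

    ``entries`` rows are (lncrna, probability, rank, percentile) over
    non-seed candidates sorted by probability descending; ties break by
    lexicographic lncRNA id. Percentile = rank / number of candidates.
    """

    disease: str
    seeds: set[str]
    entries: list[tuple[str, float, int, float]] = field(default_factory=list)

    def percentile_of(self, lncrna: str) -> float:
        for name, _, _, pct in self.entries:
            if name == lncrna:
                return pct
        raise KeyError(lncrna)

    def probabilities(self) -> dict[str, float]:
        return {name: p for name, p, _, _ in self.entries}


def rank_candidates(
    net: nx.Graph,
    disease: str,
    known: AssociationTable,
    cfg: RwrConfig | None = None,
) -> RankedList:
    """Rank all non-seed network lncRNAs for a disease by RWR probability."""
    seeds = known.lefts_of(disease) & set(net.nodes)
    if not seeds:
        raise ValueError(f"no known lncRNAs for disease {disease!r} present in the network")
    probs = rwr(net, seeds, cfg)
    candidates = sorted(
        (l for l in net.nodes if l not in seeds),
        key=lambda l: (-probs[l], l),
    )
    n_cand = len(candidates)
    entries = [
        (l, probs[l], rank, rank / n_cand)
        for rank, l in enumerate(candidates, start=1)
    ]
    return RankedList(disease=disease, seeds=seeds, entries=entries)


def export_network(net: nx.Graph, path, min_weight: float = 0.4, fmt: str = "tsv") -> None:
    """Export edges above the display threshold as TSV or GraphML."""
    sub = nx.Graph()
    sub.add_nodes_from(net.nodes)
    for a, b, data in net.edges(data=True):
        if data["weight"] > min_weight:
            sub.add_edge(a, b, **data)
    if fmt == "tsv":
        with open(path, "w", encoding="utf-8") as fh:
            for a, b, data in sorted(sub.edges(data=True)):
                fh.write(f"{a}\t{b}\t{data['weight']:.6g}\n")
    elif fmt == "graphml":
        nx.write_graphml(sub, path)
    else:
        raise ValueError(f"unknown export format {fmt!r}")
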