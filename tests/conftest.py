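"""Shared fixtures and independent brute-force oracles.

The oracles re-derive every statistic from its definition with plain Python
loops, independently of the library's vectorized paths.
"""

from __future__ import annotations

import math

import numpy as np
import pytest

import lncdisap as ld


# ---------------------------------------------------------------------------
# Independent oracles
# ---------------------------------------------------------------------------

def oracle_cosine(v1, v2) -> float:
    dot = sum(a * b for a, b in zip(v1, v2))
    n1 = math.sqrt(sum(a * a for a in v1))
    n2 = math.sqrt(sum(b * b for b in v2))
    if n1 == 0 or n2 == 0:
        return 0.0
    return dot / (n1 * n2)


def oracle_relevance(g, G, links: dict[frozenset, float]) -> float:
    if g in G:
        return 1.0
    best = 0.0
    for m in G:
        best = max(best, links.get(frozenset((g, m)), 0.0))
    return best


def oracle_fnsim(Ga, Gb, links: dict[frozenset, float]) -> float:
    if not Ga or not Gb:
        return 0.0
    total = sum(oracle_relevance(g, Gb, links) for g in Ga)
    total += sum(oracle_relevance(g, Ga, links) for g in Gb)
    return total / (len(Ga) + len(Gb))


def oracle_mrna_relevance(k, M, edges: set[frozenset]) -> float:
    if k in M:
        return 1.0
    if not M:
        return 0.0
    return sum(1 for m in M if frozenset((k, m)) in edges) / len(M)


def oracle_mr(M1, M2, edges: set[frozenset]) -> float:
    if not M1 and not M2:
        return 0.0
    total = sum(oracle_mrna_relevance(m, M1, edges) for m in M2)
    total += sum(oracle_mrna_relevance(m, M2, edges) for m in M1)
    return total / (len(M1) + len(M2))


def oracle_rwr(net, seeds, r) -> dict[str, float]:
    """Dense linear-solve RWR built directly from the graph definition."""
    order = sorted(net.nodes)
    n = len(order)
    idx = {v: i for i, v in enumerate(order)}
    W = np.zeros((n, n))
    for a, b, data in net.edges(data=True):
        W[idx[a], idx[b]] = data["weight"]
        W[idx[b], idx[a]] = data["weight"]
    p0 = np.zeros(n)
    for s in seeds:
        p0[idx[s]] = 1.0 / len(seeds)
    for j in range(n):
        col = W[:, j].sum()
        if col > 0:
            W[:, j] /= col
        else:
            W[:, j] = p0
    p = np.linalg.solve(np.eye(n) - (1 - r) * W, r * p0)
    return {v: p[idx[v]] for v in order}


def oracle_trapezoid_auc(scores, positives, negatives) -> float:
    """AUC as the trapezoidal area under the empirical ROC curve."""
    pts = sorted({scores.get(x, 0.0) for x in positives | negatives})
    thresholds = [math.inf] + pts[::-1] + [-math.inf]
    roc = []
    for t in thresholds:
        tpr = sum(1 for x in positives if scores.get(x, 0.0) >= t) / len(positives)
        fpr = sum(1 for x in negatives if scores.get(x, 0.0) >= t) / len(negatives)
        roc.append((fpr, tpr))
    roc.sort()
    area = 0.0
    for (x0, y0), (x1, y1) in zip(roc, roc[1:]):
        area += (x1 - x0) * (y0 + y1) / 2.0
    return area


def links_as_dict(linkset: ld.GeneLinkSet) -> dict[frozenset, float]:
    return {frozenset((a, b)): s for a, b, s in linkset.iter_links()}


def random_linkset(rng: np.random.Generator, items, n_links, namespace="gene") -> ld.GeneLinkSet:
    links = ld.GeneLinkSet(namespace)
    for _ in range(n_links):
        i, j = rng.choice(len(items), size=2, replace=False)
        links.add(items[int(i)], items[int(j)], float(rng.uniform(0.05, 1.0)))
    return links


# ---------------------------------------------------------------------------
# Fixtures
# ---------------------------------------------------------------------------

@pytest.fixture(scope="session")
def example_bundle() -> ld.Bundle:
    return ld.worked_example()


@pytest.fixture(scope="session")
def planted_bundle() -> ld.Bundle:
    """The headline planted-module benchmark at its default study conditions."""
    return ld.generate(ld.FixtureConfig(seed=0))


@pytest.fixture
def diamond_ontology() -> ld.DiseaseOntology:
    """Leaf D reaches root A through two paths (B and C)."""
    onto = ld.build_ontology([("D", "B"), ("D", "C"), ("B", "A"), ("C", "A")])
    table = ld.AssociationTable("disease", "gene")
    table.add("D", "g1")
    table.add("B", "g2")
    table.add("C", "g3")
    table.add("A", "g4")
    return ld.propagate_annotations(onto, table)
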