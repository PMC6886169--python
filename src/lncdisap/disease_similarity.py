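"""Disease functional similarity from gene sets, with an ontology correction.

Two diseases are compared through their annotated gene sets: each gene of one
set is scored against the other set by its best (or mean) functional link, and
the two directed sums are averaged over the total number of genes (FNSim).
The semantic variant (FNSemSim) rescales FNSim by |G_a||G_b| / |G_MICA|^2,
where G_MICA is the propagated gene set of the most informative common
ancestor of the two terms in the disease ontology DAG. The resulting raw
matrix is min-max normalized over distinct pairs into [0, 1].
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd

from .io import DiseaseOntology, GeneLinkSet

logger = logging.getLogger(__name__)


def gene_set_relevance(g: str, G: set[str], net: GeneLinkSet, mode: str = "max") -> float:
    """Degree of association between gene ``g`` and gene set ``G``.

    Returns 1 if ``g`` is a member; otherwise the maximum (or, with
    ``mode='mean'``, the mean) functional link score from ``g`` into ``G``,
    and 0 when no link exists.
    """
    if g in G:
        return 1.0
    scores = [net.score(g, m) for m in G]
    if not scores:
        return 0.0
    if mode == "max":
        return max(scores)
    if mode == "mean":
        positive = [s for s in scores if s > 0]
        return sum(positive) / len(positive) if positive else 0.0
    raise ValueError(f"unknown relevance mode {mode!r}")


def fnsim(Ga: set[str], Gb: set[str], net: GeneLinkSet, mode: str = "max") -> float:
    """Functional similarity between two disease gene sets, in [0, 1].

    Symmetric best-match average: (sum of Gb-relevance over Ga's genes +
    sum of Ga-relevance over Gb's genes) / (|Ga| + |Gb|). Empty sets are a
    degenerate branch returning 0.
    """
    if not Ga or not Gb:
        logger.warning("fnsim called with an empty gene set; returning 0")
        return 0.0
    total = sum(gene_set_relevance(g, Gb, net, mode) for g in Ga)
    total += sum(gene_set_relevance(g, Ga, net, mode) for g in Gb)
    return total / (len(Ga) + len(Gb))


def information_content(term: str, onto: DiseaseOntology) -> float:
    """IC(t) = -log(|propagated genes of t| / |all propagated genes at roots|).

    Terms with no propagated annotations get -inf (they never win MICA).
    """
    n_total = len(set().union(*(onto.propagated.get(r, set()) for r in onto.roots())) if onto.roots() else set())
    n_term = len(onto.propagated.get(term, set()))
    if n_term == 0 or n_total == 0:
        return -math.inf
    return -math.log(n_term / n_total)


def mica(da: str, db: str, onto: DiseaseOntology) -> str | None:
    """Most informative common ancestor of two terms (a term is its own ancestor).

    Ties are broken by higher IC then lexicographically smallest term id;
    returns None when the terms share no ancestor (disjoint forest roots).
    """
    if da not in onto.graph or db not in onto.graph:
        return None
    common = onto.ancestors(da) & onto.ancestors(db)
    if not common:
        return None

    # IC is antitone in propagated-annotation size, so the smallest non-empty
    # propagated set wins; zero-annotation terms (IC = -inf) never win.
    def key(t: str) -> tuple[float, str]:
        n = len(onto.propagated.get(t, set()))
        return (n if n > 0 else math.inf, t)

    return min(common, key=key)


def fnsemsim(
    da: str,
    db: str,
    gene_sets: dict[str, set[str]],
    net: GeneLinkSet,
    onto: DiseaseOntology,
    mode: str = "max",
) -> float:
    """Raw semantic functional similarity: FNSim * |Ga||Gb| / |G_MICA|^2.

    May exceed 1; the pairwise matrix is min-max normalized afterwards.
    Returns 0 when either gene set is empty, no common ancestor exists, or
    the MICA has no propagated annotations.
    """
    Ga = gene_sets.get(da, set())
    Gb = gene_sets.get(db, set())
    if not Ga or not Gb:
        return 0.0
    base = fnsim(Ga, Gb, net, mode)
    if base == 0.0:
        return 0.0
    anc = mica(da, db, onto)
    if anc is None:
        return 0.0
    n_mica = len(onto.propagated.get(anc, set()))
    if n_mica == 0:
        logger.warning("MICA %s of (%s, %s) has no annotations; similarity set to 0", anc, da, db)
        return 0.0
    return base * (len(Ga) * len(Gb)) / (n_mica ** 2)


def minmax_normalize(raw: pd.DataFrame) -> pd.DataFrame:
    """Min-max normalize off-diagonal similarities into [0, 1].

    The diagonal is excluded from the normalization pool and pinned to 1
    (self-similarity). A constant off-diagonal maps to all zeros.
    """
    mat = raw.to_numpy(dtype=float).copy()
    n = mat.shape[0]
    mask = ~np.eye(n, dtype=bool)
    if n > 1:
        vals = mat[mask]
        lo, hi = vals.min(), vals.max()
        if hi > lo:
            mat[mask] = (mat[mask] - lo) / (hi - lo)
        else:
            logger.warning("constant off-diagonal similarities; normalized to 0")
            mat[mask] = 0.0
    np.fill_diagonal(mat, 1.0)
    return pd.DataFrame(mat, index=raw.index, columns=raw.columns)


def disease_similarity_matrix(
    diseases: list[str],
    onto: DiseaseOntology,
    net: GeneLinkSet,
    use_propagated_gene_sets: bool = False,
    relevance: str = "max",
    normalize: bool = True,
) -> pd.DataFrame:
    """Pairwise normalized FNSemSim matrix over the given diseases.

    Gene sets default to the direct disease-gene annotations; diseases with
    no annotations are similar only to themselves.
    """
    source = onto.propagated if use_propagated_gene_sets else onto.annotations
    gene_sets = {d: set(source.get(d, ())) for d in diseases}
    n = len(diseases)
    mat = np.zeros((n, n))
    for i in range(n):
        mat[i, i] = fnsemsim(diseases[i], diseases[i], gene_sets, net, onto, relevance)
        for j in range(i + 1, n):
            v = fnsemsim(diseases[i], diseases[j], gene_sets, net, onto, relevance)
            mat[i, j] = mat[j, i] = v
    raw = pd.DataFrame(mat, index=diseases, columns=diseases)
    return minmax_normalize(raw) if normalize else raw


def write_similarity_tsv(sim: pd.DataFrame, path) -> None:
    """Write one row per unordered disease pair with similarity > 0."""
    with open(path, "w", encoding="utf-8") as fh:
        idx = list(sim.index)
        for i, a in enumerate(idx):
            for b in idx[i + 1:]:
                v = sim.at[a, b]
                if v > 0:
                    fh.write(f"{a}\t{b}\t{v:.6g}\n")
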