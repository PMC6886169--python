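"""Pairwise lncRNA similarity channels and their noisy-OR combination.

Three evidence channels are computed per lncRNA pair:

* CR — cosine similarity of the disease/protein association vectors;
* MR — symmetric best-match relevance of the two lncRNAs' mRNA sets over a
  background mRNA-mRNA link list;
* ER (optional) — Spearman rank correlation of tissue expression profiles,
  clamped to [0, 1].

The network edge weight combines channels as independent evidence:
weight = 1 - (1-CR)(1-MR)[(1-ER)], so any single strong channel dominates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import AssociationTable, GeneLinkSet

logger = logging.getLogger(__name__)


def cosine_cr(v1: np.ndarray, v2: np.ndarray) -> float:
    """Cosine similarity of two association-score vectors; 0 if either is zero."""
    v1 = np.asarray(v1, dtype=float)
    v2 = np.asarray(v2, dtype=float)
    n1 = np.linalg.norm(v1)
    n2 = np.linalg.norm(v2)
    if n1 == 0.0 or n2 == 0.0:
        return 0.0
    return float(np.dot(v1, v2) / (n1 * n2))


def mrna_relevance(k: str, M: set[str], linkset: GeneLinkSet) -> float:
    """Relevance of mRNA ``k`` to mRNA set ``M``: 1 on membership, else links(k,M)/|M|.

    links(k, M) counts each undirected (k, m) edge once; self-pairs are never
    counted (k in M short-circuits to 1 anyway).
    """
    if k in M:
        return 1.0
    if not M:
        return 0.0
    n_links = sum(1 for m in M if linkset.score(k, m) > 0)
    return n_links / len(M)


def mrna_mr(M1: set[str], M2: set[str], linkset: GeneLinkSet) -> float:
    """mRNA-based similarity between two lncRNAs' mRNA sets, in [0, 1].

    Sum of M2's members' relevance to M1 plus M1's members' relevance to M2,
    divided by |M1| + |M2|. Both sets empty gives 0.
    """
    if not M1 and not M2:
        logger.warning("mrna_mr called with two empty mRNA sets; returning 0")
        return 0.0
    total = sum(mrna_relevance(m, M1, linkset) for m in M2)
    total += sum(mrna_relevance(m, M2, linkset) for m in M1)
    return total / (len(M1) + len(M2))


def expression_er(x1: np.ndarray, x2: np.ndarray, transform: str = "clamp") -> float:
    """Expression similarity: Spearman rho of two profiles mapped into [0, 1].

    ``transform='clamp'`` floors negative rho at 0; ``'abs'`` takes |rho|.
    Constant profiles (rho undefined) return 0.
    """
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    if x1.size < 3 or x2.size < 3:
        raise ValueError("at least 3 shared samples required")
    if np.all(x1 == x1[0]) or np.all(x2 == x2[0]):
        logger.warning("constant expression profile; ER set to 0")
        return 0.0
    rho = stats.spearmanr(x1, x2).statistic
    if np.isnan(rho):
        return 0.0
    if transform == "clamp":
        return max(0.0, float(rho))
    if transform == "abs":
        return abs(float(rho))
    raise ValueError(f"unknown er_transform {transform!r}")


def combine_weight(cr: float, mr: float, er: float | None = None) -> float:
    """Noisy-OR combination of evidence channels: 1 - prod(1 - channel)."""
    w = 1.0 - (1.0 - cr) * (1.0 - mr)
    if er is not None:
        w = 1.0 - (1.0 - w) * (1.0 - er)
    return w


@dataclass(frozen=True)
class LncPairScore:
    """Similarity channels and combined weight for one unordered lncRNA pair."""

    lncrna_a: str
    lncrna_b: str
    cr: float
    mr: float
    er: float | None
    weight: float


def all_pair_scores(
    vectors: pd.DataFrame,
    lnc_mrna: AssociationTable,
    mrna_links: GeneLinkSet,
    expression: pd.DataFrame | None = None,
    er_transform: str = "clamp",
) -> list[LncPairScore]:
    """Score every unordered pair of lncRNAs; zero-weight pairs are dropped.

    Pairs are enumerated among the lncRNAs indexing ``vectors`` (the
    association-bearing lncRNAs). The optional expression channel applies only
    to pairs with profiles for both members.
    """
    lncrnas = sorted(vectors.index)
    mat = vectors.loc[lncrnas].to_numpy(dtype=float)
    norms = np.linalg.norm(mat, axis=1)
    msets = lnc_mrna.by_left()
    out: list[LncPairScore] = []
    for i, a in enumerate(lncrnas):
        for j in range(i + 1, len(lncrnas)):
            b = lncrnas[j]
            if norms[i] > 0 and norms[j] > 0:
                cr = float(np.dot(mat[i], mat[j]) / (norms[i] * norms[j]))
            else:
                cr = 0.0
            Ma = msets.get(a, set())
            Mb = msets.get(b, set())
            mr = mrna_mr(Ma, Mb, mrna_links) if (Ma or Mb) else 0.0
            er: float | None = None
            if expression is not None and a in expression.index and b in expression.index:
                er = expression_er(
                    expression.loc[a].to_numpy(),
                    expression.loc[b].to_numpy(),
                    transform=er_transform,
                )
            w = combine_weight(cr, mr, er)
            if w > 0.0:
                out.append(LncPairScore(a, b, cr, mr, er, w))
    return out


def write_pair_scores_tsv(scores: list[LncPairScore], path, with_er: bool = False) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for s in scores:
            cols = [s.lncrna_a, s.lncrna_b, f"{s.cr:.6g}", f"{s.mr:.6g}"]
            if with_er:
                cols.append(f"{0.0 if s.er is None else s.er:.6g}")
            cols.append(f"{s.weight:.6g}")
            fh.write("\t".join(cols) + "\n")
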