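"""Collaborative-filtering association vectors for lncRNAs.

Each lncRNA is embedded in a |D|+|P|-dimensional space whose axes are all
lncRNA-related diseases followed by all lncRNA-related proteins. A directly
associated dimension scores 1; an unobserved dimension is imputed by the MAX
rule of collaborative filtering — the best similarity between the dimension's
entity and any entity the lncRNA is directly associated with (normalized
disease similarity for diseases, protein link score for proteins). No
evidence yields 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import AssociationTable, GeneLinkSet

logger = logging.getLogger(__name__)


@dataclass
class DimensionSpace:
    """Ordered disease and protein axes shared by all lncRNA vectors."""

    diseases: list[str]
    proteins: list[str]

    @classmethod
    def from_tables(cls, lnc_disease: AssociationTable, lnc_protein: AssociationTable) -> "DimensionSpace":
        """Axes are the union over all lncRNAs of their associated entities."""
        return cls(sorted(lnc_disease.rights()), sorted(lnc_protein.rights()))

    @property
    def size(self) -> int:
        return len(self.diseases) + len(self.proteins)

    def labels(self) -> list[str]:
        return list(self.diseases) + list(self.proteins)


def association_score_disease(d: str, DRl: set[str], dsim: pd.DataFrame) -> float:
    """Predicted association score between disease ``d`` and a lncRNA.

    1 if ``d`` is directly associated (d in DRl); else MAX over the lncRNA's
    diseases of their normalized similarity to ``d``; 0 with no associations.
    """
    if d in DRl:
        return 1.0
    best = 0.0
    for di in DRl:
        if di in dsim.index and d in dsim.columns:
            s = float(dsim.at[di, d])
            if s > best:
                best = s
    return best


def association_score_protein(p: str, PRl: set[str], pnet: GeneLinkSet) -> float:
    """Predicted association score between protein ``p`` and a lncRNA.

    1 if directly associated; else MAX link score from the lncRNA's proteins
    to ``p``; 0 with no associations or no links.
    """
    if p in PRl:
        return 1.0
    return max((pnet.score(pi, p) for pi in PRl), default=0.0)


def build_vectors(
    lncrnas: list[str],
    space: DimensionSpace,
    lnc_disease: AssociationTable,
    lnc_protein: AssociationTable,
    dsim: pd.DataFrame,
    pnet: GeneLinkSet,
) -> pd.DataFrame:
    """One |D|+|P| association-score vector per lncRNA (rows), entries in [0, 1]."""
    dr = lnc_disease.by_left()
    pr = lnc_protein.by_left()
    mat = np.zeros((len(lncrnas), space.size))
    nd = len(space.diseases)
    for i, l in enumerate(lncrnas):
        DRl = dr.get(l, set())
        PRl = pr.get(l, set())
        if not DRl and not PRl:
            logger.info("lncRNA %s has no disease or protein associations; zero vector", l)
        for k, d in enumerate(space.diseases):
            mat[i, k] = association_score_disease(d, DRl, dsim)
        for j, p in enumerate(space.proteins):
            mat[i, nd + j] = association_score_protein(p, PRl, pnet)
    return pd.DataFrame(mat, index=lncrnas, columns=space.labels())


def write_vectors_tsv(vectors: pd.DataFrame, path) -> None:
    """Write nonzero entries as lncrna_id, dimension_id, score."""
    with open(path, "w", encoding="utf-8") as fh:
        for l in vectors.index:
            row = vectors.loc[l]
            for dim, v in row.items():
                if v > 0:
                    fh.write(f"{l}\t{dim}\t{v:.6g}\n")
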