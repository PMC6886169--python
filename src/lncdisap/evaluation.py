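"""Two-snapshot validation of the lncRNA functional network.

Test sets come from the difference of two lncRNA-disease snapshot versions:
per disease, positives are lncRNAs associated only in the newer snapshot (and
present as network nodes); negatives are network lncRNAs associated in
neither snapshot. Each disease is scored by one RWR seeded on its
older-snapshot lncRNAs, and performance is the Mann-Whitney ROC AUC, macro-
averaged over diseases.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.stats import rankdata

from .io import AssociationTable
from .network import RwrConfig, rwr

logger = logging.getLogger(__name__)


@dataclass
class VersionDiffTestSet:
    """Per-disease positives/negatives from an old-vs-new snapshot difference."""

    positives: dict[str, set[str]] = field(default_factory=dict)
    negatives: dict[str, set[str]] = field(default_factory=dict)
    seeds: dict[str, set[str]] = field(default_factory=dict)
    skipped: dict[str, str] = field(default_factory=dict)

    @property
    def diseases(self) -> list[str]:
        return sorted(self.positives)

    @property
    def n_pairs(self) -> int:
        return sum(len(p) for p in self.positives.values())


def version_diff(
    old: AssociationTable,
    new: AssociationTable,
    net_nodes: set[str],
) -> VersionDiffTestSet:
    """Build the per-disease test set from two snapshot versions.

    Positives(d) = lncRNAs newly paired with d in the later snapshot, present
    as network nodes, and not already old-associated with d. Seeds(d) come
    strictly from the older snapshot; removals between versions are ignored.
    Diseases with no positives, no negatives, or no in-network seeds are
    dropped with a logged reason.
    """
    old_by_d = old.by_right()
    new_by_d = new.by_right()
    out = VersionDiffTestSet()
    for d, new_lncs in sorted(new_by_d.items()):
        old_lncs = old_by_d.get(d, set())
        pos = {l for l in new_lncs - old_lncs if l in net_nodes}
        seeds = old_lncs & net_nodes
        neg = net_nodes - old_lncs - new_lncs
        if not pos:
            out.skipped[d] = "no new in-network positives"
            continue
        if not seeds:
            out.skipped[d] = "no seeds from the older snapshot present in the network"
            continue
        if not neg:
            out.skipped[d] = "no negatives"
            continue
        out.positives[d] = pos
        out.negatives[d] = neg
        out.seeds[d] = seeds
    for d, reason in out.skipped.items():
        logger.info("disease %s excluded from evaluation: %s", d, reason)
    return out


def roc_auc(scores: dict[str, float], positives: set[str], negatives: set[str]) -> float:
    """Mann-Whitney AUC: P(score_pos > score_neg) + 0.5 P(tie).

    Equivalent to the area under the empirical ROC curve; ties get
    half-credit via midranks. Missing entities score 0.
    """
    if not positives or not negatives:
        raise ValueError("positives and negatives must both be non-empty")
    if positives & negatives:
        raise ValueError("positives and negatives overlap")
    pos = sorted(positives)
    neg = sorted(negatives)
    vals = np.array([scores.get(x, 0.0) for x in pos + neg])
    ranks = rankdata(vals)  # midranks handle ties
    n_pos, n_neg = len(pos), len(neg)
    u = ranks[:n_pos].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


@dataclass
class EvaluationReport:
    """Per-disease AUCs and their unweighted (macro) average."""

    per_disease: dict[str, float]
    counts: dict[str, tuple[int, int]]  # disease -> (n_pos, n_neg)
    mode: str = "per_disease"

    @property
    def macro_auc(self) -> float:
        if not self.per_disease:
            return float("nan")
        return float(np.mean(list(self.per_disease.values())))

    def to_rows(self) -> list[tuple[str, int, int, float]]:
        rows = [
            (d, self.counts[d][0], self.counts[d][1], auc)
            for d, auc in sorted(self.per_disease.items())
        ]
        rows.append(("AVERAGE", sum(r[1] for r in rows), sum(r[2] for r in rows), self.macro_auc))
        return rows


def evaluate(
    net: nx.Graph,
    old: AssociationTable,
    new: AssociationTable,
    cfg: RwrConfig | None = None,
    mode: str = "per_disease",
) -> EvaluationReport:
    """Score the version-difference test set with RWR and report ROC AUCs.

    ``per_disease``: one AUC per disease over all its positives vs negatives.
    ``per_lncrna``: one ROC per held-out lncRNA (that lncRNA vs all the
    disease's negatives), averaged within each disease.
    """
    if mode not in ("per_disease", "per_lncrna"):
        raise ValueError(f"unknown evaluation mode {mode!r}")
    nodes = set(net.nodes)
    test = version_diff(old, new, nodes)
    per_disease: dict[str, float] = {}
    counts: dict[str, tuple[int, int]] = {}
    for d in test.diseases:
        probs = rwr(net, test.seeds[d], cfg)
        pos, neg = test.positives[d], test.negatives[d]
        if mode == "per_disease":
            auc = roc_auc(probs, pos, neg)
        else:
            auc = float(np.mean([roc_auc(probs, {l}, neg) for l in sorted(pos)]))
        per_disease[d] = auc
        counts[d] = (len(pos), len(neg))
    return EvaluationReport(per_disease=per_disease, counts=counts, mode=mode)


def write_report_tsv(report: EvaluationReport, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("disease_id\tn_pos\tn_neg\tauc\n")
        for d, n_pos, n_neg, auc in report.to_rows():
            fh.write(f"{d}\t{n_pos}\t{n_neg}\t{auc:.4f}\n")
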