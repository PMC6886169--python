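"""End-to-end wiring: from input bundle to network, rankings and evaluation."""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import pandas as pd

from .disease_similarity import disease_similarity_matrix
from .evaluation import EvaluationReport, evaluate
from .io import AssociationTable, DiseaseOntology, GeneLinkSet
from .lncrna_similarity import LncPairScore, all_pair_scores
from .network import RwrConfig, assemble_network
from .simulate import Bundle
from .vectors import DimensionSpace, build_vectors


@dataclass
class PipelineResult:
    """Intermediates of one network build, kept for inspection and export."""

    dsim: pd.DataFrame
    space: DimensionSpace
    vectors: pd.DataFrame
    pair_scores: list[LncPairScore]
    network: nx.Graph


def build_network_pipeline(
    onto: DiseaseOntology,
    gene_links: GeneLinkSet,
    lnc_disease: AssociationTable,
    lnc_protein: AssociationTable,
    protein_links: GeneLinkSet,
    lnc_mrna: AssociationTable,
    mrna_links: GeneLinkSet,
    expression: pd.DataFrame | None = None,
    tunables: dict | None = None,
) -> PipelineResult:
    """Compute disease similarities, lncRNA vectors, pair scores and the network.

    The network spans every lncRNA with at least one association of any kind;
    lncRNAs whose channels are all zero remain as isolated nodes.
    """
    from .io import DEFAULT_TUNABLES

    t = dict(DEFAULT_TUNABLES)
    if tunables:
        t.update(tunables)

    space = DimensionSpace.from_tables(lnc_disease, lnc_protein)
    dsim = disease_similarity_matrix(
        space.diseases,
        onto,
        gene_links,
        use_propagated_gene_sets=t["use_propagated_gene_sets"],
        relevance=t["relevance"],
    )
    lncrnas = sorted(lnc_disease.lefts() | lnc_protein.lefts() | lnc_mrna.lefts())
    vectors = build_vectors(lncrnas, space, lnc_disease, lnc_protein, dsim, protein_links)
    expr = expression if t["with_expression"] else None
    scores = all_pair_scores(vectors, lnc_mrna, mrna_links, expr, t["er_transform"])
    net = assemble_network(scores, min_weight=t["min_weight"], nodes=set(lncrnas))
    return PipelineResult(dsim=dsim, space=space, vectors=vectors, pair_scores=scores, network=net)


def run_bundle(bundle: Bundle, tunables: dict | None = None) -> PipelineResult:
    """Build the network from a synthetic bundle's old-snapshot associations."""
    return build_network_pipeline(
        bundle.ontology,
        bundle.gene_links,
        bundle.lnc_disease_old,
        bundle.lnc_protein,
        bundle.protein_links,
        bundle.lnc_mrna,
        bundle.mrna_links,
        expression=bundle.expression,
        tunables=tunables,
    )


def evaluate_bundle(
    bundle: Bundle,
    tunables: dict | None = None,
    mode: str = "per_disease",
) -> EvaluationReport:
    """Build the network from the old snapshot and test on the new one."""
    from .io import DEFAULT_TUNABLES

    t = dict(DEFAULT_TUNABLES)
    if tunables:
        t.update(tunables)
    result = run_bundle(bundle, t)
    cfg = RwrConfig(restart_prob=t["restart_prob"], tol=t["rwr_tol"], max_iter=t["rwr_max_iter"])
    return evaluate(result.network, bundle.lnc_disease_old, bundle.lnc_disease_new, cfg, mode=mode)
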