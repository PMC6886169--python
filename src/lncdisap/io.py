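"""Input tables, the disease ontology, and the TSV dialects shared by all stages.

All association inputs are tab-separated files of the form
``left_id<TAB>right_id[<TAB>score]`` (UTF-8, ``#`` comments ignored).
Identifiers are matched by exact string equality after whitespace trimming;
vocabulary mapping between disease nomenclatures is expected to have happened
upstream.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import yaml

logger = logging.getLogger(__name__)

NAMESPACES = ("lncrna", "disease", "gene", "protein", "mrna")


class ParseError(ValueError):
    """Raised for malformed input files (names the offending line)."""


class CycleError(ValueError):
    """Raised when the ontology edge list contains a directed cycle."""


def _clean(token: str) -> str:
    return token.strip()


# ---------------------------------------------------------------------------
# Association tables
# ---------------------------------------------------------------------------

@dataclass
class AssociationTable:
    """Bipartite set of (left, right) pairs with optional non-negative scores.

    ``pairs`` maps ``(left_id, right_id)`` to a score or ``None``.
    """

    left_ns: str
    right_ns: str
    pairs: dict[tuple[str, str], float | None] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.left_ns not in NAMESPACES or self.right_ns not in NAMESPACES:
            raise ValueError(f"unknown namespace in ({self.left_ns}, {self.right_ns})")

    def add(self, left: str, right: str, score: float | None = None) -> None:
        left, right = _clean(left), _clean(right)
        if not left or not right:
            raise ValueError("empty identifier")
        if score is not None and (not math.isfinite(score) or score < 0):
            raise ValueError(f"score must be finite and >= 0, got {score}")
        self.pairs[(left, right)] = score

    def __len__(self) -> int:
        return len(self.pairs)

    def __contains__(self, pair: tuple[str, str]) -> bool:
        return pair in self.pairs

    def lefts(self) -> set[str]:
        return {l for l, _ in self.pairs}

    def rights(self) -> set[str]:
        return {r for _, r in self.pairs}

    def rights_of(self, left: str) -> set[str]:
        return {r for (l, r) in self.pairs if l == left}

    def lefts_of(self, right: str) -> set[str]:
        return {l for (l, r) in self.pairs if r == right}

    def by_left(self) -> dict[str, set[str]]:
        out: dict[str, set[str]] = {}
        for l, r in self.pairs:
            out.setdefault(l, set()).add(r)
        return out

    def by_right(self) -> dict[str, set[str]]:
        out: dict[str, set[str]] = {}
        for l, r in self.pairs:
            out.setdefault(r, set()).add(l)
        return out


def read_association_table(path: str | Path, left_ns: str, right_ns: str) -> AssociationTable:
    """Read a 2- or 3-column TSV into an :class:`AssociationTable`.

    Rows are de-duplicated (the last score wins for repeated pairs); malformed
    rows raise :class:`ParseError` with the line number.
    """
    path = Path(path)
    table = AssociationTable(left_ns, right_ns)
    n_rows = 0
    with path.open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) not in (2, 3):
                raise ParseError(f"{path}:{lineno}: expected 2 or 3 tab-separated columns, got {len(cols)}")
            score: float | None = None
            if len(cols) == 3:
                try:
                    score = float(cols[2])
                except ValueError as exc:
                    raise ParseError(f"{path}:{lineno}: bad score {cols[2]!r}") from exc
            try:
                table.add(cols[0], cols[1], score)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            n_rows += 1
    if n_rows == 0:
        logger.warning("%s: empty association table", path)
    logger.info("%s: %d rows -> %d unique pairs", path, n_rows, len(table))
    return table


def write_association_table(table: AssociationTable, path: str | Path) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for (l, r), s in sorted(table.pairs.items()):
            if s is None:
                fh.write(f"{l}\t{r}\n")
            else:
                fh.write(f"{l}\t{r}\t{s:g}\n")


# ---------------------------------------------------------------------------
# Gene / protein / mRNA link sets
# ---------------------------------------------------------------------------

@dataclass
class GeneLinkSet:
    """Symmetric weighted links between genes (or proteins, or mRNAs).

    Scores are kept in [0, 1]; STRING-style integer scores (> 1) are divided
    by 1000 on ingest so protein relevance is comparable with the [0, 1]
    disease similarities.
    """

    namespace: str
    _adj: dict[str, dict[str, float]] = field(default_factory=dict)

    def add(self, a: str, b: str, score: float) -> None:
        a, b = _clean(a), _clean(b)
        if a == b:
            raise ValueError(f"self-link {a!r}")
        if score > 1.0:
            score = score / 1000.0
        if not (0.0 <= score <= 1.0):
            raise ValueError(f"link score out of range: {score}")
        self._adj.setdefault(a, {})[b] = score
        self._adj.setdefault(b, {})[a] = score

    def score(self, a: str, b: str) -> float:
        """Link score between a and b; 0 if no link."""
        return self._adj.get(a, {}).get(b, 0.0)

    def neighbors(self, a: str) -> Mapping[str, float]:
        return self._adj.get(a, {})

    def n_links(self) -> int:
        return sum(len(v) for v in self._adj.values()) // 2

    def iter_links(self) -> Iterable[tuple[str, str, float]]:
        for a, nbrs in self._adj.items():
            for b, s in nbrs.items():
                if a < b:
                    yield a, b, s


def read_link_set(path: str | Path, namespace: str) -> GeneLinkSet:
    """Read a 3-column ``a<TAB>b<TAB>score`` TSV into a :class:`GeneLinkSet`."""
    path = Path(path)
    links = GeneLinkSet(namespace)
    with path.open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 3:
                raise ParseError(f"{path}:{lineno}: expected 3 columns, got {len(cols)}")
            try:
                links.add(cols[0], cols[1], float(cols[2]))
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return links


def write_link_set(links: GeneLinkSet, path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        for a, b, s in sorted(links.iter_links()):
            fh.write(f"{a}\t{b}\t{s:g}\n")


def read_mrna_link_list(path: str | Path) -> GeneLinkSet:
    """Read an unscored 2-column mRNA link list (each link gets score 1)."""
    path = Path(path)
    links = GeneLinkSet("mrna")
    with path.open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) == 3:
                links.add(cols[0], cols[1], float(cols[2]))
            elif len(cols) == 2:
                links.add(cols[0], cols[1], 1.0)
            else:
                raise ParseError(f"{path}:{lineno}: expected 2 or 3 columns")
    return links


# ---------------------------------------------------------------------------
# Disease ontology
# ---------------------------------------------------------------------------

@dataclass
class DiseaseOntology:
    """DAG of disease terms (IS_A child -> parent) with gene annotations.

    ``annotations`` are direct disease-gene assignments; ``propagated`` adds,
    for each term, the genes of all its descendants (so every ancestor of an
    annotated term has a well-defined gene set for information content).
    """

    graph: nx.DiGraph = field(default_factory=nx.DiGraph)  # edges child -> parent
    annotations: dict[str, set[str]] = field(default_factory=dict)
    propagated: dict[str, set[str]] = field(default_factory=dict)

    @property
    def terms(self) -> set[str]:
        return set(self.graph.nodes)

    def roots(self) -> set[str]:
        return {t for t in self.graph.nodes if self.graph.out_degree(t) == 0}

    def ancestors(self, term: str) -> set[str]:
        """Ancestors of ``term``, inclusive of the term itself."""
        return nx.descendants(self.graph, term) | {term}

    def descendants(self, term: str) -> set[str]:
        """Descendants of ``term``, inclusive."""
        return nx.ancestors(self.graph, term) | {term}


def _check_acyclic(graph: nx.DiGraph) -> None:
    if not nx.is_directed_acyclic_graph(graph):
        cycle = nx.find_cycle(graph)
        raise CycleError(f"ontology contains a cycle: {cycle}")


def read_ontology(path: str | Path) -> DiseaseOntology:
    """Read a disease ontology from an OBO file or a 2-column child/parent TSV.

    Only ``is_a`` relations are used; obsolete OBO terms are dropped.
    """
    path = Path(path)
    graph = nx.DiGraph()
    if path.suffix.lower() == ".obo":
        import obonet

        raw = obonet.read_obo(str(path))  # obonet edges point child -> parent
        for node in raw.nodes:
            graph.add_node(_clean(node))
        for child, parent, key in raw.edges(keys=True):
            if key == "is_a":
                graph.add_edge(_clean(child), _clean(parent))
    else:
        with path.open(encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line.strip() or line.lstrip().startswith("#"):
                    continue
                cols = [_clean(c) for c in line.split("\t")]
                if len(cols) != 2:
                    raise ParseError(f"{path}:{lineno}: expected child<TAB>parent")
                graph.add_edge(cols[0], cols[1])
    _check_acyclic(graph)
    return DiseaseOntology(graph=graph)


def build_ontology(edges: Iterable[tuple[str, str]], extra_terms: Iterable[str] = ()) -> DiseaseOntology:
    """Build an ontology from in-memory child -> parent edges."""
    graph = nx.DiGraph()
    for t in extra_terms:
        graph.add_node(_clean(t))
    for child, parent in edges:
        graph.add_edge(_clean(child), _clean(parent))
    _check_acyclic(graph)
    return DiseaseOntology(graph=graph)


def propagate_annotations(
    onto: DiseaseOntology,
    disease_gene: AssociationTable,
    strict: bool = False,
) -> DiseaseOntology:
    """Attach direct disease-gene annotations and propagate them to ancestors.

    After propagation, ``propagated[t]`` is the union of the direct gene sets
    of ``t`` and of every descendant of ``t``. Idempotent: re-running with the
    same table leaves the ontology unchanged.
    """
    direct: dict[str, set[str]] = {}
    for (d, g) in disease_gene.pairs:
        if d not in onto.graph:
            if strict:
                raise KeyError(f"annotated disease {d!r} not in ontology")
            logger.warning("annotated disease %s not in ontology; skipped", d)
            continue
        direct.setdefault(d, set()).add(g)
    propagated: dict[str, set[str]] = {t: set(direct.get(t, ())) for t in onto.graph.nodes}
    # topological order over child->parent edges visits children first
    for t in nx.topological_sort(onto.graph):
        for parent in onto.graph.successors(t):
            propagated[parent] |= propagated[t]
    onto.annotations = direct
    onto.propagated = propagated
    return onto


def write_ontology_edges(onto: DiseaseOntology, path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        for child, parent in sorted(onto.graph.edges):
            fh.write(f"{child}\t{parent}\n")


# ---------------------------------------------------------------------------
# Expression matrix
# ---------------------------------------------------------------------------

def read_expression_matrix(path: str | Path):
    """Read a lncRNA x sample expression TSV (first column lncRNA id)."""
    import pandas as pd

    mat = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    mat.index = mat.index.map(str.strip)
    if (mat.values < 0).any():
        raise ParseError(f"{path}: negative expression values")
    if mat.shape[1] < 3:
        raise ParseError(f"{path}: at least 3 samples required for rank correlation")
    return mat


# ---------------------------------------------------------------------------
# Config
# ---------------------------------------------------------------------------

DEFAULT_TUNABLES = {
    "relevance": "max",          # gene-set relevance for unannotated genes: max|mean
    "use_propagated_gene_sets": False,
    "er_transform": "clamp",     # clamp|abs for negative Spearman rho
    "with_expression": False,
    "restart_prob": 0.7,
    "rwr_tol": 1e-10,
    "rwr_max_iter": 1000,
    "min_weight": 0.0,
    "display_threshold": 0.4,
}


def load_config(path: str | Path) -> dict:
    """Load a YAML config; unknown tunables raise, missing ones take defaults."""
    with Path(path).open(encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh) or {}
    tunables = dict(DEFAULT_TUNABLES)
    for key, val in cfg.get("tunables", {}).items():
        if key not in DEFAULT_TUNABLES:
            raise ValueError(f"unknown tunable {key!r}")
        tunables[key] = val
    cfg["tunables"] = tunables
    return cfg
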