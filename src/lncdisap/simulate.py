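"""Synthetic input bundles with planted lncRNA functional modules.

The generator emulates the shape of the real data sources — a disease
ontology DAG with gene annotations, a weighted gene functional network,
lncRNA-disease/protein/mRNA association tables in two snapshot versions, a
weighted protein link set, an mRNA link list, and a tissue expression
matrix — with a planted ground truth: lncRNAs are partitioned into functional
modules whose members share disease, protein and mRNA associations with
probability ``signal`` (cross-module: ``noise``). A ``holdout_fraction`` of
each disease's true lncRNA pairs appears only in the "new" snapshot, giving
an end-to-end recoverable benchmark for the two-snapshot evaluation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .io import (
    AssociationTable,
    DiseaseOntology,
    GeneLinkSet,
    build_ontology,
    propagate_annotations,
    write_association_table,
    write_link_set,
    write_ontology_edges,
)


@dataclass
class FixtureConfig:
    """Sizes, planted-signal strengths, and the master RNG seed.

    ``signal`` is the within-module association probability, ``noise`` the
    cross-module one; ``holdout_fraction`` is the share of each disease's
    true lncRNA pairs moved to the "new" snapshot only.
    """

    seed: int = 0
    n_diseases: int = 16
    n_genes: int = 60
    n_lncrnas: int = 40
    n_proteins: int = 12
    n_mrnas: int = 30
    n_samples: int = 12
    n_modules: int = 4
    signal: float = 0.8
    noise: float = 0.05
    holdout_fraction: float = 0.3

    def __post_init__(self) -> None:
        if not (0.0 <= self.noise <= self.signal <= 1.0):
            raise ValueError("need 0 <= noise <= signal <= 1")
        if not (0.0 < self.holdout_fraction < 1.0):
            raise ValueError("holdout_fraction must lie in (0, 1)")
        if self.n_modules < 1 or self.n_modules > min(
            self.n_lncrnas, self.n_diseases, self.n_proteins, self.n_mrnas
        ):
            raise ValueError("n_modules exceeds an entity count (or is < 1)")
        if self.n_samples < 3:
            raise ValueError("need at least 3 expression samples")


@dataclass
class Bundle:
    """All inputs for one synthetic study, plus the planted ground truth."""

    config: FixtureConfig
    ontology: DiseaseOntology
    disease_gene: AssociationTable
    gene_links: GeneLinkSet
    lnc_disease_old: AssociationTable
    lnc_disease_new: AssociationTable
    lnc_protein: AssociationTable
    protein_links: GeneLinkSet
    lnc_mrna: AssociationTable
    mrna_links: GeneLinkSet
    expression: pd.DataFrame
    module_of_lncrna: dict[str, int] = field(default_factory=dict)

    def write(self, outdir: str | Path) -> None:
        """Write every table in the package's TSV dialects plus a manifest."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_ontology_edges(self.ontology, outdir / "ontology_edges.tsv")
        write_association_table(self.disease_gene, outdir / "disease_gene.tsv")
        write_link_set(self.gene_links, outdir / "gene_links.tsv")
        write_association_table(self.lnc_disease_old, outdir / "lnc_disease_old.tsv")
        write_association_table(self.lnc_disease_new, outdir / "lnc_disease_new.tsv")
        write_association_table(self.lnc_protein, outdir / "lnc_protein.tsv")
        write_link_set(self.protein_links, outdir / "protein_links.tsv")
        # STRING-style integer variant of the same links (0-1000 scale)
        with (outdir / "protein_links_string.tsv").open("w", encoding="utf-8") as fh:
            for a, b, s in sorted(self.protein_links.iter_links()):
                fh.write(f"{a}\t{b}\t{round(s * 1000)}\n")
        write_association_table(self.lnc_mrna, outdir / "lnc_mrna.tsv")
        write_link_set(self.mrna_links, outdir / "mrna_links.tsv")
        self.expression.to_csv(outdir / "expression.tsv", sep="\t")
        manifest = {
            "config": {k: getattr(self.config, k) for k in vars(self.config)},
            "tables": {
                "ontology_edges": self.ontology.graph.number_of_edges(),
                "disease_gene": len(self.disease_gene),
                "gene_links": self.gene_links.n_links(),
                "lnc_disease_old": len(self.lnc_disease_old),
                "lnc_disease_new": len(self.lnc_disease_new),
                "lnc_protein": len(self.lnc_protein),
                "protein_links": self.protein_links.n_links(),
                "lnc_mrna": len(self.lnc_mrna),
                "mrna_links": self.mrna_links.n_links(),
                "expression_lncrnas": int(self.expression.shape[0]),
            },
        }
        with (outdir / "manifest.yaml").open("w", encoding="utf-8") as fh:
            yaml.safe_dump(manifest, fh, sort_keys=True)


def _disease_id(i: int) -> str:
    return f"DOID:{i + 1:07d}"


def _lncrna_id(i: int) -> str:
    return f"URS{i + 1:010X}"


def _partition(items: list[str], n_modules: int) -> dict[int, list[str]]:
    """Contiguous near-equal split of items into modules."""
    out: dict[int, list[str]] = {m: [] for m in range(n_modules)}
    for i, it in enumerate(items):
        out[i % n_modules].append(it)
    return out


def _random_links(rng: np.random.Generator, items: list[str], n_links: int,
                  namespace: str, weighted: bool = True) -> GeneLinkSet:
    links = GeneLinkSet(namespace)
    n = len(items)
    seen: set[tuple[int, int]] = set()
    attempts = 0
    while len(seen) < n_links and attempts < 20 * n_links:
        i, j = rng.integers(0, n, size=2)
        attempts += 1
        if i == j:
            continue
        key = (min(i, j), max(i, j))
        if key in seen:
            continue
        seen.add(key)
        score = float(rng.uniform(0.3, 1.0)) if weighted else 1.0
        links.add(items[key[0]], items[key[1]], score)
    return links


def generate(cfg: FixtureConfig) -> Bundle:
    """Generate a complete, internally consistent synthetic input bundle.

    Deterministic given ``cfg.seed``; each artifact draws from its own RNG
    stream spawned from the master seed, so changing one count does not
    reshuffle unrelated tables.
    """
    master = np.random.SeedSequence(cfg.seed)
    (ss_onto, ss_genes, ss_assoc, ss_links, ss_holdout, ss_expr) = master.spawn(6)
    rng_onto = np.random.default_rng(ss_onto)
    rng_genes = np.random.default_rng(ss_genes)
    rng_assoc = np.random.default_rng(ss_assoc)
    rng_links = np.random.default_rng(ss_links)
    rng_holdout = np.random.default_rng(ss_holdout)
    rng_expr = np.random.default_rng(ss_expr)

    diseases = [_disease_id(i) for i in range(cfg.n_diseases)]
    genes = [f"GENE{i:04d}" for i in range(cfg.n_genes)]
    lncrnas = [_lncrna_id(i) for i in range(cfg.n_lncrnas)]
    proteins = [f"PROT{i:03d}" for i in range(cfg.n_proteins)]
    mrnas = [f"MRNA{i:04d}" for i in range(cfg.n_mrnas)]

    # --- ontology: random DAG, each non-root term gets 1-2 earlier parents
    edges = []
    for i in range(1, cfg.n_diseases):
        n_parents = int(rng_onto.integers(1, 3))
        parents = rng_onto.choice(i, size=min(n_parents, i), replace=False)
        for p in parents:
            edges.append((diseases[i], diseases[int(p)]))
    onto = build_ontology(edges, extra_terms=diseases)

    # --- module assignments (shared by all association tables)
    dis_modules = _partition(diseases, cfg.n_modules)
    lnc_modules = _partition(lncrnas, cfg.n_modules)
    prot_modules = _partition(proteins, cfg.n_modules)
    mrna_modules = _partition(mrnas, cfg.n_modules)
    module_of = {l: m for m, ls in lnc_modules.items() for l in ls}

    # --- disease-gene annotations: module-biased gene pools so that
    # within-module diseases share genes and look functionally similar
    gene_pools = _partition(genes, cfg.n_modules)
    disease_gene = AssociationTable("disease", "gene")
    dis_module_of = {d: m for m, ds in dis_modules.items() for d in ds}
    for d in diseases:
        m = dis_module_of[d]
        size = int(rng_genes.integers(3, 9))
        pool = gene_pools[m]
        n_from_pool = min(len(pool), max(1, int(round(0.7 * size))))
        chosen = set(rng_genes.choice(pool, size=n_from_pool, replace=False))
        while len(chosen) < size:
            chosen.add(genes[int(rng_genes.integers(0, cfg.n_genes))])
        for g in sorted(chosen):
            disease_gene.add(d, g)

    gene_links = _random_links(rng_links, genes, 2 * cfg.n_genes, "gene")
    propagate_annotations(onto, disease_gene)

    # --- module-structured bipartite association tables
    def plant(right_modules: dict[int, list[str]], right_ns: str) -> AssociationTable:
        table = AssociationTable("lncrna", right_ns)
        for l in lncrnas:
            m = module_of[l]
            for mod, members in right_modules.items():
                p = cfg.signal if mod == m else cfg.noise
                for r in members:
                    if rng_assoc.random() < p:
                        table.add(l, r)
        return table

    lnc_disease_full = plant(dis_modules, "disease")
    lnc_protein = plant(prot_modules, "protein")
    lnc_mrna = plant(mrna_modules, "mrna")

    protein_links = _random_links(rng_links, proteins, cfg.n_proteins, "protein")
    mrna_links = _random_links(rng_links, mrnas, 2 * cfg.n_mrnas, "mrna", weighted=False)

    # --- two-snapshot split: hold out a fraction of each disease's lncRNAs,
    # always keeping at least one seed in the old snapshot
    old = AssociationTable("lncrna", "disease")
    new = AssociationTable("lncrna", "disease")
    by_disease = lnc_disease_full.by_right()
    for d in sorted(by_disease):
        lncs = sorted(by_disease[d])
        n_hold = min(len(lncs) - 1, int(round(cfg.holdout_fraction * len(lncs))))
        held = set(
            rng_holdout.choice(lncs, size=n_hold, replace=False)
        ) if n_hold > 0 else set()
        for l in lncs:
            new.add(l, d)
            if l not in held:
                old.add(l, d)

    # --- expression: shared module base profile + lncRNA-specific noise
    base = rng_expr.lognormal(mean=1.0, sigma=1.0, size=(cfg.n_modules, cfg.n_samples))
    rows = np.empty((cfg.n_lncrnas, cfg.n_samples))
    for i, l in enumerate(lncrnas):
        m = module_of[l]
        rows[i] = base[m] * rng_expr.lognormal(mean=0.0, sigma=0.15, size=cfg.n_samples)
    expression = pd.DataFrame(
        rows, index=lncrnas, columns=[f"tissue{j:02d}" for j in range(cfg.n_samples)]
    )

    return Bundle(
        config=cfg,
        ontology=onto,
        disease_gene=disease_gene,
        gene_links=gene_links,
        lnc_disease_old=old,
        lnc_disease_new=new,
        lnc_protein=lnc_protein,
        protein_links=protein_links,
        lnc_mrna=lnc_mrna,
        mrna_links=mrna_links,
        expression=expression,
        module_of_lncrna=module_of,
    )


def worked_example() -> Bundle:
    """Tiny deterministic bundle: one focal disease, 1 seed, 5 held-out lncRNAs.

    All intermediate quantities (FNSim, association vectors, CR, MR, weights,
    RWR probabilities) are small enough to verify by hand or brute force.
    """
    cfg = FixtureConfig(seed=0, n_diseases=3, n_genes=6, n_lncrnas=8,
                        n_proteins=2, n_mrnas=4, n_samples=3, n_modules=1,
                        signal=1.0, noise=0.0, holdout_fraction=0.5)

    focal, sibling, third, root = (
        "DOID:0000001", "DOID:0000002", "DOID:0000003", "DOID:0000004",
    )
    onto = build_ontology([(focal, root), (sibling, root), (third, root)])

    disease_gene = AssociationTable("disease", "gene")
    for g in ("GENE0", "GENE1"):
        disease_gene.add(focal, g)
    for g in ("GENE1", "GENE2"):
        disease_gene.add(sibling, g)
    disease_gene.add(third, "GENE4")
    disease_gene.add(root, "GENE3")

    gene_links = GeneLinkSet("gene")
    gene_links.add("GENE0", "GENE2", 0.5)
    gene_links.add("GENE2", "GENE4", 0.4)
    propagate_annotations(onto, disease_gene)

    seed_lnc = "URS000000000A"
    positives = [f"URS00000000{c}" for c in "123456"][:5]
    decoys = ["URS00000000D1", "URS00000000D2"]

    old = AssociationTable("lncrna", "disease")
    new = AssociationTable("lncrna", "disease")
    old.add(seed_lnc, focal)
    new.add(seed_lnc, focal)
    for l in positives:
        new.add(l, focal)
        old.add(l, sibling)  # held-out lncRNAs are known for the sibling only
        new.add(l, sibling)
    for l in decoys:
        old.add(l, sibling)
        new.add(l, sibling)
    old.add(decoys[0], third)
    new.add(decoys[0], third)

    lnc_protein = AssociationTable("lncrna", "protein")
    lnc_protein.add(seed_lnc, "PROT0")
    for l in positives:
        lnc_protein.add(l, "PROT0")
    for l in decoys:
        lnc_protein.add(l, "PROT1")
    protein_links = GeneLinkSet("protein")
    protein_links.add("PROT0", "PROT1", 0.2)

    lnc_mrna = AssociationTable("lncrna", "mrna")
    lnc_mrna.add(seed_lnc, "MRNA0")
    lnc_mrna.add(seed_lnc, "MRNA1")
    for l in positives:
        lnc_mrna.add(l, "MRNA0")
        lnc_mrna.add(l, "MRNA1")
    for l in decoys:
        lnc_mrna.add(l, "MRNA2")
        lnc_mrna.add(l, "MRNA3")
    mrna_links = GeneLinkSet("mrna")
    mrna_links.add("MRNA1", "MRNA2", 1.0)

    lncrnas = [seed_lnc] + positives + decoys
    expression = pd.DataFrame(
        [[1.0, 2.0, 3.0]] * len(lncrnas),
        index=lncrnas,
        columns=["tissue00", "tissue01", "tissue02"],
    )

    return Bundle(
        config=cfg,
        ontology=onto,
        disease_gene=disease_gene,
        gene_links=gene_links,
        lnc_disease_old=old,
        lnc_disease_new=new,
        lnc_protein=lnc_protein,
        protein_links=protein_links,
        lnc_mrna=lnc_mrna,
        mrna_links=mrna_links,
        expression=expression,
        module_of_lncrna={l: 0 for l in lncrnas},
    )
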