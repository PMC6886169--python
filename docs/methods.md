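# Methods

## Model and assumptions

`lncdisap` scores pairwise lncRNA functional similarity by integrating
three independent evidence channels and ranks disease candidates by network
diffusion. The underlying assumptions are:

1. **Guilt by association.** lncRNAs that share diseases, proteins or mRNA
   interactors are functionally related, and functional relatives of a
   disease's known lncRNAs are plausible new associations.
2. **Transferable disease similarity.** Two diseases with functionally
   linked gene sets are similar, so a lncRNA associated with one carries
   (weaker) evidence for the other. The ontology correction
   |G_a||G_b|/|G_MICA|² discounts pairs whose only commonality is a broad,
   heavily annotated ancestor: the more specific (higher-IC) the most
   informative common ancestor, the smaller its propagated gene set and the
   larger the correction factor.
3. **Channel independence.** CR (disease/protein vector cosine) and MR
   (mRNA-set relevance) are treated as independent noisy detectors of the
   same latent relatedness, hence the noisy-OR combination
   1 − (1−CR)(1−MR): one strong channel suffices, and the weight never
   drops below the strongest channel.

The min-max normalization of the raw disease similarity matrix is computed
over distinct (off-diagonal) pairs only, and the diagonal is pinned to 1:
raw FNSemSim values can exceed 1 and are only meaningful relative to one
another, while self-similarity is definitional. Consequently at least one
disease pair always has normalized similarity 1 and one has 0.

Disease gene sets entering FNSim are the *direct* disease–gene annotations
(`use_propagated_gene_sets: false` by default); DAG-propagated sets are
used only for information content and G_MICA, where ancestor terms need a
well-defined gene set. lncRNA–disease annotations are never propagated up
the DAG. The relevance of a non-member gene to a gene set is the **maximum**
link score into the set (`relevance: max`), consistent with the MAX rule
used for the association vectors; a mean-of-links alternative is available
(`relevance: mean`).

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| `restart_prob` (r) | 0.7 | RWR restart probability; higher keeps mass nearer the seeds. 0.7 is the field-standard default for protein-network prioritization. |
| `rwr_tol` | 1e−10 | L1 convergence threshold of the power iteration. |
| `rwr_max_iter` | 1000 | iteration cap (convergence is geometric at rate 1−r, so ~80 iterations suffice at r = 0.7). |
| `min_weight` | 0.0 | edge-inclusion threshold; only zero-weight pairs are dropped by default. |
| `display_threshold` | 0.4 | threshold for network *export/visualization* only; it never affects RWR or evaluation. |
| `relevance` | `max` | gene-to-gene-set relevance rule (`max` or `mean`). |
| `er_transform` | `clamp` | mapping of negative Spearman rho into [0, 1] (`clamp` floors at 0; `abs` is available). Clamping preserves the guarantee that edge weights stay in [0, 1] and treats anti-correlation as absence of evidence rather than evidence. |
| `with_expression` | `false` | the ER channel is off by default; with sparse or poorly mapped expression data it degrades rather than helps the ranking, so it is opt-in. |

Degenerate branches are total and documented: empty gene/mRNA/association
sets score 0 (a MAX over an empty set is pinned to 0 — no evidence, no
score); zero vectors have cosine 0; constant expression profiles have ER 0;
a constant off-diagonal similarity matrix normalizes to all zeros with a
warning. STRING-style integer protein scores (> 1) are divided by 1000 on
ingest so every SPscore lies in [0, 1] and is commensurable with normalized
disease similarities.

RWR implementation choices: the weighted adjacency is column-normalized;
isolated (dangling) nodes redirect their column to the restart vector so
the iteration conserves probability mass; seeds get a uniform restart
vector; ranking ties break lexicographically by lncRNA id. On every tested
graph the power iteration agrees with the dense linear solve
(I − (1−r)W)p = r·p₀ to well below 1e−8.

Two evaluation granularities are provided: `per_disease` pools all of a
disease's positives into one Mann–Whitney AUC; `per_lncrna` computes one
ROC per held-out lncRNA against the disease's negatives and averages.
Because the Mann–Whitney statistic is itself the mean over positives of
per-positive comparisons, the two modes coincide when negatives are shared;
`per_lncrna` exists to expose per-lncRNA ROC curves. Negatives are all
network lncRNAs associated with the disease in neither snapshot, and seeds
come strictly from the older snapshot (associations removed in the newer
snapshot are ignored).

## Synthetic data generator

The generator (`lncdisap.simulate`) emulates the *shape* of the real data
ecosystem — a single-rooted disease DAG (each non-root term draws 1–2
parents among earlier terms), disease–gene annotations, a weighted gene
network, two lncRNA–disease snapshot versions, lncRNA–protein and
lncRNA–mRNA tables, a weighted protein link set (emitted both on the [0, 1]
and the 0–1000 integer scale), an unscored mRNA link list, and a lognormal
expression matrix — with a planted ground truth: lncRNAs are partitioned
into functional modules, and module members share each module-entity
association with probability `signal` (0.8) versus `noise` (0.05) across
modules. Disease gene sets draw ~70% of their genes from a per-module pool
so that within-module diseases are genuinely similar. A `holdout_fraction`
(0.3) of each disease's true lncRNA pairs appears only in the "new"
snapshot, with at least one seed always retained. Expression rows are a
shared module base profile times lncRNA-specific lognormal noise
(sigma = 0.15), giving high within-module rank correlation.

Default sizes — 16 diseases, 60 genes, 40 lncRNAs, 12 proteins, 30 mRNAs,
12 tissues, 4 modules — are desk-scale: large enough that per-disease ROC
curves have ~30 negatives and module recovery is statistically meaningful,
small enough that the full test suite and the acceptance run finish in
seconds. Gene link scores are uniform(0.3, 1.0) so the MAX relevance rule
is exercised non-trivially. Each artifact draws from its own RNG stream
spawned from the master seed, so changing one count does not reshuffle
unrelated tables, and identical seeds produce byte-identical files.

**What passing the synthetic benchmark does and does not show.** It shows
the pipeline recovers planted modular structure through every stage
(annotation propagation → disease similarity → vectors → pair weights →
RWR → two-snapshot AUC) and collapses to chance when the structure is
ablated (signal = noise). It does not show performance on real databases:
real association tables have heavy-tailed degree distributions, correlated
evidence channels, annotation bias toward well-studied cancers, and
vocabulary-mapping noise, none of which are modelled. On the default
planted benchmark the mean per-disease AUC is ≈ 0.85–0.91 depending on the
seed; the residual gap to 1 comes from hard negatives — same-module lncRNAs
that happen to carry no association with the test disease in either
snapshot yet sit close to the seeds in the network.

## Numerical choices and problem sizes

* Mann–Whitney AUC is computed via midranks (`scipy.stats.rankdata`), which
  handles ties with half-credit exactly and equals the trapezoidal area
  under the empirical ROC curve (cross-checked in the tests).
* MICA ties (equal IC) break to the lexicographically smallest term id;
  terms with no propagated annotations have IC = −∞ and never win.
* The acceptance script averages the planted-benchmark AUC over 5 replicate
  bundles and the ablated null over 20, each seeded from the master seed;
  RWR/solver agreement is checked on random graphs up to 200 nodes at
  restart probabilities 0.3–0.9, and ROC calibration over 1000 draws of
  50 + 50 random scores.

## Known limitations

* No vocabulary reconciliation: identifiers must be pre-mapped (exact
  string match after trimming). Unknown entities referenced by one table
  but absent elsewhere are retained with empty neighbor sets and fall into
  the documented degenerate branches.
* The walk runs on the lncRNA layer only; no heterogeneous multi-layer
  diffusion over a joint disease–lncRNA graph.
* Whether the min-max pool should include the diagonal, and whether FNSim
  should use propagated gene sets, are genuinely open: the defaults
  (exclude diagonal; direct sets) are assumptions exposed through config.
* Negative-class choice (all never-associated network lncRNAs) inflates the
  negative set with unverified non-associations; reported AUCs are
  therefore conservative lower bounds under the open-world assumption.
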