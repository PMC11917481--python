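# slrpev

Tools for studying the evolution of the vertebrate **Small Leucine-Rich
Proteoglycan (SLRP)** gene family — a clustered family of extracellular-matrix
genes whose amplification traces back to tandem duplications and the two
rounds of whole-genome duplication (1R/2R) in early vertebrates.

The package is aimed at comparative genomicists working on gene-family
evolution in vertebrates (and at anyone who needs its individual pieces:
a PROSITE-subset motif engine, a tandem-cluster detector, or an exact
duplication/loss parsimony search on a small species/WGD tree).

## What it does

- **`motif`** — a PROSITE-syntax pattern engine (classes `[LIV]`, bounded
  wildcards `X(7,20)`, exclusions `{P}`) with the two built-in LRRCE capping
  motifs that define canonical SLRPs (standard, and relaxed at the
  C-terminus), plus N-glycosylation sequon scanning and a documented LRR
  consensus counter.
- **`alignment`** — aligned-FASTA io and the gap-column filter: a column is
  removed when its gap fraction strictly exceeds 95% (configurable).
- **`synteny`** — tandem-cluster detection on gene coordinate tables
  (single-linkage, 200 kb default gap), cluster orientation (Clade 1 genes
  first / Clade 4 genes last), and cross-genome anchoring by shared neighbor
  genes (e.g. the Atp2b family).
- **`cluster_evolution`** — the core model: gene-cluster evolution by tandem
  duplication, WGD inheritance, and loss on a history tree
  (stem → pre-1R → {A/B, C/D} → {A, B, C, D}).  Exact searches for the
  minimal number of tandem duplications and for the full
  duplications-then-losses parsimony scenario under orthology and timing
  constraints; a quartet test for the ((A,B),(C,D)) 2R signature.
- **`phylo_support`** — "SH-aLRT/UFBoot" dual support labels on newick gene
  trees, support categories (both > 95 strong; both > 85 moderate), and
  supported-monophyly tests.
- **`expression`** — row Z-score enrichment on TPM matrices
  (strong: Z > 1 and TPM > 50; weak: Z > 1 and TPM ≤ 50), group exclusivity,
  and qPCR relative quantification against the geometric mean of three
  reference genes.  Ships a 21-gene × 13-sample catshark TPM panel.
- **`synthetic_data`** — seeded generators for every input above, with known
  ground truth (replayable cluster scenarios, proteins with controlled LRRCE
  status, planted expression enrichment, known qPCR folds).

## The model at the core

A cluster's history is a rooted tree whose internal nodes are
whole-genome duplications; a WGD passes the entire cluster to both
daughter genomes.  A *scenario* is a root composition (one gene lineage
per clade) plus events on branches: `tandem_dup(branch, parent → child)`
adds an adjacent copy inherited by the whole subtree, `loss(branch,
lineage)` removes one from the subtree.  Given observed per-cluster
compositions, orthology groups (genes required to descend from one
lineage), and timing constraints ("lineage 3a existed before 1R"),
`infer_parsimony_scenario` finds the exact optimum under a lexicographic
objective — fewest tandem duplications, then fewest losses, then a
deterministic preorder tie-break.

## Worked example

Reconstruct the amplification of the canonical SLRP clusters from the four
observed gnathostome cluster compositions:

```python
from slrpev import cluster_evolution as ce

history = ce.default_2r_tree()

d, _ = ce.min_tandem_duplications({"A": 1, "B": 0, "C": 2, "D": 3}, history)
print("minimal Clade 3 tandem duplications:", d)

family, constraints = ce.canonical_slrp_family()
result = ce.infer_parsimony_scenario(family, history, constraints)
print("duplications:", result.n_duplications, "| losses:", result.n_losses)
for node in ("R", "AB", "CD"):
    comp = result.node_compositions[node]
    print(f"{node}: {len(comp)} genes {comp}")
```

prints

```
minimal Clade 3 tandem duplications: 2
duplications: 2 | losses: 5
R: 5 genes ('c1', 'c2', '3a', '3b', 'c4')
AB: 4 genes ('c1', 'c2', '3b', 'c4')
CD: 6 genes ('c1', 'c2', '3a', "3a'", '3b', 'c4')
```

Reading: the Clade 3 copy numbers observed across the four clusters
(1 on A, none on B, 2 on C, 3 on D) cannot be explained by whole-genome
duplications and loss alone — two tandem duplications are required.  The
full constrained reconstruction places a five-gene cluster in the pre-1R
ancestor (`R`), a four-gene cluster in the A/B ancestor, and a six-gene
cluster in the C/D ancestor, with five subsequent cluster-specific losses
producing the extant compositions.

The same computation is available from the shell:

```bash
slrp simulate --preset canonical --seed 1 --out sim/   # ground-truth data
slrp infer-scenario --config family.yaml               # parsimony search
slrp scan-motif --fasta proteins.fasta                 # LRRCE screen
```

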