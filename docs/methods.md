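# Methods

This note documents the models, conventions, and numerical choices behind
`slrpev`, module by module, including where a design was genuinely open and
what the synthetic-data generators do and do not emulate.

## PROSITE motif engine (`motif`)

**Grammar subset.** Patterns are `-`-separated tokens: a single residue,
a class `[LIV]`, an exclusion `{P}`, or a bounded wildcard `X`, `X(n)`,
`X(n,m)` with `0 < n ≤ m`.  Anchors (`<`, `>`) are rejected; they are not
needed for the LRRCE motifs.  A trailing `.` is tolerated.

**Matching semantics.** The matcher is a memoized backtracking search over
wildcard extents.  Every distinct start position with at least one full
match yields exactly one hit, and the reported extent is the *shortest*
satisfying end for that start (lazy expansion).  Published screens of the
LRRCE motifs quote only presence/absence, so the extent convention was
ours to pick; per-start-shortest is deterministic and cheap (the DP is
O(elements × positions) per start).  The unit and acceptance suites check
the engine against an independent brute-force enumerator on randomized
patterns and sequences.

**Input handling.** Sequences are upper-cased.  Ambiguity letters (X, B, Z)
never satisfy a residue, class, or exclusion element — a conservative rule
that avoids false LRRCE calls on low-quality translations — but wildcards
accept them.  A `*` (stop) truncates the scannable region.

**Built-in patterns.** The standard LRRCE motif and its C-terminally
relaxed variant are stored verbatim as module constants.  The relaxed tail
`X(8,12)-C` accepts every string the standard tail `X(8,9)-[FYMPVAIS]-X-C`
accepts (10- and 11-residue pre-C stretches are inside 8..12), so a
standard hit always implies a relaxed hit; this subsumption is asserted
over generated proteins.

**Heuristics.** The sequon scanner implements the canonical N-glycosylation
rule N-{P}-[S/T] (1-based position of the N).  The LRR counter scans left
to right for non-overlapping 11-residue consensus windows
L-x-x-L-x-L-x-x-N-x-L (L ∈ {L,I,V,M,F}, N ∈ {N,T,S,C}).  Both are
documented stand-ins for dedicated predictors, **not** reproductions of
them; LRR counts from this heuristic should not be compared against
structure-aware tools.

## Alignment gap filter (`alignment`)

A column is removed when its gap fraction strictly exceeds the threshold
(default 0.95), i.e. "more than 95%" — a fraction of exactly 0.95 is kept.
Both `-` and `.` count as gaps (aligner output conventions differ); `X` is
a residue.  Filtering is idempotent, monotone in the threshold, and
preserves row order; kept column indices are reported 1-based.  FASTA
output is one sequence per line, so filter output round-trips exactly.

## Tandem clusters and synteny (`synteny`)

Clustering is single linkage over family-flagged genes per chromosome: a
gene joins the current run when the inter-span gap (`next.start −
current.end − 1`) is at most `max_gap`.  The 200 kb default encodes the
qualitative convention in the comparative literature on these loci (pairs
tens of kb apart are tandem; genes "more than 200 kb away" are not); no
exact threshold is published, so the value is configurable and recorded in
output.  Gaps are measured between gene spans, not midpoints.  Strand is
ignored — the observed clusters mix orientations.

Cluster orientation follows the display convention for canonical SLRP
loci: if a Clade 1 gene sits at an extremity it is put first; otherwise a
Clade 4 gene at an extremity is put last; a cluster with the deciding
clade at both extremities is left in input order and flagged ambiguous.
The operation is idempotent and records whether it reversed the cluster.

Cross-genome anchoring normalizes neighbor gene names by case-folding and
stripping trailing paralog suffixes (`Atp2b1` ≈ `atp2b`), because locus
orthology is argued at the gene-family level, and reports cluster pairs
sharing at least one neighbor within a 10-gene window of both clusters.

## Cluster evolution model and parsimony (`cluster_evolution`)

**Model.** The history tree is a rooted tree of cluster lineages; the
default is stem → R (pre-1R) → {AB, CD} (1R) → {A, B, C, D} (2R).  WGD
nodes copy the whole cluster into both children, so replay is plain
inheritance with per-branch edits: a tandem duplication inserts the new
lineage beside its parent and is inherited by the whole subtree below; a
loss removes one lineage from the subtree.  Replay validates every event
(an event naming an absent lineage is an error naming the event).

**Copy-count bound (`min_tandem_duplications`).** With losses free, a tip
observed with c copies of one clade needs at least c − 1 duplications on
its root-to-tip path.  The search enumerates placements in increasing
count (combinations with replacement over branches) and returns the first
covering placement with a witness scenario; it is checked against an
independent replay-based enumeration oracle.

**Full inference (`infer_parsimony_scenario`).** The objective is
lexicographic: fewest tandem duplications, then fewest losses, then a
canonical tie-break (events encoded by preorder branch index and labels,
smallest tuple wins).  Duplications outrank losses because the biological
argument for these clusters is framed in duplication events, with losses
as the residual explanation; this ordering was an open choice and is
isolated in one comparison, so the alternative is easy to explore.

The root composition is fixed at one lineage per observed clade label, so
the duplication that founds a clade-internal lineage (e.g. 3b out of 3a)
is never free.  Orthology groups are treated as lineages: genes in one
group share a lineage, two explicit groups are never merged, and genes in
no group may merge with any tip-disjoint same-clade lineage (all
partitions are enumerated, smallest first).  Because duplications copy
within a clade and losses are per-lineage, clades are independent and the
search decomposes per clade; within a clade it enumerates the root
lineage, creation branches for the other lineages (any branch whose
subtree covers the lineage's tips and timing nodes), and computes minimal
losses per lineage by tree DP (lose a subtree iff it contains no required
node; timing nodes and observed tips are required).  Duplication parents
are then assigned to any same-clade lineage alive at the duplication
point, root lineage preferred.  All candidate scenarios are validated by
replay, and the returned witness always replays exactly to the observed
tip compositions.  Infeasible constraint systems (e.g. a lineage required
at a tip where it is absent) raise an explicit infeasibility error naming
the problem.

At the family sizes this model targets (≤ ~6 lineages per clade, 7
branches) the exhaustive search runs in milliseconds; it is exponential in
lineages per clade and is not meant for large families.

**2R quartet test.** A gene tree with tips labeled by cluster (≤ 1 per
cluster) is compatible with the ((A,B),(C,D)) duplication pattern iff no
edge induces the split AC|BD or AD|BC on the labeled tips.  With three or
fewer labeled tips every resolved topology is compatible (loss explains
the absent cluster).

**Cyclostome evidence.** Lineage ages argued from jawless-vertebrate
orthologs enter only as user-supplied timing constraints (e.g. "3a exists
at R"); cyclostome-specific polyploidies are not modeled.  The known
conflicting lamprey synteny observation (a Clade 1 gene clustered with a
C/D-derived Clade 3 gene) is outside the model and must be handled as
data, not by the optimizer.

## Branch support (`phylo_support`)

Internal node labels `x/y` are parsed as (SH-aLRT, UFBoot) percentages,
validated into [0, 100].  Categories follow the display convention:
strong iff both > 95, moderate iff both > 85, else weak — strict
comparisons, so a value of exactly 95 is moderate (this matches the
published description of a 90.4/95 node as "intermediate"); the strict
rule at exactly 95.0 is otherwise arbitrary and documented here.
Monophyly is evaluated on the rooted tree as given (no outgroup logic);
`supported_monophyly` requires the stem node's category to reach the
requested minimum.

## Expression (`expression`)

Z-scores are computed per gene row as (x − mean) / sd with the n−1
denominator (the convention is not fixed by the published tables; ddof is
a parameter), on raw TPM without a log transform, across exactly the
samples present in the supplied matrix.  Constant rows get Z = 0 with a
warning.  Calls: strong iff Z > 1 and TPM > 50; weak iff Z > 1 and
TPM ≤ 50 (the published footnote leaves TPM = 50 unassigned; weak takes it
so categories partition); otherwise none.  A gene is exclusive to a sample
group iff it has at least one call and all calls fall in that group —
genes with no calls are not vacuously exclusive.

The packaged `catshark_tpm.tsv` panel (21 SLRP genes × 13 adult tissues
and embryonic stages) is a transcribed selection of published catshark
transcriptome quantifications.  The original enrichment calls were made on
a 31-sample panel; Z-scores over the packaged 13-sample subset therefore
differ from the published bold marks, and the panel is used here for
value-level checks (e.g. chad1 in vertebrae > 2,700 TPM) and as a
realistic fixture, not to reproduce per-cell calls.

qPCR: ΔCp(s) = Cp_target(s) − mean(Cp of the three reference genes in s);
the arithmetic mean of Cp equals the geometric mean of expressions.  The
sample with the highest ΔCp is the 1-fold reference point and
fold(s) = E^(maxΔCp − ΔCp(s)) with efficiency E fixed at 2 (no per-primer
efficiencies are available), so all folds are ≥ 1 and the minimum is
exactly 1.

## Synthetic data (`synthetic_data`)

All generators are deterministic under a fixed seed
(`numpy.random.default_rng`).

**Cluster simulator.** Forward version of the evolution model: per branch,
Poisson numbers of duplications and losses (default rates 0; tests use
0.3–0.6 per branch, which keeps simulated histories in the ≤ 2–3
duplication regime the real family occupies) applied to uniformly chosen
lineages.  Emitted tip tables are the replay of the emitted scenario by
construction; genes are laid left-to-right with 1-based inclusive
coordinates (5 kb genes, 20 kb inter-gene gaps by default — comfortably
inside the 200 kb clustering threshold, like the real loci), and an
`atp2b1` neighbor gene is planted downstream of each cluster so synteny
anchoring is testable.  Not emulated: gene order rearrangements within
clusters, strand, sequence evolution, and cyclostome-specific genome
duplications (a custom history tree can be supplied).

**Proteins.** Built constructively: fill regions from a cysteine-free
alphabet that also avoids the `[FYMPVAIS]` letters, LRR consensus windows,
and — per mode — a realization of the standard LRRCE pattern, or of its
prefix followed by an 11-residue spacer plus `C` (legal for the relaxed
tail `X(8,12)-C`, impossible for the standard tail), or no motif region at
all (then the sequence contains no C, so neither C-anchored pattern can
match).  Post-conditions are verified with the motif engine at generation
time, with bounded retries and an explicit failure.  These sequences are
motif fixtures, not realistic proteins.

**Expression.** Per-gene log-normal baselines (log-mean 3.0, sigma 1.0 —
strictly positive and heavy-tailed, like observed TPM panels) constant
across samples; planted cells multiply the baseline by a fold > 1;
optional multiplicative log-normal noise parameterized by a coefficient of
variation (mean-1 noise).  At zero noise, a planted fold that pushes the
cell's Z above threshold is recovered exactly and unenriched rows are
constant (Z = 0), which the recovery tests exploit.  Real library-size and
batch effects are not simulated.

**qPCR.** Cp tables are built by inverting the normalization model
(target Cp = reference mean + offset − log2(fold), plus a per-sample
loading shift that cancels in ΔCp), so `qpcr_normalize` recovers the
planted folds exactly at zero noise.  One fold must equal 1 (the reference
point); Gaussian Cp noise is optional.

**What passing tests show.** The simulators guarantee internal consistency
(generate → analyze → recover) under the stated models; they do not
validate the biological models against real genomes or transcriptomes.
Analyses of real data rely on the same code paths but their correctness
claims are limited to the documented conventions above.

## Problem sizes

The test and reproduction workloads are deliberately desk-scale: the
parsimony searches run on the 7-branch 2R tree with ≤ 6 lineages per
clade; the motif property suite uses patterns of ≤ 6 elements on sequences
of ≤ 30 residues (where exhaustive enumeration is exact) plus 1,000
generated proteins; the gap-filter boundary is exercised at 20 and 549
rows.  The whole suite completes in a few seconds.
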