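# Methods

## Model and procedure

The method assumes that functional protein modules are dense subgraphs of the
PPI network *within the compartment where they operate*, and that a protein
participates in a compartment's subnetwork only if its localisation evidence
there is strong. The pipeline therefore works on the induced subgraph of each
compartment rather than on the whole interactome, and re-unifies
cross-compartment variants of the same assembly afterwards.

**Inputs.** A weighted edge list (interaction scores in [0, 1]; scores below
0.8 are treated as biologically unlikely and excluded, inclusively keeping
0.8 itself) and a localisation table (scores in [0, 1]; only scores strictly
above 0.8 are retained). Both filters are applied at load time; duplicate
records keep the maximum score and self-interactions are dropped because the
clustering fitness is defined on simple graphs. When interaction scores must
be derived from localisation alone, the package uses a noisy-OR over shared
compartments, `1 − Π_c (1 − L_a(c)·L_b(c))`: the probability that the pair
co-localises somewhere, treating compartments as independent. It reduces to 0
with no shared compartment.

**Compartment vocabulary.** Six majors by default — nucleus, cytosol,
mitochondrion, secretory-pathway, membrane, extracellular — configurable
everywhere. Proteins lacking localisation stay in the global network but
join no subnetwork, so the method is limited to localisation-annotated
proteins by design.

**Clustering backends.** Two interchangeable backends:

- *Cohesiveness-greedy* (default): grows possibly-overlapping clusters from
  seeds, supervised by `f(V) = w_in(V) / (w_in(V) + w_bound(V) + p·|V|)`,
  where `w_in`/`w_bound` sum internal/boundary edge weights and `p`
  penalises each member for untested interactions. Seeds are the unclaimed
  nodes in (weighted-degree descending, id ascending) order; each step takes
  the single boundary addition or member removal that maximally increases
  cohesiveness, so the fitness is strictly increasing along every growth
  trace (asserted in tests). Grown clusters with pairwise overlap score
  ≥ 0.8 are merged transitively, then clusters below density 0.5 or fewer
  than 3 members are discarded. Defaults `p = 2`, density 0.5, merge 0.8 are
  the publicly documented ClusterONE defaults; the Monte-Carlo significance
  filter of the original tool is intentionally not reproduced — density and
  size filters stand in, and all values are configurable. No cut-vertex
  check is performed on removals; a removal that disconnects a cluster is
  allowed if it raises cohesiveness.
- *Markov clustering*: alternates expansion (matrix power 2) and inflation
  (element-wise power 2 with column re-normalisation, entries below 1e-5
  pruned) on the column-stochastic flow matrix, up to 100 iterations or a
  max-change below 1e-6 — canonical MCL settings. Attractor rows (positive
  diagonal) are read off as clusters; attractor systems sharing nodes are
  merged so the output partitions the non-isolated nodes. Nodes whose column
  is fully pruned become singletons to preserve the partition.

Either backend's output passes the module size filter: only clusters larger
than ten proteins (`min_size = 11`) count as modules. The filter is applied
per subnetwork, before merging.

**Merging.** Module pairs are scored with `ω(A,B) = |A∩B|²/(|A|·|B|)`
(1 iff identical, 0 iff disjoint). Pairs with ω strictly greater than ω₀
become edges of an overlap graph; each connected component — components are
traversal-independent, so any correct component routine serves — is emitted
as one super module whose member set is the union over the component (a
protein contributed by several constituents counts once). ω₀ defaults to
0.5; for equal-size modules this requires just over √0.5 ≈ 70.7% shared
members. For near-complete networks (e.g. yeast) 0.75 is recommended so only
highly overlapping modules merge. The merge is a single component pass;
super modules are not re-merged against each other. Super modules with best
overlap < 0.25 against every whole-network module are "novel"; the strict
inequality mirrors the merge rule, and a pair at exactly the boundary counts
as shared.

**Evaluation.** Against reference complexes (GMT, complexes with ≥ 5 members
kept): the match matrix `t_ij = |predicted_i ∩ reference_j|` yields
`Sn = Σ_j max_i t_ij / Σ_j w_j`, `PPV = Σ_i max_j t_ij / Σ_i Σ_j t_ij`, and
`Acc = √(Sn·PPV)`, the geometric mean. A module "matches" a complex when
ω ≥ 0.25 (the same boundary as novelty; configurable). Against pathway
resources: per (module, pathway) pair a one-sided hypergeometric tail
`P(X ≥ t)` with universe N = all proteins of the analysed network (not the
union of pathway genes), module size n, pathway size T, overlap t, computed
through the survival function for stability; Benjamini–Hochberg adjustment
runs across all pairs *within one resource*, resources independently,
mirroring per-resource ORS reporting. ORS = fraction of modules with at
least one pathway at adjusted P < 0.05; the composite score sums ORS over
resources. When an explicit universe is supplied, module members outside it
are dropped with a warning and pathways are restricted to it, keeping the
hypergeometric configuration valid.

## Synthetic data

The generator emulates ComPPI-shaped inputs as a compartment-aware planted
partition: per compartment, a configured number of dense Erdős–Rényi blocks
(the planted modules), plus uniform background edges over all protein pairs.
A fraction of modules is duplicated into the neighbouring compartment: the
shared members become multi-localised, the remainder are fresh proteins, and
the duplicate keeps the same size so the pair's overlap score is exactly the
shared fraction squared (≈ 0.64 at 80% sharing) — the ground-truth positives
for the merge step. Defaults — 3 modules of 12–20 proteins per compartment,
within-module edge probability 0.9, background 0.02, 30% duplication at 80%
sharing, localisation scores in [0.85, 1.0], interaction scores in
[0.8, 1.0] — are the study conditions under which recovery is asserted:
dense modules over a sparse background, with scores drawn above the load
thresholds so no planted structure is lost at parse time. All randomness
flows from one integer seed; identical seeds give identical outputs.

What the generator does **not** emulate: realistic degree distributions,
evidence-type score structure, module-free background proteins, hub
proteins, or size-correlated noise. Passing recovery tests therefore shows
the pipeline's stages compose correctly and separate dense planted structure
from uniform noise — not performance on real interactomes, where score
calibration and coverage gaps dominate.

## Numerical choices

- Score filters follow the inequality directions of their definitions:
  interactions keep ≥ 0.8 (exclusion of "< 0.8"), localisations keep
  strictly > 0.8.
- Greedy tie-breaks are rule-based for determinism: seed order
  (weighted-degree desc, id asc); among equal-gain steps the
  lexicographically smallest protein id wins. Gains within 1e-12 are treated
  as ties so float noise cannot order steps.
- Cohesiveness uses edge `score` attributes as weights when present
  (unweighted counts are available via `weighted=False`); an isolated
  cluster with zero penalty is defined as 0 when the denominator vanishes.
- The hypergeometric tail returns exactly 1.0 at t = 0; impossible
  configurations raise instead of returning 0.
- BH-adjusted values are clipped to 1 and monotone-enforced (via
  statsmodels' step-up implementation).
- Module files emit members sorted, so equal module sets are byte-identical
  on disk.
- Problem sizes in the test suite: the planted-recovery check runs 20 seeds
  of a 3-compartment, 9-module (~165 protein) network — small enough to keep
  the whole suite in seconds while every module comfortably exceeds the
  size-11 filter.

## Known limitations

- ClusterONE's statistical cluster-significance test is not implemented; on
  sparse real networks the density/size filters alone admit more marginal
  clusters than the original tool would.
- MCL convergence is declared on max-change of the flow matrix; cyclic
  non-convergence (possible on bipartite-ish structures with self-loop
  weight 0) ends with a warning and the current matrix interpretation.
- The merge step is quadratic in the number of subcellular modules, and the
  exact module numbering of any particular run is not an output contract —
  only member sets and provenance are.
- Interaction records carry a single flattened score; per-compartment
  interaction sub-scores, where a source database provides them, must be
  reduced upstream (the noisy-OR derivation is provided for the common
  case).
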