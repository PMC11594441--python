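# Methods

## The multiscale interactome and the biased walk

The substrate is a two-class graph: protein nodes and biological-function
nodes, with three edge layers. Protein–protein and protein–function edges
are undirected and unweighted (stored once, in canonical orientation,
traversable both ways); function–function edges are stored as
(child, parent) and exposed to the walker as two distinct move classes, up
(child→parent) and down (parent→child), so ascent and descent of the
hierarchy can be weighted differently.

From node $u$, the walker steps to neighbor $v$ through edge class $c$ with
probability $w_c / Z(u)$, where $Z(u)$ sums the class weights of all of
$u$'s (neighbor, class) pairs. With restart probability $\alpha$ the walker
teleports to the seed distribution $s$. The diffusion profile is the
stationary $r = (1-\alpha) T^\top r + \alpha s$.

### Walk parameters

| parameter | default | meaning |
|---|---|---|
| $\alpha$ (restart) | 0.17 | locality of propagation; higher keeps mass near seeds |
| $w_{pp}$ | 1 | protein→protein moves |
| $w_{pf}$ | 2 | protein→function moves |
| $w_{fp}$ | 1 | function→protein moves |
| $w_{up}$ | 2 | function→parent moves |
| $w_{down}$ | 1 | function→child moves |
| tolerance | 1e−10 | L1 residual stopping rule |
| max iterations | 10 000 | convergence guard |

The doubled $w_{pf}$ and $w_{up}$ realize the intended bias toward
biological functions. No published value exists for these constants in the
setting this package addresses, so they are design defaults: every result
in the test suite is computed at explicitly pinned parameters, and nothing
downstream depends on this particular choice being optimal. Distinct
protein→function and function→protein weights are exposed (rather than a
single bias factor) because the parameterization subsumes both readings.

### Numerical choices

Power iteration with an L1 stopping rule; mass on dangling nodes (isolated
nodes, or nodes all of whose incident edge classes are weighted zero) is
redirected to the seed distribution each iteration, so total mass is exactly
conserved and the profile sums to 1 (asserted to 1e−9 in tests). Node order
is the sorted id list and summation order is fixed, so profiles are
bitwise-reproducible. With $\alpha = 1$ the iteration returns the seed
distribution after one step. Correctness is tested against the closed form
$r = \alpha (I - (1-\alpha) T^\top)^{-1} s$ (dangling rows replaced by $s$)
on random networks of ≤ 50 nodes, to 1e−8 in $L_\infty$.

## Seeding

A herb's seed set is its **top-50 targets by simple pathway count** (the
number of the herb's distinct ingredients hitting a target), uniformly
weighted; ties at the cutoff break by ascending protein id so the selection
is deterministic. Uniform seeding is the default and pathway-count weighting
is deliberately not applied (the count already governs *which* targets
seed). An ingredient's seed set is its full target set. The disease's seed
set is its full protein set. Seeds outside the network are dropped (logged)
and the rest renormalized; an entity whose seeds are all unmapped is an
error, not a silent zero.

Herbs with fewer than three targeted ingredients (ingredients having ≥ 1
target) are excluded before any scoring — too little interaction data for a
reliable profile.

## Scoring and prioritization

Correlation between profiles is Pearson on the union-aligned raw frequency
vectors (Spearman available by configuration; the method is recorded in
output metadata). A zero-variance profile raises an error rather than
returning NaN. Seed-node exclusion before aligning is available but off by
default.

The overlap test is the exact hypergeometric upper tail, computed with
integer arithmetic (summed binomial products over a common denominator), so
far-tail p-values carry no summation error; the population $N$ defaults to
the network's protein count and $K$ is the mapped disease-protein count.
Fold enrichment is $(k/n)/(K/N)$; an overloaded form accepts a fixed
background fraction $p_0$ directly, for checking published tables whose
$(K, N)$ are not printed. Rankings use the raw $p < 0.05$ cutoff (matching
common practice for this analysis); BH-adjusted values are emitted alongside
for transparency. All rankings break ties by ascending entity id.

A herb is flagged *prioritized* when $p < 0.05$, enrichment ≥ 5, and ≥ 5 of
its ingredients are individually significant (hypergeometric $p < 0.05$ of
the ingredient's own target set against the disease proteins). The
ingredient criterion uses the hypergeometric test alone; an optional
correlation floor is exposed in configuration but off by default, since the
significance reading is the more conservative one.

Core targets are the proteins hit (via any ingredient, full target sets) by
at least 3 of the top-10 ranked herbs.

## Over-representation analysis

Per library term: one-sided exact test of the 2×2 table (identical to the
hypergeometric overlap above — the two share one implementation and a test
asserts it), BH adjustment across terms, an odds ratio, a z-score, and the
combined score $-\ln(p) \cdot z$ (natural log; larger = more enriched; sign
and base recorded here because other platforms vary). The z-score null is
1,000 seeded uniform draws of $|targets|$ genes from the background —
self-contained and deterministic under a pinned seed; this differs from the
rank-deviation correction some web platforms apply, so combined scores are
comparable within a run, not across tools. The default background is the
union of library genes plus the targets; whole-genome backgrounds can be
passed explicitly. Disease-specific terms can be removed by case-insensitive
regex patterns.

## Mechanism subnetworks

For an ingredient–disease pair: take the top $k = 20$ nodes of each profile
(ties by id), add the ingredient's direct targets and any disease proteins
already selected, induce the parent network's edges, then remove direct
targets with no route to a disease protein or selected function. The
"association" required by the pruning rule is operationalized as graph
reachability within the induced subgraph — the weakest defensible reading —
with direct adjacency available by configuration. The ingredient and the
disease are attached as pseudo-nodes with their own link-edge classes; they
never participate in the walk. Exports: SIF (sorted, byte-stable) and
GraphML with role/frequency/rank attributes; $k$ per profile, not total.

## Synthetic data: what it emulates, and what it does not

The generator emulates the statistical shape of real inputs:

| knob | default | emulates |
|---|---|---|
| n_proteins / n_functions | 800 / 300 | interactome scale (desk-sized) |
| ppi_attachment m | 3 | scale-free PPI degree distribution (preferential attachment; connected) |
| annotation_density | 2.0 per protein | sparse experimentally-derived annotations |
| hierarchy_branching | 3 | shallow-rooted function hierarchy (+25% cross-links) |
| disease_module_size | 15 | a connected disease module, BFS-grown |
| n_herbs | 60 | catalog breadth |
| ingredients_per_herb | 3–8 | multi-compound herbs (filter-passing) |
| targets_per_ingredient | 1–6 | modest per-compound target sets |
| planted_fraction | 0.2 | herbs with genuine disease-directed pharmacology |
| proximity_hops | 1 | planted targets fall within 1 PPI hop of the module |
| leakage | 0.2 | planted herbs also hit unrelated targets |

Planted herbs draw each target from the module's 1-hop neighborhood with
probability 0.8 (uniform elsewhere otherwise; the first target is forced
into the neighborhood so every planted herb touches it); background herbs
draw uniformly. All draws flow from one `numpy` generator seeded by
`rng_seed`, so studies are bit-reproducible.

What the generator does **not** emulate: real GO term semantics (terms are
random gene sets), chemical target promiscuity beyond the configured range
(no quercetin-like 400-target compounds), ingredient sharing between herbs,
annotation correlation with PPI modules, or literature ascertainment bias.
Passing the recovery test therefore shows the pipeline can rank a
planted topological signal out of uniform noise at realistic sparsity — not
that it reproduces any particular real-world ranking.

Recovery under the default conditions (seeds 1–10) is part of the test
suite: mean ROC-AUC of planted vs. background herbs by correlation score
must be ≥ 0.9 and the overall median planted rank ≤ 10.

## Problem sizes used in the test suite

Unit tests run on hand-built networks of 2–10 nodes and random networks of
≤ 50 nodes; the pipeline fixture study uses 300 proteins / 60 functions /
15 herbs with an intentionally strong planted signal (targets drawn from
the module itself, 5–8 targeted ingredients per herb) so the prioritization
gates can fire at that scale; the recovery test runs the full default
800-protein study ten times. These sizes were chosen so the complete suite
exercises every stage end-to-end in well under a minute of compute.

## Known limitations

* The walk's hyperparameters are design defaults, not fitted values; no
  benchmark against gold-standard drug–disease pairs is performed here.
* The hypergeometric population $N$ (all network proteins) treats every
  protein as equally eligible to be a target, ignoring target-class bias.
* Mechanism-subnetwork pruning by reachability is permissive; on dense
  networks nearly everything is reachable, and the adjacency option is the
  stricter alternative.
* The ORA z-score null ignores gene-length/degree confounding; it matches
  the random-set semantics, not any platform-specific correction.
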