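# Methods

## Statistical model and procedure

The package quantifies two pairwise gene relations and their interplay.

**Co-expression** is the sample Pearson correlation of two genes'
expression profiles across conditions. The input matrix is assumed
complete and already normalized (e.g. RMA for microarray compendia);
normalization and replicate selection are upstream of this package. When
several ORF-level rows map to one gene, they are collapsed by the
per-condition arithmetic mean before any correlation is computed.

**Co-regulation** is the correlation of two genes' binary regulator
profiles. A network is first reduced to a regulator incidence matrix:
rows are TFs (TR networks) or interaction source nodes ("first upstream
neighbours", PPI network), columns are *all* genes appearing anywhere in
the network, entries are 0/1. The similarity of two gene columns is their
Pearson correlation, which for 0/1 data is the phi coefficient

    phi = (ad - bc) / sqrt((a+b)(c+d)(a+c)(b+d))

with (a, b, c, d) the counts of regulators hitting both genes, only the
first, only the second, and neither. Spearman is available as an
alternative but is *exactly* equal on binary columns (midranks of a 0/1
vector are an affine function of the values, and correlation is affine
invariant); the package treats this identity as a testable invariant, not
an approximation.

**CRnet selection.** For each network the top k = floor(permille/1000 * n)
scoring pairs are kept, where n counts pairs with *defined* similarity:
zero-variance columns (genes with no recorded regulator, or targeted by
every regulator) are removed before the denominator is taken, self-pairs
are never candidates, and ties at the threshold resolve in lexicographic
gene-pair order. The per-mille denominator choice matters — using defined
pairs rather than C(N,2) makes the selected count reproducible on data
where some genes lack regulators — and the tie rule makes selection a pure
function of the score multiset.

**ACEr.** The average co-expression r of an edge set is the arithmetic
mean of r over its unordered pairs. Self-pairs are rejected outright
(their r is 1 by construction and would bias the mean); pairs with a gene
absent from the matrix or with undefined r are skipped and counted, never
silently dropped. The reference ACEr averages over all C(N,2) pairs and is
the baseline every edge set is compared to.

**Significance.** The permutation null draws, per replicate, the same
number of distinct non-self pairs uniformly without replacement from all
pairs of the matrix, and reports the one-sided empirical
p = (1 + #{null >= observed}) / (B + 1), so p is bounded below by 1/(B+1)
and is reproducible under a fixed seed. This is a deliberately
assumption-free null for the quantity actually compared (edge-set mean vs
all-pairs mean); no parametric (t-based) alternative is offered.

**Sensitivity.** Robustness to condition choice is probed by recomputing
the edge set's ACEr on n_c conditions sampled without replacement within
each replicate (conditions can recur across replicates). With n_c equal to
the full condition count every replicate reproduces the full-data ACEr
bit-exactly (see numerical notes).

**Enrichment.** The genes of an edge set are tested per annotation term
with the upper-tail hypergeometric probability P(X >= k | N, K, n) against
a configurable background (default: all genes of the expression matrix).
The default significance filter is the raw p < 0.01 convention of this
analysis style; Benjamini–Hochberg adjusted values are always computed and
reported alongside, and can be made the filter instead.

## Synthetic study generator

The generator emulates exactly the structure the analysis is meant to
detect. Module gene g in module m gets the profile

    x_g = sqrt(rho) * f_m + sqrt(1 - rho) * eps_g

with f_m (one latent factor per module) and eps_g iid standard normal per
condition, so the *population* within-module correlation is exactly rho;
background genes are pure noise. Each module owns a dedicated regulator
set per network in which it is planted (drawn disjointly from the TF pool
for the TR networks and from non-module genes for the PPI network), and a
`cross_network_overlap` fraction of modules is planted in all three
networks, the rest in one network each (round-robin). A single latent
factor per module was preferred over simulating TF activities because it
pins the recovery target (rho) analytically.

Defaults are the package's standard evaluation conditions: 600 genes, 60
TFs, 400 conditions, six modules of 10 genes, rho = 0.8, 5 regulators per
module per network, background edge probability 0.01, overlap 0.5.

Background edges are Bernoulli(p_background_edge) over ordered
(any gene -> gene) pairs in *all three* networks, which gives every gene
about p*n_genes (~6 at defaults) random recorded regulators — comparable
to the per-gene regulator counts of real curated networks. This grid
choice is deliberate: restricting background sources to the 60-gene TF
pool at the same density leaves most genes with at most one recorded
regulator, and sparse binary profiles then collide at phi = 1 exactly
(hundreds of gene pairs with identical single-regulator profiles), an
artifact of binary-profile correlation on near-empty columns rather than a
signal the method claims to detect. The TF pool is drawn from the tail of
the gene list so that TR edges survive restriction to the measured-gene
universe, as in real data where TFs are themselves measured genes.

All randomness derives from one seed through named `SeedSequence` streams
(expression, per-network planted edges, per-network background edges), so
any component can be regenerated independently and outputs are bit-stable
across runs and platforms.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: scale-free degree distributions, TF-activity
dynamics, overlapping or hierarchical modules, heteroscedastic or
non-Gaussian noise, batch structure across conditions, and evidence-type
biases between binding and perturbation experiments. Recovery results on
the generator certify the pipeline's correctness, not the biological
effect size in any particular organism.

## Numerical choices

- Missing expression values are rejected, not pairwise-deleted: pairwise
  deletion silently changes the observation set per pair.
- Constant genes yield NaN co-expression entries; all downstream pair
  enumerations skip and count them.
- The co-expression kernel computes each row of the correlation matrix as
  a matrix–vector product on standardized rows; chunked (memory-limited)
  and dense modes therefore give bit-identical results, because a blocked
  matrix–matrix product would change BLAS accumulation order with the
  block shape. The upper triangle is computed once and mirrored, so the
  matrix is exactly symmetric; the diagonal is exactly 1 for non-constant
  genes; entries are clipped into [-1, 1].
- `acer` sorts canonical pairs lexicographically before extracting values,
  which makes its summation order identical to the reference's
  upper-triangle order whenever the matrix's gene ids are sorted — hence
  acer(all pairs) == reference_acer exactly, not just approximately.
- The sensitivity kernel recomputes each replicate through the same
  per-pair routine as its own full-data value, with selected columns
  sorted and forced C-contiguous; this is what makes the
  "all conditions = full data" identity exact to the bit.
- Written TSVs use shortest-roundtrip float repr and are parsed with
  numpy's correctly rounded string conversion, so fixtures round-trip
  losslessly.
- Per-mille cutoffs are validated in (0, 1000]; the analysis convention is
  1–5 per-mille and the CLI/pipeline default is 5.

## Design choices in genuinely open territory

- **PPI direction.** PPI edges are stored as ordered pairs because the
  "first upstream neighbour" construction is directional; since PPIs are
  biologically undirected, `symmetrize_ppi` is an explicit, documented
  option (default off).
- **Edges under both evidence types** are kept in both the binding and the
  expression network; the two evidence filters are independent.
- **TF–TF pairs** are ordinary candidate pairs: every gene column of the
  incidence matrix participates, whether or not that gene is also a
  regulator.
- **Intersections** are taken on unordered pairs only; per-network
  similarity scores are reported per source, never merged.
- **Merged-network mode** (union of the two TR networks, evidence tag
  `merged`) is an optional pipeline flag producing a fourth CRnet and its
  intersection with the PPI CRnet.
- **Permutation null and the +1 correction** are this package's choice of
  significance procedure for edge-set ACEr; it is declared, seeded and
  reproducible rather than inherited from any particular convention.

## Problem sizes

The test suite and the acceptance script run the full analysis at
600 genes x 400 conditions (standard evaluation study) with 999
permutations and 200 sensitivity replicates, and smaller fixtures
(150 x 60) for pipeline-level checks; the whole suite completes in a few
seconds on one CPU. The implementation itself is dense-matrix based and
comfortably handles genome-scale inputs (thousands of genes, ~10^3
conditions); the chunked co-expression mode exists for machines where the
full N x N correlation matrix is the binding constraint.

## Known limitations

- Binary incidence only: interaction strengths and signs are not modeled.
- No negative-interaction evidence; absence of an edge is treated as
  "unknown", which the phi coefficient necessarily reads as "no shared
  regulator".
- Hypergeometric enrichment takes annotations as given (no ontology
  propagation or term-redundancy reduction).
- The permutation null ignores the dependence structure among overlapping
  pairs; for very small edge sets the achievable p-values are coarse
  (multiples of 1/(B+1)).
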