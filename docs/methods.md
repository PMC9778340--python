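# Methods

## Problem setting

Epistatic interactions — joint, non-additive effects of several SNPs on a
binary disease phenotype — are hard to find above order 3 because the number
of candidate SNP sets grows as C(N, k). `epinet` sidesteps the combinatorial
search: it scores only the two- and three-order interactions exhaustively,
keeps the strong ones, turns them into an SNP network, and reads high-order
candidates off the network as dense, possibly overlapping modules. The
assumption doing the work is that a genuine k-order interaction leaves
detectable traces in its low-order projections: its pairs and triples score
above background, and the triangle edges contributed by triples knit its
SNPs into a tight subgraph.

## Interaction scoring

A k-order SNP set X′ is scored by plug-in mutual information with the
phenotype, MI(X′; Y) = H(X′) + H(Y) − H(X′, Y), in bits, from the joint
contingency table over the 3^k genotype combinations and the two classes.
Choices:

* **Log base 2.** Only the ranking is used downstream, which is
  base-invariant.
* **Maximum-likelihood estimator, no bias correction, 0·log 0 = 0.** The
  plug-in estimator is monotone under adding attributes, so (causal,
  noise) pairs score at least as high as the causal SNP alone; the
  threshold stage is designed around that background shape.
* **Radix encoding.** Each sample's combination is encoded as Σ gⱼ·3ʲ and
  tabulated in one pass; enumeration is chunked per leading index pair and
  vectorised, and the output is independent of the chunking. Ties in MI are
  broken by lexicographic index tuple, making the ranking deterministic.

## Pre-filtering (multiSURF)

For data with many SNPs, exhaustive triple scoring is capped by a
relief-based pre-filter. The "near-only" multiSURF variant is used: for
each target sample, the mean μ and standard deviation σ of its Hamming
distances to all other samples define a per-target neighbourhood
(distance < μ − σ/2); near hits decrement the score of each differing SNP,
near misses increment it, and scores are divided by the sample count. The
Hamming metric on genotype codes is the standard choice for discrete GWAS
attributes in the relief family. Default retention is m = 50 SNPs,
configurable, and filtering can be disabled outright (the scaled studies in
this repository run unfiltered at 100 SNPs).

## Threshold selection

Each ranked MI list (orders 2 and 3 separately) is cut by an elbow rule:

1. fluctuation score — the second forward difference
   Score(s(i)) = s(i+2) − 2 s(i+1) + s(i) of the descending MI sequence;
2. outlier band — values outside [M − V, M + V], with M the mean and V the
   *population variance* of the fluctuation vector. The literal variance
   band is dimensionally odd (for values ≪ 1 it is far tighter than ±σ, for
   values ≫ 1 far looser), so a `band="std"` option substitutes the
   standard deviation; both are first-class, the default stays literal.
3. sliding window — a window of preset length (default 10) slides from the
   left of the fluctuation vector and stops at the first position covering
   fewer than two outliers; the selection threshold is the window midpoint
   (start + ⌊len/2⌋), and the ranked prefix up to it is kept.

Degenerate inputs: lists shorter than 3 are kept whole. If every window
covers two or more outliers (or the window exceeds the vector), a fallback
threshold min(n, max(2·n_snps, 100)) keeps the edge set sparse while
guaranteeing termination. Interactions whose MI is ≤ 1e−12 bits are dropped
after selection: they carry no association evidence, and a constant
phenotype therefore yields the explicit "no interactions selected" outcome
rather than a spurious network.

## Network construction

Selected pairs become edges directly. A selected triple (a, b, c)
contributes its three pairwise edges a–b, a–c, b–c: a strong joint effect
is taken as evidence for all pairwise links, and it is exactly these
triangles that give high-order interactions a clique-like footprint.
Duplicate edges merge, with provenance tags ({pair, triple}) kept for
diagnostics only. Edges are unweighted — the module stage weights nodes.

## Module detection

**Connectivity.** For node v with neighbourhood subgraph SG(v) (v plus its
direct neighbours), C(v) = 2·|eN(v)|·DN(v) / (|N(v)|·(|N(v)|−1)), where
DN(v) is the density of the densest core (highest-k-core) of SG(v) — the
MCODE-lineage reading of "maximum subgraph density"; `dn="plain"` uses
SG(v)'s own density instead. Clique-embedded nodes attain C = 1; isolated
and pendant nodes are assigned 0.

**Iterated weights.** All weights start at 1. Each round, edge (vi, vj)
gets w(vi)·C(vi) + w(vj)·C(vj) + Σ_u w(u)·C(u) over common neighbours u,
and each node's new weight is the sum of its incident edge weights; after
each round weights are rescaled by their maximum (only the ranking is used,
so the rescale is behaviour-preserving and keeps values bounded). Default
t = 2 rounds: one round propagates direct-neighbourhood structure, the
second mixes in second-neighbourhood information; further rounds change
rankings little on the graphs this stage sees.

**Seeding and expansion.** Seeds are drawn in descending final weight.
Each seed grows greedily: among the module's outside neighbours, a
candidate qualifies if (a) it is adjacent to *strictly more* than λ·|M|
current members (λ = 0.5: strict majority attachment), (b) the
post-admission density stays ≥ d_min = 0.6, and (c) its weight is at least
α = 0.25 of the member mean. The best qualifying candidate is added —
highest weight, ties to the one touching more members, remaining ties to
the smallest index — until none qualifies. The strict inequality in (a)
matters: exact-half attachment would let a high-weight hub admitted at
|M| = 2 drag the module across a sparse bridge; with the strict rule a
bridged pair of cliques resolves into the two cliques.

Seeding continues while the best remaining weight is at least
mean − 1·std of all final weights (configurable as mean + `seed_floor_sigma`·std),
up to N_max = 20 accepted modules. The permissive floor is deliberate:
dense structures whose members all carry middling weights (e.g. the second
of two overlapping cliques) must still get a seed. Used seeds are excluded
from seeding but remain available as members, so modules overlap; rejected
(sub-min_size, default 3) expansions do not count against N_max. Modules
with Jaccard overlap ≥ 0.8 are merged keeping the higher mean weight, and
the report is ordered by mean weight, then density, then seed index. An
optional over-prune pass (off by default) iteratively removes non-seed
members with within-module degree < γ·(|M|−1), γ = 0.5, keeping the seed's
component.

Every tie in the stage is broken by node index, so the module list is a
deterministic function of the network and parameters.

## Simulator

The generator plants one k-order penetrance model (k ∈ [2, 8]) among
independent noise SNPs. Per-locus risk factors e(g) = 1 + θ·g grow with
minor-allele dose; the genotype-combination score is their product
(multiplicative), their sum (additive), or a step on the genotype-dose sum
reaching its maximum k (threshold). The table is baseline·score (default
baseline 0.1) clipped to [0, 1]; clipping triggers a warning because it
flattens the top of the model class. θ is found by bracketing plus Brent
root-finding so the realized heritability
h² = Σ P(g)(f(g) − K)² / (K(1 − K)) matches the target within 1e−3, with
P(g) from HWE and linkage equilibrium; unattainable targets raise an error
naming the feasible bound. The two heritability levels exercised throughout
are 0.05 and 0.40.

Samples are drawn by rejection — genotype from HWE, phenotype from
Bernoulli(f(g)), until the case/control quotas are met exactly — so
balanced designs are exact rather than reweighted. Noise SNPs are HWE draws
at MAFs uniform in (0.05, 0.5), a conventional background range. Causal
positions are randomized and recorded (ids `M0..`, noise `N0..`).

What the generator does **not** emulate: linkage disequilibrium between
SNPs, covariates and population structure, genotyping error or
missingness, and marginal-effect-free model construction — the planted
models here carry marginal effects, which the network stage exploits by
design. Passing tests therefore demonstrate correct mechanics and power
under idealized architecture, not performance on LD-rich real cohorts.

## Power evaluation

A solution is one reported module's member set. Acc = hit/order counts
recovered causal SNPs over the planted order, so over-large modules are not
penalized — a documented property, and the reason the null study below
matters. Power_all averages the per-replicate mean Acc, Power_best the
per-replicate maximum, over N replicates (30 per setting is the
full-scale convention; 10 in the desk-scale studies here); replicates with
no solutions contribute 0.

## Problem sizes used in tests and the acceptance script

The bundled studies are scaled for a single CPU: 100 SNPs × 2000 balanced
samples × 10 replicates for the power study (3-order multiplicative,
h² = 0.40, MAF 0.3, unfiltered), a matching h² = 0 null scored against a
random fake truth, 300-SNP/800-sample replicates for the filter-retention
check, 20-node planted-partition graphs for module recovery, and exhaustive
small-graph enumeration (all connected graphs on ≤ 6 nodes) for the
greedy-expansion trace check.

## Known limitations

* The elbow rule assumes the ranked MI sequence has an outlier-dense head;
  on perfectly smooth synthetic sequences outliers collapse to the
  signal/noise boundary and the window can stop immediately, selecting only
  a handful of interactions. The fallback threshold bounds the damage.
* The literal variance outlier band behaves erratically across MI scales;
  use `band="std"` when absolute MI values are far from 1.
* Acc does not penalize module size, so Power numbers should be read
  alongside module sizes and the null-study control.
* Heritability matching assumes h²(θ) is monotone on the bracketing
  interval; with heavy clipping the search can in principle stall, in which
  case the realized-h² check raises rather than returning a miscalibrated
  model.
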