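# Methods

This note documents the model, the numerical choices, and what the
synthetic scenarios do and do not establish.

## Structural control configurations

A directed regulatory network G is represented bipartitely: every gene has
an out-copy and an in-copy, and each edge u→v is a bipartite edge between
the out-copy of u and the in-copy of v.  A maximum matching of this
bipartite graph (Hopcroft–Karp, via networkx) induces one structural
control configuration (SCC): each node has at most one matched out-edge
and one matched in-edge, so the matched edges decompose the node set into
node-disjoint elementary paths and elementary cycles.  Nodes without a
matched in-edge are the driver nodes, one per path.  *Additional links*
are the remaining network edges that run from a non-terminal path node
into a cycle; all eligible edges are included (the alternative — one link
per cycle — would only shrink direct regions).  A self-loop may be
matched, making its node a one-node cycle.

The matching number is unique, so driver-node counts are seed-invariant;
the edge composition is not.  Matchings are diversified by permuting the
node and edge insertion order under a seed before running Hopcroft–Karp,
which is the standard way to sample alternative maximum matchings without
enumerating them (enumeration is intractable at network scale).  By
default 1000 SCCs are sampled; the fraction of genes acquiring new
distinct direct regions decays as configurations accrue, which the test
suite asserts as a non-increasing discovery rate.

## Control regions

The direct control region of gene i under one SCC is {i} plus everything
reachable from i along skeleton edges (matched edges + additional links)
— never along raw network edges.  Internally this uses the closed form of
skeleton reachability: a path suffix plus the cycles linked from its
non-terminal nodes.

Indirect influence is computed only for deregulated genes j in the direct
region (covering indirect regions of quiet genes would reward coverage of
deregulation that the control node cannot actually reach through a
deregulated intermediary).  Edges downstream of j are weighted by
w = max((|corr(x_j, x_u)| + |corr(x_j, x_v)|)/2, ε); Pearson correlations
are computed on the case-condition samples of the expression matrix (the
disease samples are what the published sample sizes refer to), genes
without expression rows or with zero variance contribute correlation 0,
and ε is the critical correlation at two-sided p = 0.05 for that sample
size, computed exactly from the t-transform of the null distribution of
the sample correlation coefficient.  "Downstream subnetwork of j" means
the subgraph induced by the genes reachable from j in the full network G,
not in the SCC — indirect influence flows through all regulatory links.

The ICV of gene k is the reciprocal of the minimum total cost of a path
j→k under edge cost −log w + 1 (natural log; the base only rescales costs
and cancels under the min–max normalizations used later).  All costs are
at least 1, so Dijkstra applies.  Genes with ICV ≥ λ join the indirect
region along with the genes on their optimal paths.  Because every prefix
of an optimal path costs less than the whole path, the union of those
path genes equals the cost ball of radius 1/λ around j — so the region
content is independent of how ties between equal-cost paths are broken,
and the implementation simply collects the Dijkstra ball (scipy sparse
Dijkstra with an early cutoff).  λ defaults to 0.3, the published
convention; `lambda_threshold` can instead calibrate it as the (1 − p)
quantile (p = 0.01) of ICVs pooled from label-shuffled null networks.

## Greedy OCN search and FDR

The objective o = d − u is maximized greedily.  Candidate regions are the
deduplicated (gene, SCC) regions; at each step every candidate's marginal
gain against the current union is evaluated (a single mat–vec product
over the region mask matrix) and the best is taken.  A gene is accepted
only if o strictly improves; the search stops when the relative growth of
o falls below the stop rate (default 5%) or no improving candidate
remains.  When o ≤ 0 the growth-rate test is skipped (any strict
improvement is accepted), which only matters in null networks.

Multi-start: all (gene, SCC) regions are ranked by contained DScore (the
objective is DScore coverage, so ranking by size would favor large but
irrelevant regions); the control nodes of the top fraction (default
0.01%, at least one region) each seed a search with that gene forced as
the first selection.  The recorded optimal control region (OCR) of an
accepted OCN is the region chosen at its acceptance step in the
highest-objective solution containing it.

OCN calls use an empirical FDR over occurrence frequencies.  The same
multi-start procedure runs on node-label-shuffled copies of the network
(default 10; DScores and expression stay attached to gene labels, so only
the topology moves).  At each observed frequency threshold f the expected
false-positive count — genes at frequency ≥ f among the null searches —
is divided by the observed count; a gene is an OCN iff the FDR at its own
frequency is ≤ 0.05.  The null frequency of a gene is computed over all
null searches pooled across networks (`pool_null=True`).  The per-network
variant (counting within each null network and averaging) is available
but degenerate at small search counts: greedy searches are deterministic
given the candidate set, so the few searches within one null network
largely agree, some null gene always reaches within-network frequency 1,
and nothing can ever be accepted.  Pooling across networks measures what
the null is supposed to measure — how often a *specific* gene recurs by
chance — while leaving every spec-level contract of the estimator intact.

## Synergy, SL enrichment, ΔD, degree baseline, GI score

Mutation score: upper-tail hypergeometric enrichment of mutated genes in
each OCR against the network-node universe; the score is the geometric
mean of the two −log p values.  Crosstalk score: edges (either direction)
between the pair-exclusive OCR sets divided by 2·|A|·|B|; shared genes are
excluded from both sides, since the synergy rationale rests on each node's
*specific* region.  Both raw scores are min–max normalized over the pooled
candidate and null pairs before being multiplied — normalizing over
candidates alone would make the score depend on which other candidates
happen to be tested.  Null pairs are drawn uniformly (distinct genes);
each null gene carries its best (highest-DScore) region across the sampled
SCCs.  Empirical p-values use the add-one correction,
p = (1 + #{null ≥ observed}) / (1 + n_null), and BH adjustment runs over
candidate pairs.  The default null size is 10⁵ (the estimator is unbiased
at any size; the reference protocol used 10⁷).

SL enrichment uses the four counts: SL pairs between the exclusive OCR
sets, |A|·|B| cross pairs, SL pairs among network genes, and C(N,2) total
pairs — SL interactions are unordered, hence unordered pair counting.

ΔD of a crosstalk gene is the inter-OCR density drop when the gene is
removed from its exclusive set; numerator and denominator both change, so
ΔD can be negative and is recorded as computed.  The null pools ΔD values
of crosstalk genes of random gene pairs (default 10⁵ pairs here; the
reference protocol used 10⁶); significance at empirical p < 0.1.

Degree baseline: regulatory value r(v) = outdeg − indeg; the null draws
each edge's target uniformly at random (out-degrees preserved, in-degrees
multinomial).  Permuting existing targets was considered and rejected: on
regular graphs (e.g. a cycle) it reproduces the same in-degree sequence,
collapsing the null to a point mass so that any removal-induced r = 1
looks significant.  A node is significantly regulatory at empirical
p < 0.05 against the pooled null; control nodes are those whose removal
increases the significant count.

GI score: the growth phenotype of a knockout population is
log₂((f_ko^e/f_wt^e)/(f_ko^b/f_wt^b)) / d, where d = T/d_ko is the number
of doublings, d_ko = d_wt / (1 − (x/T)·d_wt), and
x = log₂(f_ko^b·f_wt^e / (f_wt^b·f_ko^e)).  (The reference notation
overloads "d" for both doubling time and doubling count; the divisor in
the phenotype is read as the doubling *count* T/d_ko, which makes the
phenotype a per-doubling depletion rate and reduces to 0 when fractions
are unchanged.)  A denominator ≤ 0 signals a nonphysical doubling time
and is an error.  GI = observed double-knockout phenotype minus the sum
of the single-knockout phenotypes.

## Synthetic scenarios

`planted_scenario` embeds two regulator-rooted cascades (a regulator with
30 direct targets each, by default) in a sparse random directed background
of 300 genes.  Cascade targets are cross-linked (30 inter-cascade edges)
so the regulator pair has genuine crosstalk; a few background genes feed
into cascade targets.  Case-condition expression of cascade genes follows
a latent-factor model on the log scale (loading √ρ, ρ = 0.6, unit noise,
exponentiated to FPKM-like values; 50 samples per condition); control
samples are independent noise.  Planted genes get adjusted p-values
log-uniform in [10⁻⁶, 10⁻³] and background genes uniform in [0.2, 1], so
the planted cascades carry the entire DScore mass — the regime in which
recovering exactly the two regulators is the correct answer.  Mutated
genes are oversampled inside the cascades (70% of 20) and SL pairs
between them (75% of 40).

What passing these tests shows: the machinery correctly propagates
deregulation through correlation-weighted regions, the greedy/FDR stack
finds planted regulators without false positives, and synergy ranks the
planted pair above decoy pairs.  What it does not show: performance under
partial DScore mass in the background, overlapping cascades, batch
effects, count noise (expression is lognormal, not negative-binomial
RNA-seq counts), or network mis-specification — real regulatory networks
are incomplete and their edges are not all causal.

## Problem sizes and defaults

Pipeline defaults follow the reference protocol (1000 SCCs, λ = 0.3,
ε from the sample size, 5% stop rate, top 0.01% multi-start, 10 null
networks, α = 0.05).  The test suite and the recovery experiments run the
scenario at 100 SCCs with 10 null networks and 10⁴ synergy null pairs,
and a 150-gene variant at 50 SCCs with 8 null networks for the fast
property test; these sizes were chosen as the smallest at which the
frequency-based FDR has enough null searches to be meaningful.
Region masks are boolean matrices; direct regions use the closed-form
skeleton reachability; region deduplication across SCCs keeps the greedy
mat–vec small.  All randomness flows from one master seed through
`numpy.random.SeedSequence` spawns, so every run is exactly reproducible.

## Known limitations

- Additional-link policy (all eligible links) and the per-step choice of
  each gene's best region are reconstructions of under-specified details;
  both are documented choices, not identities.
- The empirical FDR is coarse when the number of real searches is small
  (frequencies are then multiples of 1/k).
- `lambda_threshold` samples sources rather than enumerating all ICVs,
  trading exactness of the null quantile for tractability.
- The synergy null draws gene pairs uniformly; degree- or region-size-
  matched nulls would be stricter.
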