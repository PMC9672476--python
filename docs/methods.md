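# Methods

## The model

`winner` ranks genes in a weighted gene–gene interaction network and
grows the network one statistically justified gene at a time.  The
inputs are a seed-gene list (genes believed relevant: differentially
expressed genes, a curated pathway, literature hits) and a global
collection of gene–gene interactions, each carrying a confidence score
c(j, i) ∈ [0, 1] (set to 1 when the source database provides none).

### Scoring

Each gene starts from an initial score determined by its weighted
connectivity,

    S₀(i) = exp(2 ln w(i) − ln I(i)) = w(i)² / I(i),

with w(i) the summed confidence of the gene's interactions under the
active mode and I(i) their count.  Genes isolated under the mode get
S₀ = 0.  The score is refined by a damped random-walk update

    S_t(i) = (1 − σ) S₀(i) + σ Σ_j c(j, i) S_{t−1}(j) / d(j),

iterated until max_i |S_t(i) − S_{t−1}(i)| < tol.  σ is the standard
PageRank damping parameter; d(j) is the total confidence of the edges
along which gene j passes score in the active mode.  In an undirected
network d(j) = w(j) and the update is the classical
confidence-proportional score diffusion; for an undirected network
with all confidences 1 the degree vector is an exact fixed point, so
the converged score *is* the node degree — a useful analytic identity
that the test suite checks to machine precision.

Directed (regulatory) networks support two readings.  In *upstream*
mode gene i collects score from the genes it regulates, so regulators
of high-scoring targets rank high; in *downstream* mode from its
regulators.  The mode redefines w, I, c accordingly.

Ranks are assigned descending by converged score with average-rank tie
handling, then rescaled to percentiles, (n − r)/(n − 1)·100, so the
top gene sits at 100% and the bottom at 0% and pathways of different
sizes can be pooled.

### Parameters

| parameter | default | meaning |
|---|---|---|
| `damping` σ | 0.85 | fraction of score diffused per iteration (vs. retained from S₀); the conventional random-walk value |
| `tol` | 0.001 | convergence threshold on the maximum per-gene score change |
| `max_iter` | 200 | iteration cap; converged rankings on our fixtures need far fewer |
| `mode` | `undirected` | `undirected` / `upstream` / `downstream` |
| `alpha` | 0.05 | significance gate for both expansion tests |
| null `replicates` | 1000 | randomized networks per ensemble |

### Numerical choices

- **Convergence norm** — maximum absolute per-gene change: the
  strictest scale-free choice when no norm is otherwise specified.
- **Directed denominator** — the literal within-mode w(j) vanishes on
  pathway sources/sinks, leaving the update undefined on chains.  We
  define d(j) as the total confidence of the edges along which j
  *distributes* score in the active mode (upstream: j's incoming
  regulatory edges; downstream: j's outgoing edges), which reduces to
  w(j) in the undirected case and keeps propagation well defined
  everywhere.
- **Degenerate inputs** — isolated genes keep S = S₀ = 0; genes with
  d(j) = 0 simply contribute nothing; a single-gene network gets
  percentile 100.
- **Ties** — average (fractional) ranks; output rows ordered by rank
  then identifier so files are deterministic.
- **Duplicate edges** are merged keeping the maximum confidence
  (strongest evidence); self-loops are dropped (the score equations
  give them no meaning).

## Ranking significance

p-values for the observed converged scores come from ensembles of
randomized networks.  Five randomization schemes are implemented:
total rewiring (destroys all topology, keeps |E|), degree-preserving
double-edge swaps (10·|E| attempted swaps per replicate), modularity-
preserving swaps (double-edge swaps restricted to edge pairs whose
community-pair labels under a fixed greedy-modularity partition match,
which preserves degrees and all within/between-community edge counts,
hence the partition's Newman Q exactly), and adding or removing 5% of
edges.  Swaps operate on unweighted topology, so every replicate's
weights are redrawn with replacement from the original network's
empirical weight distribution.

Per gene the ensemble scores are summarized by a fitted normal
N(μ(i), σ(i)) (sample mean/std), and

    p_r(i) = lower tail mass at S(i) if S(i) < μ(i), upper tail mass
             if S(i) > μ(i), 0.5 at the mean.

This printed form is one-sided per branch and therefore bounded by
0.5; it rejects at twice the nominal level under its own null.  The
`two_sided` option doubles the tail, which makes p_r uniform under the
null — the calibration test uses this form, and the rejection rate
lands at 0.05 ± 0.02.  Degenerate σ = 0 (e.g. unweighted regular
graphs under a degree-preserving null, where every replicate rescores
each gene at its degree) returns p_r = 1 at the mean and 0 elsewhere.

A chi-square goodness-of-fit test (10 equal-probability bins under the
fitted normal, adjacent bins pooled to expected counts ≥ 5,
df = bins − 3) quantifies how normal the per-gene null samples look;
smaller statistics under degree-preserving than under total rewiring
randomization reproduce the motivating observation that topology-
preserving nulls give better-behaved score distributions.

The noise-robustness assay spikes round(ρ·|E|) spurious edges into the
network, re-ranks, and records per gene whether the rank moved by ≥ 10
(configurable), summarized separately for significant (p_r < 0.05) and
non-significant genes.

## Expansion

Candidates are the genes adjacent to ≥ 1 ranked gene in the global
collection.  Two hypergeometric over-representation tests gate
admission; both must fall below alpha, and p_e = max(p1e, p2e):

- **Test 1** — population: all genes except the candidate (N), of
  which the ranked genes are successes (K); draw the candidate's n
  neighbors; k of them are ranked.  p1e = P[X ≥ k].
- **Test 2** — the candidate is compared to its degree-closest ranked
  gene g* (ties toward the larger degree, then lexicographic).  With
  deg(cand) ≤ deg(g*): p2e = P[X ≥ k(cand)] for
  X ~ HG(N = deg(g*), K = k(g*), n = deg(cand)).  With
  deg(cand) > deg(g*) the neighborhoods swap roles and the
  complementary tail 1 − P[X ≤ k(cand) − 1] under
  X ~ HG(N = deg(cand), K = k(cand), n = deg(g*)) is used, clipped to
  [0, 1].  The parameterizations are isolated in the two test
  functions so alternatives can be swapped; conventions: a candidate
  with no interactions, no ranked links, or a matched seed without
  ranked links gets p = 1.

The printed combination operator is used with the standard
hypergeometric normalizer C(N, n) — the alternative C(N, K) in the
denominator would not normalize the distribution.

Among passing candidates the one with the highest expansion score
e(i) = Σ_j c(i, j) S(j) / W(j) (j over ranked neighbors; W(j) the
total incident confidence of j in the *global* collection, not the
within-ranked-set w(j)) is added; ties broken by smaller p_e, then
lexicographically.  The grown set is re-ranked on its induced
subnetwork — including edges among previously added genes — and the
loop repeats until no candidate passes or `max_add` is reached.  The
loop is deterministic: no randomness enters anywhere.

## Evaluation procedures

- **Retrieval** — precision = |E∩U|/|E|, recall = |E∩U|/|U|, F1 their
  harmonic mean, for predicted expansion set E against reference
  update set U.
- **Layers** — strongly connected components of a directed network are
  condensed (a regulatory cycle acts as one node); components with no
  incoming edges form layer 1 and BFS distance from the nearest root
  assigns the rest.  Percentiles pooled per layer across pathways
  support boxplot summaries.
- **Baselines** — PageRank (damping 0.85, confidence-weighted), node
  degree, normalized betweenness, eigenvector centrality (power
  iteration, tol 1e-8), clustering coefficient; compared by Pearson
  correlation over shared genes.
- **Pathway levels** — spine-and-offset assignment on the
  pathway-to-pathway regulatory network: the longest shortest path is
  numbered 1..n upstream-to-downstream (ties on the spine broken
  lexicographically by (source, target) and along lexicographically
  smallest successors); remaining pathways get levels offset by
  shortest directed distance from assigned ones (upstream subtracts),
  with multiple assignments averaged, repeated to exhaustion;
  disconnected remainders restart with their own spine.
- **Bin–level correlation** — the top 2^x ranked genes (x = 1..X)
  define nested bins; the pathways newly enriched at bin x (set
  difference against all smaller bins) are paired with their levels
  and (x, level) feeds a Pearson correlation.

## Synthetic fixtures and what they do (not) show

The generators emulate the shape of real inputs at desk scale:
preferential-attachment networks for interactome collections (heavy-
tailed degrees), a dense planted module with withheld members for the
retrieval benchmark, layered DAGs for regulatory pathways, regular
graphs as symmetric controls.  Edge confidences default to Beta(2, 2)
on [0, 1], emulating full-range database confidence scores; the
retrieval benchmark passes an explicit `min_weight = 0.75` floor,
emulating the common practice of keeping only high-confidence
interactions.  All generators are pure functions of their seed.

What the fixtures do **not** reproduce: real interactomes' degree
exponents, study-coverage bias (hub edges being better attested),
identifier semantics, or curated pathway sizes.  Consequently two
cautions.  First, because fixture weights are i.i.d., a fixture
network is statistically exchangeable with its own degree-preserving
null, so "significant" genes on a fixture are genes with extreme
weight draws rather than biologically persistent structure; the
noise-robustness ordering (significant genes more rank-stable) holds
under full-range weights, where significance reflects large genuine
score margins, but is *not* expected to hold when weight variance is
squeezed (e.g. a 0.75 confidence floor), where p_r mostly picks up
normal-fit error on low-degree genes.  Second, the per-gene null
normality is approximate: at 1,000 replicates the chi-square test has
power against the mild non-normality of low-degree gene nulls (sums of
few beta-distributed weights), so we assert the *ordering* of
chi-square statistics between randomization schemes, plus approximate
normality at moderate sample size, rather than universal normality.

## Problem sizes

The test suite and the acceptance script run: 100-node / 196-edge
scale-free fixtures with 1,000-replicate null ensembles for the
normality, calibration, and noise experiments; 20 draws of a 20-gene
module (10 withheld) in a 200-node background for expansion recovery;
20 six-layer × 8-wide DAGs for layer ordering; exhaustive
hypergeometric enumeration up to N = 12.  These sizes give the
Monte-Carlo checks comfortable margins while keeping a full run in
tens of seconds.

## Known limitations

- Randomization schemes are defined for undirected networks (the
  significance machinery targets the undirected ranking, as in the
  motivating experiments); directed nulls would need in/out-degree
  preserving swaps.
- Modularity preservation is exact only for the fixed detected
  partition; Q under a re-detected partition of the randomized network
  may differ.
- The expansion test parameterizations are one concrete reading of the
  published tests (the authoritative supplementary definitions are not
  public); they are deliberately isolated in two small functions.
- Empirical (rank-counting) p-values are not offered; the normal fit
  is the supported route.
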