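# Methods

This note documents the models and procedures implemented in
`netpaleo`, the assumptions behind them, the defaults and why they
were chosen, and what the synthetic studies used in testing do and do
not establish about real data.

## The dating model

### Why not standard parsimony

The analysis starts from a set of interactions known in one reference
species (human).  Three features of such data break ordinary
ancestral-state reconstruction: every interaction is present in human
by construction; orthology calls resting on sequence *and* gene order
make independent re-appearance of a gene state effectively impossible;
and an ortholog may be scored absent because of annotation or
orthology-calling failure rather than true loss.  The package
therefore infers only the **latest possible origin** of each gene: the
branch immediately ancestral to the MRCA of the species carrying its
ortholog.  This is a constrained parsimony — one appearance, losses
free — and deliberately not a maximum-likelihood or Bayesian
reconstruction.  It yields an upper bound on interaction age: a pair
is dated to the younger of its two gene origins, because both genes
must exist before they can interact, while nothing prevents the
interaction itself from being younger still.

### The tree

All analyses run on the fixed rooted topology
`((((human,chimp),macaque),(mouse,rat)),((horse,dog),cow))` with
branch lengths equal to mean synonymous divergence Ks (substitutions
per synonymous site), a near-neutral clock.  The unrooted tree has 13
branches; the central branch separating Euarchontoglires from
Laurasiatheria carries the root, and since the codon models that
produce the lengths are unrooted, its two rooted halves are
indistinguishable — each origin class on it (root,
euarchontoglires-stem) is assigned half the central separation.
Branch "age" for the degree-versus-age analysis is the cumulative Ks
from the human tip to the branch midpoint; the midpoint convention is
a package choice, made because the x-axis anchor of such plots is
otherwise arbitrary.

### Rates and the steady-state correction

Loss rates are estimated on the two internal branches not containing
human ancestors (mouse-rat and horse-dog stems), where a loss is
observable without contradicting the human data.  A pair is *exposed*
on a calibration branch if both genes are inferred present at the
branch's parent node (equivalently, the pair's origin class is at or
above that node — under the single-appearance model a gene whose MRCA
spans the parent is necessarily present there).  An *event* is an
exposed pair with at least one gene absent from both descendants of
the branch; minimal loss places a single loss on the stem.  Gain rates
divide the pairs originating on a branch by the pairs present at its
child node.  Both are events per exposed PPI per unit Ks, so under a
steady-state network (edge count stationary) they are comparable.

The corrected root-presence fraction is
`corrected = raw × max(0, 1 − Σᵢ g·Nᵢ·Ksᵢ / N)` over the five lineage
branch classes, where `g` is the gain rate, `Nᵢ` the pairs present at
branch *i*'s child node and `N` the total pair count.  This linear
expected-gains form is a first-order stand-in for an exponential gain
model; with per-branch `g·Ks ≪ 1` the two agree, and the output flags
the formula in its metadata.  Whether gain exposure should use the
child or parent node of a branch is not determined by the model;
child-node exposure is implemented and logged.

## Null models

Three randomisation engines back every test:

* **Pseudo-pair (pr-PPI) sampling** — pair members are drawn
  independently from the interactome's genes with probability
  proportional to degree; self-pairs, true edges and duplicate pairs
  are rejected and redrawn.  Uniqueness is enforced at the pair level
  only: a gene may appear in many pseudo-pairs of one replicate, which
  mirrors the degree-weighted gene-draw description of the null rather
  than a configuration model.
* **Node-weight permutation** — a uniform random permutation of the
  node-attribute multiset over the same gene set.
* **Degree-preserving rewiring** — repeated double-edge swaps,
  rejecting any proposal creating a self-loop or multi-edge, with
  10 attempted swaps per edge by default (a conventional mixing
  heuristic).  Degrees are preserved exactly by construction.

All engines are deterministic under a seed; replicated callers use one
stream per replicate seeded `seed + replicate index` so individual
replicates are reproducible in isolation.  Empirical p-values
throughout are `(r + 1)/(n + 1)` with `r` the number of replicates at
least as extreme, reported as `<1/(n+1)` when `r = 0` — the standard
bias-avoiding estimator.

## Co-evolution statistics

Branch-wise ω vectors of an interacting pair are aligned on their
shared branches (a mirrortree, at most 13 paired values) and
correlated.  Spearman's ρ with average ranks is the primary statistic
because ω is bounded below by 0, heavily right-skewed and occasionally
extreme: a single shared outlier branch inflates Pearson's r while
leaving ranks almost untouched (a property the test suite reproduces
explicitly).  Branches where either member has ω ≥ 5 can be dropped
(large sampling variance); pairs need at least 6 shared branches, and
pairs with constant rank vectors are excluded and counted.  The mean ρ
over eligible true pairs is compared to the distribution of means from
1000 pseudo-pair datasets of the same size meeting the same
eligibility rules, one-sided for excess.  The clade-removal scan
deletes a clade's tip branches and internal stems (config-driven
mapping) and repeats the test with pair eligibility re-evaluated.

The shared-selection test is a per-branch 1-df χ² goodness-of-fit on
the concordant count: observed pairs with both members' ω above a
threshold versus `n·f₁·f₂` from the members' marginal exceedance
frequencies, one-sided for excess.  A 2×2 contingency χ² would have
been equally defensible; the concordant-count form was chosen because
it tests exactly "more shared cases than expected" and is recorded in
the output metadata.  Branches with fewer than 20 scorable pairs or an
expected concordant count below 5 are flagged as having too few
observations instead of receiving a p-value.

## Network weights

Edge weight for the constraint analysis is the absolute difference of
the two genes' whole-alignment ω, `e = |ωₙ − ωₘ|`, and the network
weight `w` is its mean over scorable edges.  The squared difference
would change only magnitudes, not conclusions; the weight function is
pluggable.  Edges missing ω on either end are excluded *before*
permutation so observed and null statistics share one edge set.  The
constraint test is one-sided for `w` smaller than the node-permutation
null (similar-constraint partners); the degree-difference test against
rewired networks reports both tails with its direction, since either
assortative or disassortative wiring is a meaningful finding.

## Gene sets and enrichment

Three sets connect dating and selection to function: genes in at least
one primate-specific pair (origin in the primate-stem or younger
classes); genes *all* of whose pairs are primate-specific; and genes
in at least one pair with some branch where both members' ω exceeds a
threshold (default 0.5).  Each is tested against its own explicit
complement — the universe is members ∪ complement for that contrast,
not the genome.  Term probabilities use the hypergeometric
distribution; the smaller tail is reported with its direction (over /
under) rather than a doubled two-sided p, and Bonferroni correction
across tested terms is on by default and recorded in the output.

## The synthetic-data generator

The generator emulates the statistical structure the analyses assume,
at desk scale; its defaults are the package's standing study
conditions and were fixed once:

* **Tree**: the 8-mammal topology with Ks lengths at the scale
  reported for placental mammals (human terminal ≈ 0.01 up to ≈ 0.3
  for the central separation).
* **Origins**: gene origin probabilities 0.95 / 0.015 / 0.015 / 0.01 /
  0.01 from root to human terminal — most mammalian genes are ancient,
  and with pair origin the younger of two genes this puts roughly 90%
  of pairs at the root before loss-induced misdating.
* **Loss**: each gene, once born, is lost along every off-lineage
  branch below its origin with probability `1 − exp(−λ·Ks)` (λ = 0.1
  per unit Ks by default); losses remove the branch's whole tip set.
  The human lineage is loss-protected because the real gene universe
  is conditioned on human genes.
* **Network**: zipf-distributed degrees (exponent 2.2, capped),
  realised exactly by Havel–Hakimi construction and randomised by
  degree-preserving swaps.  An age-coupled mode assigns the largest
  degrees to the oldest genes *and* wires stubs age-assortatively, the
  mechanism needed for ancient hubs to produce the degree-versus-age
  trend at the pair level; in this mode realised degrees may fall
  slightly short of the requested sequence where stub pairing would
  create self- or multi-edges.
* **Branch ω**: a latent Gaussian field — per-branch effects shared by
  every gene (sd 0.35; these give non-interacting pairs a nonzero
  baseline rank correlation, as real pseudo-pair datasets show) plus,
  for a planted subset of edges, a pair-shared factor with latent
  correlation ρ* (default 0.3 on half the pairable edges).  Flagged
  pairs form a vertex-disjoint matching so each shared factor belongs
  to exactly one pair; the requested fraction is capped by the
  matching.  The latent score is pushed through a fixed monotone
  quantile map onto the ω marginal — a lognormal bulk (log-mean
  log 0.2, log-sd 0.8) truncated below 1, plus spike masses of 4% on
  (1,5) and 1% on (5,9) to exercise the directional-selection
  thresholds and the ω < 5 filter — so rank correlations are exactly
  those of the latent field.  Per-gene branch coverage follows the
  gene's ortholog span (a human-only gene has no alignment and no ω).
* **Gene ω**: each gene mixes its latent constraint with the mean over
  its closed neighbourhood (strength s, default 0.4), then is affinely
  rescaled to the latent marginal's moments; s = 0 is
  topology-independent, s = 1 on a clique collapses the clique to one
  value.
* **Annotations**: a flat gene → term table with a 20-term vocabulary
  and Poisson(2) terms per gene.

What passing tests on these data show — and what they do not: the
generator plants independence, exchangeability and effect sizes by
construction, so calibration results (uniform p-values under the null)
validate the test machinery, not the biology; real interactomes add
ascertainment bias, correlated study effort, protein complexes and
expression-driven covariation of ω that the generator deliberately
omits.  Parameter-recovery results demonstrate that the estimators
measure what they claim under the stated model, with pair-level rates
derived from the per-gene loss rate by enumeration rather than assumed
equal to it.

## Numerical choices and degenerate inputs

* Unordered pairs are stored lexicographically smaller-first; the
  "first gene" of the 4/2/1/0 status coding refers to this canonical
  order.
* Spearman ties use average ranks; constant vectors make ρ undefined
  and exclude the pair (counted in the log).
* Rate estimates with zero exposure or zero branch Ks are errors, not
  zeros; zero events with positive exposure is a valid rate of 0.
* Pseudo-pair requests exceeding the available non-edges raise before
  sampling; with extra eligibility predicates feasibility cannot be
  pre-checked and exhaustion of the draw budget raises instead.
* Hypergeometric under-representation uses the lower tail directly
  (not doubled); the choice is flagged in the row's direction field.
* Batch correlation work groups pairs by shared-branch mask and ranks
  within groups, which is what keeps 1000-replicate permutation tests
  at interactive speed; the scalar path (`pair_correlation`) is the
  reference implementation and the suite asserts the two agree.

## Problem sizes

The packaged default study is 300–400 genes with ≈ 1.1 edges per gene
— about twenty-fold smaller than a whole-interactome study — with
1000-replicate co-evolution nulls, 10,000 weight permutations and
1,000 rewirings at analysis time.  Calibration experiments in the test
suite use 200 replicate datasets of ~100 pairs with 200-replicate
nulls, and parameter recovery uses 5,000 genes on a matching network
(so pairs are independent and binomial standard errors are exact).
These sizes were chosen so every statistic is estimated with
comfortable Monte-Carlo error while a full run remains a
few-minute desk computation.

## Known limitations

* The dating is an upper bound: gains between pre-existing orthologs
  are only corrected in aggregate, via the steady-state argument.
* The loss model scores annotation artifacts as losses, exactly as the
  orthology-based original data would.
* The linear steady-state correction can exceed the raw fraction's
  floor only by clipping at 0; strongly non-steady-state networks make
  it meaningless.
* Clade-removal p-values across rows of the scan are not independent
  (same network, same seed policy) and are meant for qualitative
  localisation of the signal, not joint inference.
* The generator's ω marginal is a stylised two-component form, not a
  fit to any empirical distribution; only its qualitative shape (bulk
  under purifying selection, rare large values) matters to the tests.
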