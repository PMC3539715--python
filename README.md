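# netpaleo

Evolutionary dating and selection analysis of protein–protein
interaction (PPI) networks from ortholog presence and selective
constraint.

## The problem

Physical interactions between proteins are catalogued almost
exclusively in a handful of model organisms, so the *history* of an
interactome cannot be read off interaction data from outgroups.  What
can be compared across genomes is the presence of the two interacting
genes' orthologs.  `netpaleo` implements a phylogenomic workflow that
uses ortholog presence across eight mammals (human, chimpanzee,
macaque, mouse, rat, horse, dog, cow) to place an upper bound on the
age of each human PPI, and then interrogates the selection acting on
the network through branch-wise and gene-wise selective constraint
(ω = Ka/Ks).  It is aimed at researchers in network evolution who have
an edge list, an ortholog presence matrix and codeml-style ω tables
(or want realistic synthetic versions of all three).

## The model and statistics

**Constrained-parsimony dating.**  Because the gene universe is
conditioned on human, orthology calling uses synteny (so a gene state
cannot arise twice), and an absent ortholog may be an annotation
artifact, ordinary parsimony is inappropriate.  Each gene is instead
assigned the *latest* branch on the root-to-human path consistent with
its ortholog distribution — the branch immediately ancestral to the
MRCA of the species carrying it — and each pair is dated to the
younger of its two gene origins, yielding a census over five
origin-eligible branch classes (root, euarchontoglires stem, primate
stem, human-chimp stem, human terminal).

**Ks-calibrated rates.**  Interaction loss is observable on internal
branches off the human lineage (mouse-rat and horse-dog stems):
`rate = events / exposed pairs / Ks`.  Gains are read off the origin
census the same way.  Under a steady-state network the two rates
should agree, and the gain rate converts the raw root-presence
fraction into a corrected estimate
`corrected = raw × (1 − Σᵢ g·Nᵢ·Ksᵢ / N)` over the lineage branches.

**Mirrortree co-evolution.**  For each pair, the branch-wise ω vectors
of the two genes are aligned on their shared branches and correlated
(Spearman ρ; branches with ω ≥ 5 can be dropped, at least 6 shared
branches required).  The mean ρ over true pairs is compared to 1000
pseudo-pair datasets of the same size drawn degree-proportionally from
non-interacting genes.  A clade-removal scan localises the signal and
a per-branch χ² test asks whether both members of a pair exceed an ω
threshold (1.0, 0.5) more often than the marginal exceedance
frequencies predict.

**Network weights.**  The average edge weight `w = Σ|ωₙ − ωₘ| / n_E`
measures whether interacting proteins share similar constraint, tested
against 10,000 node-weight permutations; the analogous degree
difference `Δk = |k₁ − k₂|` is tested against 1,000 degree-preserving
rewirings.  Hypergeometric term enrichment (Bonferroni-corrected) is
run on the primate-specific and shared-selection gene sets.

A fully parameterised synthetic-data generator produces internally
consistent studies (network, presence matrix, ω tables, annotations)
with every planted parameter recorded, so each analysis can be
closed-loop tested against ground truth.

## Worked example

```python
from netpaleo import SimulationConfig, simulate_dataset
from netpaleo.origins import origin_census, loss_rate, gain_rate, steady_state_correction
from netpaleo.coevolution import mean_rho_test
from netpaleo.network_stats import constraint_assortativity_test

ds = simulate_dataset(SimulationConfig(n_genes=400), seed=1)
census = origin_census(ds.network, ds.presence, ds.phylo)
print(f"{ds.network.n_nodes} genes, {ds.network.n_edges} interactions")
print(f"pairs present at the root: {100 * census.node_fraction('root'):.1f}%")

loss = loss_rate("mouse-rat", ds.network, ds.presence, ds.phylo)
gain = gain_rate("primates", census, ds.phylo)
corr = steady_state_correction(gain.rate, census, ds.phylo, loss=loss.rate)
print(f"loss rate (mouse-rat stem): {loss.rate:.3f} per PPI per unit Ks")
print(f"gain rate (primate stem):   {gain.rate:.3f} per PPI per unit Ks")
print(f"corrected root presence:    {100 * corr.corrected_root_fraction:.1f}%")

coev = mean_rho_test(ds.network, ds.branch_omega, n_null=1000, seed=2)
print(f"mean mirrortree Spearman rho: {coev.mean_rho:.3f} "
      f"(pseudo-pair mean of means {coev.mean_of_means:.3f}, p {coev.perm.p_label})")

w = constraint_assortativity_test(ds.network, ds.gene_omega, n_perm=10_000, seed=3)
print(f"mean |d-omega| across edges: {w.observed:.3f} "
      f"(permutation null {w.perm.null_mean:.3f}, p {w.perm.p_label})")
```

prints

```
400 genes, 451 interactions
pairs present at the root: 82.5%
loss rate (mouse-rat stem): 0.261 per PPI per unit Ks
gain rate (primate stem):   0.329 per PPI per unit Ks
corrected root presence:    72.3%
mean mirrortree Spearman rho: 0.188 (pseudo-pair mean of means 0.118, p <0.000999)
mean |d-omega| across edges: 0.182 (permutation null 0.235, p 0.0003)
```

Most pairs in this synthetic study date to the root of the tree; the
gain-corrected estimate discounts pairs whose orthologs predate the
interaction.  True pairs co-evolve in constraint above the pseudo-pair
baseline (which is nonzero because branch effects are shared by all
genes), and interacting proteins are under more similar constraint
than the permutation null — the same qualitative signatures the
analyses are designed to detect in real interactomes.

The same pipeline runs from the shell on files:

```sh
netpaleo simulate --seed 1 --out study/
netpaleo run-all --config config.yaml --seed 1 --out reports/
```

where `config.yaml` either points at input files (`inputs:` with
`network`, `presence`, `tree`, `roles`, `branch_omega`, `gene_omega`,
`annotations`) or requests a synthetic study (`simulate:` with
`SimulationConfig` fields).  Reports are plain TSV plus a JSON run
manifest with input digests and per-stage runtimes.

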