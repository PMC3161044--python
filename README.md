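# dpclust

Bayesian clustering of multilocus genotypes under a Dirichlet-process
prior: infer the number of populations **K** and the assignment of
individuals to populations *jointly* from diploid (or haploid) genotype
data, without fixing K in advance.

The package is aimed at population geneticists working with
microsatellite or SNP genotypes — assessing genetic diversity, detecting
cryptic structure, or screening for stratification — and in particular
at data sets with **unbalanced sample sizes** among populations, where
fixed-K STRUCTURE-style algorithms tend to equalise cluster sizes and
fail.

## The model

Individuals fall into an unknown number of populations, each defined by
its own allele-frequency vectors φ. A Dirichlet process with
concentration α and base measure G₀ (a symmetric Dirichlet(λ_l) on the
frequencies at locus *l*) induces a Chinese-restaurant-process prior
over partitions η = {S₁, …, S_K}:

* an individual joins existing cluster S_j with prior probability
  |S_j| / (i − 1 + α), or opens a new cluster with probability
  α / (i − 1 + α) — the "rich get richer" property that makes the prior
  robust to unbalanced sampling;
* the full partition prior is
  P(η) = α^K Γ(α)/Γ(α+n) ∏_j Γ(|S_j|);
* allele frequencies are integrated out analytically, leaving
  Dirichlet-multinomial predictive likelihoods driven by per-cluster
  allele-copy counts y_jlh (with a factor 2 per heterozygous genotype).

Posterior inference runs a Markov chain mixing full Gibbs scans with
**sequentially-allocated merge-split (SAMS)** moves — by default four
split-merge iterations per Gibbs scan — which move many individuals at
once and dramatically improve mixing when several populations are
present. The hyperparameter λ may be fixed, inferred as a single shared
value, or inferred per locus (uniform prior on (0, 10],
Metropolis-Hastings updates); λ controls how uniform the prior expects
allele frequencies to be, and its choice materially changes the
inferred partition on skewed-frequency data.

Posterior partition samples are summarised by the **mean partition**
(the partition minimising the summed partition distance to all samples,
computed via the Hungarian algorithm on cluster-overlap matrices) and
by the **co-assignment matrix** with a complete-linkage dendrogram.

Also included:

* fixed-K baseline samplers — FUM (uncorrelated flat-Dirichlet allele
  frequencies) and FCM (frequencies correlated through ancestral
  frequencies and per-population drift parameters F_j), with the
  admixture-style warm-up used to keep clusters populated;
* genotype simulators — a correlated-frequency generator
  (Dirichlet(Pa·(1−F)/F) population frequencies around ancestral Pa)
  and a finite-island Wright–Fisher model with K-allele mutation;
* Weir–Cockerham F_ST, observed heterozygosity, and (size-weighted)
  partition-distance scoring.

## Worked example

```python
import dpclust as dc

# two populations of 25, 30 microsatellite loci, ancestral
# frequencies {0.2 x 5}, drift F = 0.05
table, truth = dc.simulate_correlated(dc.microsat_scenario("uniform", 30), seed=11)

est = dc.DirichletProcessClustering(expected_k=2, lam=1.0,
                                    iterations=20_000, random_state=0).fit(table)
print("posterior mean K:", round(est.mean_k_, 2))
print("mean partition clusters:", est.n_clusters_)
print("distance to truth:",
      dc.partition_distance(truth, est.labels_, normalized=True))
print(est.posterior_k_.round(3).to_string())
```

prints

```
posterior mean K: 2.36
mean partition clusters: 2
distance to truth: 0.0
2    0.679
3    0.289
4    0.029
5    0.003
```

The prior expected K was set to 2 (solving α from
E[K] = Σᵢ α/(α+i−1)); the chain's posterior concentrates on K = 2 with
some mass on small extra clusters, and the mean partition recovers the
planted structure exactly (normalised partition distance 0 to the
truth). `est.coassignment_matrix()` gives pairwise co-assignment
probabilities, and `dpclust.coassignment_dendrogram` renders them as a
Newick tree.

The same estimator API covers the baselines, e.g.
`FixedKClustering(n_clusters=2, model="correlated")` for the
drift-model sampler, and everything is scriptable from the shell:

```bash
dpclust simulate correlated -o sim --marker microsat --scenario uniform --seed 3
dpclust dp sim/genotypes.txt -o run --expected-k 2 --lam 1.0 --seed 1
dpclust summarize run --truth sim/truth.tsv
```

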