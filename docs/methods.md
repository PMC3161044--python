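# Methods

## Model

A sample of n individuals genotyped at L unlinked loci is modelled as a
Dirichlet-process mixture over populations. Writing η = {S₁,…,S_K} for
a partition of the individuals and φ_jl for the allele-frequency vector
of population j at locus l:

* **Partition prior (CRP).** The DP with concentration α > 0 induces
  sequential assignment probabilities |S_j|/(i−1+α) for existing
  clusters and α/(i−1+α) for a new one; multiplying them over any
  insertion order gives P(η) = α^K Γ(α)/Γ(α+n) ∏_j Γ(|S_j|). The prior
  expected K is Σ_{i=1..n} α/(α+i−1); `alpha_for_expected_k` inverts
  this numerically so users can parameterise by prior mean K instead of
  α. α is held fixed during inference.
* **Likelihood with frequencies integrated out.** G₀ is a symmetric
  Dirichlet(λ_l) at each locus. Conditional on cluster allele-copy
  counts y_jl· (total y_jl), the two copies h₁,h₂ of a genotype have
  predictive probability
  2^δ (y_jlh₁+λ_l)(y_jlh₂+λ_l+[h₁=h₂]) / (d(d+1)), d = y_jl + J_l λ_l,
  with δ = 1 for heterozygotes. A single observed copy contributes
  (y_jlh+λ_l)/d; a fully missing locus contributes 1. The set marginal
  is the standard Dirichlet-multinomial closed form and is exchangeable;
  the implementation carries all of this in log space through log-gamma
  (J_l up to ~40 and counts in the hundreds would overflow otherwise).
* **Missing data.** Missing allele copies contribute nothing to counts
  or likelihoods; normalisation over the observed data is preserved.
  Haploid data degenerate to the single-copy predictive throughout.

## Samplers

* **Gibbs scan.** Each individual is removed (its cluster deleted if
  emptied) and reassigned with weight |S_j|·predictive for existing
  clusters and α·predictive for a new one, in index order; sufficient
  statistics are updated incrementally and cross-checked against full
  recounts in the tests.
* **SAMS merge-split.** Two distinct individuals are drawn uniformly.
  If they share a cluster, the cluster is split: the two seeds become
  singletons and the remaining members are allocated sequentially, in a
  uniformly random order, to one side or the other with probability
  proportional to (current side size) × (predictive under the side's
  accumulated counts); the product of these probabilities is the
  proposal density q(η′|η), and the reverse merge is deterministic.
  If they sit in different clusters, the merge is proposed (q = 1) and
  q(η|η′) is obtained by replaying the reverse split towards the two
  original subsets in a random order. Acceptance is Metropolis-Hastings
  with the CRP prior ratio (e.g. α Γ(|S_i|)Γ(|S_j|)/Γ(|S|) for a split)
  and the marginal-likelihood ratio; the 2^δ heterozygote factors cancel
  in every ratio and are omitted there. Acceptance rates are low
  (order 10⁻²–10⁻³), as expected for this move type; the value of the
  move is the occasional large jump, which Gibbs scans alone essentially
  never make (see the mixing test: on four-population data the combined
  chain reaches the true K within tens of iterations, Gibbs-only not
  within hundreds).
* **Schedule.** Four SAMS iterations followed by one Gibbs scan, then
  repeat; the ratio is configurable (alternatives behave similarly).
  One "iteration" is one SAMS attempt or one full Gibbs scan. Default
  chain: 20,000 iterations, first half burn-in, thinning 10.
* **λ updates.** With `lambda_mode="unique"` each λ_l gets one MH
  update per iteration (normal proposal, s.d. δ = 0.02 by default);
  with `"single"` one shared λ is updated against the all-locus
  likelihood. The prior is uniform on (0, 10]; out-of-support proposals
  are rejected outright. λ is also updated during burn-in, and the
  update runs after the partition move within an iteration — both
  choices are this package's (they are a matter of schedule, not of the
  stationary distribution).
* **Initialisation.** All individuals in one cluster by default (a
  random CRP draw is available). With informative data and the
  merge-split moves the chain leaves the single-cluster state quickly.

### Fixed-K baselines

FUM resamples labels with equal prior weight 1/K given per-cluster
frequencies, then frequencies from Dirichlet(y+1) (flat prior). FCM
draws frequencies from Dirichlet(y + Pa·f_j), f_j = (1−F_j)/F_j, and
updates the ancestral frequencies Pa by a per-locus Dirichlet
neighbourhood MH proposal (concentration 200, flat Dirichlet prior) and
each drift parameter F_j by a logit-scale random walk (s.d. 0.3,
uniform prior on (0,1)) with the appropriate Jacobian. During the first
half of burn-in both models run an admixture-style warm-up: flat
per-individual mixture weights are drawn each sweep and every allele
copy is assigned to a cluster independently, which keeps all K clusters
populated early; the weights are discarded at the switch. Sampled
labelings are aligned to a running reference by maximum shared
membership (Hungarian) before assignment probabilities are averaged, so
label switching cannot blur them; the reported partition assigns each
individual to its highest-probability cluster.

## Partition summaries

The partition distance d(η,u) is the minimum number of individuals to
remove from both partitions so they coincide, computed as n minus the
maximum-overlap cluster matching (assignment problem on the K₁×K₂
overlap matrix, solved by `scipy.optimize.linear_sum_assignment`), and
normalised by n when reported. The size-weighted variant gives each
individual a positive weight — by default max true-cluster size over
its own true-cluster size, so every true population carries equal total
weight (e.g. weight 30 per small-subset individual for sizes 10/300) —
and minimises removed weight; with uniform weights it reduces exactly
to the plain normalised distance.

The mean partition minimises D = Σ_i d(η_i, u) over the posterior
sample. Search is greedy coordinate descent: start from the stored
sample with smallest D, sweep individuals in index order, try every
existing cluster and a new singleton, keep strict improvements only
(ties rejected, guaranteeing termination), and stop when a full sweep
makes no progress. Sweep order and the strict-improvement tie policy
are this package's choices. Duplicate sampled partitions are collapsed
with multiplicities first; inside the search, overlap matchings are
solved exactly by bitmask dynamic programming over the smaller side
when both partitions have ≤ 10 clusters (the compiled fast path) and by
the Hungarian algorithm otherwise — the two routes are cross-checked in
the tests, and the greedy result is checked against exhaustive search
over all partitions on small instances (it attains the optimum in
≥ 95% of random trials).

Co-assignment probabilities are averaged over sampled partitions;
complete-linkage clustering on 1 − co-assignment gives a dendrogram,
emitted as Newick. The posterior of K is tabulated from the samples.

## Simulators

* **Correlated-frequency populations.** Population frequencies are
  drawn from Dirichlet(Pa·(1−F)/F) around ancestral frequencies Pa with
  drift F (mean Pa, variance Pa(1−Pa)F — verified against the analytic
  moments in tests); genotypes are two independent allele draws
  (random mating); loci monomorphic in the realised sample are dropped.
  Preset scenarios: microsatellites (J=5, F=0.05) with ancestral
  frequencies {0.2×5} ("uniform") or {0.8, 0.05×4} ("skewed"), SNPs
  (J=2, F=0.07) with {0.5,0.5} or {0.8,0.2}, plus mixed designs; two
  populations of 25 by default.
* **Island model.** d=8 demes of N=1000 diploids; each generation, deme
  frequencies receive a fraction m of the average of the other demes,
  mutate at rate μ to a uniformly chosen state among A possible states
  (K-allele model), and are resampled as 2N multinomial allele copies.
  Defaults follow the microsatellite scenario (50 loci, A=10, μ=5e-4,
  m=0.003, 20,000 generations; the SNP preset uses 100 loci, A=2,
  μ=5e-7, m=0.002, 5,000 generations). The first generation assigns
  allele copies uniformly over the states. The model is simulated at
  allele-frequency resolution rather than as individual pedigrees: for
  unlinked loci under random mating the two are distributionally
  equivalent for every statistic used here, and it makes 20,000
  generations a matter of seconds. Genotype samples are drawn from the
  final deme frequencies as two independent copies per locus, with
  truth labels given by the source demes.
* **Calibration.** At m=0.003 the microsatellite scenario yields mean
  pairwise Weir–Cockerham θ ≈ 0.061–0.063 and observed heterozygosity
  ≈ 0.80, the calibration this design is built around (verified by the
  acceptance script); θ is
  computed from 100 sampled individuals per deme (the sample size is
  this package's choice). F_ST decreases monotonically in m across
  {0.001, 0.003, 0.005}.
* **What the generators do not emulate.** Real data features such as
  genotyping error, null alleles, departures from Hardy–Weinberg within
  populations, linkage, admixed individuals, and family structure are
  absent; passing tests demonstrate correctness of the inference
  machinery under the stated models, not robustness to those
  violations.

* **F_ST estimator.** Weir–Cockerham (1984) θ from per-allele variance
  components, summed over alleles and loci before the ratio; small
  numerical differences from other estimators are expected.

## Numerical choices

All probability arithmetic is in log space; categorical draws use the
max-shifted softmax (kernels) or the Gumbel-argmax trick (vectorised
fixed-K code). Cluster slots are kept dense with swap-deletion when a
cluster empties; proposal clusters live in zeroed scratch slots so a
rejected move costs nothing to undo. Frequencies are clipped at 1e-300
before logs in the fixed-K code, and FCM Dirichlet shape parameters are
floored at 1e-6 to keep degenerate draws finite. One seed drives
everything: a `SeedSequence` splits into the initialisation RNG and the
compiled kernels' RNG, making every run bit-reproducible from its seed.

## Problem sizes used by `scripts/acceptance.py`

Chosen as desk-scale versions of the full experimental designs:
prior-of-K Monte Carlo with 100,000 draws; the λ experiment with 10
replicate skewed-scenario data sets (2×25 individuals, 100 loci) and
10,000-iteration chains; 3 island base populations at 20,000
generations; 10 two-deme 25+25 replicates at 10,000 iterations; the
N(10,300) comparison with 16 replicates (20 loci; DP chains 20,000
iterations, FCM 20,000 sweeps). The replicate-level behaviour matches
the full-scale characterisation: e.g. under λ = 1/J a few percent of
skewed-scenario replicates genuinely favour K = 1 (the full design
reports 96/100 successes), so small-replicate means fluctuate
accordingly.

## Known limitations

* The mean-partition search is a local optimiser; on diffuse posteriors
  it can return a local minimum (rare in practice, quantified above).
* The admixture warm-up in the fixed-K samplers is a documented
  stand-in for the analogous behaviour of the reference fixed-K
  programs; what is asserted of it is its effect (no empty clusters),
  not byte-level equivalence.
* α is fixed; only λ is inferred. Admixture proportions are not
  modelled (the goal is assignment, not ancestry decomposition).
* The SNP island preset starts from uniform 50/50 frequencies, so its
  5,000-generation output is mildly initialisation-dependent, as in the
  design it mirrors.
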