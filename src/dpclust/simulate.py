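"""Genotype simulators and differentiation statistics.

Two generators cover the study designs used throughout the package:

* a correlated-frequency simulator — per-population allele frequencies
  drawn from Dirichlet(Pa * (1-F)/F) around ancestral frequencies Pa
  with drift parameter F, genotypes by random mating (two independent
  allele draws), monomorphic loci dropped;
* a finite-island Wright-Fisher simulator — d demes of N diploids, KAM
  mutation (a mutant moves to any of A states with equal probability),
  symmetric migration at rate m, evolved at allele-frequency resolution
  (distributionally equivalent to individual-based simulation for
  unlinked loci under random mating) and sampled into genotype tables.

Differentiation is measured by the Weir-Cockerham (1984) theta
estimator from allele-frequency variance components.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genotypes import MISSING, GenotypeTable, observed_heterozygosity
from .partition import canonical_labels


# ---------------------------------------------------------------------------
# Correlated-frequency populations
# ---------------------------------------------------------------------------

@dataclass
class CorrelatedSimConfig:
    """Blocks of loci sharing ancestral frequencies; e.g. the mixed
    design uses one near-uniform and one skewed block."""

    blocks: list[tuple[np.ndarray, int]]  # (ancestral frequencies, n_loci)
    drift: float = 0.05
    n_populations: int = 2
    n_per_population: int = 25

    def __post_init__(self):
        if not 0.0 < self.drift < 1.0:
            raise ValueError("drift F must lie in (0, 1)")
        blocks = []
        for pa, nl in self.blocks:
            pa = np.asarray(pa, dtype=float)
            if np.any(pa <= 0) or abs(pa.sum() - 1.0) > 1e-9:
                raise ValueError("ancestral frequencies must be positive and sum to 1")
            if nl < 1:
                raise ValueError("each block needs at least one locus")
            blocks.append((pa, int(nl)))
        self.blocks = blocks


def microsat_scenario(kind: str, n_loci=None) -> CorrelatedSimConfig:
    """Preset microsatellite scenarios (5 ancestral alleles, F=0.05):
    'uniform' {0.2 x 5} over 30 loci, 'skewed' {0.8, 0.05 x 4} over 100
    loci, 'mixed' 30 + 30 loci."""
    uni = np.full(5, 0.2)
    skew = np.array([0.8, 0.05, 0.05, 0.05, 0.05])
    if kind == "uniform":
        return CorrelatedSimConfig([(uni, n_loci or 30)], 0.05)
    if kind == "skewed":
        return CorrelatedSimConfig([(skew, n_loci or 100)], 0.05)
    if kind == "mixed":
        return CorrelatedSimConfig([(uni, n_loci or 30), (skew, n_loci or 30)], 0.05)
    raise ValueError("kind must be 'uniform', 'skewed' or 'mixed'")


def snp_scenario(kind: str, n_loci=None) -> CorrelatedSimConfig:
    """Preset SNP scenarios (F=0.07): 'uniform' {0.5,0.5} x 50,
    'skewed' {0.8,0.2} x 200, 'mixed' 50 + 50."""
    uni = np.array([0.5, 0.5])
    skew = np.array([0.8, 0.2])
    if kind == "uniform":
        return CorrelatedSimConfig([(uni, n_loci or 50)], 0.07)
    if kind == "skewed":
        return CorrelatedSimConfig([(skew, n_loci or 200)], 0.07)
    if kind == "mixed":
        return CorrelatedSimConfig([(uni, n_loci or 50), (skew, n_loci or 50)], 0.07)
    raise ValueError("kind must be 'uniform', 'skewed' or 'mixed'")


def population_frequencies(config: CorrelatedSimConfig, rng) -> list[np.ndarray]:
    """Per-population, per-locus frequencies ~ Dirichlet(Pa (1-F)/F)."""
    f = (1.0 - config.drift) / config.drift
    out = []
    for pa, nl in config.blocks:
        draws = rng.dirichlet(pa * f, size=(config.n_populations, nl))
        out.append(draws)  # (K, nl, J)
    return out


def simulate_correlated(config: CorrelatedSimConfig, seed=None):
    """Generate a genotype table plus true labels from the correlated
    model; loci at which only one allele was observed are excluded."""
    rng = np.random.default_rng(seed)
    freqs = population_frequencies(config, rng)
    npp = config.n_per_population
    K = config.n_populations
    labels = np.repeat(np.arange(K), npp)
    cols = []
    for block, (pa, nl) in zip(freqs, config.blocks):
        J = len(pa)
        for l in range(nl):
            geno = np.empty((K * npp, 2), dtype=np.int64)
            for k in range(K):
                sl = slice(k * npp, (k + 1) * npp)
                geno[sl] = rng.choice(J, size=(npp, 2), p=block[k, l])
            cols.append(geno)
    alleles = np.stack(cols, axis=1)  # (n, L, 2)
    # drop monomorphic loci and recode observed alleles densely
    keep = []
    for l in range(alleles.shape[1]):
        obs = np.unique(alleles[:, l])
        if obs.size > 1:
            recode = -np.ones(int(obs.max()) + 1, dtype=np.int64)
            recode[obs] = np.arange(obs.size)
            alleles[:, l] = recode[alleles[:, l]]
            keep.append(l)
    if not keep:
        raise ValueError("all loci monomorphic; increase loci or drift")
    table = GenotypeTable(alleles[:, keep])
    return table, labels


# ---------------------------------------------------------------------------
# Island-model Wright-Fisher populations
# ---------------------------------------------------------------------------

@dataclass
class IslandSimConfig:
    """Finite-island scenario; defaults follow the microsatellite
    setting (8 demes of 1000, 50 loci, 10 allelic states, mutation
    5e-4, migration 0.003, 20,000 generations)."""

    n_demes: int = 8
    deme_size: int = 1000
    n_loci: int = 50
    n_alleles: int = 10
    mutation_rate: float = 5e-4
    migration_rate: float = 0.003
    generations: int = 20_000

    def __post_init__(self):
        if min(self.n_demes, self.deme_size, self.n_loci, self.n_alleles,
               self.generations) < 1:
            raise ValueError("island config values must be positive")
        if not 0.0 <= self.migration_rate <= 1.0:
            raise ValueError("migration rate must lie in [0, 1]")
        if not 0.0 <= self.mutation_rate <= 1.0:
            raise ValueError("mutation rate must lie in [0, 1]")


def snp_island_config() -> IslandSimConfig:
    """The SNP island scenario: 100 biallelic loci, mutation 5e-7,
    migration 0.002, 5,000 generations."""
    return IslandSimConfig(n_loci=100, n_alleles=2, mutation_rate=5e-7,
                           migration_rate=0.002, generations=5_000)


class IslandModel:
    """Wright-Fisher island model evolved at allele-frequency resolution.

    Each generation: deme frequencies are mixed with the average of the
    other demes at rate m, pushed towards uniform by KAM mutation at
    rate mu, and resampled as 2N multinomial allele copies.  The first
    generation assigns the 2N copies uniformly over the allelic states.
    """

    def __init__(self, config: IslandSimConfig):
        self.config = config

    def run(self, seed=None) -> np.ndarray:
        """Evolve the base populations; returns deme allele frequencies
        of shape (n_demes, n_loci, n_alleles)."""
        cfg = self.config
        rng = np.random.default_rng(seed)
        d, L, A = cfg.n_demes, cfg.n_loci, cfg.n_alleles
        two_n = 2 * cfg.deme_size
        counts = rng.multinomial(two_n, np.full(A, 1.0 / A), size=(d, L))
        p = counts / two_n
        m, mu = cfg.migration_rate, cfg.mutation_rate
        for _ in range(cfg.generations):
            if d > 1 and m > 0:
                others = (p.sum(axis=0, keepdims=True) - p) / (d - 1)
                p = (1.0 - m) * p + m * others
            if mu > 0:
                p = (1.0 - mu) * p + mu / A
            counts = rng.multinomial(two_n, p)
            p = counts / two_n
        return p

    def draw_sample(self, frequencies, sizes, demes=None, loci=None, seed=None):
        """Draw diploid genotypes (two independent allele copies per
        locus) from final deme frequencies.

        ``sizes`` gives the number of individuals per sampled deme;
        ``demes`` selects which demes (default: random distinct demes);
        ``loci`` selects a subset of loci (default: all).  Returns
        ``(GenotypeTable, true labels)``; truth labels index the sampled
        demes in order.
        """
        rng = np.random.default_rng(seed)
        freqs = np.asarray(frequencies)
        d, L, A = freqs.shape
        sizes = list(sizes)
        if demes is None:
            demes = rng.choice(d, size=len(sizes), replace=False)
        demes = np.asarray(demes)
        loci = np.arange(L) if loci is None else np.asarray(loci)
        n = sum(sizes)
        alleles = np.empty((n, len(loci), 2), dtype=np.int64)
        labels = np.empty(n, dtype=np.int64)
        row = 0
        for k, (deme, sz) in enumerate(zip(demes, sizes)):
            for l_out, l in enumerate(loci):
                p = freqs[deme, l]
                alleles[row:row + sz, l_out] = rng.choice(A, size=(sz, 2), p=p)
            labels[row:row + sz] = k
            row += sz
        # dense recode per locus; drop loci monomorphic in the sample
        keep = []
        for l in range(len(loci)):
            obs = np.unique(alleles[:, l])
            if obs.size > 1:
                recode = -np.ones(int(obs.max()) + 1, dtype=np.int64)
                recode[obs] = np.arange(obs.size)
                alleles[:, l] = recode[alleles[:, l]]
                keep.append(l)
        if not keep:
            raise ValueError("sample is monomorphic at every locus")
        return GenotypeTable(alleles[:, keep]), labels


def simulate_island(config: IslandSimConfig, seed=None) -> np.ndarray:
    """Convenience wrapper: evolve an island-model base population and
    return the final deme allele frequencies."""
    return IslandModel(config).run(seed)


# ---------------------------------------------------------------------------
# Differentiation statistics
# ---------------------------------------------------------------------------

def _wc_components(a1, a2, labels):
    """Weir-Cockerham (1984) variance components summed over loci and
    alleles for one set of populations.  Returns (a, a+b+c)."""
    pops = np.unique(labels)
    r = pops.size
    num = 0.0
    den = 0.0
    L = a1.shape[1]
    for l in range(L):
        g1, g2 = a1[:, l], a2[:, l]
        ok = (g1 != MISSING) & (g2 != MISSING)
        if not ok.any():
            continue
        alleles = np.unique(np.concatenate([g1[ok], g2[ok]]))
        if alleles.size < 2:
            continue
        n_i = np.array([np.sum(ok & (labels == p)) for p in pops], dtype=float)
        if np.any(n_i < 1):
            continue
        n_bar = n_i.mean()
        n_c = (r * n_bar - (n_i ** 2).sum() / (r * n_bar)) / (r - 1)
        for h in alleles:
            p_i = np.empty(r)
            h_i = np.empty(r)
            for k, p in enumerate(pops):
                sel = ok & (labels == p)
                c1, c2 = g1[sel] == h, g2[sel] == h
                p_i[k] = (c1.sum() + c2.sum()) / (2 * sel.sum())
                h_i[k] = np.mean(c1 ^ c2)
            p_bar = (n_i * p_i).sum() / (r * n_bar)
            s2 = (n_i * (p_i - p_bar) ** 2).sum() / ((r - 1) * n_bar)
            h_bar = (n_i * h_i).sum() / (r * n_bar)
            a = (n_bar / n_c) * (
                s2 - (p_bar * (1 - p_bar) - (r - 1) / r * s2 - h_bar / 4) / (n_bar - 1)
            )
            b = (n_bar / (n_bar - 1)) * (
                p_bar * (1 - p_bar) - (r - 1) / r * s2
                - (2 * n_bar - 1) / (4 * n_bar) * h_bar
            )
            c = h_bar / 2
            num += a
            den += a + b + c
    return num, den


def wc_theta(table_or_arrays, labels) -> float:
    """Multi-locus Weir-Cockerham theta over all populations at once."""
    a1, a2 = _as_arrays(table_or_arrays)
    labels = np.asarray(labels)
    if np.unique(labels).size < 2:
        raise ValueError("theta requires at least two populations")
    num, den = _wc_components(a1, a2, labels)
    return num / den if den != 0 else 0.0


def pairwise_fst(table_or_arrays, labels) -> np.ndarray:
    """K x K matrix of pairwise Weir-Cockerham theta values."""
    a1, a2 = _as_arrays(table_or_arrays)
    labels = canonical_labels(labels)
    K = int(labels.max()) + 1
    if K < 2:
        raise ValueError("pairwise Fst requires at least two populations")
    sizes = np.bincount(labels)
    if np.any(sizes < 2):
        raise ValueError("each population needs at least two individuals")
    out = np.zeros((K, K))
    for i in range(K):
        for j in range(i + 1, K):
            sel = (labels == i) | (labels == j)
            num, den = _wc_components(a1[sel], a2[sel], labels[sel])
            out[i, j] = out[j, i] = num / den if den != 0 else 0.0
    return out


def _as_arrays(table_or_arrays):
    if isinstance(table_or_arrays, GenotypeTable):
        return table_or_arrays.allele_arrays()
    a1, a2 = table_or_arrays
    return np.asarray(a1), np.asarray(a2)


__all__ = [
    "CorrelatedSimConfig", "IslandSimConfig", "IslandModel",
    "microsat_scenario", "snp_scenario", "snp_island_config",
    "simulate_correlated", "simulate_island", "population_frequencies",
    "wc_theta", "pairwise_fst", "observed_heterozygosity",
]
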