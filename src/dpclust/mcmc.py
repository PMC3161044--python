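"""Markov-chain driver for the Dirichlet-process genotype mixture.

The chain alternates sequentially-allocated merge-split (SAMS) moves
with full Gibbs scans — by default four SAMS iterations followed by one
Gibbs scan — and, when the allele-frequency hyperparameter lambda is
treated as a variable, one Metropolis-Hastings lambda update per
iteration after the partition move.  Sampled partitions are recorded in
canonical form at thinned iterations after burn-in.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _kernels
from .genotypes import GenotypeTable
from .partition import canonical_labels

LAMBDA_PRIOR_UPPER = 10.0


def _resolve_lambda(lam, J) -> np.ndarray:
    """Accept a scalar, a per-locus vector, or the string '1/J'."""
    L = len(J)
    if isinstance(lam, str):
        if lam in ("1/J", "1/j"):
            return 1.0 / np.asarray(J, dtype=float)
        raise ValueError(f"unknown lambda spec {lam!r}")
    lam = np.asarray(lam, dtype=float)
    out = np.full(L, float(lam)) if lam.ndim == 0 else lam.astype(float).copy()
    if out.shape != (L,):
        raise ValueError("lambda must be scalar, '1/J', or one value per locus")
    if np.any(out <= 0) or np.any(out > LAMBDA_PRIOR_UPPER):
        raise ValueError(f"lambda must lie in (0, {LAMBDA_PRIOR_UPPER}]")
    return out


@dataclass
class SamplerState:
    """Mutable chain state: genotype arrays, partition, sufficient
    statistics and hyperparameters.  Cluster slots beyond K are all-zero
    scratch used by proposal moves."""

    a1: np.ndarray
    a2: np.ndarray
    J: np.ndarray
    lam: np.ndarray
    alpha: float
    labels: np.ndarray
    sizes: np.ndarray
    y: np.ndarray
    ytot: np.ndarray
    K: int
    lambda_mode: str = "fixed"  # fixed | single | unique
    delta: float = 0.02
    lambda_upper: float = LAMBDA_PRIOR_UPPER
    accept: dict = field(default_factory=lambda: {
        "split_prop": 0, "split_acc": 0, "merge_prop": 0, "merge_acc": 0,
        "lambda_prop": 0, "lambda_acc": 0,
    })

    @classmethod
    def from_arrays(cls, a1, a2, J, *, alpha, lam=1.0, lambda_mode="fixed",
                    delta=0.02, init="single", rng=None) -> "SamplerState":
        if alpha <= 0:
            raise ValueError("alpha must be > 0")
        if delta <= 0:
            raise ValueError("delta must be > 0")
        if lambda_mode not in ("fixed", "single", "unique"):
            raise ValueError("lambda_mode must be fixed, single or unique")
        rng = np.random.default_rng(rng)
        a1 = np.ascontiguousarray(a1, dtype=np.int64)
        a2 = np.ascontiguousarray(a2, dtype=np.int64)
        n, L = a1.shape
        J = np.ascontiguousarray(J, dtype=np.int64)
        lam_vec = _resolve_lambda(lam, J)
        if lambda_mode == "single" and not np.allclose(lam_vec, lam_vec[0]):
            raise ValueError("single lambda mode requires a shared initial value")
        kcap = n + 2
        if isinstance(init, str):
            if init == "single":
                labels = np.zeros(n, dtype=np.int64)
            elif init == "crp":
                labels = _crp_draw(n, alpha, rng)
            else:
                raise ValueError("init must be 'single', 'crp' or a label vector")
        else:
            labels = canonical_labels(init)
        K = int(labels.max()) + 1
        y = np.zeros((kcap, L, int(J.max())), dtype=np.int64)
        ytot = np.zeros((kcap, L), dtype=np.int64)
        sizes = np.zeros(kcap, dtype=np.int64)
        state = cls(a1, a2, J, lam_vec, float(alpha), labels, sizes, y, ytot, K,
                    lambda_mode, float(delta))
        state._recount()
        return state

    @classmethod
    def from_table(cls, table: GenotypeTable, **kwargs) -> "SamplerState":
        a1, a2 = table.allele_arrays()
        return cls.from_arrays(a1, a2, table.n_alleles, **kwargs)

    # -- bookkeeping -----------------------------------------------------
    def _recount(self) -> None:
        self.y[:] = 0
        self.ytot[:] = 0
        self.sizes[:] = 0
        for i in range(self.a1.shape[0]):
            _kernels._move_counts(i, self.labels[i], 1, self.a1, self.a2,
                                  self.y, self.ytot, self.sizes)

    def consistent(self) -> bool:
        """Full recount check: incremental statistics match the partition."""
        y, ytot, sizes = self.y.copy(), self.ytot.copy(), self.sizes.copy()
        self._recount()
        ok = (np.array_equal(y, self.y) and np.array_equal(ytot, self.ytot)
              and np.array_equal(sizes, self.sizes))
        self.y, self.ytot, self.sizes = y, ytot, sizes
        return ok

    # -- moves -----------------------------------------------------------
    def gibbs_scan(self) -> None:
        self.K = _kernels.gibbs_scan(self.a1, self.a2, self.J, self.lam, self.alpha,
                                     self.labels, self.sizes, self.y, self.ytot, self.K)

    def sams_move(self) -> tuple[str, bool]:
        self.K, kind, acc = _kernels.sams_move(
            self.a1, self.a2, self.J, self.lam, self.alpha,
            self.labels, self.sizes, self.y, self.ytot, self.K)
        name = "split" if kind == 0 else "merge"
        self.accept[f"{name}_prop"] += 1
        self.accept[f"{name}_acc"] += int(acc)
        return name, bool(acc)

    def lambda_update(self) -> None:
        if self.lambda_mode == "fixed":
            return
        if self.lambda_mode == "unique":
            acc = _kernels.lambda_update_unique(self.J, self.lam, self.delta,
                                                self.lambda_upper, self.y, self.ytot, self.K)
            self.accept["lambda_prop"] += len(self.J)
        else:
            acc = _kernels.lambda_update_single(self.J, self.lam, self.delta,
                                                self.lambda_upper, self.y, self.ytot, self.K)
            self.accept["lambda_prop"] += 1
        self.accept["lambda_acc"] += int(acc)


def _crp_draw(n: int, alpha: float, rng) -> np.ndarray:
    labels = np.zeros(n, dtype=np.int64)
    sizes = [1]
    for i in range(1, n):
        w = np.array(sizes + [alpha], dtype=float)
        j = rng.choice(len(w), p=w / w.sum())
        if j == len(sizes):
            sizes.append(1)
        else:
            sizes[j] += 1
        labels[i] = j
    return labels


@dataclass
class MCMCTrace:
    """Thinned posterior sample of partitions (canonical label vectors),
    lambda draws when inferred, and acceptance tallies."""

    partitions: np.ndarray          # (samples, n) int64
    k: np.ndarray                   # (samples,)
    lambdas: np.ndarray | None      # (samples, L) or None
    iterations: int
    burn_in: int
    thin: int
    acceptance: dict

    @property
    def n_samples(self) -> int:
        return self.partitions.shape[0]

    def to_frame(self) -> pd.DataFrame:
        it = self.burn_in + self.thin * (1 + np.arange(self.n_samples))
        df = pd.DataFrame({
            "iteration": it,
            "k": self.k,
            "partition": [" ".join(map(str, row)) for row in self.partitions],
        })
        if self.lambdas is not None:
            df["lambda"] = [" ".join(f"{v:.6g}" for v in row) for row in self.lambdas]
        return df


def run_mcmc(
    table,
    *,
    alpha: float,
    lam=1.0,
    lambda_mode: str = "fixed",
    iterations: int = 20_000,
    burn_in: int | None = None,
    thin: int = 10,
    sams_per_cycle: int = 4,
    gibbs_per_cycle: int = 1,
    delta: float = 0.02,
    init="single",
    seed=None,
) -> MCMCTrace:
    """Run the DP-mixture partition sampler on a genotype table.

    ``table`` may be a :class:`GenotypeTable` or a tuple ``(a1, a2, J)``.
    ``burn_in`` defaults to half the iterations.  Reproducible from
    ``seed``: one seed sequence drives initialisation and the compiled
    kernels.
    """
    if burn_in is None:
        burn_in = iterations // 2
    if burn_in >= iterations:
        raise ValueError("burn_in must be smaller than iterations")
    if thin < 1 or sams_per_cycle < 0 or gibbs_per_cycle < 1:
        raise ValueError("bad schedule configuration")
    ss = np.random.SeedSequence(seed)
    init_seed, kern_seed = ss.spawn(2)
    rng = np.random.default_rng(init_seed)
    _kernels.seed_kernels(int(kern_seed.generate_state(1, np.uint32)[0] % (2**31)))

    if isinstance(table, GenotypeTable):
        state = SamplerState.from_table(table, alpha=alpha, lam=lam,
                                        lambda_mode=lambda_mode, delta=delta,
                                        init=init, rng=rng)
    else:
        a1, a2, J = table
        state = SamplerState.from_arrays(a1, a2, J, alpha=alpha, lam=lam,
                                         lambda_mode=lambda_mode, delta=delta,
                                         init=init, rng=rng)

    n = state.a1.shape[0]
    cycle = sams_per_cycle + gibbs_per_cycle
    n_samples = (iterations - burn_in) // thin
    parts = np.empty((n_samples, n), dtype=np.int64)
    ks = np.empty(n_samples, dtype=np.int64)
    lams = (np.empty((n_samples, len(state.J))) if lambda_mode != "fixed" else None)
    s = 0
    for t in range(1, iterations + 1):
        if n >= 2 and (t - 1) % cycle < sams_per_cycle:
            state.sams_move()
        else:
            state.gibbs_scan()
        state.lambda_update()
        if t > burn_in and (t - burn_in) % thin == 0:
            parts[s] = canonical_labels(state.labels)
            ks[s] = state.K
            if lams is not None:
                lams[s] = state.lam
            s += 1
    return MCMCTrace(parts[:s], ks[:s], None if lams is None else lams[:s],
                     iterations, burn_in, thin, dict(state.accept))
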