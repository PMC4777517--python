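"""The uncorrelated random GP map and its analytic expectations.

A random GP map keeps the alphabet size K, genotype length L and the
whole phenotype frequency spectrum {F_p} of a source map, but assigns the
F_p genotypes of each phenotype uniformly at random over the genotype
space.  Because assignment is independent of neighbourhood, every
correlation statistic has a closed-form null value against which the
biophysical engines are compared:

* robustness          rho_p = f_p, and <n_{g,p}> = (K-1) L f_p
* n-robustness        rho_p^(n) = f_p for every radius n, <rho^(n)> = 1/N_P
* mutation probability phi_qp = f_q (for q frequent enough to be sampled)

Percolation thresholds on the Hamming graph (mean-field):

* delta = 1/((K-1) L)     giant-component onset (f_p above delta: large
  connected neutral components appear)
* lambda = 1 - (1/K)^(1/(K-1))   single-component onset (f_p above
  lambda: the neutral set is essentially one connected component)
* gamma = 1/(F_p (K-1) L)  sampling threshold: phenotypes with
  f_q below gamma may not appear at all in the neighbourhood of G_p
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .space import GenotypeSpace, GPMap, PhenotypeTable

__all__ = [
    "Thresholds",
    "thresholds",
    "randomize",
    "null_overrep_P1",
    "null_overrep_P2",
    "null_overrep_curve",
    "null_robustness",
]


@dataclass(frozen=True)
class Thresholds:
    delta: float
    lam: float
    gamma: float | None = None


def thresholds(K: int, L: int, F_p: int | None = None) -> Thresholds:
    """Closed-form percolation thresholds for a K-letter, length-L space."""
    if K < 2 or L < 1:
        raise ValueError("need K >= 2 and L >= 1")
    delta = 1.0 / ((K - 1) * L)
    lam = 1.0 - (1.0 / K) ** (1.0 / (K - 1))
    gamma = None if F_p is None else 1.0 / (F_p * (K - 1) * L)
    return Thresholds(delta=delta, lam=lam, gamma=gamma)


def randomize(table: PhenotypeTable, space: GenotypeSpace, seed: int | None = None) -> GPMap:
    """Frequency-matched random map: a uniform random partition of the space.

    Permutes the genotype ranks with a seeded shuffle (NumPy PCG64
    ``permutation``) and slices the permuted order into consecutive
    blocks of the given sizes F_p, so each phenotype's redundancy is
    preserved exactly.
    """
    counts = np.asarray(table.counts, dtype=np.int64)
    if counts.sum() != space.n_genotypes:
        raise ValueError(
            f"spectrum sums to {counts.sum()}, but the space has {space.n_genotypes} genotypes"
        )
    if (counts < 1).any():
        raise ValueError("all F_p must be >= 1")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(space.n_genotypes)
    codes = np.empty(space.n_genotypes, dtype=np.int32)
    start = 0
    for code, c in enumerate(counts):
        codes[perm[start : start + c]] = code
        start += c
    return GPMap(space, codes=codes, labels=list(table.labels), del_label=table.del_label)


def _check_m(m: int, K: int, L: int) -> None:
    if not 1 <= m <= (K - 1) * L:
        raise ValueError(f"m={m} outside [1, (K-1)L={(K - 1) * L}]")


def null_overrep_P1(m: int, f_q: float, K: int, L: int) -> float:
    """Binomial null for local over-representation, driven by the global f_q.

    Probability that q appears exactly m times in a 1-mutation
    neighbourhood, conditioned on one specified neighbour being q: a
    binomial over the remaining (K-1)L - 1 neighbours with rate f_q.
    """
    _check_m(m, K, L)
    return float(stats.binom.pmf(m - 1, (K - 1) * L - 1, f_q))


def null_overrep_P2(m: int, phi_qp: float, K: int, L: int) -> float:
    """Same binomial form with the map's phenotype mutation probability phi_qp."""
    _check_m(m, K, L)
    return float(stats.binom.pmf(m - 1, (K - 1) * L - 1, phi_qp))


def null_overrep_curve(rate: float, K: int, L: int) -> np.ndarray:
    """Vector of the binomial null over the full support m = 1..(K-1)L."""
    m = np.arange(1, (K - 1) * L + 1)
    return stats.binom.pmf(m - 1, (K - 1) * L - 1, rate)


def null_robustness(table: PhenotypeTable) -> tuple[np.ndarray, float]:
    """Analytic null columns: per-phenotype rho_p = f_p and <rho^(n)> = 1/N_P."""
    return table.frequencies, 1.0 / table.n_phenotypes
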