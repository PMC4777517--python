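"""Genotype-space primitives and the genotype-phenotype (GP) map container.

A genotype space is the Hamming graph ``H(L, K)``: all strings of length
``L`` over an ordered alphabet of ``K`` characters, with an edge between
two strings whenever they differ at exactly one position.  Every genotype
therefore has exactly ``(K - 1) * L`` one-mutation neighbours.  A GP map
assigns each genotype exactly one phenotype label; all correlation
statistics in this package are defined on top of that assignment.

Complete maps are stored as a dense integer-coded array indexed by the
mixed-radix rank of the genotype (position 0 most significant), with
phenotype labels interned to integers in a sidecar label table.  Spaces
that are too large to enumerate are wrapped as *sampled* maps around a
deterministic phenotype oracle with a memo cache.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeSpace",
    "GPMap",
    "PhenotypeTable",
    "NeutralSet",
    "neighbours",
    "mutant_shell",
    "shell_size",
    "tabulate",
    "estimate_frequencies",
    "InvalidGenotypeError",
    "UnsupportedModeError",
    "GuardError",
    "RNA_ALPHABET",
    "HP_ALPHABET",
    "POLYOMINO_ALPHABET",
    "WORD_ALPHABET",
]

RNA_ALPHABET = "AUGC"
HP_ALPHABET = "HP"
POLYOMINO_ALPHABET = "01234567"
WORD_ALPHABET = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"


class InvalidGenotypeError(ValueError):
    """A genotype string has the wrong length or characters outside the alphabet."""


class UnsupportedModeError(RuntimeError):
    """An operation requiring a complete map was called on a sampled map (or vice versa)."""


class GuardError(RuntimeError):
    """An enumeration guard refused a space too large to enumerate by default."""


@dataclass(frozen=True)
class GenotypeSpace:
    """The Hamming space of all length-``L`` strings over a ``K``-letter alphabet.

    Parameters
    ----------
    alphabet
        Ordered string of ``K`` distinct single characters.  Canonical
        choices: ``"AUGC"`` (RNA), ``"HP"`` (lattice proteins),
        ``"01234567"`` (polyomino interface types), ``"A".."Z"`` (word game).
    L
        Genotype length (>= 1).
    """

    alphabet: str
    L: int

    def __post_init__(self) -> None:
        if len(set(self.alphabet)) != len(self.alphabet) or len(self.alphabet) < 2:
            raise ValueError("alphabet must have >= 2 distinct characters")
        if self.L < 1:
            raise ValueError("L must be >= 1")

    @property
    def K(self) -> int:
        return len(self.alphabet)

    @property
    def n_genotypes(self) -> int:
        """Total genotype count N_G = K^L (exact integer)."""
        return self.K**self.L

    @property
    def n_neighbours(self) -> int:
        """Number of one-mutation neighbours of any genotype: (K-1)*L."""
        return (self.K - 1) * self.L

    # -- rank <-> string -------------------------------------------------

    @property
    def _powers(self) -> np.ndarray:
        # K^(L-1), ..., K^0 — position 0 most significant
        return self.K ** np.arange(self.L - 1, -1, -1, dtype=np.int64)

    @property
    def _char_index(self) -> dict[str, int]:
        return {c: i for i, c in enumerate(self.alphabet)}

    def validate(self, g: str) -> None:
        if len(g) != self.L:
            raise InvalidGenotypeError(f"genotype {g!r} has length {len(g)}, expected {self.L}")
        idx = self._char_index
        for c in g:
            if c not in idx:
                raise InvalidGenotypeError(f"character {c!r} not in alphabet {self.alphabet!r}")

    def rank(self, g: str) -> int:
        """Mixed-radix rank of a genotype string (position 0 most significant)."""
        self.validate(g)
        idx = self._char_index
        r = 0
        for c in g:
            r = r * self.K + idx[c]
        return r

    def genotype(self, rank: int) -> str:
        """Inverse of :meth:`rank`."""
        if not 0 <= rank < self.n_genotypes:
            raise ValueError(f"rank {rank} out of range")
        chars = []
        for _ in range(self.L):
            rank, d = divmod(rank, self.K)
            chars.append(self.alphabet[d])
        return "".join(reversed(chars))

    def digits(self, ranks: np.ndarray) -> np.ndarray:
        """Alphabet-index digits of an array of ranks, shape ``(n, L)``."""
        ranks = np.asarray(ranks, dtype=np.int64)
        return (ranks[:, None] // self._powers[None, :]) % self.K

    def neighbour_ranks(self, ranks: np.ndarray) -> np.ndarray:
        """Ranks of all one-mutation neighbours, shape ``(n, (K-1)L)``.

        Column order is position-major, then alphabet order — identical to
        :func:`neighbours` on strings.
        """
        ranks = np.asarray(ranks, dtype=np.int64)
        dg = self.digits(ranks)  # (n, L)
        letters = np.arange(self.K, dtype=np.int64)
        # candidate rank for letter b at position i: rank + (b - digit)*K^(L-1-i)
        cand = (
            ranks[:, None, None]
            + (letters[None, None, :] - dg[:, :, None]) * self._powers[None, :, None]
        )  # (n, L, K)
        keep = letters[None, None, :] != dg[:, :, None]
        return cand[keep].reshape(len(ranks), self.n_neighbours)


def neighbours(g: str, space: GenotypeSpace) -> list[str]:
    """All genotypes at Hamming distance 1 from ``g``.

    Deterministic order: position-major, alphabet order.  Returns exactly
    ``(K-1)*L`` distinct strings.
    """
    space.validate(g)
    out = []
    for i in range(space.L):
        for c in space.alphabet:
            if c != g[i]:
                out.append(g[:i] + c + g[i + 1 :])
    return out


def shell_size(space: GenotypeSpace, n: int) -> int:
    """Number of genotypes at Hamming distance exactly ``n``: C(L,n)*(K-1)^n."""
    if not 0 <= n <= space.L:
        raise ValueError(f"radius n={n} outside [0, L={space.L}]")
    return math.comb(space.L, n) * (space.K - 1) ** n


def mutant_shell(
    g: str,
    n: int,
    space: GenotypeSpace,
    sample_size: int | str = "all",
    seed: int | np.random.Generator | None = None,
) -> list[str]:
    """Genotypes at Hamming distance exactly ``n`` from ``g``.

    With ``sample_size="all"``, enumerates the entire shell of size
    ``C(L,n)*(K-1)^n``.  Otherwise returns ``sample_size`` independent
    uniform draws from the shell (``n`` distinct positions chosen
    uniformly, then a non-identical letter at each), reproducible under
    ``seed``.
    """
    space.validate(g)
    if not 1 <= n <= space.L:
        raise ValueError(f"radius n={n} outside [1, L={space.L}]")
    if sample_size == "all":
        out = []
        for positions in itertools.combinations(range(space.L), n):
            choices = [[c for c in space.alphabet if c != g[i]] for i in positions]
            for repl in itertools.product(*choices):
                chars = list(g)
                for i, c in zip(positions, repl):
                    chars[i] = c
                out.append("".join(chars))
        return out
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out = []
    for _ in range(int(sample_size)):
        positions = rng.choice(space.L, size=n, replace=False)
        chars = list(g)
        for i in positions:
            others = [c for c in space.alphabet if c != g[i]]
            chars[i] = others[rng.integers(len(others))]
        out.append("".join(chars))
    return out


@dataclass
class PhenotypeTable:
    """Per-phenotype redundancy F_p and frequency f_p = F_p / N_G.

    ``labels[i]`` is the phenotype with integer code ``i`` in the parent
    map; ``counts[i]`` its redundancy.  ``se`` is populated only for
    Monte-Carlo estimates (:func:`estimate_frequencies`).
    """

    labels: list[str]
    counts: np.ndarray
    n_genotypes: int
    del_label: str | None = None
    se: np.ndarray | None = None

    @property
    def n_phenotypes(self) -> int:
        return len(self.labels)

    @property
    def frequencies(self) -> np.ndarray:
        return self.counts / self.n_genotypes

    def count(self, p: str) -> int:
        return int(self.counts[self.labels.index(p)])

    def frequency(self, p: str) -> float:
        return self.count(p) / self.n_genotypes

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "phenotype": self.labels,
                "count": self.counts.astype(np.int64),
                "frequency": self.frequencies,
            }
        )
        if self.se is not None:
            df["se"] = self.se
        return df

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


@dataclass
class NeutralSet:
    """All genotypes mapping to one phenotype, as ranks in the parent space."""

    phenotype: str
    space: GenotypeSpace
    ranks: np.ndarray

    @property
    def size(self) -> int:
        return len(self.ranks)

    def genotypes(self) -> list[str]:
        return [self.space.genotype(int(r)) for r in self.ranks]


class GPMap:
    """A genotype -> phenotype assignment over a ``K^L`` Hamming space.

    Two modes:

    * *complete* — a dense integer-coded array covering every genotype
      (``codes[rank] = phenotype code``), with a label table.
    * *sampled* — a deterministic phenotype oracle ``genotype -> label``
      queried on demand, with a memo cache, for spaces too large to
      enumerate.

    ``del_label`` designates the deleterious phenotype (non-folding /
    non-assembling / UND), when the map has one.
    """

    def __init__(
        self,
        space: GenotypeSpace,
        codes: np.ndarray | None = None,
        labels: Sequence[str] | None = None,
        oracle: Callable[[str], str] | None = None,
        del_label: str | None = None,
    ):
        if (codes is None) == (oracle is None):
            raise ValueError("provide exactly one of codes (complete) or oracle (sampled)")
        self.space = space
        self.del_label = del_label
        self._oracle = oracle
        self._memo: dict[str, str] = {}
        if codes is not None:
            codes = np.asarray(codes)
            if len(codes) != space.n_genotypes:
                raise ValueError(
                    f"complete map needs {space.n_genotypes} entries, got {len(codes)}"
                )
            if labels is None:
                raise ValueError("complete mode requires a label table")
            self.codes = codes
            self.labels = list(labels)
            if codes.size and (codes.min() < 0 or codes.max() >= len(self.labels)):
                raise ValueError("phenotype codes outside label table")
        else:
            self.codes = None
            self.labels = None

    # -- construction ----------------------------------------------------

    @classmethod
    def from_assignment(
        cls, space: GenotypeSpace, assignment: Mapping[str, str], del_label: str | None = None
    ) -> "GPMap":
        """Build a complete map from a total dict ``genotype -> label``."""
        if len(assignment) != space.n_genotypes:
            raise ValueError(
                f"assignment must be total: {space.n_genotypes} genotypes, got {len(assignment)}"
            )
        labels = sorted(set(assignment.values()))
        code_of = {p: i for i, p in enumerate(labels)}
        dtype = np.int32
        codes = np.empty(space.n_genotypes, dtype=dtype)
        for g, p in assignment.items():
            codes[space.rank(g)] = code_of[p]
        return cls(space, codes=codes, labels=labels, del_label=del_label)

    @classmethod
    def from_oracle(
        cls, space: GenotypeSpace, oracle: Callable[[str], str], del_label: str | None = None
    ) -> "GPMap":
        return cls(space, oracle=oracle, del_label=del_label)

    # -- queries ---------------------------------------------------------

    @property
    def mode(self) -> str:
        return "complete" if self.codes is not None else "sampled"

    def require_complete(self, what: str = "this operation") -> None:
        if self.mode != "complete":
            raise UnsupportedModeError(f"{what} requires a complete map")

    def phenotype(self, g: str) -> str:
        """Phenotype label of a genotype (memoised in sampled mode)."""
        if self.codes is not None:
            return self.labels[int(self.codes[self.space.rank(g)])]
        if g in self._memo:
            return self._memo[g]
        self.space.validate(g)
        p = self._oracle(g)
        self._memo[g] = p
        return p

    def phenotype_of_rank(self, rank: int) -> str:
        if self.codes is not None:
            return self.labels[int(self.codes[rank])]
        return self.phenotype(self.space.genotype(rank))

    def code_of(self, p: str) -> int:
        self.require_complete("label interning")
        try:
            return self.labels.index(p)
        except ValueError:
            raise KeyError(f"unknown phenotype {p!r}") from None

    def neutral_set(self, p: str) -> NeutralSet:
        """Ranks of all genotypes mapping to ``p`` (complete mode)."""
        self.require_complete("neutral-set enumeration")
        ranks = np.flatnonzero(self.codes == self.code_of(p))
        return NeutralSet(phenotype=p, space=self.space, ranks=ranks)


def tabulate(gpmap: GPMap) -> PhenotypeTable:
    """Count every genotype once and return the phenotype frequency table.

    Complete mode only; for sampled maps use :func:`estimate_frequencies`.
    """
    gpmap.require_complete("tabulate")
    counts = np.bincount(gpmap.codes, minlength=len(gpmap.labels)).astype(np.int64)
    keep = counts > 0
    labels = [p for p, k in zip(gpmap.labels, keep) if k]
    return PhenotypeTable(
        labels=labels,
        counts=counts[keep],
        n_genotypes=gpmap.space.n_genotypes,
        del_label=gpmap.del_label,
    )


def estimate_frequencies(gpmap: GPMap, n_samples: int, seed: int | None = None) -> PhenotypeTable:
    """Monte-Carlo phenotype frequency estimates from uniform genotype draws.

    Works in either mode.  Counts are raw sample counts; frequencies are
    ``count / n_samples`` with binomial standard errors
    ``sqrt(f(1-f)/n_samples)``.  The returned table's ``n_genotypes`` is
    set to ``n_samples`` so that ``frequencies`` is the estimate.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    rng = np.random.default_rng(seed)
    counts: dict[str, int] = {}
    N = gpmap.space.n_genotypes
    for _ in range(n_samples):
        r = int(rng.integers(N))
        p = gpmap.phenotype_of_rank(r)
        counts[p] = counts.get(p, 0) + 1
    labels = sorted(counts)
    c = np.array([counts[p] for p in labels], dtype=np.int64)
    f = c / n_samples
    se = np.sqrt(f * (1.0 - f) / n_samples)
    return PhenotypeTable(
        labels=labels, counts=c, n_genotypes=n_samples, del_label=gpmap.del_label, se=se
    )
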