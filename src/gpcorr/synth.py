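"""Synthetic GP-map generators: random spectra, correlated positive
controls, and the four-letter word game.

These generators make every pipeline stage testable offline.  The random
generator realises an arbitrary phenotype frequency spectrum and
delegates to the frequency-matched null; the correlated generators plant
neutral correlations by construction (clustered Hamming-ball neutral
sets, or phenotypes determined by a subset of loci) so that every
correlation statistic has a positive control with a known direction.
The word-game builder turns any plain-text word list into a
two-phenotype map over 26-letter strings, the classic illustration of
neutral correlations in a non-biological map.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .nullmodel import randomize
from .space import GenotypeSpace, GPMap, PhenotypeTable, WORD_ALPHABET

__all__ = [
    "SpectrumSpec",
    "realize_spectrum",
    "generate_random_map",
    "generate_correlated_map",
    "build_wordgame_map",
    "demo_wordlist_path",
]


@dataclass(frozen=True)
class SpectrumSpec:
    """A phenotype frequency spectrum over a K-letter, length-L space.

    Either an explicit list of redundancies ``counts`` (must sum to
    K^L), or a parametric spectrum: ``n_phenotypes`` frequencies spaced
    log-uniformly over ``decades`` decades, with an optional deleterious
    phenotype absorbing ``del_fraction`` of the space.  Realised counts
    are rounded to integers (>= 1 each) and the largest phenotype is
    adjusted so the total is exactly K^L.
    """

    K: int
    L: int
    counts: tuple | None = None
    n_phenotypes: int = 10
    decades: float = 2.0
    del_fraction: float = 0.0
    alphabet: str | None = None
    del_label: str | None = None

    def space(self) -> GenotypeSpace:
        alphabet = self.alphabet
        if alphabet is None:
            digits = "0123456789ABCDEFGHIJKLMNOPQRSTUVWXYZ"
            if self.K > len(digits):
                raise ValueError("provide an explicit alphabet for K > 36")
            alphabet = digits[: self.K]
        return GenotypeSpace(alphabet=alphabet, L=self.L)


def realize_spectrum(spec: SpectrumSpec) -> PhenotypeTable:
    """Integer redundancies summing exactly to K^L, with labels p0, p1, ..."""
    space = spec.space()
    N = space.n_genotypes
    if spec.counts is not None:
        counts = np.asarray(spec.counts, dtype=np.int64)
        if counts.sum() != N:
            raise ValueError(f"explicit counts sum to {counts.sum()}, need {N}")
        if (counts < 1).any():
            raise ValueError("all F_p must be >= 1")
        labels = [f"p{i}" for i in range(len(counts))]
        if spec.del_label is not None:
            labels[-1] = spec.del_label
        return PhenotypeTable(labels, counts, N, del_label=spec.del_label)
    n = spec.n_phenotypes
    if n < 1:
        raise ValueError("n_phenotypes must be >= 1")
    if not 0.0 <= spec.del_fraction < 1.0:
        raise ValueError("del_fraction must be in [0, 1)")
    del_count = int(round(spec.del_fraction * N))
    budget = N - del_count
    if budget < n:
        raise ValueError("spectrum infeasible: fewer free genotypes than phenotypes")
    # log-uniform frequencies spanning `decades`, largest first
    if n == 1:
        raw = np.array([1.0])
    else:
        raw = 10.0 ** (-spec.decades * np.arange(n) / (n - 1))
    raw = raw / raw.sum()
    counts = np.maximum(1, np.round(raw * budget).astype(np.int64))
    counts[0] += budget - counts.sum()  # repair the total on the largest phenotype
    if counts[0] < 1:
        raise ValueError("spectrum infeasible after rounding repair")
    labels = [f"p{i}" for i in range(n)]
    all_counts = list(counts)
    del_label = spec.del_label
    if del_count > 0:
        del_label = del_label or "del"
        labels.append(del_label)
        all_counts.append(del_count)
    return PhenotypeTable(labels, np.array(all_counts, dtype=np.int64), N, del_label=del_label)


def generate_random_map(spec: SpectrumSpec, seed: int | None = None) -> GPMap:
    """Uncorrelated map with the requested spectrum (delegates to the null)."""
    table = realize_spectrum(spec)
    return randomize(table, spec.space(), seed=seed)


def generate_correlated_map(
    spec: SpectrumSpec,
    clustering: str = "hamming_ball",
    strength: float = 1.0,
    seed: int | None = None,
    n_block_loci: int = 2,
) -> GPMap:
    """Positively correlated map with the exact requested spectrum.

    ``hamming_ball``: each phenotype is seeded at a random unassigned
    genotype and grown by neutral accretion (uniform draws from the
    frontier of unassigned neighbours) to its full redundancy; with
    probability ``1 - strength`` a growth step instead jumps to a random
    unassigned genotype, so ``strength=0`` reproduces the random map.

    ``locus_block``: the phenotype is determined primarily by
    ``n_block_loci`` randomly chosen loci — genotypes are sorted by their
    digits at those loci (random tie-break) and sliced by cumulative
    redundancy; a fraction ``1 - strength`` of genotypes get fully random
    sort keys.
    """
    if not 0.0 <= strength <= 1.0:
        raise ValueError("strength must be in [0, 1]")
    table = realize_spectrum(spec)
    space = spec.space()
    N = space.n_genotypes
    rng = np.random.default_rng(seed)
    if clustering == "hamming_ball":
        codes = np.full(N, -1, dtype=np.int32)
        # O(1) uniform sampling over unassigned ranks: swap-remove list
        pool = list(range(N))
        pos = list(range(N))

        def pool_remove(r: int) -> None:
            i = pos[r]
            last = pool[-1]
            pool[i] = last
            pos[last] = i
            pool.pop()
            pos[r] = -1

        def pool_draw() -> int:
            return pool[int(rng.integers(len(pool)))]

        # grow smallest phenotypes first so their balls are not fragmented by
        # the remainder left behind by larger ones
        order = np.argsort(table.counts, kind="stable")
        for code in order:
            target = int(table.counts[code])
            frontier: list[int] = []
            in_frontier = set()
            for _ in range(target):
                pick = None
                if frontier and rng.random() < strength:
                    # neutral accretion: uniform draw from the unassigned frontier
                    while frontier:
                        i = int(rng.integers(len(frontier)))
                        cand = frontier[i]
                        frontier[i] = frontier[-1]
                        frontier.pop()
                        in_frontier.discard(cand)
                        if codes[cand] == -1:
                            pick = cand
                            break
                if pick is None:
                    pick = pool_draw()  # seed or jump
                codes[pick] = code
                pool_remove(pick)
                for r in space.neighbour_ranks(np.array([pick]))[0]:
                    r = int(r)
                    if codes[r] == -1 and r not in in_frontier:
                        frontier.append(r)
                        in_frontier.add(r)
        return GPMap(space, codes=codes, labels=list(table.labels), del_label=table.del_label)
    if clustering == "locus_block":
        loci = rng.choice(space.L, size=min(n_block_loci, space.L), replace=False)
        digits = space.digits(np.arange(N, dtype=np.int64))
        key = np.zeros(N, dtype=np.float64)
        for i in loci:
            key = key * space.K + digits[:, i]
        key = key + rng.random(N) * 0.5  # tie-break within blocks
        scramble = rng.random(N) < (1.0 - strength)
        key[scramble] = rng.random(int(scramble.sum())) * space.K ** len(loci)
        order = np.argsort(key, kind="stable")
        codes = np.empty(N, dtype=np.int32)
        start = 0
        for code, c in enumerate(table.counts):
            codes[order[start : start + int(c)]] = code
            start += int(c)
        return GPMap(space, codes=codes, labels=list(table.labels), del_label=table.del_label)
    raise ValueError(f"unknown clustering {clustering!r}")


VALID_LABEL = "valid"
INVALID_LABEL = "invalid"


def demo_wordlist_path() -> Path:
    """Path of the bundled demo list of common four-letter words."""
    return Path(importlib.resources.files("gpcorr.data") / "words4.txt")


def build_wordgame_map(word_list_path=None, L: int = 4) -> GPMap:
    """Two-phenotype word-game map over A-Z strings of length ``L``.

    Lines are case-folded to A-Z; non-alphabetic and non-length-``L``
    entries (and ``#`` comments) are ignored.  Valid words form the
    ``valid`` phenotype; everything else is ``invalid``, which plays the
    deleterious role.
    """
    path = Path(word_list_path) if word_list_path is not None else demo_wordlist_path()
    words = set()
    for line in path.read_text().splitlines():
        w = line.strip().upper()
        if w.startswith("#") or len(w) != L or not w.isalpha():
            continue
        if set(w) <= set(WORD_ALPHABET):
            words.add(w)
    if not words:
        raise ValueError(f"no valid length-{L} words in {path}")
    space = GenotypeSpace(alphabet=WORD_ALPHABET, L=L)
    codes = np.zeros(space.n_genotypes, dtype=np.int8)
    for w in words:
        codes[space.rank(w)] = 1
    return GPMap(
        space, codes=codes, labels=[INVALID_LABEL, VALID_LABEL], del_label=INVALID_LABEL
    )
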