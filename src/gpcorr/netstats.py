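"""Neutral-component decomposition and percolation summaries.

A neutral component (neutral network) is a maximal subset of a neutral
set G_p whose members are mutually reachable by neutral point mutations.
Components are found exactly with union-find (union-by-size with path
compression) over the neutral Hamming-1 edges, which are streamed
position-major so runs are deterministic.  Only complete maps are
supported: component analysis is meaningful only on fully enumerated
spaces.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .nullmodel import thresholds
from .space import GPMap, PhenotypeTable, tabulate

__all__ = ["ComponentDecomposition", "components", "percolation_summary"]


@dataclass
class ComponentDecomposition:
    """Partition of a neutral set into point-mutation-connected components."""

    phenotype: str
    component_sizes: np.ndarray  # descending
    component_labels: np.ndarray  # per member of the (sorted) neutral set
    member_ranks: np.ndarray

    @property
    def n_components(self) -> int:
        return len(self.component_sizes)

    @property
    def largest(self) -> int:
        return int(self.component_sizes[0]) if self.n_components else 0

    def component_members(self, i: int) -> np.ndarray:
        return self.member_ranks[self.component_labels == i]


class _UnionFind:
    def __init__(self, n: int):
        self.parent = np.arange(n, dtype=np.int64)
        self.size = np.ones(n, dtype=np.int64)

    def find(self, i: int) -> int:
        root = i
        while self.parent[root] != root:
            root = self.parent[root]
        while self.parent[i] != root:  # path compression
            self.parent[i], i = root, self.parent[i]
        return root

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return
        if self.size[ra] < self.size[rb]:
            ra, rb = rb, ra
        self.parent[rb] = ra
        self.size[ra] += self.size[rb]


def components(gpmap: GPMap, p: str, chunk: int = 1 << 14) -> ComponentDecomposition:
    """Exact neutral-component decomposition of phenotype ``p``."""
    gpmap.require_complete("component decomposition")
    members = gpmap.neutral_set(p).ranks  # sorted ascending
    n = len(members)
    uf = _UnionFind(n)
    space = gpmap.space
    for lo in range(0, n, chunk):
        block = members[lo : lo + chunk]
        nbr = space.neighbour_ranks(block)  # (b, (K-1)L), position-major
        # locate neighbours inside the member list
        pos = np.searchsorted(members, nbr)
        pos_clip = np.minimum(pos, n - 1)
        is_member = members[pos_clip] == nbr
        rows, cols = np.nonzero(is_member)
        for r, c in zip(rows, cols):
            uf.union(lo + r, pos[r, c])
    roots = np.array([uf.find(i) for i in range(n)])
    _, labels, sizes = np.unique(roots, return_inverse=True, return_counts=True)
    order = np.argsort(-sizes, kind="stable")
    relabel = np.empty_like(order)
    relabel[order] = np.arange(len(order))
    return ComponentDecomposition(
        phenotype=p,
        component_sizes=sizes[order],
        component_labels=relabel[labels],
        member_ranks=members,
    )


def percolation_summary(gpmap: GPMap, table: PhenotypeTable | None = None) -> pd.DataFrame:
    """One row per phenotype: frequency, largest component, component count,
    and flags against the giant-component (delta) and single-component
    (lambda) thresholds of the random null model."""
    gpmap.require_complete("percolation summary")
    if table is None:
        table = tabulate(gpmap)
    th = thresholds(gpmap.space.K, gpmap.space.L)
    rows = []
    for p, F, f in zip(table.labels, table.counts, table.frequencies):
        dec = components(gpmap, p)
        rows.append(
            {
                "phenotype": p,
                "f_p": f,
                "F_p": int(F),
                "largest_component": dec.largest,
                "n_components": dec.n_components,
                "above_delta": bool(f > th.delta),
                "above_lambda": bool(f > th.lam),
            }
        )
    return pd.DataFrame(rows)
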