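"""HP lattice protein GP map: square-lattice fold enumeration and assignment.

Genotypes are binary H/P sequences; a phenotype is a fold (self-avoiding
walk on the square lattice, Hamiltonian path of a W x W grid in compact
mode) that is the *unique* minimum-energy structure of the sequence under
the contact potential E_HH = -1, E_HP = E_PP = 0.  A contact is a pair of
residues that are non-adjacent along the chain (|i - j| >= 3; |i - j| = 2
can never be lattice-adjacent) but adjacent on the lattice.  Sequences
whose minimum energy is attained by two or more symmetry-distinct folds do
not fold and map to the deleterious label.

Fold identity is the equivalence class under translation, the four
rotations and reflection (the 8-element dihedral group), with chain
direction fixed (residue 1 distinguished).  The canonical id of a fold is
the lexicographically minimal coordinate string over all 8 symmetry
images, each translated so its minimum corner sits at the origin.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .space import GenotypeSpace, GPMap, GuardError, HP_ALPHABET

__all__ = ["Fold", "HPModelConfig", "enumerate_folds", "fold_energy", "assign_phenotype", "build_hp_map", "DEL_LABEL"]

DEL_LABEL = "del"

_STEPS = ((1, 0), (-1, 0), (0, 1), (0, -1))

# The 8 point-group operations of the square lattice as (x, y) -> (x', y').
_SYMMETRIES = (
    lambda x, y: (x, y),
    lambda x, y: (-y, x),
    lambda x, y: (-x, -y),
    lambda x, y: (y, -x),
    lambda x, y: (x, -y),
    lambda x, y: (-x, y),
    lambda x, y: (y, x),
    lambda x, y: (-y, -x),
)


def _normalise(coords):
    xs = [c[0] for c in coords]
    ys = [c[1] for c in coords]
    x0, y0 = min(xs), min(ys)
    return tuple((x - x0, y - y0) for x, y in coords)


def canonical_coords(coords) -> tuple:
    """Minimal translated image over the 8-element dihedral group."""
    best = None
    for sym in _SYMMETRIES:
        img = _normalise([sym(x, y) for x, y in coords])
        if best is None or img < best:
            best = img
    return best


def _coords_id(coords) -> str:
    return ";".join(f"{x},{y}" for x, y in coords)


def _contacts(coords) -> tuple:
    """Chain-non-adjacent (|i-j| >= 3), lattice-adjacent residue pairs."""
    pos = {c: i for i, c in enumerate(coords)}
    out = []
    for i, (x, y) in enumerate(coords):
        for dx, dy in _STEPS:
            j = pos.get((x + dx, y + dy))
            if j is not None and j - i >= 3:
                out.append((i, j))
    return tuple(sorted(out))


@dataclass(frozen=True)
class Fold:
    """A symmetry class of lattice embeddings of the chain."""

    coords: tuple  # canonical representative, min corner at origin
    contacts: tuple = field(default=None)

    def __post_init__(self):
        if self.contacts is None:
            object.__setattr__(self, "contacts", _contacts(self.coords))

    @property
    def fold_id(self) -> str:
        return _coords_id(self.coords)

    @property
    def L(self) -> int:
        return len(self.coords)


@dataclass(frozen=True)
class HPModelConfig:
    """Chain length, compactness mode and (fixed) contact energies."""

    L: int
    mode: str = "noncompact"  # "noncompact" | "compact"
    W: int | None = None
    E_HH: int = -1
    E_HP: int = 0
    E_PP: int = 0

    def __post_init__(self):
        if self.mode not in ("noncompact", "compact"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "compact":
            if self.W is None or self.L != self.W**2:
                raise ValueError("compact mode requires L = W^2 with W given")


def enumerate_folds(config: HPModelConfig, allow_large: bool = False) -> list[Fold]:
    """One representative fold per dihedral symmetry class.

    Non-compact mode enumerates all self-avoiding walks of ``L`` residues;
    the first step is fixed along +x and the first turn (if any) to +y,
    which selects exactly one representative per symmetry class.  Compact
    mode enumerates Hamiltonian paths of the W x W grid and deduplicates
    by canonical id.  Folds with empty contact sets are retained.
    """
    if config.mode == "noncompact" and config.L > 20 and not allow_large:
        raise GuardError(
            f"non-compact enumeration at L={config.L} exceeds the default guard (20); "
            "pass allow_large=True to override"
        )
    found: dict[tuple, tuple] = {}

    if config.mode == "noncompact":
        L = config.L

        def dfs(path, occupied, turned):
            if len(path) == L:
                can = canonical_coords(path)
                found.setdefault(can, tuple(path))
                return
            x, y = path[-1]
            for dx, dy in _STEPS:
                nxt = (x + dx, y + dy)
                if nxt in occupied:
                    continue
                # quotient reflections: before the first turn only +x and +y allowed,
                # and the first off-axis step must be +y
                if not turned:
                    if dy < 0 or dx < 0:
                        continue
                    new_turned = dy > 0
                else:
                    new_turned = True
                occupied.add(nxt)
                path.append(nxt)
                dfs(path, occupied, new_turned)
                path.pop()
                occupied.remove(nxt)

        if L == 1:
            found[((0, 0),)] = ((0, 0),)
        else:
            start = [(0, 0), (1, 0)]
            dfs(start, set(start), False)
    else:
        W = config.W
        cells = [(x, y) for x in range(W) for y in range(W)]

        def dfs_compact(path, occupied):
            if len(path) == W * W:
                can = canonical_coords(path)
                found.setdefault(can, tuple(path))
                return
            x, y = path[-1]
            for dx, dy in _STEPS:
                nxt = (x + dx, y + dy)
                if nxt in occupied or not (0 <= nxt[0] < W and 0 <= nxt[1] < W):
                    continue
                occupied.add(nxt)
                path.append(nxt)
                dfs_compact(path, occupied)
                path.pop()
                occupied.remove(nxt)

        for start in cells:
            dfs_compact([start], {start})

    folds = [Fold(coords=can) for can in found]
    folds.sort(key=lambda f: f.fold_id)
    return folds


def fold_energy(seq: str, fold: Fold) -> int:
    """Contact energy: -1 per contact pair with both residues H."""
    if len(seq) != fold.L:
        raise ValueError(f"sequence length {len(seq)} != fold length {fold.L}")
    return -sum(1 for i, j in fold.contacts if seq[i] == "H" and seq[j] == "H")


def assign_phenotype(seq: str, folds: list[Fold], del_label: str = DEL_LABEL) -> str:
    """Canonical id of the unique minimum-energy fold, or the deleterious label.

    A sequence is deleterious when two or more symmetry-distinct folds
    attain its minimum energy (the generic case for sequences whose
    minimum is 0 whenever several folds exist).
    """
    if not folds:
        raise ValueError("fold list is empty")
    energies = [fold_energy(seq, f) for f in folds]
    emin = min(energies)
    winners = [f for f, e in zip(folds, energies) if e == emin]
    if len(winners) > 1:
        return del_label
    return winners[0].fold_id


def build_hp_map(
    config: HPModelConfig,
    del_label: str = DEL_LABEL,
    guard_L: int = 25,
    allow_large: bool = False,
) -> GPMap:
    """Complete GP map over all 2^L HP sequences (vectorised assignment)."""
    if config.L > guard_L and not allow_large:
        raise GuardError(
            f"2^{config.L} sequences exceed the default guard (L <= {guard_L}); "
            "pass allow_large=True to override"
        )
    folds = enumerate_folds(config, allow_large=allow_large)
    space = GenotypeSpace(alphabet=HP_ALPHABET, L=config.L)
    N = space.n_genotypes
    # alphabet "HP": digit 0 encodes H.  is_H[r, i] for residue i of rank r.
    ranks = np.arange(N, dtype=np.int64)
    is_h = space.digits(ranks) == 0  # (N, L) bool

    best = np.zeros(N, dtype=np.int16)
    best_idx = np.full(N, -1, dtype=np.int32)
    n_best = np.zeros(N, dtype=np.int32)
    first = True
    for fi, fold in enumerate(folds):
        e = np.zeros(N, dtype=np.int16)
        for i, j in fold.contacts:
            e -= (is_h[:, i] & is_h[:, j]).astype(np.int16)
        if first:
            best = e
            best_idx[:] = fi
            n_best[:] = 1
            first = False
        else:
            lower = e < best
            equal = e == best
            best = np.where(lower, e, best)
            best_idx = np.where(lower, fi, best_idx)
            n_best = np.where(lower, 1, n_best + equal)
    unique = n_best == 1

    labels = [f.fold_id for f in folds] + [del_label]
    codes = np.where(unique, best_idx, len(folds)).astype(np.int32)
    # drop fold labels never attained uniquely, re-interning codes
    attained = np.zeros(len(labels), dtype=bool)
    attained[np.unique(codes)] = True
    remap = np.cumsum(attained) - 1
    labels = [p for p, a in zip(labels, attained) if a]
    codes = remap[codes].astype(np.int32)
    return GPMap(space, codes=codes, labels=labels, del_label=del_label if del_label in labels else None)
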