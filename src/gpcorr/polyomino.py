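"""Polyomino lattice self-assembly GP map.

A genotype of length ``4 * N_t`` over the interface alphabet ``0..N_c-1``
encodes ``N_t`` square tiles, four interface labels per tile written
clockwise from north.  Interface types interact in ordered odd-even
pairs (1-2, 3-4, 5-6); labels 0 and 7 bind nothing.  Assembly seeds the
first tile at the origin, then repeatedly draws a random (perimeter
cell, tile type, orientation) triple and keeps the placement iff at
least one edge facing an occupied neighbour forms an interacting pair.
Assembly halts when nothing can attach (decided exactly by an exhaustive
attachability scan once random attempts stall) or is declared unbounded
when the structure exceeds a size cap.

A genotype maps to a shape phenotype only when several independent
assembly attempts all terminate in the identical canonical shape;
otherwise it maps to the undefined/deleterious phenotype UND.  Shape
identity uses translation and the four rotations (no reflections by
default: oriented interface chirality makes mirror shapes physically
distinct; pass ``reflections=True`` for the sensitivity variant).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .space import GenotypeSpace, GPMap, GuardError, InvalidGenotypeError

__all__ = [
    "TileSet",
    "AssemblyConfig",
    "UNBOUNDED",
    "UND_LABEL",
    "parse_tileset",
    "assemble_once",
    "classify",
    "build_polyomino_map",
    "canonical_shape",
    "shape_label",
]

UND_LABEL = "UND"
UNBOUNDED = "UNBOUNDED"

# ordered odd-even interacting pairs among interface types 0..7
_INTERACTING = {(1, 2), (2, 1), (3, 4), (4, 3), (5, 6), (6, 5)}

# world directions, clockwise from north; index i faces direction _DIRS[i]
_DIRS = ((0, 1), (1, 0), (0, -1), (-1, 0))  # N, E, S, W


def interacts(a: int, b: int) -> bool:
    return (a, b) in _INTERACTING


@dataclass(frozen=True)
class TileSet:
    """Tile edge labels in written order (north, east, south, west)."""

    edges: tuple  # tuple of 4-tuples of ints
    N_c: int = 8

    @property
    def N_t(self) -> int:
        return len(self.edges)

    @property
    def genotype(self) -> str:
        return "".join(str(e) for tile in self.edges for e in tile)


def parse_tileset(genotype: str, N_c: int = 8) -> TileSet:
    if len(genotype) % 4 != 0 or not genotype:
        raise InvalidGenotypeError(f"genotype length {len(genotype)} is not a multiple of 4")
    try:
        vals = [int(c) for c in genotype]
    except ValueError:
        raise InvalidGenotypeError(f"non-digit character in genotype {genotype!r}") from None
    if any(v >= N_c for v in vals):
        raise InvalidGenotypeError(f"interface label >= N_c={N_c} in genotype {genotype!r}")
    edges = tuple(tuple(vals[4 * t : 4 * t + 4]) for t in range(len(vals) // 4))
    return TileSet(edges=edges, N_c=N_c)


@dataclass(frozen=True)
class AssemblyConfig:
    """Repeat protocol and termination bookkeeping for the assembly process."""

    n_repeats: int = 20
    size_cap: int | None = None  # default 16 * N_t
    max_stall: int = 50
    seed: int = 0

    def __post_init__(self):
        if self.n_repeats < 2:
            raise ValueError("n_repeats must be >= 2 for the determinism check")

    def cap_for(self, tiles: TileSet) -> int:
        return self.size_cap if self.size_cap is not None else 16 * tiles.N_t


def canonical_shape(cells, reflections: bool = False) -> tuple:
    """Translation-normalised, rotation-minimal cell set."""
    cells = list(cells)
    images = []
    variants = [cells]
    for _ in range(3):
        variants.append([(y, -x) for x, y in variants[-1]])
    if reflections:
        mirror = [(-x, y) for x, y in cells]
        variants.append(mirror)
        for _ in range(3):
            variants.append([(y, -x) for x, y in variants[-1]])
    for var in variants:
        xs = [c[0] for c in var]
        ys = [c[1] for c in var]
        x0, y0 = min(xs), min(ys)
        images.append(tuple(sorted((x - x0, y - y0) for x, y in var)))
    return min(images)


def shape_label(canon: tuple) -> str:
    return ";".join(f"{x},{y}" for x, y in canon)


def _edge_facing(tiles: TileSet, t: int, rot: int, d: int) -> int:
    # rot = number of clockwise 90-degree rotations; the edge facing world
    # direction d is the written edge (d - rot) mod 4
    return tiles.edges[t][(d - rot) % 4]


def _can_attach(tiles: TileSet, placed: dict, cell, t: int, rot: int) -> bool:
    x, y = cell
    for d, (dx, dy) in enumerate(_DIRS):
        nb = placed.get((x + dx, y + dy))
        if nb is None:
            continue
        nt, nrot = nb
        mine = _edge_facing(tiles, t, rot, d)
        theirs = _edge_facing(tiles, nt, nrot, (d + 2) % 4)
        if interacts(mine, theirs):
            return True
    return False


def _inert(tiles: TileSet) -> bool:
    """True when no pair of labels present in the tile set interacts: the
    seed tile can never be joined and every assembly is the monomer."""
    present = {e for tile in tiles.edges for e in tile}
    return not any((a, b) in _INTERACTING for a in present for b in present)


def assemble_once(tiles: TileSet, config: AssemblyConfig, rng: np.random.Generator):
    """One stochastic assembly; returns a frozenset of cells or ``UNBOUNDED``."""
    placed = {(0, 0): (0, 0)}  # cell -> (tile type, rotation); seed tile 1, orientation 0
    if _inert(tiles):
        return frozenset(placed)
    frontier: list = []
    in_frontier: set = set()

    def grow_frontier(cell):
        x, y = cell
        for dx, dy in _DIRS:
            nxt = (x + dx, y + dy)
            if nxt not in placed and nxt not in in_frontier:
                frontier.append(nxt)
                in_frontier.add(nxt)

    def take(cell):
        in_frontier.discard(cell)
        # lazy deletion: stale entries are skipped when drawn

    grow_frontier((0, 0))
    cap = config.cap_for(tiles)
    stall = 0
    while True:
        if len(placed) > cap:
            return UNBOUNDED
        cell = frontier[int(rng.integers(len(frontier)))]
        if cell in placed:
            continue  # stale entry
        t = int(rng.integers(tiles.N_t))
        rot = int(rng.integers(4))
        if _can_attach(tiles, placed, cell, t, rot):
            placed[cell] = (t, rot)
            take(cell)
            grow_frontier(cell)
            stall = 0
            continue
        stall += 1
        if stall >= config.max_stall:
            # decide halting exactly: enumerate every (cell, tile, orientation)
            cells = sorted(in_frontier)
            attachable = [
                (c, tt, rr)
                for c in cells
                for tt in range(tiles.N_t)
                for rr in range(4)
                if _can_attach(tiles, placed, c, tt, rr)
            ]
            if not attachable:
                return frozenset(placed)
            c, tt, rr = attachable[int(rng.integers(len(attachable)))]
            placed[c] = (tt, rr)
            take(c)
            grow_frontier(c)
            stall = 0


def classify(
    tiles: TileSet | str,
    config: AssemblyConfig | None = None,
    reflections: bool = False,
) -> str:
    """Phenotype label of a tile set: canonical shape or ``UND``.

    Runs ``n_repeats`` independent assemblies (per-repeat RNG streams
    seeded by (master seed, genotype rank, repeat index)); the genotype
    maps to a shape only if every repeat terminates in that identical
    canonical shape, and to ``UND`` on any unbounded run or shape
    mismatch.
    """
    if isinstance(tiles, str):
        tiles = parse_tileset(tiles)
    if config is None:
        config = AssemblyConfig()
    if _inert(tiles):  # no interacting labels present: monomer, exactly
        return shape_label(canonical_shape({(0, 0)}, reflections=reflections))
    grank = 0
    for c in tiles.genotype:
        grank = grank * tiles.N_c + int(c)
    result = None
    for rep in range(config.n_repeats):
        rng = np.random.default_rng([config.seed, grank, rep])
        out = assemble_once(tiles, config, rng)
        if out == UNBOUNDED:
            return UND_LABEL
        canon = canonical_shape(out, reflections=reflections)
        if result is None:
            result = canon
        elif canon != result:
            return UND_LABEL
    return shape_label(result)


def build_polyomino_map(
    N_t: int,
    N_c: int = 8,
    config: AssemblyConfig | None = None,
    reflections: bool = False,
    guard: int = 1 << 20,
    allow_large: bool = False,
) -> GPMap:
    """GP map over the space S_{N_t, N_c}: complete when enumerable, else a sampled oracle.

    The genotype space has ``N_c ** (4 * N_t)`` genotypes (8^8 ~ 1.7e7 for
    S_2,8 and 8^12 ~ 6.9e10 for S_3,8).  Spaces above ``guard`` genotypes
    are returned in sampled mode unless fully enumerable is forced.
    """
    if config is None:
        config = AssemblyConfig()
    alphabet = "".join(str(i) for i in range(N_c))
    space = GenotypeSpace(alphabet=alphabet, L=4 * N_t)
    if space.n_genotypes > guard and not allow_large:
        oracle = lambda g: classify(parse_tileset(g, N_c=N_c), config, reflections=reflections)
        return GPMap.from_oracle(space, oracle, del_label=UND_LABEL)
    assignment = {}
    for r in range(space.n_genotypes):
        g = space.genotype(r)
        assignment[g] = classify(parse_tileset(g, N_c=N_c), config, reflections=reflections)
    del_label = UND_LABEL if UND_LABEL in assignment.values() else None
    return GPMap.from_assignment(space, assignment, del_label=del_label)
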