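"""RNA secondary-structure GP map with a pluggable folding backend.

The built-in *toy* backend is a Nussinov-style dynamic program that
maximises the number of allowed base pairs (AU, UA, GC, CG, GU, UG)
subject to a minimum hairpin loop of ``hairpin_min`` unpaired bases, with
a deterministic traceback.  It is self-contained and fast enough to
enumerate small sequence spaces exhaustively; it makes no claim to
thermodynamic accuracy.  The *external* backend shells out to an
installed ``RNAfold`` binary (ViennaRNA) and parses its dot-bracket
output, for users who want free-energy minimum structures.

The phenotype is the dot-bracket string; the deleterious label is exactly
the fully unpaired structure (the strand does not fold).
"""

from __future__ import annotations

import shutil
import subprocess
from dataclasses import dataclass
from functools import lru_cache

from .space import GenotypeSpace, GPMap, GuardError, RNA_ALPHABET

__all__ = [
    "SecondaryStructure",
    "RNAFoldConfig",
    "fold",
    "max_pairs",
    "build_rna_map",
    "rna_oracle",
    "parse_dotbracket",
    "render_dotbracket",
]

ALLOWED_PAIRS = frozenset({("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")})


def parse_dotbracket(db: str) -> frozenset:
    """Pair set {(i, j)} encoded by a dot-bracket string (0-based, i < j)."""
    stack, pairs = [], []
    for i, c in enumerate(db):
        if c == "(":
            stack.append(i)
        elif c == ")":
            if not stack:
                raise ValueError(f"unbalanced brackets in {db!r}")
            pairs.append((stack.pop(), i))
        elif c != ".":
            raise ValueError(f"invalid character {c!r} in dot-bracket string")
    if stack:
        raise ValueError(f"unbalanced brackets in {db!r}")
    return frozenset(pairs)


def render_dotbracket(pairs, L: int) -> str:
    chars = ["."] * L
    for i, j in pairs:
        chars[i], chars[j] = "(", ")"
    return "".join(chars)


@dataclass(frozen=True)
class SecondaryStructure:
    """A nested (pseudoknot-free) pairing pattern of an RNA strand."""

    dotbracket: str

    @property
    def pairs(self) -> frozenset:
        return parse_dotbracket(self.dotbracket)

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    @property
    def is_unfolded(self) -> bool:
        return set(self.dotbracket) <= {"."}


@dataclass(frozen=True)
class RNAFoldConfig:
    backend: str = "toy"  # "toy" | "external"
    hairpin_min: int = 3
    external_cmd: str = "RNAfold"

    def __post_init__(self):
        if self.backend not in ("toy", "external"):
            raise ValueError(f"unknown backend {self.backend!r}")
        if self.hairpin_min < 1:
            raise ValueError("hairpin_min must be >= 1")


def _pairable(a: str, b: str) -> bool:
    return (a, b) in ALLOWED_PAIRS


def _max_pairs_table(seq: str, h: int) -> list:
    """DP table M[i][j] = max pairs in seq[i..j] with loop constraint h."""
    L = len(seq)
    M = [[0] * L for _ in range(L)]
    for span in range(h + 1, L):
        for i in range(L - span):
            j = i + span
            best = M[i + 1][j]  # i unpaired
            for k in range(i + h + 1, j + 1):
                if _pairable(seq[i], seq[k]):
                    left = M[i + 1][k - 1] if k - 1 > i else 0
                    right = M[k + 1][j] if k + 1 <= j else 0
                    cand = 1 + left + right
                    if cand > best:
                        best = cand
            M[i][j] = best
    return M


def _traceback(seq: str, M: list, h: int) -> list:
    """Deterministic traceback: pair i with the smallest j achieving the optimum."""
    L = len(seq)
    pairs = []
    stack = [(0, L - 1)]
    while stack:
        i, j = stack.pop()
        if j - i <= h:
            continue
        target = M[i][j]
        paired = False
        for k in range(i + h + 1, j + 1):
            if _pairable(seq[i], seq[k]):
                left = M[i + 1][k - 1] if k - 1 > i else 0
                right = M[k + 1][j] if k + 1 <= j else 0
                if 1 + left + right == target:
                    pairs.append((i, k))
                    stack.append((i + 1, k - 1))
                    stack.append((k + 1, j))
                    paired = True
                    break
        if not paired:
            stack.append((i + 1, j))
    return pairs


def _fold_external(seq: str, cmd: str) -> str:
    if shutil.which(cmd) is None:
        raise RuntimeError(f"external folding backend {cmd!r} not found on PATH")
    out = subprocess.run(
        [cmd, "--noPS"], input=seq + "\n", capture_output=True, text=True, check=True
    ).stdout
    # second line: "<structure> (<energy>)"
    structure = out.splitlines()[1].split()[0]
    return structure


def fold(seq: str, config: RNAFoldConfig | None = None) -> SecondaryStructure:
    """Fold one sequence; raises on characters outside AUGC."""
    if config is None:
        config = RNAFoldConfig()
    if set(seq) - set(RNA_ALPHABET):
        raise ValueError(f"sequence {seq!r} has characters outside {RNA_ALPHABET}")
    if config.backend == "external":
        return SecondaryStructure(_fold_external(seq, config.external_cmd))
    h = config.hairpin_min
    if len(seq) <= h + 1:
        return SecondaryStructure("." * len(seq))
    M = _max_pairs_table(seq, h)
    pairs = _traceback(seq, M, h)
    return SecondaryStructure(render_dotbracket(pairs, len(seq)))


def max_pairs(seq: str, hairpin_min: int = 3) -> int:
    """Maximum number of allowed pairs (the toy DP optimum)."""
    if len(seq) <= hairpin_min + 1:
        return 0
    return _max_pairs_table(seq, hairpin_min)[0][len(seq) - 1]


def build_rna_map(
    L: int,
    config: RNAFoldConfig | None = None,
    guard_L: int = 12,
    allow_large: bool = False,
) -> GPMap:
    """Complete GP map over all 4^L sequences; phenotype = dot-bracket string.

    The deleterious label is the all-dot structure.  Spaces beyond the
    guard must be built through sampled-mode oracles instead.
    """
    if L > guard_L and not allow_large:
        raise GuardError(f"4^{L} sequences exceed the default guard (L <= {guard_L})")
    if config is None:
        config = RNAFoldConfig()
    space = GenotypeSpace(alphabet=RNA_ALPHABET, L=L)
    del_label = "." * L
    assignment = {}
    for r in range(space.n_genotypes):
        g = space.genotype(r)
        assignment[g] = fold(g, config).dotbracket
    return GPMap.from_assignment(space, assignment, del_label=del_label)


def rna_oracle(config: RNAFoldConfig | None = None):
    """Phenotype oracle ``seq -> dot-bracket`` for sampled-mode maps."""
    cfg = config or RNAFoldConfig()
    return lru_cache(maxsize=1 << 16)(lambda seq: fold(seq, cfg).dotbracket)
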