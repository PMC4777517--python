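"""Correlation statistics for GP maps.

Quantifies how a map departs from its frequency-matched random null:

* **Neutral correlations** — phenotype robustness ``rho_p`` (mean
  fraction of a genotype's (K-1)L single-mutant neighbours sharing its
  phenotype, averaged over the neutral set G_p; null value f_p), its
  generalisation to exact Hamming-distance-n shells (``n``-robustness),
  and the neutral correlation length ``n*``: the smallest radius at which
  the statistic drops strictly below its null value.
* **Phenotype mutation probabilities** ``phi_qp`` — the probability that
  a random point mutation of a random member of G_p yields phenotype q;
  the diagonal is the robustness, columns sum to one, and the null value
  is f_q for q frequent enough to be sampled (f_q > gamma).
* **Local over-representation** — the conditional distribution of the
  number of occurrences m of a phenotype q in a 1-mutation
  neighbourhood, given q occurs at least once, versus binomial nulls
  built from f_q (P1) and phi_qp (P2).
* **Neighbourhood similarity** — the Bhattacharyya coefficient between
  the local phenotype distributions of two neutral neighbours, relative
  to that of a non-neighbouring neutral pair (ratio > 1: neighbourhoods
  of neutral neighbours are more alike than chance).
* **Deleterious correlations** — the ratio phi_del,p / f_del per folding
  or assembling phenotype (below 1: the dead-end phenotype is avoided in
  their neighbourhoods), plus rho_del / f_del.

Exact mode walks the whole neutral set; sampled mode draws members
uniformly (by rejection from the full space, or by neutral random walks
with a burn-in of 10 L accepted neutral steps when the phenotype is
rare) and reports standard errors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .nullmodel import null_overrep_curve, thresholds
from .space import GPMap, PhenotypeTable, mutant_shell, shell_size, tabulate

__all__ = [
    "RobustnessResult",
    "NRobustnessCurve",
    "PhiMatrix",
    "OverrepDistribution",
    "SimilaritySample",
    "robustness",
    "robustness_all",
    "n_robustness",
    "average_n_robustness",
    "phi_matrix",
    "overrep",
    "neighbourhood_similarity",
    "deleterious_correlation",
    "sample_neutral_members",
]


# ---------------------------------------------------------------------------
# shared plumbing


def _neutral_counts_matrix(gpmap: GPMap, chunk: int = 1 << 14) -> np.ndarray:
    """M[q, p] = sum over g in G_p of n_{q,g}, streamed over the whole map."""
    gpmap.require_complete("exact phi counts")
    NP = len(gpmap.labels)
    M = np.zeros((NP, NP), dtype=np.int64)
    space = gpmap.space
    codes = gpmap.codes
    for lo in range(0, space.n_genotypes, chunk):
        ranks = np.arange(lo, min(lo + chunk, space.n_genotypes), dtype=np.int64)
        nbr = space.neighbour_ranks(ranks)
        pc = codes[ranks]
        qc = codes[nbr]
        np.add.at(M, (qc.ravel(), np.repeat(pc, nbr.shape[1])), 1)
    return M


def sample_neutral_members(
    gpmap: GPMap,
    p: str,
    n: int,
    seed: int | np.random.Generator | None = None,
    method: str = "auto",
    max_tries: int = 2_000_000,
) -> list[str]:
    """Draw ``n`` members of G_p for sampled-mode statistics.

    ``search`` rejects uniform genotype draws until they map to ``p``
    (exactly uniform; practical when f_p is not tiny).  ``walk`` runs a
    neutral random walk from a found member with a burn-in of ``10*L``
    accepted neutral steps between samples (approximately uniform; used
    automatically when rejection stalls).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    space = gpmap.space
    if gpmap.mode == "complete":
        ranks = gpmap.neutral_set(p).ranks
        if len(ranks) == 0:
            raise ValueError(f"empty neutral set for {p!r}")
        pick = rng.integers(len(ranks), size=n)
        return [space.genotype(int(ranks[i])) for i in pick]

    out: list[str] = []
    tries = 0
    if method in ("auto", "search"):
        while len(out) < n and tries < max_tries:
            g = space.genotype(int(rng.integers(space.n_genotypes)))
            tries += 1
            if gpmap.phenotype(g) == p:
                out.append(g)
            if method == "auto" and tries > 50_000 and not out:
                break
        if len(out) == n:
            return out
        if method == "search":
            raise RuntimeError(f"rejection sampling found only {len(out)}/{n} members of {p!r}")
    # neutral random walk from the last found member (or keep searching for one)
    current = out[-1] if out else None
    while current is None:
        g = space.genotype(int(rng.integers(space.n_genotypes)))
        tries += 1
        if tries > max_tries:
            raise RuntimeError(f"could not locate any member of {p!r}")
        if gpmap.phenotype(g) == p:
            current = g
    burn = 10 * space.L
    while len(out) < n:
        accepted = 0
        while accepted < burn:
            i = int(rng.integers(space.L))
            others = [c for c in space.alphabet if c != current[i]]
            c = others[int(rng.integers(len(others)))]
            cand = current[:i] + c + current[i + 1 :]
            if gpmap.phenotype(cand) == p:
                current = cand
                accepted += 1
        out.append(current)
    return out


def _neighbour_code_counts(gpmap: GPMap, g: str) -> dict[str, int]:
    """Phenotype counts over the (K-1)L neighbourhood of one genotype."""
    space = gpmap.space
    counts: dict[str, int] = {}
    if gpmap.mode == "complete":
        nbr = space.neighbour_ranks(np.array([space.rank(g)]))[0]
        for q in gpmap.codes[nbr]:
            lab = gpmap.labels[int(q)]
            counts[lab] = counts.get(lab, 0) + 1
        return counts
    for i in range(space.L):
        for c in space.alphabet:
            if c != g[i]:
                lab = gpmap.phenotype(g[:i] + c + g[i + 1 :])
                counts[lab] = counts.get(lab, 0) + 1
    return counts


# ---------------------------------------------------------------------------
# robustness


@dataclass
class RobustnessResult:
    phenotype: str
    rho: float
    f_p: float | None  # null column (complete maps)
    mode: str
    n_genotypes_used: int
    se: float | None = None


def robustness(
    gpmap: GPMap,
    p: str,
    mode: str = "exact",
    sample_size: int = 1000,
    seed: int | None = None,
) -> RobustnessResult:
    """Phenotype robustness rho_p, exactly or by neutral-set sampling."""
    space = gpmap.space
    D = space.n_neighbours
    if mode == "exact":
        members = gpmap.neutral_set(p).ranks
        if len(members) == 0:
            raise ValueError(f"empty neutral set for {p!r}")
        code = gpmap.code_of(p)
        total = 0
        for lo in range(0, len(members), 1 << 14):
            block = members[lo : lo + (1 << 14)]
            nbr = space.neighbour_ranks(block)
            total += int((gpmap.codes[nbr] == code).sum())
        rho = total / (len(members) * D)
        f_p = len(members) / space.n_genotypes
        return RobustnessResult(p, rho, f_p, "exact", len(members))
    if mode != "sampled":
        raise ValueError(f"unknown mode {mode!r}")
    rng = np.random.default_rng(seed)
    members = sample_neutral_members(gpmap, p, sample_size, seed=rng)
    fracs = np.empty(len(members))
    for i, g in enumerate(members):
        counts = _neighbour_code_counts(gpmap, g)
        fracs[i] = counts.get(p, 0) / D
    f_p = None
    if gpmap.mode == "complete":
        f_p = gpmap.neutral_set(p).size / space.n_genotypes
    return RobustnessResult(
        p,
        float(fracs.mean()),
        f_p,
        "sampled",
        len(members),
        se=float(fracs.std(ddof=1) / math.sqrt(len(fracs))) if len(fracs) > 1 else None,
    )


def robustness_all(gpmap: GPMap) -> pd.DataFrame:
    """Exact rho_p for every phenotype of a complete map, with the null column f_p."""
    M = _neutral_counts_matrix(gpmap)
    table = np.bincount(gpmap.codes, minlength=len(gpmap.labels)).astype(np.int64)
    D = gpmap.space.n_neighbours
    rho = np.diag(M) / (table * D)
    return pd.DataFrame(
        {
            "phenotype": gpmap.labels,
            "F_p": table,
            "f_p": table / gpmap.space.n_genotypes,
            "rho": rho,
        }
    )


# ---------------------------------------------------------------------------
# n-robustness


@dataclass
class NRobustnessCurve:
    phenotype: str | None  # None for the map-level average
    radii: np.ndarray
    rho_n: np.ndarray
    null: float  # f_p (phenotype) or 1/N_P (map level)
    se: np.ndarray | None = None
    n_star: int | None = None  # smallest n with rho^(n) strictly below the null

    def as_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"n": self.radii, "rho_n": self.rho_n, "null": self.null})
        if self.se is not None:
            df["se"] = self.se
        return df


def _first_crossing(radii: np.ndarray, rho_n: np.ndarray, null: float) -> int | None:
    below = rho_n < null
    idx = np.flatnonzero(below)
    return int(radii[idx[0]]) if len(idx) else None


def n_robustness(
    gpmap: GPMap,
    p: str,
    n_max: int | None = None,
    genotype_sample: int | str = 100,
    shell_sample: int = 500,
    seed: int | None = None,
    exact_shell_limit: int = 20_000,
) -> NRobustnessCurve:
    """rho_p^(n) over radii 1..n_max with the null line f_p and the crossing n*.

    Shells with at most ``exact_shell_limit`` genotypes are enumerated
    exactly; larger shells are Monte-Carlo sampled with ``shell_sample``
    uniform draws per genotype.  ``genotype_sample="all"`` uses the whole
    neutral set (complete maps).
    """
    space = gpmap.space
    if n_max is None:
        n_max = space.L
    if n_max > space.L:
        raise ValueError(f"n_max={n_max} exceeds L={space.L}")
    rng = np.random.default_rng(seed)
    if genotype_sample == "all":
        gpmap.require_complete("exhaustive neutral-set traversal")
        members = [space.genotype(int(r)) for r in gpmap.neutral_set(p).ranks]
    else:
        members = sample_neutral_members(gpmap, p, int(genotype_sample), seed=rng)
    if gpmap.mode == "complete":
        f_p = gpmap.neutral_set(p).size / space.n_genotypes
    else:
        f_p = None

    radii = np.arange(1, n_max + 1)
    per_g = np.empty((len(members), n_max))
    for gi, g in enumerate(members):
        for ni, n in enumerate(radii):
            if shell_size(space, int(n)) <= exact_shell_limit:
                shell = mutant_shell(g, int(n), space, "all")
            else:
                shell = mutant_shell(g, int(n), space, shell_sample, seed=rng)
            same = sum(1 for h in shell if gpmap.phenotype(h) == p)
            per_g[gi, ni] = same / len(shell)
    rho_n = per_g.mean(axis=0)
    se = per_g.std(axis=0, ddof=1) / math.sqrt(len(members)) if len(members) > 1 else None
    n_star = _first_crossing(radii, rho_n, f_p) if f_p is not None else None
    return NRobustnessCurve(p, radii, rho_n, f_p if f_p is not None else np.nan, se, n_star)


def average_n_robustness(
    gpmap: GPMap,
    n_max: int | None = None,
    phenotype_panel: list[str] | None = None,
    genotype_sample: int | str = 100,
    shell_sample: int = 500,
    seed: int | None = None,
    exact_shell_limit: int = 20_000,
) -> NRobustnessCurve:
    """Map-level <rho^(n)>: the mean of rho_p^(n) over phenotypes, null 1/N_P.

    ``phenotype_panel`` restricts the average to a subset (e.g. a random
    sample of phenotypes for maps with very many); the null line is
    always 1/N_P of the full map.
    """
    table = tabulate(gpmap)
    panel = phenotype_panel if phenotype_panel is not None else list(table.labels)
    rng = np.random.default_rng(seed)
    curves = []
    for p in panel:
        curves.append(
            n_robustness(
                gpmap,
                p,
                n_max=n_max,
                genotype_sample=genotype_sample,
                shell_sample=shell_sample,
                seed=int(rng.integers(2**31)),
                exact_shell_limit=exact_shell_limit,
            )
        )
    radii = curves[0].radii
    stack = np.vstack([c.rho_n for c in curves])
    avg = stack.mean(axis=0)
    se = stack.std(axis=0, ddof=1) / math.sqrt(len(curves)) if len(curves) > 1 else None
    null = 1.0 / table.n_phenotypes
    return NRobustnessCurve(None, radii, avg, null, se, _first_crossing(radii, avg, null))


# ---------------------------------------------------------------------------
# phenotype mutation probabilities


@dataclass
class PhiMatrix:
    """phi_qp columns over a phenotype panel; diagonal entries are rho_p."""

    labels: list[str]  # all phenotypes q (rows)
    panel: list[str]  # phenotypes p (columns)
    phi: np.ndarray  # (len(labels), len(panel))
    f_q: np.ndarray
    gamma: np.ndarray  # per column p
    mode: str
    se: np.ndarray | None = None

    def column(self, p: str) -> pd.DataFrame:
        j = self.panel.index(p)
        return pd.DataFrame({"q": self.labels, "phi_qp": self.phi[:, j], "f_q": self.f_q})

    def phi_qp(self, q: str, p: str) -> float:
        return float(self.phi[self.labels.index(q), self.panel.index(p)])

    def unreachable(self, p: str) -> list[str]:
        """Phenotypes q with phi_qp = 0 (never found around G_p)."""
        j = self.panel.index(p)
        return [q for q, v in zip(self.labels, self.phi[:, j]) if v == 0.0]

    def spearman(self, p: str) -> tuple[float, float]:
        """Spearman rank correlation of phi_qp vs f_q over q with f_q > gamma."""
        j = self.panel.index(p)
        keep = self.f_q > self.gamma[j]
        if keep.sum() < 3:
            return float("nan"), float("nan")
        r, pv = sps.spearmanr(self.phi[keep, j], self.f_q[keep])
        return float(r), float(pv)


def phi_matrix(
    gpmap: GPMap,
    phenotype_panel: list[str] | None = None,
    mode: str = "exact",
    sample_size: int = 1000,
    seed: int | None = None,
) -> PhiMatrix:
    """Phenotype mutation probabilities phi_qp for columns p in the panel.

    Exact mode streams every genotype of a complete map; sampled mode
    averages neighbourhood compositions over ``sample_size`` members of
    each G_p.  Columns are normalised probabilities (exact mode: sums are
    exactly one).
    """
    if mode == "exact":
        M = _neutral_counts_matrix(gpmap)
        counts = np.bincount(gpmap.codes, minlength=len(gpmap.labels)).astype(np.int64)
        D = gpmap.space.n_neighbours
        labels = list(gpmap.labels)
        panel = phenotype_panel if phenotype_panel is not None else labels
        cols = [labels.index(p) for p in panel]
        phi = M[:, cols] / (counts[cols] * D)
        f_q = counts / gpmap.space.n_genotypes
        gam = np.array(
            [thresholds(gpmap.space.K, gpmap.space.L, int(counts[c])).gamma for c in cols]
        )
        return PhiMatrix(labels, list(panel), phi, f_q, gam, "exact")
    if mode != "sampled":
        raise ValueError(f"unknown mode {mode!r}")
    if phenotype_panel is None:
        raise ValueError("sampled mode needs an explicit phenotype panel")
    rng = np.random.default_rng(seed)
    D = gpmap.space.n_neighbours
    col_counts: list[dict[str, int]] = []
    totals = []
    for p in phenotype_panel:
        members = sample_neutral_members(gpmap, p, sample_size, seed=rng)
        agg: dict[str, int] = {}
        for g in members:
            for q, c in _neighbour_code_counts(gpmap, g).items():
                agg[q] = agg.get(q, 0) + c
        col_counts.append(agg)
        totals.append(len(members) * D)
    labels = sorted({q for agg in col_counts for q in agg})
    phi = np.zeros((len(labels), len(phenotype_panel)))
    se = np.zeros_like(phi)
    for j, (agg, tot) in enumerate(zip(col_counts, totals)):
        for i, q in enumerate(labels):
            est = agg.get(q, 0) / tot
            phi[i, j] = est
            se[i, j] = math.sqrt(est * (1 - est) / tot)
    f_q = np.full(len(labels), np.nan)
    gam = np.full(len(phenotype_panel), np.nan)
    if gpmap.mode == "complete":
        table = tabulate(gpmap)
        fmap = dict(zip(table.labels, table.frequencies))
        cmap = dict(zip(table.labels, table.counts))
        f_q = np.array([fmap.get(q, 0.0) for q in labels])
        gam = np.array(
            [
                thresholds(gpmap.space.K, gpmap.space.L, int(cmap[p])).gamma
                for p in phenotype_panel
            ]
        )
    return PhiMatrix(labels, list(phenotype_panel), phi, f_q, gam, "sampled", se)


def _largest_non_del_panel(table: PhenotypeTable, exclude: set[str], n: int) -> list[str]:
    """The n largest phenotypes by redundancy, excluding del and ``exclude``."""
    order = np.argsort(-table.counts, kind="stable")
    panel = []
    for i in order:
        p = table.labels[i]
        if p in exclude or p == table.del_label:
            continue
        panel.append(p)
        if len(panel) == n:
            break
    return panel


# ---------------------------------------------------------------------------
# local over-representation


@dataclass
class OverrepDistribution:
    """Conditional occurrence distribution P(q, p, m) and its binomial nulls."""

    q: str
    panel: list[str]
    m: np.ndarray  # support 1..(K-1)L
    P: np.ndarray  # panel-averaged observed distribution
    P1: np.ndarray  # null from f_q
    P2: np.ndarray  # panel-averaged null from phi_qp
    n_conditioned: int  # neighbourhoods where q appeared at least once
    p_at_least_once: float = float("nan")  # panel-averaged P(m >= 1)
    status: str = "ok"  # "empty" when the conditioning event never sampled

    @property
    def mean(self) -> float:
        return float((self.m * self.P).sum()) if self.status == "ok" else float("nan")

    @property
    def mean_P1(self) -> float:
        return float((self.m * self.P1).sum())

    @property
    def mean_P2(self) -> float:
        return float((self.m * self.P2).sum())


def at_least_once_null(phi_qp: float, K: int, L: int) -> float:
    """Null probability that q appears at least once in a neighbourhood."""
    return 1.0 - (1.0 - phi_qp) ** ((K - 1) * L)


def overrep(
    gpmap: GPMap,
    q: str,
    phenotype_panel: list[str] | None = None,
    panel_size: int = 10,
    n_neigh_samples: int = 10_000,
    seed: int | None = None,
) -> OverrepDistribution:
    """Local over-representation of phenotype ``q`` around other phenotypes.

    For each panel phenotype p (default: the ``panel_size`` largest
    non-deleterious phenotypes, excluding q itself), samples
    ``n_neigh_samples`` neighbourhoods of members of G_p and conditions
    on q occurring.  The conditioning is *size-biased* — each sampled
    neighbourhood contributes with weight m, equivalent to drawing a
    uniform (genotype, neighbour-mapping-to-q) pair — which is the
    conditioning under which the binomial nulls are exact for the random
    map.  Nulls: P1 from the global f_q, P2 from the panel phi_qp; the
    unweighted fraction of neighbourhoods containing q at least once is
    reported as ``p_at_least_once`` (null: 1 - (1 - phi_qp)^((K-1)L)).
    """
    space = gpmap.space
    K, L = space.K, space.L
    D = space.n_neighbours
    table = tabulate(gpmap) if gpmap.mode == "complete" else None
    if phenotype_panel is None:
        if table is None:
            raise ValueError("sampled-mode maps need an explicit phenotype panel")
        phenotype_panel = _largest_non_del_panel(table, {q}, panel_size)
    if not phenotype_panel:
        raise ValueError("empty phenotype panel")
    if table is not None and q not in table.labels:
        raise ValueError(f"phenotype {q!r} not present in the map")
    rng = np.random.default_rng(seed)
    m_support = np.arange(1, D + 1)
    dists = []
    phis = []
    at_least_once = []
    n_cond_total = 0
    for p in phenotype_panel:
        members = sample_neutral_members(gpmap, p, n_neigh_samples, seed=rng)
        weighted = np.zeros(D + 1, dtype=np.int64)
        n_hit = 0
        q_total = 0
        for g in members:
            m = _neighbour_code_counts(gpmap, g).get(q, 0)
            q_total += m
            if m >= 1:
                weighted[m] += m  # size-biased conditioning
                n_hit += 1
        phis.append(q_total / (len(members) * D))
        at_least_once.append(n_hit / len(members))
        if weighted.sum() > 0:
            dists.append(weighted[1:] / weighted.sum())
            n_cond_total += n_hit
    f_q = table.frequency(q) if table is not None else None
    P1 = null_overrep_curve(f_q, K, L) if f_q is not None else np.full(D, np.nan)
    P2 = np.vstack([null_overrep_curve(phi, K, L) for phi in phis]).mean(axis=0)
    p_once = float(np.mean(at_least_once))
    if not dists:
        return OverrepDistribution(
            q, list(phenotype_panel), m_support, np.zeros(D), P1, P2, 0, p_once, status="empty"
        )
    P = np.vstack(dists).mean(axis=0)
    return OverrepDistribution(q, list(phenotype_panel), m_support, P, P1, P2, n_cond_total, p_once)


# ---------------------------------------------------------------------------
# neighbourhood similarity


def _bhattacharyya(x: np.ndarray, y: np.ndarray) -> float:
    return float(np.sqrt(x * y).sum())


@dataclass
class SimilaritySample:
    """Bhattacharyya similarity of neutral-neighbour vs non-neighbour neighbourhoods."""

    phenotype: str
    bc_gh: np.ndarray  # per completed draw
    bc_gg2: np.ndarray
    n_zero_bc: int  # draws where either BC was zero
    status: str = "ok"

    @property
    def ratios(self) -> np.ndarray:
        """BC(g,h)/BC(g,g2) over draws with a nonzero denominator."""
        keep = self.bc_gg2 > 0
        return self.bc_gh[keep] / self.bc_gg2[keep]

    @property
    def mean(self) -> float:
        """Mean ratio over all draws with a nonzero denominator."""
        r = self.ratios
        return float(r.mean()) if len(r) else float("nan")

    @property
    def se(self) -> float:
        r = self.ratios
        if len(r) < 2:
            return float("nan")
        return float(r.std(ddof=1) / math.sqrt(len(r)))

    @property
    def mean_nonzero(self) -> float:
        """Mean ratio restricted to draws where both coefficients were nonzero."""
        keep = (self.bc_gg2 > 0) & (self.bc_gh > 0)
        r = self.bc_gh[keep] / self.bc_gg2[keep]
        return float(r.mean()) if len(r) else float("nan")


def neighbourhood_similarity(
    gpmap: GPMap,
    p: str,
    n_samples: int = 1000,
    seed: int | None = None,
    include_del: bool = True,
    matched_control: bool = True,
    max_redraws: int = 200,
) -> SimilaritySample:
    """Similarity ratio BC(g, h) / BC(g, g2) over neutral triples of G_p.

    Per draw: g uniform in G_p; h uniform among g's neutral neighbours
    (g redrawn if it has none); g2 uniform in G_p excluding g and its
    neighbours.  Local distributions are the neighbourhood phenotype
    frequencies; for the (g, h) pair the K-2 mutual neighbours at the
    differing locus are removed from both distributions (they contribute
    identical counts to both, a trivial similarity).  With
    ``matched_control=True`` (default) the control pair's distributions
    likewise drop K-2 neighbours, chosen at a random locus, so both
    Bhattacharyya coefficients are estimated from the same number of
    counts and share the same small-sample bias; ``False`` reproduces
    the raw convention (full neighbourhoods for the control pair), whose
    ratio sits slightly below one even on uncorrelated maps.  With
    ``include_del=False`` the deleterious phenotype is dropped as a
    category (both distributions renormalised).
    """
    gpmap.require_complete("similarity sampling (needs the neutral set)")
    space = gpmap.space
    members = gpmap.neutral_set(p).ranks
    if len(members) < 3:
        raise ValueError(f"need F_p >= 3, got {len(members)}")
    code = gpmap.code_of(p)
    rng = np.random.default_rng(seed)

    def local_counts(g: str, exclude: set[str]) -> dict[str, int]:
        counts: dict[str, int] = {}
        for i in range(space.L):
            for c in space.alphabet:
                if c == g[i]:
                    continue
                h = g[:i] + c + g[i + 1 :]
                if h in exclude:
                    continue
                lab = gpmap.phenotype(h)
                counts[lab] = counts.get(lab, 0) + 1
        return counts

    def to_dist(counts: dict[str, int], cats: list[str]) -> np.ndarray:
        v = np.array([counts.get(c, 0) for c in cats], dtype=float)
        tot = v.sum()
        return v / tot if tot > 0 else v

    bcs_gh, bcs_gg2 = [], []
    n_zero = 0
    n_no_edge = 0
    for _ in range(n_samples):
        g = h = None
        for _ in range(max_redraws):
            gr = int(members[rng.integers(len(members))])
            g_str = space.genotype(gr)
            nbr = space.neighbour_ranks(np.array([gr]))[0]
            neutral = nbr[gpmap.codes[nbr] == code]
            if len(neutral):
                g = g_str
                h = space.genotype(int(neutral[rng.integers(len(neutral))]))
                break
        if g is None:
            n_no_edge += 1
            continue
        # g2: uniform member excluding g and its neighbours (rejection; the
        # excluded set has at most (K-1)L + 1 elements)
        excluded = {gr} | {int(x) for x in nbr}
        g2 = None
        for _ in range(max_redraws):
            cand = int(members[rng.integers(len(members))])
            if cand not in excluded:
                g2 = space.genotype(cand)
                break
        if g2 is None:
            continue
        # locus where g and h differ; the K-2 mutual neighbours live there
        locus = next(i for i in range(space.L) if g[i] != h[i])
        mutual = {
            g[:locus] + c + g[locus + 1 :]
            for c in space.alphabet
            if c not in (g[locus], h[locus])
        }
        cg = local_counts(g, mutual)
        ch = local_counts(h, mutual)
        if matched_control and space.K > 2:
            # drop K-2 neighbours at a random locus from each control
            # distribution so both BCs average over equally many counts
            def random_drop(x: str) -> set[str]:
                loc = int(rng.integers(space.L))
                others = [c for c in space.alphabet if c != x[loc]]
                keep = others[int(rng.integers(len(others)))]
                return {
                    x[:loc] + c + x[loc + 1 :] for c in others if c != keep
                }

            cg_full = local_counts(g, random_drop(g))
            cg2 = local_counts(g2, random_drop(g2))
        else:
            cg_full = local_counts(g, set())
            cg2 = local_counts(g2, set())
        if not include_del and gpmap.del_label is not None:
            for d in (cg, ch, cg_full, cg2):
                d.pop(gpmap.del_label, None)
        cats = sorted(set(cg) | set(ch) | set(cg_full) | set(cg2))
        bc_gh = _bhattacharyya(to_dist(cg, cats), to_dist(ch, cats))
        bc_gg2 = _bhattacharyya(to_dist(cg_full, cats), to_dist(cg2, cats))
        bcs_gh.append(bc_gh)
        bcs_gg2.append(bc_gg2)
        if bc_gg2 == 0 or bc_gh == 0:
            n_zero += 1
    if not bcs_gh:
        return SimilaritySample(
            p, np.array([]), np.array([]), n_zero, status="no-neutral-edges"
        )
    return SimilaritySample(p, np.array(bcs_gh), np.array(bcs_gg2), n_zero)


# ---------------------------------------------------------------------------
# deleterious correlations


def deleterious_correlation(
    gpmap: GPMap, phenotype_panel: list[str] | None = None
) -> tuple[pd.DataFrame, float]:
    """Per-phenotype ratio phi_del,p / f_del, and rho_del / f_del.

    Ratios below one mean the deleterious phenotype is found less often
    around folding/assembling phenotypes than its global frequency
    predicts; rho_del / f_del above one is the mirror-image
    over-representation of del around itself.
    """
    if gpmap.del_label is None:
        raise ValueError("map has no deleterious phenotype defined")
    gpmap.require_complete("deleterious correlation (exact phi column)")
    table = tabulate(gpmap)
    f_del = table.frequency(gpmap.del_label)
    panel = (
        phenotype_panel
        if phenotype_panel is not None
        else [p for p in table.labels if p != gpmap.del_label]
    )
    pm = phi_matrix(gpmap, phenotype_panel=panel + [gpmap.del_label], mode="exact")
    rows = []
    for p in panel:
        rows.append(
            {
                "phenotype": p,
                "f_p": table.frequency(p),
                "phi_del_p": pm.phi_qp(gpmap.del_label, p),
                "ratio": pm.phi_qp(gpmap.del_label, p) / f_del,
            }
        )
    rho_del = pm.phi_qp(gpmap.del_label, gpmap.del_label)
    return pd.DataFrame(rows), rho_del / f_del
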