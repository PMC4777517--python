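# Methods

`gpcorr` quantifies *genetic correlations* in genotype–phenotype (GP)
maps: the ways in which the mutational neighbourhood of a genotype
differs from what a frequency-matched random assignment of phenotypes
would predict. This note records the models, the estimators, the
numerical conventions, and the design choices that were genuinely open.

## The genotype space and the null model

All maps live on the Hamming graph H(L, K): strings of length L over an
ordered K-letter alphabet, with edges between strings differing at one
position, so every genotype has D = (K−1)L point-mutation neighbours.
Only point mutations are considered — no indels, recombination or
fitness.

The null model keeps the entire phenotype frequency spectrum {F_p} of a
source map and redistributes the genotypes uniformly: a seeded PCG64
permutation of the K^L ranks is sliced into consecutive blocks of sizes
F_p, so each redundancy is preserved *exactly* and the realisation is
bit-reproducible from its 64-bit seed. Under this null every statistic
has a closed form: robustness ρ_p = f_p, n-robustness ρ_p^(n) = f_p at
every radius, map average ⟨ρ^(n)⟩ = 1/N_P, and mutation probabilities
φ_qp = f_q for phenotypes frequent enough to be sampled.

Three thresholds summarise percolation on H(L, K) under random
assignment (mean-field):

* δ = 1/((K−1)L) — giant-component onset: above it a phenotype's
  neutral set develops large connected components;
* λ = 1 − (1/K)^(1/(K−1)) — single-component onset, independent of L
  (0.5 at K=2, ≈0.37 at K=4, ≈0.12 at K=26);
* γ = 1/(F_p(K−1)L) — sampling threshold: phenotypes with f_q below γ
  may not appear at all around G_p, so φ_qp = 0 is then uninformative.

## Model engines

**HP lattice proteins.** Binary H/P chains on the square lattice with
contact energies E_HH = −1, E_HP = E_PP = 0; a contact is a
chain-non-adjacent (|i−j| ≥ 3), lattice-adjacent residue pair. A
sequence's phenotype is the *unique* minimum-energy fold; ties across
symmetry-distinct folds mean the chain does not fold and map to `del`.
Fold identity is the dihedral class (translations, 4 rotations,
reflection) with residue 1 distinguished; the canonical id is the
lexicographically minimal coordinate string over the 8 images after
translating the minimum corner to the origin. Non-compact enumeration
fixes the first step along +x and the first turn to +y, which yields
exactly one representative per class (4-residue chains: 36 directed
walks in 5 classes — straight, two L-bends, zigzag, U-bend — of which
only the U-bend has a contact). Compact mode enumerates Hamiltonian
paths of the W×W grid and deduplicates by canonical id. Whole-map
assignment is vectorised: per fold, a contact-sum energy over all 2^L
sequences, streaming minimum/argmin/degeneracy counters. Guards refuse
non-compact L > 20 and maps beyond 2^25 without an explicit override.

**Polyomino self-assembly.** A genotype of length 4·N_t over interface
labels 0..N_c−1 encodes N_t square tiles (edges written clockwise from
north). Labels interact in odd–even pairs (1↔2, 3↔4, 5↔6); 0 and 7 are
inert. Assembly seeds tile 1 at the origin in written orientation, then
repeatedly draws a uniformly random (perimeter cell, tile type,
rotation) triple, keeping the placement iff at least one edge facing an
occupied neighbour forms an interacting pair (mismatching facing pairs
are tolerated — there is no steric veto). After 50 consecutive
rejections an exhaustive attachability scan decides halting exactly, so
termination is deterministic rather than probabilistic. Structures
exceeding a size cap (default 16·N_t tiles) are declared unbounded. A
genotype maps to a shape only when `n_repeats` (default 20) independent
attempts — RNG streams seeded by (master seed, genotype rank, repeat) —
all terminate in the identical canonical shape; any unbounded run or
mismatch yields the undefined phenotype UND, the deleterious label.
Shape identity uses translations and the 4 rotations only: oriented
interface chirality makes mirror shapes physically distinct (a
`reflections` switch provides the sensitivity variant). Tile sets whose
labels admit no interacting pair are classified as monomers directly;
this shortcut is exact. The repeat count and cap are knobs because
published descriptions say only that assembly is attempted "several
times"; 20 repeats and 16·N_t are conservative and the classification
is stable to doubling both on the spaces we enumerate.

**RNA secondary structure.** The default *toy* backend maximises the
number of Watson–Crick + wobble pairs (AU, UA, GC, CG, GU, UG) with a
minimum hairpin loop of 3 unpaired bases, by a Nussinov-style O(L³)
dynamic program with a deterministic traceback (pair position i with
the smallest admissible j attaining the optimum; otherwise leave i
unpaired). The traceback structure is taken as the phenotype without a
degeneracy test — a deliberate divergence from thermodynamic folders,
documented here; the toy backend exists so that every statistic has a
fast, self-contained RNA-like engine, and it makes no claim to
reproduce thermodynamic phenotype counts. The *external* backend shells
out to an installed `RNAfold` binary and parses its dot-bracket output.
The deleterious phenotype is exactly the fully unpaired structure.

## Correlation statistics

* **Robustness** ρ_p: the mean, over the neutral set G_p, of the
  fraction of a genotype's D neighbours sharing its phenotype. Exact
  mode streams the whole map in vectorised rank chunks; sampled mode
  averages over uniform members with a binomial standard error.
* **n-robustness** ρ_p^(n): the same fraction over the exact
  Hamming-distance-n shell of size C(L,n)(K−1)^n. Shells up to 20,000
  genotypes (configurable) are enumerated; larger shells are sampled
  uniformly (n distinct positions, then a non-identical letter each).
  The **correlation length n\*** is the smallest radius at which the
  statistic falls *strictly* below its null (f_p per phenotype, 1/N_P
  for the map average); when no crossing occurs within n_max the length
  is reported as undefined rather than clamped. Sampled curves use the
  point estimate for the crossing, with standard errors reported
  alongside — the crossing definition predates any noise model, so we
  do not adjust it.
* **Phenotype mutation probabilities** φ_qp: column-normalised counts
  of neighbour phenotypes over G_p; diagonal entries are ρ_p and exact
  columns sum to one by construction. Per column we flag unreachable
  phenotypes (φ_qp = 0) and report the Spearman rank correlation of
  φ_qp against f_q restricted to q with f_q > γ.
* **Local over-representation**: the distribution of the number of
  occurrences m of a phenotype q in a single neighbourhood, conditioned
  on q occurring. The conditioning is *size-biased*: each sampled
  neighbourhood contributes with weight m, i.e. the sample is a uniform
  (genotype, neighbour-mapping-to-q) pair. This is the conditioning
  under which the binomial references P1 (rate f_q) and P2 (rate φ_qp)
  over the remaining D−1 neighbours are exact on the null model —
  plain at-least-once conditioning is *not* (its null mean is lower:
  Dφ/(1−(1−φ)^D) versus 1+(D−1)φ), so using it would make the null
  fail its own reference. The unweighted fraction of neighbourhoods
  containing q at all is reported separately with its null
  1−(1−φ_qp)^D. Panels default to the 10 largest non-deleterious
  phenotypes excluding q. A conditioning event that is never sampled
  returns an explicit empty status, not a crash.
* **Neighbourhood similarity**: for a neutral edge (g, h) and a
  non-neighbouring neutral control g2, the Bhattacharyya coefficient
  BC(x, y) = Σ_q √(x_q y_q) between local neighbourhood phenotype
  distributions, and the ratio BC(g,h)/BC(g,g2). The K−2 mutual
  neighbours of g and h (the other letters at their differing locus)
  are removed from both of their distributions, since they contribute
  identically to both by construction. By default the control pair's
  distributions also drop K−2 neighbours, at a random locus: the
  plug-in BC estimator is biased downwards by an amount that depends on
  the number of counts, so matching the denominators is required for
  the null ratio to centre on 1 (unmatched, it centres near 0.997 at
  K=4, L=10). The unmatched convention remains available
  (`matched_control=False`), and means both including and excluding
  zero-coefficient draws are reported, since either convention is
  defensible for sparse neighbourhoods.
* **Deleterious correlations**: the ratio φ_del,p/f_del per
  non-deleterious phenotype (below 1 when folding/assembling phenotypes
  avoid the dead-end phenotype) and ρ_del/f_del (above 1 when the
  dead-end set is over-connected to itself).

Neutral components are found with union-find (union-by-size, path
compression) over neutral Hamming-1 edges streamed position-major, so
runs are deterministic and the state is O(F_p) integers; a
breadth-first-search oracle cross-checks the decomposition in the test
suite. Component analysis requires a fully enumerated map: sampled-mode
maps cannot support it and are refused.

For sampled-mode maps, neutral-set members are drawn by rejection from
uniform genotypes when the phenotype is common; when rejection stalls,
a neutral random walk from a found member with a burn-in of 10·L
accepted steps between samples takes over. The walk is only
approximately uniform (it over-weights high-robustness regions); all
sampled results carry their seeds and sample sizes in metadata.

## Synthetic data

The generators define the study conditions for every test:

* **Random maps** realise an explicit or parametric spectrum
  (log-uniform frequencies over a stated number of decades, optional
  deleterious fraction; counts rounded to integers ≥ 1 with the total
  repaired on the largest phenotype) and delegate to the null model.
* **Correlated maps** plant known positive correlations while
  preserving the spectrum exactly. `hamming_ball` grows each phenotype
  from a random seed by uniform accretion over the unassigned frontier
  (smallest phenotypes first, so their balls are not fragmented by the
  remainder of larger ones); a `strength` parameter mixes in uniform
  jumps, with strength 0 reproducing the random map. `locus_block`
  sorts genotypes by their digits at a random subset of loci (default
  2) and slices by cumulative redundancy, scrambling a (1−strength)
  fraction of sort keys. With full strength the pure block construction
  makes all members of a phenotype share identical neighbourhood
  compositions, so similarity tests use strength ≈ 0.9.
* **The word game** maps length-4 strings over A–Z to valid/invalid
  according to any plain-text word list (case-folded; non-conforming
  lines ignored); invalid plays the deleterious role. A demo list of
  ~700 common four-letter words, written for this package, ships in
  `gpcorr/data/words4.txt` so the tests need no download. On it the
  valid phenotype has f ≈ 0.0016 and ρ ≈ 0.05, thirty-fold above the
  null — the direction, not the magnitude, is the reproducible claim,
  because both numbers depend on the dictionary used.

What the generators deliberately do not emulate: biophysical constraint
structure (e.g. the stem epistasis that fragments RNA neutral sets into
~2^n components), genotype spaces too large to enumerate, or realistic
phenotype counts. Tests passing on them show that the estimators
recover planted correlations and analytic nulls, not that any
particular biophysical map has a particular value.

## Problem sizes and numerics

Exhaustively enumerated spaces in the test suite are at most a few
times 10^5 genotypes (compact HP up to 4×4, toy RNA to L = 6, polyomino
S_2,2 and S_1,8, word game 26^4); ensemble checks use 20 seeds on
spaces of 10^3–10^5. The compact 5×5 HP map (2^25 sequences) and the
full S_2,8 classification (8^8 genotypes × 20 repeats) are supported by
the same code paths behind explicit override flags but are not part of
the default suite; they are multi-hour single-CPU enumerations.
Frequencies from complete maps are exact integer ratios; Monte-Carlo
estimates carry binomial standard errors; statistical assertions in the
tests use three-standard-error bands (with an allowance for the
expected rate of 3σ misses when many comparisons are made). All
randomness flows through `numpy.random.default_rng` with explicit
seeds; derived streams use seed sequences, never arithmetic on seeds.

## Known limitations

* The toy RNA folder's phenotypes are maximum-pairing structures; its
  counts and deleterious fractions are not comparable to thermodynamic
  folders, and no degeneracy test is applied to its traceback.
* The neutral-walk sampler for oracle maps is approximately uniform
  only; its bias is unquantified and grows as robustness varies
  strongly across a neutral set.
* Percolation thresholds are mean-field; on small L the transitions
  they locate are soft.
* The polyomino UND classification is stochastic evidence, not proof:
  a nondeterministic tile set can in principle pass `n_repeats`
  identical assemblies, with probability decreasing rapidly in the
  repeat count.
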