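"""Correlation statistics: exact identities, null recovery, positive controls."""

import math

import numpy as np
import pytest

from gpcorr.correlations import (
    at_least_once_null,
    average_n_robustness,
    deleterious_correlation,
    n_robustness,
    neighbourhood_similarity,
    overrep,
    phi_matrix,
    robustness,
    robustness_all,
    sample_neutral_members,
)
from gpcorr.hp import DEL_LABEL, HPModelConfig, build_hp_map
from gpcorr.space import GenotypeSpace, GPMap, tabulate
from gpcorr.synth import SpectrumSpec, generate_correlated_map, generate_random_map


class TestRobustness:
    def test_whole_space_phenotype(self):
        sp = GenotypeSpace("01", 5)
        m = GPMap(sp, codes=np.zeros(32, dtype=np.int32), labels=["p"])
        assert robustness(m, "p").rho == 1.0

    def test_hand_enumerated_pair(self):
        """G_p = {00, 01}: each member has 1 neutral of 2 neighbours."""
        sp = GenotypeSpace("01", 2)
        m = GPMap.from_assignment(sp, {"00": "p", "01": "p", "10": "q", "11": "q"})
        assert robustness(m, "p").rho == 0.5

    def test_empty_set_rejected(self, ball_map):
        with pytest.raises(KeyError):
            robustness(ball_map, "nope")

    def test_sampled_matches_exact(self, small_random_map):
        """Sampled-mode estimate converges to the exact value (3 SE)."""
        for p in small_random_map.labels:
            exact = robustness(small_random_map, p).rho
            est = robustness(small_random_map, p, mode="sampled", sample_size=800, seed=1)
            assert abs(est.rho - exact) <= 3 * est.se + 1e-9

    def test_robustness_all_matches_per_phenotype(self, small_random_map):
        df = robustness_all(small_random_map).set_index("phenotype")
        for p in small_random_map.labels:
            assert df.loc[p, "rho"] == pytest.approx(robustness(small_random_map, p).rho)


@pytest.fixture(scope="module", params=["random", "correlated", "hp3x3"])
def any_map(request):
    if request.param == "random":
        return generate_random_map(SpectrumSpec(K=4, L=5, n_phenotypes=4, decades=1.5), seed=2)
    if request.param == "correlated":
        return generate_correlated_map(SpectrumSpec(K=2, L=8, n_phenotypes=3, decades=1.0), seed=3)
    return build_hp_map(HPModelConfig(L=9, mode="compact", W=3))


class TestExactIdentities:
    """phi_pp = rho_p, column sums = 1, rho^(1) = rho — on every complete map."""

    def test_phi_identities(self, any_map):
        pm = phi_matrix(any_map, mode="exact")
        assert np.allclose(pm.phi.sum(axis=0), 1.0, atol=1e-12)
        rho = robustness_all(any_map).set_index("phenotype")["rho"]
        for p in pm.panel:
            assert pm.phi_qp(p, p) == pytest.approx(rho[p])

    def test_rho1_equals_robustness(self, any_map):
        table = tabulate(any_map)
        p = table.labels[int(np.argmax(table.counts))]
        curve = n_robustness(any_map, p, n_max=1, genotype_sample="all")
        assert curve.rho_n[0] == pytest.approx(robustness(any_map, p).rho)


class TestPhiMatrix:
    def test_single_locus_map(self):
        sp = GenotypeSpace("01", 1)
        m = GPMap.from_assignment(sp, {"0": "A", "1": "B"})
        pm = phi_matrix(m, mode="exact")
        assert pm.phi_qp("B", "A") == 1.0
        assert pm.phi_qp("A", "A") == 0.0

    def test_null_phi_tracks_frequency(self):
        """On random maps phi_qp = f_q within 3 SE for q above gamma."""
        spec = SpectrumSpec(K=4, L=6, n_phenotypes=5, decades=1.0)
        devs, total = 0, 0
        for seed in range(10):
            m = generate_random_map(spec, seed=seed)
            table = tabulate(m)
            p = table.labels[int(np.argmax(table.counts))]
            pm = phi_matrix(m, phenotype_panel=[p], mode="exact")
            F_p = table.count(p)
            n_trials = F_p * m.space.n_neighbours
            for q, f_q in zip(pm.labels, pm.f_q):
                if q == p or f_q <= pm.gamma[0]:
                    continue
                se = math.sqrt(f_q * (1 - f_q) / n_trials)
                total += 1
                if abs(pm.phi_qp(q, p) - f_q) > 3 * se:
                    devs += 1
        assert total >= 20
        assert devs <= max(1, int(0.05 * total))  # 3-sigma misses are rare

    def test_spearman_positive_on_null(self, random_map_k4):
        pm = phi_matrix(random_map_k4, mode="exact")
        r, pval = pm.spearman("p0")
        assert r > 0.9

    def test_unreachable_flagged(self, ball_map):
        pm = phi_matrix(ball_map, mode="exact")
        assert pm.unreachable("bg") == []  # both phenotypes touch

    def test_sampled_matches_exact(self, small_random_map):
        p = small_random_map.labels[0]
        exact = phi_matrix(small_random_map, phenotype_panel=[p], mode="exact")
        est = phi_matrix(
            small_random_map, phenotype_panel=[p], mode="sampled", sample_size=600, seed=4
        )
        for q in est.labels:
            i = est.labels.index(q)
            se = max(est.se[i, 0], 1e-6)
            assert abs(est.phi[i, 0] - exact.phi_qp(q, p)) <= 4 * se


class TestNRobustness:
    def test_whole_space_flat_at_one(self):
        sp = GenotypeSpace("01", 6)
        m = GPMap(sp, codes=np.zeros(64, dtype=np.int32), labels=["p"])
        curve = n_robustness(m, "p", n_max=6, genotype_sample="all")
        assert np.allclose(curve.rho_n, 1.0)
        assert curve.n_star is None  # never crosses the null

    def test_null_flat_at_frequency(self):
        """Random maps: rho^(n) ~ f_p at every radius."""
        spec = SpectrumSpec(K=2, L=10, counts=(307, 1024 - 307))
        m = generate_random_map(spec, seed=8)
        curve = n_robustness(m, "p0", n_max=8, genotype_sample="all")
        f = 307 / 1024
        se = np.sqrt(f * (1 - f) / 307)  # conservative per-radius error
        assert np.all(np.abs(curve.rho_n - f) <= 3 * se)

    def test_correlated_ball_decays_and_crosses(self, ball_map):
        curve = n_robustness(ball_map, "ball", n_max=10, genotype_sample="all")
        assert curve.rho_n[0] > curve.null  # rho > f: positive correlations
        assert curve.n_star is not None and curve.n_star > 1
        assert curve.rho_n[0] > curve.rho_n[5]

    def test_map_average_null(self, random_map_k4):
        curve = average_n_robustness(
            random_map_k4, n_max=4, genotype_sample=25, shell_sample=150, seed=0
        )
        assert curve.phenotype is None
        assert curve.null == pytest.approx(1 / 3)
        assert np.all(np.abs(curve.rho_n - curve.null) <= 0.05)

    def test_radius_beyond_length_rejected(self, ball_map):
        with pytest.raises(ValueError):
            n_robustness(ball_map, "ball", n_max=11)


class TestOverrep:
    def test_null_matches_P1(self, random_map_k4):
        o = overrep(
            random_map_k4, "p0", phenotype_panel=["p1"], n_neigh_samples=3000, seed=1
        )
        # size-biased mean of Binomial(24, 1/2) is 12.5; multinomial error
        assert abs(o.mean - o.mean_P1) <= 0.15
        assert o.P.sum() == pytest.approx(1.0, abs=1e-9)

    def test_ball_shifts_mass_upwards(self, ball_map):
        """q occupying a Hamming ball: every outside contact sees it 3 times."""
        o = overrep(ball_map, "ball", phenotype_panel=["bg"], n_neigh_samples=4000, seed=2)
        assert o.mean > o.mean_P1
        assert o.mean > o.mean_P2
        assert o.mean == pytest.approx(3.0)

    def test_at_least_once_identity_on_null(self, random_map_k4):
        o = overrep(
            random_map_k4, "p2", phenotype_panel=["p0"], n_neigh_samples=8000, seed=3
        )
        pm = phi_matrix(random_map_k4, phenotype_panel=["p0"], mode="exact")
        null = at_least_once_null(pm.phi_qp("p2", "p0"), 4, 8)
        se = math.sqrt(null * (1 - null) / 8000)
        assert abs(o.p_at_least_once - null) <= 4 * se

    def test_empty_conditioning_reported(self):
        """If q never appears around the panel, the result says so."""
        sp = GenotypeSpace("01", 6)
        dist = sp.digits(np.arange(64)).sum(axis=1)
        # q only at distance-6 corner, p only at the origin: never adjacent
        codes = np.where(dist == 0, 1, np.where(dist == 6, 2, 0)).astype(np.int32)
        m = GPMap(sp, codes=codes, labels=["bg", "p", "q"])
        o = overrep(m, "q", phenotype_panel=["p"], n_neigh_samples=200, seed=0)
        assert o.status == "empty"
        assert math.isnan(o.mean)

    def test_unknown_q_rejected(self, ball_map):
        with pytest.raises(ValueError):
            overrep(ball_map, "nope", phenotype_panel=["bg"], n_neigh_samples=10)


class TestSimilarity:
    def test_fully_neutral_map(self):
        sp = GenotypeSpace("01", 4)
        m = GPMap(sp, codes=np.zeros(16, dtype=np.int32), labels=["p"])
        sim = neighbourhood_similarity(m, "p", n_samples=50, seed=0)
        assert sim.mean == pytest.approx(1.0)
        assert np.allclose(sim.bc_gh, 1.0)

    def test_null_ratio_is_one(self):
        """Ensemble over seeds: mean BC ratio = 1 within 3 SE on random maps."""
        spec = SpectrumSpec(K=4, L=10, n_phenotypes=5, decades=1.0)
        means = []
        for seed in range(8):
            m = generate_random_map(spec, seed=seed)
            sim = neighbourhood_similarity(m, "p0", n_samples=300, seed=seed)
            means.append(sim.mean)
        grand = np.mean(means)
        se = np.std(means, ddof=1) / math.sqrt(len(means))
        assert abs(grand - 1.0) <= 3 * se + 0.003

    def test_correlated_map_ratio_above_one(self):
        m = generate_correlated_map(
            SpectrumSpec(K=4, L=8, n_phenotypes=6, decades=1.0),
            "hamming_ball",
            strength=1.0,
            seed=7,
        )
        sim = neighbourhood_similarity(m, "p1", n_samples=400, seed=1)
        assert sim.mean - 1.0 > 3 * sim.se

    def test_locus_block_ratio_above_one(self):
        m = generate_correlated_map(
            SpectrumSpec(K=2, L=10, counts=(256, 256, 256, 256)),
            "locus_block",
            strength=0.9,
            seed=5,
        )
        sim = neighbourhood_similarity(m, "p0", n_samples=400, seed=1)
        assert sim.mean - 1.0 > 3 * sim.se

    def test_small_set_rejected(self):
        sp = GenotypeSpace("01", 3)
        codes = np.zeros(8, dtype=np.int32)
        codes[0] = 1
        m = GPMap(sp, codes=codes, labels=["bg", "tiny"])
        with pytest.raises(ValueError):
            neighbourhood_similarity(m, "tiny", n_samples=5)

    def test_both_conventions_reported(self, ball_map):
        sim = neighbourhood_similarity(ball_map, "ball", n_samples=200, seed=3)
        assert np.isfinite(sim.mean) and np.isfinite(sim.mean_nonzero)


class TestDeleteriousCorrelation:
    def test_null_ratios_near_one(self):
        spec = SpectrumSpec(K=2, L=10, counts=(204, 308, 512), del_label="del")
        m = generate_random_map(spec, seed=6)
        df, rho_ratio = deleterious_correlation(m)
        f_del = 0.5
        for _, row in df.iterrows():
            F_p = int(row.f_p * 1024)
            se = math.sqrt(f_del * (1 - f_del) / (F_p * 10)) / f_del
            assert abs(row.ratio - 1.0) <= 3 * se
        assert abs(rho_ratio - 1.0) <= 0.05

    def test_del_hemisphere_avoided(self):
        """del occupying the 1***... hemisphere: phenotypes inside the other
        hemisphere reach del through only 1 of their 10 neighbours."""
        sp = GenotypeSpace("01", 10)
        first_bit = sp.digits(np.arange(1024))[:, 0]
        rest = np.arange(1024) % 2
        codes = np.where(first_bit == 1, 2, rest).astype(np.int32)
        m = GPMap(sp, codes=codes, labels=["a", "b", "del"], del_label="del")
        df, rho_ratio = deleterious_correlation(m)
        assert (df.ratio < 1).all()
        assert rho_ratio > 1.0

    def test_hp_map_del_underrepresented_around_folders(self):
        """Compact HP: folding phenotypes see del less often than f_del."""
        m = build_hp_map(HPModelConfig(L=16, mode="compact", W=4))
        df, rho_ratio = deleterious_correlation(m)
        assert df.ratio.mean() < 1.0
        assert rho_ratio > 1.0

    def test_missing_del_label(self, ball_map):
        with pytest.raises(ValueError):
            deleterious_correlation(ball_map)


class TestSampledMembers:
    def test_uniform_complete_mode(self, small_random_map):
        got = sample_neutral_members(small_random_map, "p0", 50, seed=0)
        assert len(got) == 50
        assert all(small_random_map.phenotype(g) == "p0" for g in got)

    def test_oracle_mode_walk(self):
        """Neutral-walk sampling on an oracle map returns genuine members."""
        sp = GenotypeSpace("01", 12)
        oracle = lambda g: "even" if g.count("1") % 2 == 0 else "odd"
        m = GPMap.from_oracle(sp, oracle)
        got = sample_neutral_members(m, "even", 10, seed=1, method="search")
        assert all(oracle(g) == "even" for g in got)
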