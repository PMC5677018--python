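import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cageqtl import cis_qtl
from cageqtl.io import GenomicInterval
from cageqtl.synthetic import SimulationConfig, simulate_genotypes


class TestResidualize:
    def test_intercept_only_centers(self):
        y = np.array([1.0, 2, 3, 4, 5, 9])
        r = cis_qtl.residualize(y, None)
        np.testing.assert_allclose(r, y - y.mean(), atol=1e-12)

    def test_phenotype_equal_to_covariate_gives_zero(self, rng):
        c = rng.normal(size=12)
        r = cis_qtl.residualize(c, c)
        np.testing.assert_allclose(r, 0, atol=1e-10)

    def test_matches_normal_equations_on_hand_example(self):
        X = np.array([[1.0, 2], [2, 1], [3, 5], [4, 3], [5, 7],
                      [0, 1], [2, 2]])
        y = np.array([3.0, 1, 7, 4, 9, 0.5, 2])
        Xd = np.column_stack([np.ones(7), X])
        beta = np.linalg.solve(Xd.T @ Xd, Xd.T @ y)
        expected = y - Xd @ beta
        np.testing.assert_allclose(cis_qtl.residualize(y, X), expected,
                                   atol=1e-10)
        # orthogonality to every covariate
        r = cis_qtl.residualize(y, X)
        assert np.abs(Xd.T @ r).max() < 1e-8

    def test_rank_deficiency_signalled(self, rng):
        c = rng.normal(size=12)
        with pytest.raises(ValueError, match="rank"):
            cis_qtl.residualize(rng.normal(size=12), np.column_stack([c, 2 * c]))


class TestNominalScan:
    def test_perfect_association(self):
        g = np.array([0.0, 1, 2, 0, 1, 2, 0, 1])
        scan, lead = cis_qtl.nominal_scan(g - g.mean(), g)
        assert scan["r"][0] == pytest.approx(1.0)
        assert scan["p"][0] < 1e-12
        assert lead == 0

    def test_beta_equals_cov_over_var_hand_computation(self):
        g = np.array([0.0, 1, 2, 0, 2, 1])
        y = np.array([0.3, 1.1, 2.4, -0.2, 1.9, 0.8])
        scan, _ = cis_qtl.nominal_scan(y - y.mean(), g)
        expected = np.cov(y, g, ddof=1)[0, 1] / np.var(g, ddof=1)
        assert scan["beta"][0] == pytest.approx(expected)

    def test_monomorphic_variant_skipped(self, rng):
        y = rng.normal(size=10)
        G = np.column_stack([np.ones(10), rng.integers(0, 3, 10)])
        scan, lead = cis_qtl.nominal_scan(y - y.mean(), G)
        assert not scan["tested"][0] and np.isnan(scan["p"][0])
        assert lead == 1

    def test_null_pvalues_uniform(self, rng):
        # one noise phenotype scanned against 10^4 independent variants
        n = 60
        y = rng.normal(size=n)
        G = rng.binomial(2, 0.3, size=(n, 10_000)).astype(float)
        scan, _ = cis_qtl.nominal_scan(y - y.mean(), G)
        ps = scan["p"][scan["tested"]]
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_lead_tie_broken_by_position(self):
        g = np.array([0.0, 1, 2, 0, 1, 2])
        y = g - g.mean()
        G = np.column_stack([g, g])  # identical variants, tied p
        _, lead = cis_qtl.nominal_scan(y, G, positions=[500, 100])
        assert lead == 1


def brute_force_exhaustive_p(y, G, n_cov=0):
    """Full enumeration of sample permutations with naive per-variant stats."""
    n, m = G.shape
    dof = n - 2 - n_cov

    def best_p(yv):
        ps = []
        for j in range(m):
            r = np.corrcoef(yv, G[:, j])[0, 1]
            t2 = dof * r * r / (1 - r * r)
            ps.append(stats.f.sf(t2, 1, dof))
        return min(ps)

    obs = best_p(y)
    count = total = 0
    for perm in itertools.permutations(range(n)):
        count += best_p(y[list(perm)]) <= obs + 1e-12
        total += 1
    return count / total


class TestPermutationAdjust:
    def test_exhaustive_matches_bruteforce_enumeration(self, rng):
        n, m = 7, 5
        G = rng.binomial(2, 0.4, size=(n, m)).astype(float)
        G[:, 0] = [0, 1, 2, 0, 1, 2, 1]  # guarantee polymorphism
        y = 0.8 * G[:, 0] + rng.normal(size=n)
        res = cis_qtl.permutation_adjust(y - y.mean(), G, mode="exhaustive")
        expected = brute_force_exhaustive_p(y - y.mean(), G)
        assert res["adjusted_p"] == pytest.approx(expected, abs=1e-12)

    def test_empirical_floor_when_observed_is_best(self, rng):
        n = 40
        g = np.tile([0.0, 1, 2, 1], 10)
        y = g * 3.0  # deterministic, unbeatable by permutation
        res = cis_qtl.permutation_adjust(y - y.mean(), g[:, None],
                                         n_perm=500, mode="empirical",
                                         rng=np.random.default_rng(0))
        assert res["adjusted_p"] == pytest.approx(1 / 501)

    def test_adjusted_at_least_nominal_for_strong_signal(self, rng):
        n = 50
        g = rng.binomial(2, 0.4, size=n).astype(float)
        y = g + 0.5 * rng.normal(size=n)
        res = cis_qtl.permutation_adjust(y - y.mean(), g[:, None],
                                         n_perm=1000, mode="empirical",
                                         rng=np.random.default_rng(1))
        assert res["adjusted_p"] >= res["nominal_best_p"]

    def test_beta_and_empirical_agree_within_002(self, rng):
        # moderate signals with adjusted p in [0.01, 0.5]
        n = 80
        G = rng.binomial(2, 0.3, size=(n, 15)).astype(float)
        checked = 0
        for k in range(12):
            y = 0.3 * G[:, 0] * (k % 3) + rng.normal(size=n)
            y = y - y.mean()
            r1 = cis_qtl.permutation_adjust(
                y, G, n_perm=1000, mode="empirical",
                rng=np.random.default_rng(100 + k))
            r2 = cis_qtl.permutation_adjust(
                y, G, n_perm=1000, mode="beta",
                rng=np.random.default_rng(100 + k))
            if 0.01 <= r1["adjusted_p"] <= 0.5:
                checked += 1
                assert abs(r1["adjusted_p"] - r2["adjusted_p"]) <= 0.02
        assert checked >= 3

    def test_null_adjusted_p_roughly_uniform(self, rng):
        n = 30
        G = rng.binomial(2, 0.4, size=(n, 8)).astype(float)
        ps = []
        for k in range(60):
            y = rng.normal(size=n)
            res = cis_qtl.permutation_adjust(
                y - y.mean(), G, n_perm=200, mode="empirical",
                rng=np.random.default_rng(k))
            ps.append(res["adjusted_p"])
        assert stats.kstest(ps, "uniform").pvalue > 0.005

    def test_low_perm_beta_falls_back(self, rng):
        g = rng.binomial(2, 0.4, size=20).astype(float)
        y = rng.normal(size=20)
        res = cis_qtl.permutation_adjust(y - y.mean(), g[:, None], n_perm=50,
                                         mode="beta",
                                         rng=np.random.default_rng(0))
        assert res["mode"] == "empirical"


class TestQvalue:
    def test_all_ones(self):
        pi0, q = cis_qtl.qvalue(np.ones(500))
        assert pi0 == 1.0
        np.testing.assert_allclose(q, 1.0)

    def test_uniform_null_pi0_near_one(self, rng):
        p = rng.uniform(size=5000)
        pi0 = cis_qtl.storey_pi0(p)
        assert 0.9 <= pi0 <= 1.0

    def test_mixture_recovers_pi0(self, rng):
        p = np.concatenate([rng.uniform(size=4000),
                            rng.beta(0.05, 10, size=1000)])
        pi0 = cis_qtl.storey_pi0(p)
        assert abs(pi0 - 0.8) <= 0.05

    def test_q_monotone_in_p(self, rng):
        p = rng.uniform(size=300)
        _, q = cis_qtl.qvalue(p)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            cis_qtl.qvalue([])


class TestCallSignificant:
    def test_fdr_boundary(self):
        df = pd.DataFrame({"q": [0.049, 0.051], "phenotype_id": ["a", "b"]})
        kept = cis_qtl.call_significant(df, fdr=0.05)
        assert list(kept["phenotype_id"]) == ["a"]
        assert len(cis_qtl.call_significant(df, fdr=1.0)) == 2


@pytest.fixture(scope="module")
def setup():
    cfg = SimulationConfig(n_samples=80, n_variants=600, ld_block_span=2000,
                           n_genes=20, n_enhancers=5, tad_span=150_000,
                           seed=5)
    gt = simulate_genotypes(cfg)
    tads = [GenomicInterval("chr1", t * cfg.tad_span, (t + 1) * cfg.tad_span,
                            ".", f"tad{t}") for t in range(cfg.n_tads)]
    return gt, tads


class TestMapCis:
    def _phenotypes(self, gt, seed, slope=1.0):
        rng = np.random.default_rng(seed)
        cols = rng.choice(gt.n_variants, size=6, replace=False)
        rows, anchors = [], []
        for k, j in enumerate(cols):
            y = slope * (k % 2) * gt.dosages[:, j] + rng.normal(size=gt.n_samples)
            rows.append(y)
            anchors.append({"phenotype_id": f"p{k}", "chrom": "chr1",
                            "pos": int(gt.variants.iloc[j]["pos"])})
        phen = pd.DataFrame(rows, index=[a["phenotype_id"] for a in anchors],
                            columns=gt.sample_ids)
        return phen, pd.DataFrame(anchors)

    def test_deterministic_under_seed(self, setup):
        gt, tads = setup
        phen, anchors = self._phenotypes(gt, 3)
        r1 = cis_qtl.map_cis(phen, anchors, gt, tads, n_perm=100, seed=9)
        r2 = cis_qtl.map_cis(phen, anchors, gt, tads, n_perm=100, seed=9)
        pd.testing.assert_frame_equal(r1, r2)

    def test_result_order_independent_rng(self, setup):
        # per-phenotype seeds: reversing the phenotype order leaves each
        # phenotype's adjusted p unchanged
        gt, tads = setup
        phen, anchors = self._phenotypes(gt, 3)
        r1 = cis_qtl.map_cis(phen, anchors, gt, tads, n_perm=100, seed=9)
        r2 = cis_qtl.map_cis(phen.iloc[::-1], anchors.iloc[::-1], gt, tads,
                             n_perm=100, seed=9)
        m = r1.merge(r2, on="phenotype_id", suffixes=("_a", "_b"))
        np.testing.assert_allclose(m["adjusted_p_a"], m["adjusted_p_b"])

    def test_power_monotone_in_slope(self, setup):
        gt, tads = setup
        hits = {}
        for slope in (0.2, 1.5):
            phen, anchors = self._phenotypes(gt, 11, slope=slope)
            res = cis_qtl.map_cis(phen, anchors, gt, tads, n_perm=200, seed=1)
            hits[slope] = (res["adjusted_p"] < 0.05).sum()
        assert hits[1.5] >= hits[0.2]

    def test_orphan_anchor_uses_fallback_window(self, setup):
        gt, _ = setup
        phen, anchors = self._phenotypes(gt, 3)
        far_tads = [GenomicInterval("chr9", 0, 100, ".", "t0")]
        windows = cis_qtl.build_cis_windows(anchors, gt, far_tads)
        for w, anchor in zip(windows, anchors.itertuples(index=False)):
            assert w.n_variants > 0
            assert w.end - w.start <= 2_000_000
            assert w.start <= anchor.pos < w.end
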