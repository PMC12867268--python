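"""TWAS association statistic, BH adjustment and feature clustering."""

import numpy as np
import pytest
from scipy import stats as sps

from chemtwas import io as ctio
from chemtwas.simulate import SimConfig, sim_gwas_z, sim_ld, sim_weights, simulate_all
from chemtwas.twas import (
    TwasResult,
    bh_adjust,
    cluster_features,
    expression_correlation,
    pooled_fdr,
    run_twas,
    segment_id,
    twas_zscore,
)

from conftest import naive_twas_z, random_psd_corr


class TestTwasZscore:
    def test_single_snp_reduction(self):
        for i in range(4):
            w = np.zeros(4)
            w[i] = 1.0
            z = np.array([1.0, -2.0, 0.5, 3.0])
            assert twas_zscore(w, z, np.eye(4)) == z[i]

    def test_hand_evaluation(self):
        w = np.array([0.5, 0.5, 0.0])
        z = np.array([1.0, 1.0, 0.0])
        assert twas_zscore(w, z, np.eye(3)) == pytest.approx(np.sqrt(2), abs=1e-12)

    def test_matches_naive_double_loop(self):
        rng = np.random.default_rng(42)
        for _ in range(1000):
            n = int(rng.integers(1, 9))
            L = random_psd_corr(rng, n)
            w = rng.standard_normal(n)
            z = rng.standard_normal(n)
            expected = naive_twas_z(list(w), list(z), L.tolist())
            assert twas_zscore(w, z, L) == pytest.approx(expected, abs=1e-10)

    def test_degenerate_predictor_errors(self):
        with pytest.raises(ValueError, match="degenerate"):
            twas_zscore(np.zeros(2), np.ones(2), np.eye(2))

    def test_length_mismatch_errors(self):
        with pytest.raises(ValueError, match="mismatch"):
            twas_zscore(np.ones(2), np.ones(3), np.eye(3))

    def test_joint_sign_flip_invariance(self):
        """Flipping (w_i, z_i) jointly with the LD row/col signs preserves Z."""
        rng = np.random.default_rng(7)
        n = 6
        L = random_psd_corr(rng, n)
        w = rng.standard_normal(n)
        z = rng.standard_normal(n)
        base = twas_zscore(w, z, L)
        signs = rng.choice([-1.0, 1.0], size=n)
        S = np.diag(signs)
        assert twas_zscore(w * signs, z * signs, S @ L @ S) == pytest.approx(
            base, abs=1e-12
        )

    def test_permutation_invariance(self):
        rng = np.random.default_rng(8)
        n = 7
        L = random_psd_corr(rng, n)
        w = rng.standard_normal(n)
        z = rng.standard_normal(n)
        base = twas_zscore(w, z, L)
        perm = rng.permutation(n)
        assert twas_zscore(w[perm], z[perm], L[np.ix_(perm, perm)]) == pytest.approx(
            base, abs=1e-12
        )


class TestBhAdjust:
    def test_hand_step_up(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_single_p_unchanged(self):
        assert bh_adjust([0.37])[0] == pytest.approx(0.37)

    def test_matches_statsmodels_on_random_vectors(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(3)
        for _ in range(1000):
            p = rng.uniform(1e-12, 1.0, size=int(rng.integers(1, 40)))
            expected = multipletests(p, method="fdr_bh")[1]
            np.testing.assert_allclose(bh_adjust(p), expected, atol=1e-12)

    def test_permutation_invariant(self):
        rng = np.random.default_rng(4)
        p = rng.uniform(0.001, 1.0, size=25)
        adj = bh_adjust(p)
        perm = rng.permutation(25)
        np.testing.assert_allclose(bh_adjust(p[perm]), adj[perm], atol=1e-15)

    @pytest.mark.parametrize("bad", [[0.0], [1.5], [-0.1]])
    def test_rejects_out_of_range(self, bad):
        with pytest.raises(ValueError):
            bh_adjust(bad)


class TestRunTwas:
    def test_single_gene_single_snp(self):
        gwas = ctio.GwasSummary([ctio.SnpRecord("rs1", "1", 500, "A", "G", 2.0)])
        ld = ctio.LdMatrix(["rs1"], np.eye(1))
        panel = ctio.WeightPanel(
            [ctio.WeightEntry("g1", "t", "rs1", 1.0, "A", "G")],
            {"g1": ("1", 500)},
        )
        results, skipped = run_twas(panel, gwas, ld, "t")
        assert not skipped
        (r,) = results
        assert r.z == pytest.approx(2.0)
        assert r.p == pytest.approx(2 * sps.norm.sf(2.0), abs=1e-12)
        assert r.p == pytest.approx(0.0455, abs=5e-5)
        assert r.q == pytest.approx(r.p)
        assert r.n_snps_used == 1

    def test_p_is_two_sided_normal_tail_of_z(self):
        config = SimConfig(seed=5, n_genes=25, n_blocks=25)
        bundle = simulate_all(config)
        results, _ = run_twas(bundle.panel, bundle.gwas, bundle.ld, "tissue0")
        assert len(results) == 25
        for r in results:
            assert r.p == pytest.approx(2 * sps.norm.sf(abs(r.z)), abs=1e-12)

    def test_empty_panel_errors(self):
        gwas = ctio.GwasSummary([ctio.SnpRecord("rs1", "1", 500, "A", "G", 2.0)])
        ld = ctio.LdMatrix(["rs1"], np.eye(1))
        panel = ctio.WeightPanel(
            [ctio.WeightEntry("g1", "t", "rs1", 1.0, "A", "G")], {"g1": ("1", 500)}
        )
        with pytest.raises(ctio.ValidationError, match="empty"):
            run_twas(panel, gwas, ld, "other_tissue")

    def test_planted_gene_expectation_alpha(self):
        """Monte-Carlo mean of the causal gene's TWAS Z is alpha (3 SE band)."""
        alpha = 5.0
        config = SimConfig(
            seed=0, n_genes=4, n_blocks=4, block_size=10,
            causal_genes={"G1": alpha},
        )
        ld = sim_ld(config)
        panel = sim_weights(config, ld)
        zs = []
        n_rep = 400
        for rep in range(n_rep):
            rep_config = SimConfig(**{**config.__dict__, "seed": 10_000 + rep})
            gwas = sim_gwas_z(rep_config, ld, panel)
            results, _ = run_twas(panel, gwas, ld, "tissue0")
            zs.append(next(r.z for r in results if r.gene_id == "G1"))
        mean = np.mean(zs)
        se = np.std(zs, ddof=1) / np.sqrt(n_rep)
        assert abs(mean - alpha) < 3 * se + 1e-9

    def test_power_monotone_in_alpha(self):
        """Detection rate never decreases along alpha = 0..6 (1 MC SE slack)."""
        rates = []
        n_seeds = 30
        for alpha in range(0, 7, 2):
            hits = 0
            for seed in range(n_seeds):
                config = SimConfig(
                    seed=20_000 + seed, n_genes=10, n_blocks=10, block_size=10,
                    causal_genes={"G01": float(alpha)},
                )
                bundle = simulate_all(config)
                results, _ = run_twas(bundle.panel, bundle.gwas, bundle.ld, "tissue0")
                r = next(x for x in results if x.gene_id == "G01")
                hits += r.p < 0.05
            rates.append(hits / n_seeds)
        se = np.sqrt(0.25 / n_seeds)
        for lo, hi in zip(rates, rates[1:]):
            assert hi >= lo - se

    def test_pooled_fdr_spans_tissues(self):
        bundle = simulate_all(SimConfig(seed=9, n_genes=10, n_blocks=10, n_tissues=2))
        all_results = []
        for t in ("tissue0", "tissue1"):
            res, _ = run_twas(bundle.panel, bundle.gwas, bundle.ld, t)
            all_results.extend(res)
        pooled_fdr(all_results)
        expected = bh_adjust([r.p for r in all_results])
        np.testing.assert_allclose([r.q_pooled for r in all_results], expected)


class TestExpressionCorrelation:
    def test_identical_weights(self):
        rng = np.random.default_rng(1)
        L = random_psd_corr(rng, 5)
        w = rng.standard_normal(5)
        assert expression_correlation(w, w, L) == pytest.approx(1.0, abs=1e-12)

    def test_disjoint_snps_identity_ld(self):
        w_i = np.array([1.0, 0.0])
        w_j = np.array([0.0, 1.0])
        assert expression_correlation(w_i, w_j, np.eye(2)) == 0.0

    def test_matches_monte_carlo_sampling(self):
        """r equals the sample correlation of simulated predicted expressions."""
        rng = np.random.default_rng(2)
        n = 6
        L = random_psd_corr(rng, n)
        w_i = rng.standard_normal(n)
        w_j = rng.standard_normal(n)
        analytic = expression_correlation(w_i, w_j, L)
        chol = np.linalg.cholesky(L + 1e-12 * np.eye(n))
        draws = (chol @ rng.standard_normal((n, 50_000))).T
        mc = np.corrcoef(draws @ w_i, draws @ w_j)[0, 1]
        assert analytic == pytest.approx(mc, abs=0.02)

    def test_degenerate_errors(self):
        with pytest.raises(ValueError, match="degenerate"):
            expression_correlation(np.zeros(2), np.ones(2), np.eye(2))


def _results(pmap):
    return [
        TwasResult(g, "t", 0.0, p, p, 1, 0) for g, p in sorted(pmap.items())
    ]


class TestClusterFeatures:
    def test_merge_above_threshold(self):
        res = _results({"a": 0.01, "b": 0.02})
        clusters = cluster_features(res, lambda x, y: 0.95)
        assert len(clusters) == 1
        assert clusters[0].relation == "merged"
        assert clusters[0].representative == "a"

    def test_independent_below_threshold(self):
        res = _results({"a": 0.01, "b": 0.02})
        clusters = cluster_features(res, lambda x, y: 0.0)
        assert [c.relation for c in clusters] == ["independent", "independent"]

    def test_transitive_closure_chain(self):
        """r(a,b)=r(b,c)=0.95, r(a,c)=0.5 -> one merged cluster {a,b,c}."""
        corr = {("a", "b"): 0.95, ("b", "c"): 0.95, ("a", "c"): 0.5}

        def corr_fn(x, y):
            return corr.get((x, y), corr.get((y, x), 0.0))

        res = _results({"a": 0.01, "b": 0.02, "c": 0.03})
        clusters = cluster_features(res, corr_fn)
        assert len(clusters) == 1
        assert clusters[0].member_genes == frozenset({"a", "b", "c"})
        assert clusters[0].relation == "merged"

    def test_in_between_correlation_is_joint(self):
        res = _results({"a": 0.01, "b": 0.02})
        clusters = cluster_features(res, lambda x, y: 0.5)
        assert len(clusters) == 1
        assert clusters[0].relation == "joint"

    def test_high_p_genes_excluded(self):
        res = _results({"a": 0.01, "b": 0.5})
        clusters = cluster_features(res, lambda x, y: 0.95)
        assert len(clusters) == 1
        assert clusters[0].member_genes == frozenset({"a"})

    def test_matches_union_find_oracle_on_random_instances(self):
        rng = np.random.default_rng(11)
        for _ in range(30):
            genes = [f"g{i}" for i in range(8)]
            rmat = {}
            for i, a in enumerate(genes):
                for b in genes[i + 1 :]:
                    rmat[(a, b)] = float(rng.uniform(0, 1))

            def corr_fn(x, y):
                return rmat.get((x, y), rmat.get((y, x), 0.0))

            res = _results({g: 0.01 for g in genes})
            clusters = cluster_features(res, corr_fn)
            # oracle: transitive closure of the merge relation
            parent = {g: g for g in genes}

            def find(x):
                while parent[x] != x:
                    x = parent[x]
                return x

            for (a, b), r in rmat.items():
                if r > 0.9:
                    parent[find(a)] = find(b)
            groups = {}
            for g in genes:
                groups.setdefault(find(g), set()).add(g)
            merged_oracle = {frozenset(s) for s in groups.values() if len(s) > 1}
            # every closure group must sit inside a single cluster (a larger
            # joint component may absorb it, but never split it)
            for m in merged_oracle:
                assert any(m <= c.member_genes for c in clusters)
            # and a cluster labeled merged must be exactly a closure group
            for c in clusters:
                if c.relation == "merged":
                    assert c.member_genes in merged_oracle


def test_segment_id_is_position_div_100kb():
    assert segment_id(1) == 0
    assert segment_id(99_999) == 0
    assert segment_id(100_000) == 1
    assert segment_id(1_234_567) == 12
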