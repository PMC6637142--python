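import numpy as np
import pytest
from scipy import stats

import macsim as m
from macsim.fitting import (FCMatrix, fisher_z, signed_degrees,
                            threshold_absolute, threshold_proportional_to_count)


def random_fc_z(n, seed, rank=6, t=400):
    rng = np.random.default_rng(seed)
    ts = rng.standard_normal((n, rank)) @ rng.standard_normal((rank, t))
    z = fisher_z(np.corrcoef(ts))
    np.fill_diagonal(z, 0.0)
    return z


class TestComputeFc:
    def test_duplicated_rows_fully_correlated(self):
        rng = np.random.default_rng(0)
        row = rng.standard_normal(100)
        fc = m.compute_fc(np.stack([row, row + 0.0, row * 2]))
        iu = np.triu_indices(3, 1)
        np.testing.assert_allclose(fc.values[iu], 1.0)

    def test_independent_noise_nearly_uncorrelated(self):
        rng = np.random.default_rng(42)
        fc = m.compute_fc(rng.standard_normal((8, 10 ** 4)))
        iu = np.triu_indices(8, 1)
        assert np.abs(fc.values[iu]).max() < 0.05

    def test_matches_bruteforce_covariance(self):
        rng = np.random.default_rng(1)
        ts = rng.standard_normal((3, 5))
        fc = m.compute_fc(ts)
        for i in range(3):
            for j in range(3):
                xi = ts[i] - ts[i].mean()
                xj = ts[j] - ts[j].mean()
                expect = (xi @ xj) / np.sqrt((xi @ xi) * (xj @ xj))
                assert fc.values[i, j] == pytest.approx(expect)

    def test_constant_region_named_in_error(self):
        ts = np.random.default_rng(2).standard_normal((3, 50))
        ts[1] = 4.2
        with pytest.raises(ValueError, match=r"\[1\]"):
            m.compute_fc(ts)

    def test_fisher_z_space_tagged(self):
        rng = np.random.default_rng(3)
        fc = m.compute_fc(rng.standard_normal((4, 60)), fisher_z_transform=True)
        assert fc.space == "fisher_z"


class TestAverageFc:
    def test_identical_matrices_average_to_themselves(self):
        z = FCMatrix(random_fc_z(5, 0), "fisher_z")
        out = m.average_fc([z, z, z])
        np.testing.assert_allclose(out.values, z.values)

    def test_opposite_matrices_cancel(self):
        z = random_fc_z(5, 1)
        out = m.average_fc([FCMatrix(z, "fisher_z"), FCMatrix(-z, "fisher_z")])
        np.testing.assert_allclose(out.values, 0.0)

    def test_matches_bruteforce_mean(self):
        mats = [random_fc_z(4, s) for s in range(3)]
        out = m.average_fc([FCMatrix(v, "fisher_z") for v in mats])
        np.testing.assert_allclose(out.values, np.mean(mats, axis=0))

    def test_mixed_spaces_rejected(self):
        r = FCMatrix(np.eye(3), "pearson_r")
        z = FCMatrix(np.zeros((3, 3)), "fisher_z")
        with pytest.raises(ValueError, match="fisher_z"):
            m.average_fc([r, z])

    def test_two_level_grand_average(self):
        scans = [[FCMatrix(random_fc_z(4, s * 10 + k), "fisher_z")
                  for k in range(2)] for s in range(3)]
        grand = m.grand_average_fc(scans)
        expect = np.mean([np.mean([f.values for f in sub], axis=0)
                          for sub in scans], axis=0)
        np.testing.assert_allclose(grand.values, expect)


class TestCosineSimilarity:
    def test_self_similarity_is_one(self):
        z = random_fc_z(6, 0)
        assert m.cosine_similarity(z, z) == pytest.approx(1.0)

    def test_orthogonal_triangles_are_zero(self):
        a = np.zeros((3, 3))
        b = np.zeros((3, 3))
        a[0, 1] = a[1, 0] = 1.0
        b[0, 2] = b[2, 0] = 1.0
        assert m.cosine_similarity(a, b) == pytest.approx(0.0)

    def test_closed_form_value(self):
        a = np.zeros((3, 3))
        b = np.zeros((3, 3))
        a[0, 1] = a[1, 0] = 1.0            # u_a = (1, 0, 0)
        b[0, 1] = b[1, 0] = 1.0
        b[0, 2] = b[2, 0] = 1.0            # u_b = (1, 1, 0)
        assert m.cosine_similarity(a, b) == pytest.approx(1 / np.sqrt(2))

    def test_symmetric_and_scale_invariant(self):
        a, b = random_fc_z(6, 1), random_fc_z(6, 2)
        assert m.cosine_similarity(a, b) == pytest.approx(m.cosine_similarity(b, a))
        assert m.cosine_similarity(3.7 * a, b) == pytest.approx(
            m.cosine_similarity(a, b))

    def test_zero_triangle_rejected(self):
        with pytest.raises(ValueError):
            m.cosine_similarity(np.zeros((3, 3)), random_fc_z(3, 0))


class TestParameterGrid:
    def test_default_lattice_is_100_by_30(self):
        G, s = m.parameter_grid()
        assert len(G) == 100 and len(s) == 30
        assert G[0] == 0.1 and G[-1] == 5.0
        assert s[0] == 0.01 and s[-1] == 0.1


class TestNullModel:
    def test_degree_and_weight_multiset_preserved(self):
        z = random_fc_z(30, 5)
        iu = np.triu_indices(30, 1)
        for seed in range(5):
            null = m.null_model_und_sign(z, seed=seed)
            assert signed_degrees(null)[0].tolist() == signed_degrees(z)[0].tolist()
            assert signed_degrees(null)[1].tolist() == signed_degrees(z)[1].tolist()
            np.testing.assert_allclose(np.sort(null[iu]), np.sort(z[iu]))

    def test_strengths_approximately_preserved(self):
        z = random_fc_z(40, 0)
        s0 = np.abs(z).sum(axis=1)
        devs = [np.max(np.abs(np.abs(m.null_model_und_sign(z, seed=k)).sum(1) - s0)
                       / s0) for k in range(10)]
        assert max(devs) <= 0.10

    def test_sparse_degree_preservation(self):
        rng = np.random.default_rng(8)
        w = np.zeros((20, 20))
        iu = np.triu_indices(20, 1)
        pick = rng.choice(len(iu[0]), size=40, replace=False)
        w[iu[0][pick], iu[1][pick]] = rng.standard_normal(40)
        w = w + w.T
        null = m.null_model_und_sign(w, seed=0)
        assert signed_degrees(null)[0].tolist() == signed_degrees(w)[0].tolist()
        assert signed_degrees(null)[1].tolist() == signed_degrees(w)[1].tolist()
        assert not np.allclose(null, w)   # actually rewired

    def test_null_fit_pvalue_small_for_self_fit(self):
        z = random_fc_z(30, 9)
        emp = FCMatrix(z, "fisher_z")
        p, nulls = m.null_fit_pvalue(emp, emp, n_nulls=99, seed=0)
        assert len(nulls) == 99
        assert p <= 0.05

    def test_pvalue_uses_geq_convention(self, monkeypatch):
        z = random_fc_z(10, 3)
        emp = FCMatrix(z, "fisher_z")
        # force every null to equal the empirical network: all similarities tie
        monkeypatch.setattr(m.fitting, "null_model_und_sign",
                            lambda w, seed=0, **k: w.copy())
        p, _ = m.null_fit_pvalue(emp, emp, n_nulls=50, seed=0)
        assert p == 1.0

    def test_tiny_network_rejected(self):
        with pytest.raises(ValueError):
            m.null_fit_pvalue(FCMatrix(np.zeros((3, 3)), "fisher_z"),
                              FCMatrix(np.zeros((3, 3)), "fisher_z"))


class TestPcaNetworks:
    def test_rank_one_data_explained_by_first_component(self):
        rng = np.random.default_rng(0)
        pattern = rng.standard_normal(10)
        ts = np.outer(pattern, rng.standard_normal(300))
        out = m.pca_networks(ts, n_components=3, top_k=4)
        assert out["variance_fractions"][0] == pytest.approx(1.0)
        assert out["all_fractions"].sum() == pytest.approx(1.0)

    def test_fractions_sum_to_one(self):
        rng = np.random.default_rng(1)
        out = m.pca_networks(rng.standard_normal((7, 200)))
        assert out["all_fractions"].sum() == pytest.approx(1.0)

    def test_matches_bruteforce_eigensolve(self):
        rng = np.random.default_rng(2)
        ts = rng.standard_normal((5, 200))
        out = m.pca_networks(ts, n_components=5)
        x = ts - ts.mean(axis=1, keepdims=True)
        evals = np.sort(np.linalg.eigvalsh(np.cov(x)))[::-1]
        np.testing.assert_allclose(out["all_fractions"], evals / evals.sum(),
                                   atol=1e-10)

    def test_fractions_invariant_to_region_order(self):
        rng = np.random.default_rng(3)
        ts = rng.standard_normal((8, 6)) @ rng.standard_normal((6, 300))
        perm = rng.permutation(8)
        a = m.pca_networks(ts)["variance_fractions"]
        b = m.pca_networks(ts[perm])["variance_fractions"]
        np.testing.assert_allclose(a, b, atol=1e-12)

    def test_too_few_regions_rejected(self):
        with pytest.raises(ValueError):
            m.pca_networks(np.random.default_rng(0).standard_normal((2, 50)),
                           n_components=3)


class TestStrengthComparison:
    def test_identical_all_positive_networks_correlate_perfectly(self):
        rng = np.random.default_rng(0)
        z = np.abs(random_fc_z(12, 4)) + 0.01
        np.fill_diagonal(z, 0)
        fc = FCMatrix(z, "fisher_z")
        out = m.strength_comparison(fc, fc, n_perm=200, seed=0)
        assert out["r"] == pytest.approx(1.0)
        assert out["p"] <= 0.05

    def test_densities_match_after_thresholding(self):
        sim = FCMatrix(random_fc_z(15, 1), "fisher_z")
        emp = FCMatrix(random_fc_z(15, 2), "fisher_z")
        out = m.strength_comparison(sim, emp, n_perm=10, seed=0)
        emp_pos = threshold_absolute(emp.values, 0.0)
        iu = np.triu_indices(15, 1)
        n_emp = np.count_nonzero(emp_pos[iu])
        simv = sim.values.copy()
        np.fill_diagonal(simv, 0)
        sim_thr = threshold_proportional_to_count(simv, n_emp)
        assert np.count_nonzero(sim_thr[iu]) == n_emp == out["density_edges"]

    def test_toy_hand_computation(self):
        emp = np.zeros((6, 6))
        emp[0, 1] = emp[1, 0] = 0.6
        emp[2, 3] = emp[3, 2] = 0.4
        emp[4, 5] = emp[5, 4] = -0.2   # dropped by positive threshold
        sim = np.zeros((6, 6))
        sim[0, 1] = sim[1, 0] = 0.9
        sim[2, 3] = sim[3, 2] = 0.5
        sim[0, 2] = sim[2, 0] = 0.1    # dropped by proportional threshold
        out = m.strength_comparison(FCMatrix(sim, "fisher_z"),
                                    FCMatrix(emp, "fisher_z"),
                                    n_perm=50, seed=1)
        np.testing.assert_allclose(out["strength_emp"], [0.6, 0.6, 0.4, 0.4, 0, 0])
        np.testing.assert_allclose(out["strength_sim"], [0.9, 0.9, 0.5, 0.5, 0, 0])
        expect_r = np.corrcoef([0.6, 0.6, 0.4, 0.4, 0, 0],
                               [0.9, 0.9, 0.5, 0.5, 0, 0])[0, 1]
        assert out["r"] == pytest.approx(expect_r)


class TestBinnedWeightDistance:
    def test_identical_weights_give_unit_bin_correlations(self):
        rng = np.random.default_rng(0)
        w = rng.lognormal(-5, 1.5, size=60)
        lengths = rng.uniform(5, 80, size=60)
        out = m.binned_weight_distance(w, w, lengths, n_bins=8, n_boot=20, seed=0)
        np.testing.assert_allclose(out["bin_r"], 1.0)
        assert out["trend_r"] == 0.0   # uniform agreement: no distance trend

    def test_bin_sizes_differ_by_at_most_one(self):
        rng = np.random.default_rng(1)
        n = 61
        w = rng.lognormal(-5, 1.5, size=n)
        lengths = np.sort(rng.uniform(5, 80, size=n))
        sizes = [len(b) for b in np.array_split(np.arange(n), 8)]
        assert max(sizes) - min(sizes) <= 1
        out = m.binned_weight_distance(w, w * np.exp(0.1 * rng.standard_normal(n)),
                                       lengths, n_bins=8, n_boot=20, seed=1)
        assert len(out["bin_r"]) == 8

    def test_distance_attenuated_weights_show_negative_trend(self, truth30):
        # tractography-like estimates: true weight times distance decay + noise
        rng = np.random.default_rng(2)
        mask = truth30.adjacency == 1
        tracer_w = truth30.true_weights[mask]
        lengths = truth30.distances()[mask]
        noise = np.exp(rng.normal(0, 0.5 + 0.02 * lengths))
        tract_w = tracer_w * np.exp(-0.05 * lengths) * noise
        out = m.binned_weight_distance(tracer_w, tract_w, lengths,
                                       n_bins=8, n_boot=100, seed=2)
        assert out["trend_r"] < 0
        assert out["trend_ci"][0] < out["trend_r"] < out["trend_ci"][1]

    def test_too_few_edges_rejected(self):
        with pytest.raises(ValueError):
            m.binned_weight_distance(np.ones(10), np.ones(10),
                                     np.arange(10.0), n_bins=8)


class TestPermutationCorr:
    def test_identity_relationship_maximally_significant(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(50)
        r, p = m.permutation_corr(x, x, n_perm=1000, seed=0)
        assert r == pytest.approx(1.0)
        assert p <= 0.001 + 1 / 1001

    def test_null_calibration_roughly_uniform(self):
        rng = np.random.default_rng(1)
        ps = []
        for k in range(40):
            x = rng.standard_normal(30)
            y = rng.standard_normal(30)
            ps.append(m.permutation_corr(x, y, n_perm=200, seed=k)[1])
        ps = np.array(ps)
        # one-sided p under the null: roughly uniform on (0, 1]
        assert 0.25 < ps.mean() < 0.75
        assert (ps < 0.1).mean() < 0.35

    def test_identical_seed_reproduces_p(self):
        rng = np.random.default_rng(2)
        x, y = rng.standard_normal((2, 40))
        a = m.permutation_corr(x, y, n_perm=500, seed=3)
        b = m.permutation_corr(x, y, n_perm=500, seed=3)
        assert a == b

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            m.permutation_corr(np.ones(10), np.arange(10.0))


class TestGridSearchSmall:
    def test_deterministic_per_seed_and_argmax_consistent(self, conn8):
        emp = m.make_surrogate_empirical_fc(conn8, G=2.0, sigma=0.04,
                                            duration_s=20.0, noise_sd=0.02,
                                            rng_seed=31)
        kw = dict(G_values=[1.0, 2.0], sigma_values=[0.03, 0.05], seed=5,
                  duration=20.0)
        fit1 = m.grid_search_fit(conn8, emp, **kw)
        fit2 = m.grid_search_fit(conn8, emp, **kw)
        np.testing.assert_array_equal(fit1.similarity, fit2.similarity)
        assert (fit1.best_G, fit1.best_sigma) == (fit2.best_G, fit2.best_sigma)
        assert fit1.best_similarity == pytest.approx(np.nanmax(fit1.similarity))
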