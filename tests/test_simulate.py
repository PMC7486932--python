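"""Generator behaviour: determinism, conservation laws, structural limits,
and the Monte-Carlo oracle for closed-form segment dating."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score
from sklearn.mixture import GaussianMixture

import structkit as sk


class TestConfigValidation:
    @pytest.mark.parametrize("kwargs, field", [
        ({"n_per_deme": 1}, "n_per_deme"),
        ({"genome_length_cM": 0.0}, "genome_length_cM"),
        ({"spatial_decay": -1.0}, "spatial_decay"),
        ({"dirichlet_concentration": 0.0}, "dirichlet_concentration"),
        ({"tmrca_within": (0.0, 10.0)}, "tmrca_within"),
        ({"deme_centers": [(0, 0), (0, 0), (1, 1)]}, "deme_centers"),
        ({"phenotype_intercepts": [0.0]}, "phenotype_intercepts"),
    ])
    def test_invalid_config_names_field(self, kwargs, field):
        with pytest.raises(sk.ConfigError, match=field):
            sk.ScenarioConfig(**kwargs)

    def test_yaml_round_trip(self, tmp_path):
        cfg = sk.ScenarioConfig(n_demes=2, n_per_deme=5,
                                deme_centers=[(0.0, 0.0), (1.0, 2.0)], seed=3)
        path = tmp_path / "scenario.yaml"
        cfg.to_yaml(path)
        assert sk.ScenarioConfig.from_yaml(path) == cfg


class TestCohortInvariants:
    def test_row_sums_and_diagonal(self, structured_cohort):
        m = structured_cohort.coancestry
        total = structured_cohort.config.genome_length_cM
        np.testing.assert_allclose(m.df.sum(axis=1), total, rtol=1e-6)
        assert (np.diag(m.values) == 0).all()

    def test_truth_rows_on_simplex(self, structured_cohort):
        truth = structured_cohort.true_ancestry.to_numpy()
        assert (truth >= 0).all()
        np.testing.assert_allclose(truth.sum(axis=1), 1.0, atol=1e-9)

    def test_segments_above_detection_floor(self, structured_cohort):
        floor = structured_cohort.config.min_length_cM
        assert (structured_cohort.ibd.df["length_cM"] >= floor).all()

    def test_deterministic_in_seed(self, tmp_path):
        cfg = sk.ScenarioConfig(n_demes=2, n_per_deme=5, seed=11)
        d1, d2 = tmp_path / "run1", tmp_path / "run2"
        p1 = sk.write_cohort(sk.generate_cohort(cfg), d1)
        p2 = sk.write_cohort(sk.generate_cohort(cfg), d2)
        for name in p1:
            assert p1[name].read_bytes() == p2[name].read_bytes()

    def test_different_seeds_differ(self):
        a = sk.generate_cohort(sk.ScenarioConfig(n_demes=2, n_per_deme=5, seed=1))
        b = sk.generate_cohort(sk.ScenarioConfig(n_demes=2, n_per_deme=5, seed=2))
        assert not a.coancestry.df.equals(b.coancestry.df)


class TestStructureLimits:
    def test_no_structure_limit_tvd_near_floor(self):
        # flat kernel, no boost, near-deterministic rows: demes are
        # indistinguishable up to the finite-size floor 1/(n-1) that the
        # excluded self-donation imposes on equal-size clusters
        for n_per_deme, seed in ((10, 5), (25, 6)):
            cfg = sk.ScenarioConfig(n_demes=2, n_per_deme=n_per_deme,
                                    within_deme_boost=0.0, spatial_decay=1e6,
                                    dirichlet_concentration=1e7, seed=seed)
            coh = sk.generate_cohort(cfg)
            cv = sk.copying_vectors(coh.coancestry,
                                    sk.ClusterAssignment(coh.deme_labels()))
            floor = 1.0 / (2 * n_per_deme - 1)
            assert abs(sk.tvd_pair(cv, "deme0", "deme1") - floor) < 0.005

    def test_strong_structure_recovers_demes(self, structured_cohort):
        scores = sk.pca_coancestry(structured_cohort.coancestry, 2)
        labels = GaussianMixture(3, n_init=10, random_state=0).fit_predict(scores)
        truth = structured_cohort.deme_labels().loc[scores.index]
        assert adjusted_rand_score(truth, labels) == 1.0

    def test_tvd_increases_with_within_deme_boost(self):
        # expected TVD between demes grows strictly with the boost kappa
        means = []
        for kappa in (0.5, 2.0, 8.0):
            tvds = []
            for rep in range(20):
                cfg = sk.ScenarioConfig(n_demes=2, n_per_deme=6,
                                        within_deme_boost=kappa,
                                        spatial_decay=1e6,
                                        dirichlet_concentration=200.0,
                                        seed=1000 + rep)
                ind = sk.simulate_geography(cfg)
                m = sk.simulate_coancestry(cfg, ind)
                cv = sk.copying_vectors(
                    m, sk.ClusterAssignment(
                        pd.Series(ind["deme"].values, index=ind["id"].values)))
                tvds.append(sk.tvd_pair(cv, "deme0", "deme1"))
            means.append(np.mean(tvds))
        assert means[0] < means[1] < means[2]


class TestIBDSimulation:
    def test_zero_rate_gives_empty_set(self):
        cfg = sk.ScenarioConfig(n_demes=2, n_per_deme=5, ibd_rate_within=0.0)
        assert len(sk.simulate_ibd_pairs(cfg, "within", n_pairs=50)) == 0

    def test_invalid_pair_count(self):
        cfg = sk.ScenarioConfig()
        with pytest.raises(sk.ConfigError):
            sk.simulate_ibd_pairs(cfg, "within", n_pairs=0)

    def test_validation_mode_length_distribution(self):
        # under an (effectively) improper uniform time prior the retained
        # length density in a bin is proportional to 1/l^2, so the mean
        # length in [L1, L2) is ln(L2/L1) / (1/L1 - 1/L2)
        cfg = sk.ScenarioConfig(n_demes=2, n_per_deme=5, ibd_rate_within=40.0,
                                min_length_cM=1.0, seed=9)
        s = sk.simulate_ibd_pairs(cfg, "within", n_pairs=10000,
                                  validation_mode=True, t_max=5000.0)
        lengths = s.df["length_cM"].to_numpy()
        sel = lengths[(lengths >= 3.0) & (lengths < 5.0)]
        expected = np.log(5.0 / 3.0) / (1.0 / 3.0 - 1.0 / 5.0)
        assert len(sel) > 500
        assert abs(sel.mean() - expected) < 0.1

    def test_long_segments_shared_within_demes(self):
        # recent within-deme coalescence puts nearly all >7 cM segments
        # inside demes, while 1-3 cM segments cross deme boundaries freely
        cfg = sk.ScenarioConfig(n_demes=2, n_per_deme=12, ibd_rate_within=20.0,
                                ibd_rate_between=20.0, tmrca_within=(4, 10),
                                tmrca_between=(4, 30), seed=3)
        ind = sk.simulate_geography(cfg)
        ibd = sk.simulate_cohort_ibd(cfg, ind)
        deme = pd.Series(ind["deme"].values, index=ind["id"].values)
        same = (deme.loc[ibd.df["id1"]].to_numpy()
                == deme.loc[ibd.df["id2"]].to_numpy())
        lengths = ibd.df["length_cM"].to_numpy()
        short = (lengths >= 1) & (lengths < 3)
        long = lengths > 7
        assert long.sum() > 20
        assert same[long].mean() > same[short].mean()
        assert same[long].mean() > 0.9


class TestAncestryTargets:
    def test_noiseless_targets_invert_exactly(self, structured_cohort):
        est = sk.AncestryNNLS(prune_threshold=0).fit(structured_cohort.donor_matrix)
        profiles = est.transform(structured_cohort.ancestry_targets)
        err = np.abs(profiles.to_numpy() - structured_cohort.true_ancestry.to_numpy())
        assert err.max() < 1e-8

    def test_degenerate_donor_matrix_rejected(self):
        cfg = sk.ScenarioConfig()
        X = sk.make_donor_matrix(cfg.source_names).df.copy()
        X.iloc[1] = X.iloc[0]
        degenerate = sk.DonorCopyMatrix(X)
        with pytest.raises(ValueError, match="rank"):
            sk.simulate_ancestry_targets(cfg, degenerate)

    def test_flat_gradients_give_no_axis_signal(self):
        specs = (sk.GradientSpec("a", 73.0, 0.5, 0.0, 0.01),
                 sk.GradientSpec("b", 253.0, 0.5, 0.0, 0.01))
        cfg = sk.ScenarioConfig(n_demes=2, n_per_deme=30, gradient_specs=specs,
                                seed=21)
        targets, _ = sk.simulate_ancestry_targets(cfg, sk.make_donor_matrix(["a", "b"]))
        coords = sk.simulate_geography(cfg)[["longitude", "latitude"]].to_numpy()
        g = sk.gradient_axis_scan(targets["a"].to_numpy(), coords)
        assert g.r_squared < 0.15

    def test_injected_bearing_recovered(self):
        specs = (sk.GradientSpec("a", 73.0, 0.5, 0.05, 0.0),
                 sk.GradientSpec("b", 253.0, 0.5, 0.05, 0.0))
        cfg = sk.ScenarioConfig(n_demes=2, n_per_deme=30, gradient_specs=specs,
                                seed=2)
        _, truth = sk.simulate_ancestry_targets(cfg, sk.make_donor_matrix(["a", "b"]))
        coords = sk.simulate_geography(cfg)[["longitude", "latitude"]].to_numpy()
        g = sk.gradient_axis_scan(truth["a"].to_numpy(), coords)
        assert abs(g.bearing_deg - 73.0) <= 1.0
        assert g.r_squared > 0.99


class TestPhenotype:
    def test_extreme_negative_base_gives_all_controls(self):
        cfg = sk.ScenarioConfig(n_demes=2, n_per_deme=20, phenotype_base=-30.0)
        ind = sk.simulate_geography(cfg)
        assert sk.simulate_phenotype(cfg, ind).sum() == 0

    def test_stratified_phenotype_predicted_by_pc1(self):
        cfg = sk.ScenarioConfig(n_demes=2, n_per_deme=50, within_deme_boost=50.0,
                                spatial_decay=0.2,
                                phenotype_intercepts=(-2.0, 2.0), seed=13)
        coh = sk.generate_cohort(cfg)
        scores = sk.pca_coancestry(coh.coancestry, 1)
        res = sk.nagelkerke_r2(coh.phenotype.loc[scores.index], scores)
        assert res.r2 > 0.1

    def test_null_phenotype_not_predicted(self):
        # with no deme offsets structure PCs explain almost nothing at n=600
        below = 0
        for seed in range(20):
            cfg = sk.ScenarioConfig(n_demes=3, n_per_deme=200,
                                    within_deme_boost=50.0, spatial_decay=0.2,
                                    seed=seed)
            ind = sk.simulate_geography(cfg)
            pheno = sk.simulate_phenotype(cfg, ind)
            # structure covariate: deme indicator projected to one axis
            covar = ind["deme"].str.removeprefix("deme").astype(float)
            res = sk.nagelkerke_r2(pheno, covar.to_frame("pc"))
            below += res.r2 < 0.02
        assert below >= 18


class TestEq2Oracle:
    def test_matches_closed_form(self):
        got = sk.eq2_oracle(3.0, 5.0, n_draws=10 ** 6, seed=4)
        assert abs(got - 40.0) < 0.5
        got = sk.eq2_oracle(5.0, 7.0, n_draws=10 ** 6, seed=4)
        assert abs(got - 75.0 * (1 / 5 + 1 / 7)) < 0.5

    def test_narrow_bin_approaches_degenerate_limit(self):
        # E[t | l = L] -> 150/L as the bin collapses
        got = sk.eq2_oracle(4.8, 5.2, n_draws=2 * 10 ** 6, seed=8)
        assert abs(got - 30.0) < 2.0

    def test_truncated_time_prior_rejected(self):
        with pytest.raises(ValueError, match="T_max"):
            sk.eq2_oracle(3.0, 5.0, n_draws=1000, T_max=100.0)

    def test_invalid_bin_rejected(self):
        with pytest.raises(ValueError):
            sk.eq2_oracle(5.0, 3.0, n_draws=1000)
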