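"""Gibbs-sampled phylogenetic mixed model: contracts and parameter recovery."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from nutriphylo import (
    McmcConfig,
    VariancePrior,
    fit_phylo_mixed_model,
    prior_sensitivity,
    regress_optimal_on_selfregulated,
    simulate_bm_traits,
    simulate_trait_dataset,
    simulate_tree,
    vcv_from_tree,
)

FAST = McmcConfig(n_iter=4000, burn_in=1000, thin=3, n_chains=1, seed=0)


@pytest.fixture(scope="module")
def tree30():
    return simulate_tree(30, seed=4)


class TestConfig:
    def test_reference_settings_retain_900_samples(self):
        cfg = McmcConfig(n_iter=20000, burn_in=2000, thin=20)
        assert cfg.n_retained == 900

    def test_retained_count_matches_run(self, tree30):
        cfg = McmcConfig(n_iter=600, burn_in=100, thin=5, n_chains=2, seed=1)
        tr = simulate_bm_traits(tree30, seed=0)
        res = fit_phylo_mixed_model(tr, tree30, config=cfg)
        assert res.n_retained_per_chain == cfg.n_retained == 100
        assert len(res.lambda_samples) == 200

    @pytest.mark.parametrize("bad", [
        dict(burn_in=20000), dict(thin=0), dict(fixed_prior_variance=0.0),
    ])
    def test_invalid_config_rejected(self, bad):
        with pytest.raises(ValueError):
            McmcConfig(**bad)

    def test_invalid_prior_rejected(self):
        with pytest.raises(ValueError):
            VariancePrior(V=-1.0)


class TestConjugacy:
    def test_residual_only_posterior_matches_closed_form(self):
        # with phylogenetic and study terms removed and no intercept, the
        # residual-variance posterior is inverse-gamma in closed form
        rng = np.random.default_rng(8)
        y = rng.normal(0.0, 1.3, 40)
        df = pd.DataFrame({"species": [f"x{i}" for i in range(40)], "value": y})
        tree = simulate_tree(4, seed=0)  # unused by the residual-only model
        nu, V = 0.02, 1.0
        cfg = McmcConfig(n_iter=21000, burn_in=1000, thin=2, n_chains=1,
                         seed=2, residual_prior=VariancePrior(V, nu))
        # species absent from tree is fine: the term is disabled
        res = fit_phylo_mixed_model(
            df.assign(species="t1"), tree, config=cfg,
            random_terms=(), include_intercept=False,
        )
        samples = np.concatenate([c["sigma2_resid"] for c in res.chains])
        assert len(samples) == 10000
        shape = (nu + len(y)) / 2
        scale = (nu * V + float(y @ y)) / 2
        ks = stats.kstest(samples, stats.invgamma(shape, scale=scale).cdf)
        assert ks.statistic < 0.02

    def test_bit_reproducible_single_chain(self, tree30):
        tr = simulate_bm_traits(tree30, seed=1)
        a = fit_phylo_mixed_model(tr, tree30, config=FAST)
        b = fit_phylo_mixed_model(tr, tree30, config=FAST)
        np.testing.assert_array_equal(a.lambda_samples, b.lambda_samples)


class TestRecovery:
    def test_bm_traits_give_high_lambda(self, tree30):
        lams = []
        for r in range(3):
            tr = simulate_trait_dataset(tree30, lam=1.0, n_studies=3,
                                        study_sd=0.3, resid_sd=0.1,
                                        seed=40 + r)
            cfg = McmcConfig(n_iter=4000, burn_in=1000, thin=3, n_chains=1,
                             seed=r)
            lams.append(fit_phylo_mixed_model(tr, tree30, config=cfg).lambda_mean)
        assert np.mean(lams) > 0.7

    def test_iid_traits_give_low_lambda(self, tree30):
        cov = vcv_from_tree(tree30)
        lams = []
        for r in range(3):
            rng = np.random.default_rng(50 + r)
            frames = [
                pd.DataFrame({"species": cov.labels,
                              "value": rng.standard_normal(30),
                              "study": f"s{s}"})
                for s in range(3)
            ]
            tr = pd.concat(frames, ignore_index=True)
            cfg = McmcConfig(n_iter=4000, burn_in=1000, thin=3, n_chains=1,
                             seed=r)
            lams.append(fit_phylo_mixed_model(tr, tree30, config=cfg).lambda_mean)
        assert np.mean(lams) < 0.3

    def test_posterior_mean_monotone_in_true_lambda(self, tree30):
        # one observation per species: the residual is then the
        # non-phylogenetic species-level noise that lambda is defined against
        from nutriphylo import simulate_lambda_traits

        means = []
        for lam in (0.0, 0.5, 1.0):
            vals = []
            for r in range(4):
                tr = simulate_lambda_traits(tree30, lam,
                                            seed=int(60 + 10 * lam) + r)
                cfg = McmcConfig(n_iter=3000, burn_in=800, thin=2,
                                 n_chains=1, seed=r)
                vals.append(
                    fit_phylo_mixed_model(tr, tree30, config=cfg).lambda_mean
                )
            means.append(np.mean(vals))
        assert means[0] < means[1] < means[2]

    def test_study_term_dropped_with_note_when_single_study(self, tree30):
        tr = simulate_bm_traits(tree30, seed=2)
        res = fit_phylo_mixed_model(tr, tree30, config=FAST)
        assert any("study term dropped" in n for n in res.notes)

    def test_species_mismatch_reported(self, tree30):
        tr = simulate_bm_traits(tree30, seed=2)
        tr.loc[0, "species"] = "unknown_sp"
        with pytest.raises(ValueError, match="unknown_sp"):
            fit_phylo_mixed_model(tr, tree30, config=FAST)

    def test_rhat_reported_per_component_with_two_chains(self, tree30):
        tr = simulate_bm_traits(tree30, seed=3)
        cfg = McmcConfig(n_iter=2000, burn_in=500, thin=2, n_chains=2, seed=5)
        res = fit_phylo_mixed_model(tr, tree30, config=cfg)
        assert set(res.rhat) >= {"lambda", "sigma2_resid", "sigma2_phylo"}
        assert all(v >= 1.0 for v in res.rhat.values())
        assert res.converged in (True, False)


class TestPriorSensitivity:
    def test_default_grid_has_four_rows(self, tree30):
        tr = simulate_trait_dataset(tree30, lam=1.0, n_studies=2,
                                    resid_sd=0.1, seed=9)
        cfg = McmcConfig(n_iter=1500, burn_in=400, thin=2, n_chains=1, seed=0)
        tab = prior_sensitivity(tr, tree30, config=cfg)
        assert len(tab) == 4
        assert list(tab["nu"]) == [1e-6, 0.002, 0.02, 0.2]

    def test_strong_signal_robust_across_priors(self, tree30):
        tr = simulate_trait_dataset(tree30, lam=1.0, n_studies=3,
                                    study_sd=0.2, resid_sd=0.1, seed=10)
        cfg = McmcConfig(n_iter=2500, burn_in=600, thin=2, n_chains=1, seed=0)
        tab = prior_sensitivity(tr, tree30, config=cfg)
        assert (tab["lambda_mean"] > 0.5).all()

    def test_flat_traits_flagged_degenerate(self, tree30):
        cov = vcv_from_tree(tree30)
        tr = pd.DataFrame({"species": cov.labels, "value": 1.0})
        tab = prior_sensitivity(tr, tree30, config=FAST)
        assert (tab["flag"].str.contains("degenerate")).all()
        assert tab["lambda_mean"].isna().all()


def _paired_table(tree, slope, noise_sd, seed):
    cov = vcv_from_tree(tree)
    rng = np.random.default_rng(seed)
    rows = []
    for s in range(3):
        x = rng.uniform(0.2, 2.0, len(cov.labels))
        y = slope * x + rng.normal(0, noise_sd, len(x))
        for sp, xi, yi in zip(cov.labels, x, y):
            rows.append((sp, "optimal_pc_ratio", yi, f"s{s}", "female"))
            rows.append((sp, "self_regulated_pc_ratio", xi, f"s{s}", "female"))
    return pd.DataFrame(rows, columns=["species", "trait", "value", "study", "sex"])


class TestRegression:
    def test_unit_slope_recovered(self, tree30):
        table = _paired_table(tree30, slope=1.0, noise_sd=0.05, seed=11)
        cfg = McmcConfig(n_iter=4000, burn_in=1000, thin=3, n_chains=1, seed=0)
        res = regress_optimal_on_selfregulated(table, tree30, config=cfg)
        assert res.slope_mean == pytest.approx(1.0, abs=0.15)
        lo, hi = res.slope_hpd
        assert lo > 0

    def test_independent_predictor_interval_spans_zero(self, tree30):
        table = _paired_table(tree30, slope=0.0, noise_sd=1.0, seed=12)
        cfg = McmcConfig(n_iter=4000, burn_in=1000, thin=3, n_chains=1, seed=0)
        res = regress_optimal_on_selfregulated(table, tree30, config=cfg)
        lo, hi = res.slope_hpd
        assert lo < 0 < hi

    def test_constant_predictor_rejected(self, tree30):
        table = _paired_table(tree30, slope=1.0, noise_sd=0.1, seed=13)
        table.loc[table["trait"] == "self_regulated_pc_ratio", "value"] = 1.0
        with pytest.raises(ValueError, match="constant"):
            regress_optimal_on_selfregulated(table, tree30)
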