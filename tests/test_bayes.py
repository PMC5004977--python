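"""Bayesian estimation: model assembly, sampler correctness, diagnostics, DIC."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from glidebuoy import (
    GlideTableDesign,
    ModelSpec,
    Priors,
    TruthConfig,
    build_model,
    draw_truth,
    gelman_rubin,
    run_mcmc,
    simulate_glide_table,
)
from glidebuoy.errors import InsufficientDataError

GLOBAL_SPEC = ModelSpec(
    density_level="global", drag_level="global", gas_level="global",
    include_compressibility=True,
)


def _table(n_ind=3, glides=60, seed=0, sigma=(0.005, 0.05), depth=(20.0, 800.0), **truth_kw):
    cfg = TruthConfig(n_individuals=n_ind, dives_per_individual=4, **truth_kw)
    truth = draw_truth(cfg, seed=seed)
    design = GlideTableDesign(
        glides_per_individual=glides, sigma_a_range=sigma, depth_range=depth
    )
    return truth, simulate_glide_table(truth, design, seed=seed)


class TestBuildModel:
    def test_global_spec_has_four_free_parameters(self):
        _, tab = _table()
        model = build_model(tab, GLOBAL_SPEC)
        n_free = sum(len(v) for v in (b.group_names for b in model.blocks)) + 1  # + r
        assert n_free == 4

    def test_hierarchical_density_parameter_count(self):
        _, tab = _table(n_ind=12, glides=12)
        spec = ModelSpec(density_level="hierarchical", drag_level="global",
                         gas_level="global")
        model = build_model(tab, spec)
        # 12 individual densities + mean + s.d. hyperparameters
        assert model.density.size == 12
        assert model.density.prior_kind == "hier"

    def test_noiseless_table_perfect_fit_at_truth(self):
        truth, tab = _table(n_ind=2, glides=40, sigma=(0.0, 0.0))
        spec = ModelSpec(density_level="individual", drag_level="individual",
                         gas_level="dive", include_compressibility=True)
        model = build_model(tab, spec)
        gas = np.empty(model.n_dives)
        for j, key in enumerate(model.dive_ids):
            ind, dive = key.split(":")
            i = truth.individual_ids.index(ind)
            mask = (truth.dive_individual == i) & (truth.dive_ids == int(dive))
            gas[j] = truth.vair_per_mass[mask][0]
        ll = model.log_likelihood(truth.rho_tissue, truth.drag_term, gas, truth.r)
        # residual sum is exactly zero: only the sigma-floor constants remain
        assert ll == pytest.approx(
            -model.log_sigma_sum - model.n_seg * 0.5 * np.log(2 * np.pi), abs=1e-9
        )

    def test_empty_table_rejected(self):
        with pytest.raises(InsufficientDataError):
            build_model(pd.DataFrame(columns=["a"]), GLOBAL_SPEC)


def _fixed(value):
    return (value, value)


class TestSamplerCorrectness:
    def test_linear_gas_posterior_matches_closed_form(self):
        """With density, drag and r fixed, the model is linear in the gas
        volume, so the posterior is a truncated Gaussian available in
        closed form."""
        truth, tab = _table(n_ind=2, glides=80, seed=4, density_sd=0.0,
                            drag_sd=0.0, gas_dive_sd=0.0)
        priors = Priors(
            density_bounds=_fixed(truth.rho_tissue[0]),
            drag_bounds=_fixed(truth.drag_term[0]),
            drag_mean=truth.drag_term[0],
            gas_global_bounds=(5.0, 50.0),
        )
        spec = ModelSpec(density_level="global", drag_level="global",
                         gas_level="global", include_compressibility=False)
        model = build_model(tab, spec, priors)
        # independent closed form: a_i = c0_i + c2_i * V + noise
        c2 = model.gas_factor
        c0 = (
            -0.5 * truth.drag_term[0] * model.rho_sw * model.v2
            + model.gsinp * (model.rho_sw / truth.rho_tissue[0] - 1.0)
        )
        w = model.inv_var
        s2 = 1.0 / np.sum(w * c2**2)
        m = s2 * np.sum(w * c2 * (model.a_obs - c0))
        a, b = (5.0 - m) / np.sqrt(s2), (50.0 - m) / np.sqrt(s2)
        ref = stats.truncnorm(a, b, loc=m, scale=np.sqrt(s2))
        res = run_mcmc(model, n_iter=8000, n_burn=3000, thin=5, seed=9)
        draws = res.pooled("vair")
        assert np.mean(draws) == pytest.approx(ref.mean(), abs=0.15 * ref.std())
        assert np.std(draws) == pytest.approx(ref.std(), rel=0.2)

    def test_same_seed_bit_identical(self):
        _, tab = _table(n_ind=2, glides=30)
        model = build_model(tab, GLOBAL_SPEC)
        r1 = run_mcmc(model, n_iter=1200, n_burn=600, thin=6, seed=7)
        r2 = run_mcmc(model, n_iter=1200, n_burn=600, thin=6, seed=7)
        for k in r1.draws:
            assert np.array_equal(r1.draws[k], r2.draws[k])
        assert r1.summaries.equals(r2.summaries)

    def test_posterior_equals_prior_without_information(self):
        """An (effectively) flat likelihood must return the priors."""
        _, tab = _table(n_ind=2, glides=40, seed=2)
        tab = tab.assign(sigma_a=1.0e6)
        model = build_model(tab, GLOBAL_SPEC, sigma_floor=1e-3)
        res = run_mcmc(model, n_iter=40000, n_burn=4000, thin=36, seed=3)
        r_draws = res.pooled("r")
        dens_draws = res.pooled("rho_tissue")
        assert stats.kstest(r_draws, stats.uniform(0.3e-9, 0.4e-9).cdf).pvalue > 0.01
        assert stats.kstest(dens_draws, stats.uniform(800.0, 400.0).cdf).pvalue > 0.01

    def test_truncations_respected(self):
        _, tab = _table(n_ind=3, glides=40, seed=5)
        spec = ModelSpec(density_level="hierarchical", drag_level="individual",
                         gas_level="global")
        model = build_model(tab, spec)
        res = run_mcmc(model, n_iter=3000, n_burn=1000, thin=4, seed=5)
        drag = res.draws["drag"]
        assert drag.min() >= 5.0e-6 and drag.max() <= 20.0e-6
        r = res.draws["r"]
        assert r.min() >= 0.3e-9 and r.max() <= 0.7e-9

    def test_parameter_recovery_reduced_scale(self):
        truth, tab = _table(n_ind=4, glides=150, seed=8, gas_dive_sd=0.0)
        spec = ModelSpec(density_level="hierarchical", drag_level="hierarchical",
                         gas_level="global", include_compressibility=True)
        model = build_model(tab, spec)
        res = run_mcmc(model, n_iter=8000, n_burn=4000, thin=4, seed=8)
        for i, ind in enumerate(model.individual_ids):
            est = res.summaries.loc[f"rho_tissue[{ind}]", "mean"]
            assert est == pytest.approx(truth.rho_tissue[i], abs=1.5)
        assert res.pooled("vair").mean() == pytest.approx(truth.vair_per_mass[0], abs=5.0)
        assert res.pooled("r").mean() == pytest.approx(truth.r, abs=0.05e-9)

    def test_gas_information_lives_near_surface(self):
        """Deep-only glides leave the gas volume weakly identified: the
        posterior stays far wider than with the same number of glides
        spanning shallow depths."""
        _, tab_deep = _table(n_ind=2, glides=150, seed=6, depth=(300.0, 800.0),
                             gas_dive_sd=0.0)
        _, tab_full = _table(n_ind=2, glides=150, seed=6, depth=(20.0, 800.0),
                             gas_dive_sd=0.0)
        widths = {}
        for name, tab in (("deep", tab_deep), ("full", tab_full)):
            model = build_model(tab, GLOBAL_SPEC)
            res = run_mcmc(model, n_iter=6000, n_burn=3000, thin=3, seed=6)
            s = res.summaries.loc["vair"]
            widths[name] = s["ci_97.5"] - s["ci_2.5"]
        assert widths["deep"] > 3.0 * widths["full"]


class TestGelmanRubin:
    def test_hand_computed_toy(self):
        chains = np.array([[1.0, 2.0, 3.0, 4.0], [3.0, 4.0, 5.0, 6.0]])
        w = 5.0 / 3.0  # mean within-chain variance
        b_over_n = 2.0  # variance of the chain means
        expected = np.sqrt(((4 - 1) / 4 * w + b_over_n) / w)
        assert gelman_rubin(chains) == pytest.approx(expected, abs=1e-12)

    def test_well_mixed_chains_near_one(self):
        rng = np.random.default_rng(0)
        chains = rng.normal(size=(3, 2000))
        assert gelman_rubin(chains) < 1.1

    def test_disjoint_chains_far_above_one(self):
        rng = np.random.default_rng(1)
        chains = np.stack([rng.normal(0, 1, 500), rng.normal(100, 1, 500)])
        assert gelman_rubin(chains) > 10

    def test_degenerate_chains_warn(self):
        with pytest.warns(UserWarning):
            gelman_rubin(np.ones((2, 50)))

    def test_matches_arviz_on_mixed_chains(self):
        az = pytest.importorskip("arviz")
        rng = np.random.default_rng(2)
        chains = rng.normal(size=(4, 1000))
        ours = gelman_rubin(chains)
        theirs = float(az.rhat(az.convert_to_dataset(chains))["x"].values)
        assert abs(ours - theirs) < 0.05


class TestDIC:
    def test_flat_likelihood_gives_zero_complexity(self):
        _, tab = _table(n_ind=2, glides=30, seed=3)
        tab = tab.assign(sigma_a=1.0e6)
        model = build_model(tab, GLOBAL_SPEC)
        res = run_mcmc(model, n_iter=4000, n_burn=2000, thin=4, seed=3)
        assert res.pd_eff == pytest.approx(0.0, abs=0.05)

    def test_one_free_parameter_has_pd_near_one(self):
        truth, tab = _table(n_ind=2, glides=250, seed=4, density_sd=0.0,
                            drag_sd=0.0, gas_dive_sd=0.0)
        priors = Priors(
            density_bounds=_fixed(truth.rho_tissue[0]),
            drag_bounds=_fixed(truth.drag_term[0]),
            drag_mean=truth.drag_term[0],
        )
        spec = ModelSpec(density_level="global", drag_level="global",
                         gas_level="global", include_compressibility=False)
        model = build_model(tab, spec, priors)
        res = run_mcmc(model, n_iter=8000, n_burn=3000, thin=5, seed=4)
        assert res.pd_eff == pytest.approx(1.0, abs=0.4)
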