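import math
from dataclasses import replace

import numpy as np
import pytest

from rcikit.design import DesignConfig, build_paired_design, build_single_design
from rcikit.errors import GrowthModelError
from rcikit.growth import (
    cell_label,
    design_matrices,
    fit_growth_model,
    test_provenance_effect,
)
from rcikit.simulate import TrueParams, generate_dataset


def _sp_pots(config=None, species="arvense", paired=True):
    config = config or DesignConfig()
    pots = list(build_single_design("SP", config))
    if paired:
        pots += build_paired_design("SP", config)
    return [p for p in pots if p.species == species]


def _sp_params(**overrides):
    defaults = dict(
        single_cell_means_log={("arvense", "SP", "NZ"): -3.3, ("arvense", "SP", "SP"): -3.5},
        true_rci={("arvense", "SP", "NZ", "SP"): 0.35, ("arvense", "SP", "SP", "NZ"): 0.15},
        beta_nod=0.08,
        sigma_site=0.10,
        sigma_resid=0.30,
        seed=0,
    )
    defaults.update(overrides)
    return TrueParams(**defaults)


def brute_force_gls(records, sigma_site, sigma_resid, **kwargs):
    """Independent oracle: explicit V = s2*I + s_site^2*ZZ' and direct solve."""
    X, y, _, _, groups = design_matrices(records, **kwargs)
    Z = (groups[:, None] == np.unique(groups)[None, :]).astype(float)
    V = sigma_resid**2 * np.eye(len(y)) + sigma_site**2 * (Z @ Z.T)
    Vi = np.linalg.inv(V)
    A = X.T @ Vi @ X
    return np.linalg.solve(A, X.T @ Vi @ y), np.linalg.inv(A)


class TestFitGrowthModel:
    def test_noiseless_recovery(self):
        params = _sp_params(sigma_site=1e-8, sigma_resid=1e-8, beta_nod=0.0)
        records = generate_dataset(_sp_pots(), params)
        fit = fit_growth_model(records)
        assert fit.coef("NZ") == pytest.approx(-3.3, abs=1e-6)
        assert fit.coef("SP") == pytest.approx(-3.5, abs=1e-6)
        assert fit.coef("NZ(SP)") == pytest.approx(-3.3 + math.log1p(-0.35), abs=1e-6)
        assert fit.coef("SP(NZ)") == pytest.approx(-3.5 + math.log1p(-0.15), abs=1e-6)

    def test_gls_oracle_12_rows(self):
        # 12 observations: 2 provenances x 3 sites x 2 replicates, singles only
        config = DesignConfig(sites_per_country=3)
        records = generate_dataset(_sp_pots(config, paired=False), _sp_params(seed=8))
        assert len(records) == 12
        fit = fit_growth_model(records, include_paired=False)
        beta, vcov = brute_force_gls(
            records, fit.sigma_site_hat, fit.sigma_resid_hat, include_paired=False
        )
        np.testing.assert_allclose(fit.coefficients, beta, atol=1e-8)
        np.testing.assert_allclose(fit.vcov_fixed, vcov, atol=1e-8)

    def test_gls_oracle_with_paired_cells(self, sp_soil_records):
        fit = fit_growth_model(sp_soil_records)
        beta, _ = brute_force_gls(sp_soil_records, fit.sigma_site_hat, fit.sigma_resid_hat)
        np.testing.assert_allclose(fit.coefficients, beta, atol=1e-8)

    def test_nodulation_slope_recovery(self):
        # DERIVED: slope estimate within 3 SEs of the generating value
        config = DesignConfig(sites_per_country=5, replicates=40)  # n = 400 singles
        params = _sp_params(beta_nod=0.2, seed=31)
        records = generate_dataset(_sp_pots(config, paired=False), params)
        assert len(records) == 400
        fit = fit_growth_model(records, include_paired=False)
        i = fit.index("nodulation")
        se = math.sqrt(fit.vcov_fixed[i, i])
        assert abs(fit.coefficients[i] - 0.2) < 3 * se

    def test_single_site_falls_back_to_ols(self):
        config = DesignConfig(sites_per_country=1, replicates=6)
        records = generate_dataset(_sp_pots(config, paired=False), _sp_params(seed=2))
        with pytest.warns(UserWarning, match="one soil site"):
            fit = fit_growth_model(records, include_paired=False)
        assert fit.fitted_by == "ols_fallback"
        assert fit.sigma_site_hat == 0.0
        # exactly OLS on the same design matrix
        X, y, _, _, _ = design_matrices(records, include_paired=False)
        beta_ols = np.linalg.lstsq(X, y, rcond=None)[0]
        np.testing.assert_allclose(fit.coefficients, beta_ols, atol=1e-10)

    def test_missing_expected_cell_named(self, sp_soil_records):
        with pytest.raises(GrowthModelError, match="UK"):
            fit_growth_model(sp_soil_records, expected_cells=("NZ", "SP", "UK"))

    def test_multiple_soils_rejected(self, full_records):
        with pytest.raises(GrowthModelError, match="soil_country"):
            fit_growth_model(full_records[full_records["species"] == "arvense"])

    def test_vcov_symmetric_psd(self, sp_soil_records):
        fit = fit_growth_model(sp_soil_records)
        np.testing.assert_allclose(fit.vcov_fixed, fit.vcov_fixed.T)
        assert np.linalg.eigvalsh(fit.vcov_fixed).min() > -1e-12
        assert fit.vcov_fixed.shape == (len(fit.coefficients),) * 2
        assert len(set(fit.coef_labels)) == len(fit.coef_labels)

    def test_vcov_shrinks_with_replication(self):
        # widely spaced replication levels so sampling noise in the variance
        # components cannot mask the 1/n shrinkage
        diags = []
        for reps in (2, 8, 32):
            config = DesignConfig(sites_per_country=5, replicates=reps)
            records = generate_dataset(_sp_pots(config), _sp_params(seed=17))
            fit = fit_growth_model(records)
            diags.append(np.diag(fit.vcov_fixed)[: len(fit.cell_labels)])
        assert np.all(diags[1] < diags[0])
        assert np.all(diags[2] < diags[1])

    def test_nodulation_adjustment_benign_when_unneeded(self):
        # stochastic invariant: across seeds, the adjustment rarely moves a
        # cell mean by more than its standard error when beta_nod = 0
        violations = total = 0
        for seed in range(20):
            params = _sp_params(beta_nod=0.0, seed=100 + seed)
            records = generate_dataset(_sp_pots(), params)
            with_nod = fit_growth_model(records)
            without = fit_growth_model(records, include_nodulation=False)
            for label in with_nod.cell_labels:
                i = with_nod.index(label)
                se = math.sqrt(with_nod.vcov_fixed[i, i])
                violations += abs(with_nod.coef(label) - without.coef(label)) >= se
                total += 1
        assert violations / total < 0.2

    def test_nodulation_as_factor(self, sp_soil_records):
        fit = fit_growth_model(sp_soil_records, nod_as_factor=True)
        assert any(l.startswith("nodulation_") for l in fit.coef_labels)

    def test_loglik_ordering(self, sp_soil_records):
        fit = fit_growth_model(sp_soil_records)
        assert np.isfinite(fit.loglik_reml) and np.isfinite(fit.loglik_ml)


class TestProvenanceTest:
    @staticmethod
    def _null_records(seed, replicates=2):
        config = DesignConfig(replicates=replicates)
        means = {("arvense", "SP", "NZ"): -3.4, ("arvense", "SP", "SP"): -3.4}
        params = _sp_params(single_cell_means_log=means, seed=seed)
        return generate_dataset(_sp_pots(config, paired=False), params)

    def test_single_provenance_rejected(self):
        records = self._null_records(1)
        only_nz = records[records["focal_provenance"] == "NZ"]
        with pytest.raises(GrowthModelError, match="two provenances"):
            test_provenance_effect(only_nz)

    def test_lrt_fields(self):
        t = test_provenance_effect(self._null_records(3))
        assert t.method == "lrt_ml" and t.df_num == 1 and t.df_den is None
        assert 0 <= t.p_value <= 1 and t.statistic >= 0

    def test_approx_f_fields(self):
        t = test_provenance_effect(self._null_records(3), method="approx_f")
        assert t.method == "approx_f" and t.df_den is not None and t.df_den > 0

    def test_type_one_error_smoke(self):
        # quick version; the full 1000-replicate check lives in test_acceptance
        rejections = sum(
            test_provenance_effect(self._null_records(100 + i, replicates=4)).p_value < 0.05
            for i in range(150)
        )
        assert rejections / 150 < 0.12

    def test_power_with_twofold_difference(self):
        # DERIVED: power simulation at a log(2) growth-rate gap, n = 20
        config = DesignConfig()
        means = {("arvense", "SP", "NZ"): -3.4 + math.log(2), ("arvense", "SP", "SP"): -3.4}
        hits = 0
        n_sims = 60
        for i in range(n_sims):
            params = _sp_params(single_cell_means_log=means, seed=500 + i)
            records = generate_dataset(_sp_pots(config, paired=False), params)
            assert len(records) == 20
            hits += test_provenance_effect(records).p_value < 0.05
        assert hits / n_sims > 0.7  # large majority

    def test_shuffled_labels_behave_like_null(self, rng):
        # permutation sanity: shuffling provenance labels kills the signal
        config = DesignConfig(replicates=4)
        means = {("arvense", "SP", "NZ"): -2.9, ("arvense", "SP", "SP"): -3.5}
        params = _sp_params(single_cell_means_log=means, seed=900)
        records = generate_dataset(_sp_pots(config, paired=False), params)
        assert test_provenance_effect(records).p_value < 0.01
        pvals = []
        for _ in range(60):
            shuffled = records.copy()
            shuffled["focal_provenance"] = rng.permutation(
                shuffled["focal_provenance"].to_numpy()
            )
            pvals.append(test_provenance_effect(shuffled).p_value)
        assert 0.25 < np.mean(pvals) < 0.75

    def test_unknown_method_rejected(self):
        with pytest.raises(GrowthModelError):
            test_provenance_effect(self._null_records(4), method="bayes")


def test_cell_label():
    assert cell_label("NZ", None) == "NZ"
    assert cell_label("NZ", float("nan")) == "NZ"
    assert cell_label("NZ", "SP") == "NZ(SP)"
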