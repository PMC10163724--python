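import numpy as np
import pandas as pd
import pytest

from gsel.grm import RelationshipMatrix, build_grm, regularize
from gsel.mixed_model import (
    REMLConvergenceError,
    VarianceComponents,
    build_design,
    classify_correlation,
    classify_heritability,
    heritability,
    reml_bivariate,
    reml_univariate,
    restricted_loglik,
    solve_mme,
)
from gsel.simulate import (
    SimConfig,
    simulate_bivariate_phenotypes,
    simulate_genotypes,
    simulate_phenotypes,
)

from conftest import make_geno


def identity_rel(n):
    return RelationshipMatrix(
        np.eye(n), np.array([f"a{i}" for i in range(n)], dtype=object), "SP"
    )


def vc(sa, se):
    return VarianceComponents(sa, se, 0.0, 0.0, np.eye(2), 0.0, 0, True)


class TestBuildDesign:
    def _pheno(self):
        return pd.DataFrame(
            {
                "animal_id": ["a0", "a1", "a2", "a3"],
                "bw": [1.0, 2.0, np.nan, 4.0],
                "sex": ["F", "M", "F", "M"],
            }
        )

    def test_treatment_coding_dimensions(self):
        rel = identity_rel(4)
        y, x, z, names = build_design(self._pheno(), "bw", rel, ("sex",))
        assert x.shape == (3, 2)  # intercept + one dummy
        assert names == ["intercept", "sex[M]"]
        assert len(y) == 3 and z.shape == (3, 4)

    def test_missing_trait_records_excluded(self):
        rel = identity_rel(4)
        y, _, z, _ = build_design(self._pheno(), "bw", rel, ("sex",))
        assert list(y) == [1.0, 2.0, 4.0]
        assert z[:, 2].sum() == 0  # a2 has no record

    def test_unknown_animal_rejected(self):
        rel = identity_rel(2)  # a0, a1 only
        with pytest.raises(KeyError, match="a3"):
            build_design(self._pheno(), "bw", rel, ("sex",))

    def test_single_level_factor_dropped_with_warning(self):
        df = self._pheno()
        df["sex"] = "F"
        rel = identity_rel(4)
        with pytest.warns(UserWarning, match="single level"):
            _, x, _, names = build_design(df, "bw", rel, ("sex",))
        assert names == ["intercept"]

    def test_confounded_factors_rejected(self):
        df = self._pheno()
        df["pen"] = df["sex"]  # perfectly aliased with sex
        rel = identity_rel(4)
        with pytest.raises(ValueError, match="confounded"):
            build_design(df, "bw", rel, ("sex", "pen"))


class TestSolveMme:
    def test_identity_kernel_matches_ridge_oracle(self):
        rng = np.random.default_rng(0)
        n = 6
        y = rng.normal(size=n)
        x = np.column_stack([np.ones(n), rng.normal(size=n)])
        z = np.eye(n)
        sa, se = 2.0, 3.0
        sol = solve_mme(y, x, z, identity_rel(n), vc(sa, se))
        # brute-force joint normal equations for [beta; u] with ridge se/sa I
        lam = se / sa
        top = np.hstack([x.T @ x, x.T])
        bot = np.hstack([x, np.eye(n) + lam * np.eye(n)])
        direct = np.linalg.solve(np.vstack([top, bot]), np.concatenate([x.T @ y, y]))
        assert sol.beta == pytest.approx(direct[:2], abs=1e-6)
        assert sol.u == pytest.approx(direct[2:], abs=1e-6)

    def test_beta_matches_gls_oracle(self):
        rng = np.random.default_rng(1)
        n = 8
        d = rng.integers(0, 3, size=(n, 12)).astype(np.int8)
        k = regularize(build_grm(make_geno(d), "SP"), 0.05)
        y = rng.normal(size=n)
        x = np.column_stack([np.ones(n), rng.normal(size=n)])
        z = np.eye(n)
        sa, se = 1.5, 0.7
        sol = solve_mme(y, x, z, k, vc(sa, se))
        v = sa * k.values + se * np.eye(n)
        vinv = np.linalg.inv(v)
        beta_gls = np.linalg.solve(x.T @ vinv @ x, x.T @ vinv @ y)
        assert sol.beta == pytest.approx(beta_gls, abs=1e-6)
        # u = sa K Z' V^-1 (y - X beta)
        u_direct = sa * k.values @ vinv @ (y - x @ beta_gls)
        assert sol.u == pytest.approx(u_direct, abs=1e-6)

    def test_vanishing_genetic_variance_shrinks_u_to_zero(self):
        rng = np.random.default_rng(2)
        n = 10
        y = rng.normal(size=n)
        x = np.ones((n, 1))
        sol = solve_mme(y, x, np.eye(n), identity_rel(n), vc(1e-10, 1.0))
        assert np.abs(sol.u).max() < 1e-6

    def test_gblup_equals_snp_blup(self):
        """GEBVs from the kernel model must equal Z alpha from the matched
        ridge regression on markers (the classical equivalence)."""
        rng = np.random.default_rng(3)
        n, m = 30, 40
        d = rng.integers(0, 3, size=(n, m)).astype(np.int8)
        geno = make_geno(d)
        # a fixed (non-mean) shift keeps Z Z' non-singular for the toy
        zc = d.astype(float) - 1.0
        c = float(m)
        g = RelationshipMatrix(zc @ zc.T / c, geno.animal_ids, "SV")
        y = rng.normal(size=n)
        x = np.ones((n, 1))
        sa, se = 1.0, 2.0
        sol = solve_mme(y, x, np.eye(n), g, vc(sa, se))
        # ridge marker effects with per-marker variance sa/c
        lam_r = se / (sa / c)
        alpha = np.linalg.solve(zc.T @ zc + lam_r * np.eye(m), zc.T @ (y - x @ sol.beta))
        assert sol.u == pytest.approx(zc @ alpha, abs=1e-6)


class TestRemlUnivariate:
    def test_recovers_moderate_heritability(self):
        cfg = SimConfig(n_animals=500, n_markers=1000, seed=42, mode="f2_cross",
                        target_h2=0.5, n_qtl=50)
        geno, _ = simulate_genotypes(cfg)
        pheno, truth = simulate_phenotypes(geno, cfg)
        rel = regularize(build_grm(geno, "IV"))
        y, x, z, _ = build_design(pheno, "trait", rel)
        est = reml_univariate(y, x, z, rel)
        h2, se = heritability(est)
        assert abs(h2 - truth.realized_h2) < 3 * se

    def test_null_data_estimate_near_lower_bound(self):
        cfg = SimConfig(n_animals=300, n_markers=500, seed=5, target_h2=0.0)
        geno, _ = simulate_genotypes(cfg)
        pheno, _ = simulate_phenotypes(geno, cfg)
        rel = regularize(build_grm(geno, "IV"))
        y, x, z, _ = build_design(pheno, "trait", rel)
        est = reml_univariate(y, x, z, rel)
        assert est.h2 < 0.15

    def test_optimum_beats_random_probes(self):
        rng = np.random.default_rng(11)
        cfg = SimConfig(n_animals=150, n_markers=300, seed=6, target_h2=0.4, n_qtl=20)
        geno, _ = simulate_genotypes(cfg)
        pheno, _ = simulate_phenotypes(geno, cfg)
        rel = regularize(build_grm(geno, "IV"))
        y, x, z, _ = build_design(pheno, "trait", rel)
        est = reml_univariate(y, x, z, rel)
        vy = np.var(y)
        for _ in range(20):
            probe = rng.uniform(0.05, 2.0, size=2) * vy
            assert restricted_loglik(probe, y, x, z, rel) <= est.loglik + 1e-6

    def test_location_and_scale_equivariance(self):
        cfg = SimConfig(n_animals=200, n_markers=400, seed=7, target_h2=0.5, n_qtl=20)
        geno, _ = simulate_genotypes(cfg)
        pheno, _ = simulate_phenotypes(geno, cfg)
        rel = regularize(build_grm(geno, "IV"))
        y, x, z, _ = build_design(pheno, "trait", rel)
        base = reml_univariate(y, x, z, rel)
        shifted = reml_univariate(y + 100.0, x, z, rel)
        assert shifted.sigma_a2 == pytest.approx(base.sigma_a2, rel=1e-6)
        assert shifted.sigma_e2 == pytest.approx(base.sigma_e2, rel=1e-6)
        scaled = reml_univariate(3.0 * y, x, z, rel)
        # individual components are weakly identified along the a/e ridge;
        # their sum (phenotypic variance) is stiff and must scale exactly
        total = base.sigma_a2 + base.sigma_e2
        assert scaled.sigma_a2 + scaled.sigma_e2 == pytest.approx(9.0 * total, rel=5e-3)
        assert scaled.sigma_a2 == pytest.approx(9.0 * base.sigma_a2, rel=0.05)
        assert scaled.sigma_e2 == pytest.approx(9.0 * base.sigma_e2, rel=0.05)


class TestRemlBivariate:
    def test_duplicated_trait_gives_unit_correlations(self):
        cfg = SimConfig(n_animals=150, n_markers=300, seed=8, target_h2=0.5, n_qtl=20)
        geno, _ = simulate_genotypes(cfg)
        pheno, _ = simulate_phenotypes(geno, cfg)
        rel = regularize(build_grm(geno, "IV"))
        y, x, z, _ = build_design(pheno, "trait", rel)
        est = reml_bivariate(y, y.copy(), x, z, rel)
        assert est.r_g == pytest.approx(1.0, abs=0.01)
        assert est.r_p == pytest.approx(1.0, abs=0.01)

    def test_independent_traits_near_zero_correlation(self):
        cfg = SimConfig(n_animals=400, n_markers=800, seed=9,
                        mode="independent_loci", n_qtl=200)
        geno, _ = simulate_genotypes(cfg)
        pheno, truth = simulate_bivariate_phenotypes(geno, cfg, r_g=0.0)
        rel = regularize(build_grm(geno, "IV"))
        y1, x, z, _ = build_design(pheno, "trait1", rel)
        y2 = pheno["trait2"].to_numpy()
        est = reml_bivariate(y1, y2, x, z, rel)
        se = est.r_g_se if np.isfinite(est.r_g_se) else 0.15
        assert abs(est.r_g) < max(3 * se, 0.3)

    def test_too_few_records_rejected(self):
        rel = identity_rel(10)
        with pytest.raises(ValueError, match="joint records"):
            reml_bivariate(
                np.ones(10), np.ones(10), np.ones((10, 1)), np.eye(10), rel
            )


class TestHeritabilityAndClassification:
    def test_equal_components_give_half(self):
        h2, _ = heritability(vc(1.0, 1.0))
        assert h2 == 0.5

    def test_zero_additive_gives_zero(self):
        h2, _ = heritability(vc(0.0, 1.0))
        assert h2 == 0.0

    def test_delta_se_close_to_bootstrap(self):
        """Delta-method SE vs a parametric bootstrap on a fixed toy."""
        rng = np.random.default_rng(13)
        n = 120
        d = rng.integers(0, 3, size=(n, 200)).astype(np.int8)
        rel = regularize(build_grm(make_geno(d), "IV"))
        x = np.ones((n, 1))
        z = np.eye(n)
        sa_true, se_true = 1.0, 1.0
        la = np.linalg.cholesky(rel.values)
        y = la @ rng.normal(size=n) * np.sqrt(sa_true) + rng.normal(size=n) * np.sqrt(se_true)
        est = reml_univariate(y, x, z, rel)
        _, se_delta = heritability(est)
        boot = []
        for _ in range(200):
            yb = la @ rng.normal(size=n) * np.sqrt(est.sigma_a2) + rng.normal(
                size=n
            ) * np.sqrt(est.sigma_e2)
            try:
                eb = reml_univariate(yb, x, z, rel)
            except REMLConvergenceError:
                continue
            boot.append(eb.h2)
        se_boot = np.std(boot)
        assert se_delta == pytest.approx(se_boot, rel=0.25)

    @pytest.mark.parametrize(
        "h2, label",
        [(0.08, "low"), (0.2, "low"), (0.32, "moderate"), (0.39999, "moderate"),
         (0.4, "high"), (0.63, "high")],
    )
    def test_heritability_bins(self, h2, label):
        assert classify_heritability(h2) == label

    @pytest.mark.parametrize(
        "r, label",
        [(0.1, "little"), (0.2, "weak"), (0.39, "weak"), (0.5, "moderate"),
         (0.976, "strong"), (-0.976, "strong"), (0.7, "strong")],
    )
    def test_correlation_bins(self, r, label):
        assert classify_correlation(r) == label

    def test_out_of_range_inputs_rejected(self):
        with pytest.raises(ValueError):
            classify_heritability(1.2)
        with pytest.raises(ValueError):
            classify_correlation(1.2)
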