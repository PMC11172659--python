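"""REML, whitening and Wald-scan machinery against independent oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from holowas.io import GenotypeMatrix
from holowas.kernels import RelationshipMatrix
from holowas.lmm import (
    ModelSpec,
    VarianceComponents,
    build_covariance,
    fit_variance_components,
    run_model,
    wald_scan,
    whiten,
)

rng = np.random.default_rng(77)


def _rm(values, kind="GRM", samples=None):
    n = values.shape[0]
    return RelationshipMatrix(samples or [f"s{i}" for i in range(n)], values, kind)


def _geno(dosages):
    dosages = np.asarray(dosages, dtype=float)
    n, q = dosages.shape
    snps = pd.DataFrame(
        {"id": [f"v{j}" for j in range(q)], "chrom": "1",
         "pos": np.arange(1, q + 1), "ref": "A", "alt": "B"}
    )
    return GenotypeMatrix([f"s{i}" for i in range(n)], snps, dosages)


def _psd_kernel(n, rank, kind="GRM", scale=1.0):
    a = rng.standard_normal((n, rank))
    return _rm(scale * a @ a.T / rank, kind)


def reml_loglik_direct(y, x, v):
    """From-scratch restricted log-likelihood via explicit inverses."""
    vi = np.linalg.inv(v)
    xtvix = x.T @ vi @ x
    beta = np.linalg.solve(xtvix, x.T @ vi @ y)
    r = y - x @ beta
    return -0.5 * (
        np.linalg.slogdet(v)[1]
        + np.linalg.slogdet(xtvix)[1]
        + float(r @ vi @ r)
    )


class TestREML:
    def test_no_kernels_reduces_to_sample_variance(self):
        y = rng.standard_normal(40)
        x = np.ones((40, 1))
        vc = fit_variance_components(y, x, [])
        assert vc.sigma2[0] == pytest.approx(np.var(y, ddof=1), abs=1e-8)

    def test_loglik_beats_grid_search_oracle(self):
        n = 60
        k = _psd_kernel(n, 40)
        v_true = 0.6 * k.values + 0.4 * np.eye(n)
        y = np.linalg.cholesky(v_true) @ rng.standard_normal(n)
        x = np.ones((n, 1))
        vc = fit_variance_components(y, x, [k])
        grid = np.linspace(0.01, 2.0, 50)
        best = max(
            reml_loglik_direct(y, x, sg * k.values + se * np.eye(n))
            for sg in grid
            for se in grid
        )
        assert vc.reml_loglik >= best - 1e-4

    def test_loglik_agrees_with_direct_formula(self):
        n = 30
        k = _psd_kernel(n, 20)
        y = rng.standard_normal(n)
        x = np.column_stack([np.ones(n), rng.standard_normal(n)])
        vc = fit_variance_components(y, x, [k])
        v = build_covariance([k], vc.sigma2)
        assert vc.reml_loglik == pytest.approx(reml_loglik_direct(y, x, v), abs=1e-6)

    def test_two_kernel_recovery_over_replicates(self):
        # truth (sigma_g2, sigma_m2, sigma_e2) = (0.4, 0.3, 0.3) at n=150:
        # mean estimates over replicates should track the truth
        n, reps = 150, 30
        truth = np.array([0.4, 0.3, 0.3])
        est = np.zeros((reps, 3))
        local = np.random.default_rng(5)
        for r in range(reps):
            kg = _psd_kernel(n, 400)
            km = _psd_kernel(n, 60, "MRM")
            v = truth[0] * kg.values + truth[1] * km.values + truth[2] * np.eye(n)
            y = np.linalg.cholesky(v) @ local.standard_normal(n)
            vc = fit_variance_components(y, np.ones((n, 1)), [kg, km])
            est[r] = vc.sigma2
        np.testing.assert_allclose(est.mean(axis=0), truth, rtol=0.25)

    def test_rank_deficient_design_rejected(self):
        y = rng.standard_normal(20)
        x = np.ones((20, 2))
        with pytest.raises(ValueError, match="rank"):
            fit_variance_components(y, x, [])

    def test_unconstrained_component_may_go_negative(self):
        # covariance-like kernel with negative true coefficient
        n = 80
        kg = _psd_kernel(n, 100)
        km = _psd_kernel(n, 50, "MRM")
        from holowas.kernels import compute_hrm_cg

        hc = compute_hrm_cg(_rm(kg.values + 0.05 * np.eye(n)),
                            _rm(km.values + 0.05 * np.eye(n), "MRM"))
        est = []
        local = np.random.default_rng(9)
        for r in range(10):
            v = 0.5 * kg.values + 0.5 * km.values - 0.15 * hc.values + 0.6 * np.eye(n)
            w = np.linalg.eigvalsh(v)
            assert w[0] > 0
            y = np.linalg.cholesky(v) @ local.standard_normal(n)
            vc = fit_variance_components(
                y, np.ones((n, 1)), [kg, km, hc], unconstrained={2}
            )
            est.append(vc.sigma2[2])
        assert np.mean(est) < 0.0  # sign recovered on average


class TestWhitening:
    def test_identity_covariance_is_pure_rotation(self):
        y = rng.standard_normal(12)
        x = np.column_stack([np.ones(12), rng.standard_normal(12)])
        ys, xs, rot = whiten(np.eye(12), y, x)
        b_direct = np.linalg.lstsq(x, y, rcond=None)[0]
        b_white = np.linalg.lstsq(xs, ys, rcond=None)[0]
        np.testing.assert_allclose(b_white, b_direct, atol=1e-10)

    def test_diagonal_covariance_rescales(self):
        v = np.diag([4.0, 1.0, 1.0])
        y = np.array([2.0, 3.0, 4.0])
        x = np.ones((3, 1))
        ys, _, _ = whiten(v, y, x)
        # the eigenvector for eigenvalue 4 is e1 -> y*_last = y_1 / 2
        assert np.any(np.isclose(np.abs(ys), 1.0))

    def test_gls_equals_ols_on_whitened(self):
        n = 8
        v = _psd_kernel(n, 12).values + 0.5 * np.eye(n)
        y = rng.standard_normal(n)
        x = np.column_stack([np.ones(n), rng.standard_normal(n)])
        ys, xs, _ = whiten(v, y, x)
        vi = np.linalg.inv(v)
        beta_gls = np.linalg.solve(x.T @ vi @ x, x.T @ vi @ y)
        beta_ols = np.linalg.lstsq(xs, ys, rcond=None)[0]
        np.testing.assert_allclose(beta_ols, beta_gls, atol=1e-8)

    def test_non_pd_covariance_rejected(self):
        with pytest.raises(np.linalg.LinAlgError):
            whiten(np.diag([1.0, 0.0]), np.zeros(2), np.ones((2, 1)))


def gls_oracle(y, x, snp, v):
    """Explicit-inverse GLS for a single SNP: effect, se, Wald."""
    xa = np.column_stack([x, snp])
    vi = np.linalg.inv(v)
    info_inv = np.linalg.inv(xa.T @ vi @ xa)
    beta = info_inv @ (xa.T @ vi @ y)
    gamma = beta[-1]
    se = np.sqrt(info_inv[-1, -1])
    return gamma, se, gamma**2 / info_inv[-1, -1]


class TestWaldScan:
    def test_matches_explicit_gls_oracle(self):
        n, q = 10, 6
        g = _geno(rng.binomial(2, 0.4, size=(n, q)))
        v = _psd_kernel(n, 15).values + 0.7 * np.eye(n)
        y = rng.standard_normal(n)
        x = np.column_stack([np.ones(n), rng.standard_normal(n)])
        ys, xs, rot = whiten(v, y, x)
        res = wald_scan(ys, xs, g, rot)
        for j in range(q):
            gamma, se, w = gls_oracle(y, x, g.dosages[:, j], v)
            assert res.table.loc[j, "effect"] == pytest.approx(gamma, abs=1e-8)
            assert res.table.loc[j, "se"] == pytest.approx(se, abs=1e-8)
            assert res.table.loc[j, "wald"] == pytest.approx(w, abs=1e-8)

    def test_null_type1_rate_in_binomial_interval(self):
        n, q = 200, 500
        local = np.random.default_rng(31)
        g = _geno(local.binomial(2, 0.3, size=(n, q)))
        y = local.standard_normal(n)
        x = np.ones((n, 1))
        vc = fit_variance_components(y, x, [])
        v = vc.sigma2[0] * np.eye(n)
        ys, xs, rot = whiten(v, y, x)
        res = wald_scan(ys, xs, g, rot)
        rate = np.mean(res.table["p"] <= 0.05)
        half = 1.96 * np.sqrt(0.05 * 0.95 / q)
        assert 0.05 - half <= rate <= 0.05 + half

    def test_constant_snp_flagged_not_error(self):
        n = 15
        d = rng.binomial(2, 0.4, size=(n, 3)).astype(float)
        d[:, 1] = 1.0
        g = _geno(d)
        y = rng.standard_normal(n)
        ys, xs, rot = whiten(np.eye(n), y, np.ones((n, 1)))
        res = wald_scan(ys, xs, g, rot)
        assert res.table.loc[1, "flag"] == "degenerate"
        assert np.isnan(res.table.loc[1, "p"])
        assert res.table.loc[0, "flag"] == ""


class TestRunModel:
    def test_model_kernel_mismatch_rejected(self, tiny_dataset):
        with pytest.raises(ValueError, match="requires kernels"):
            ModelSpec("GWAS", [tiny_dataset["kernels"]["MRM"]])

    def test_deterministic_given_identical_inputs(self, tiny_dataset):
        d = tiny_dataset
        y = d["phenos"].data["y"].to_numpy()
        x = np.ones((len(y), 1))
        spec = ModelSpec("GWAS", [d["kernels"]["GRM"]])
        r1 = run_model(spec, y, x, d["genotypes"])
        r2 = run_model(spec, y, x, d["genotypes"])
        pd.testing.assert_frame_equal(r1.table, r2.table)

    def test_nesting_hologenome_reduces_to_gwas(self, tiny_dataset):
        # with microbial and hologenome variances forced to zero the
        # hologenome scans must reproduce GWAS p-values
        d = tiny_dataset
        y = d["phenos"].data["y"].to_numpy()
        x = np.ones((len(y), 1))
        k = d["kernels"]
        vc_g = fit_variance_components(y, x, [k["GRM"]])
        gwas = run_model(ModelSpec("GWAS", [k["GRM"]]), y, x, d["genotypes"],
                         components=vc_g)
        for name, kinds in [("HWAS-CG", ["GRM", "MRM", "HRM_CG"]),
                            ("HWAS-H", ["GRM", "MRM", "HRM_H"])]:
            comps = VarianceComponents(
                kinds + ["residual"],
                np.array([vc_g.sigma2[0], 0.0, 0.0, vc_g.sigma2[1]]),
                np.nan, 0, True,
            )
            res = run_model(ModelSpec(name, [k[kk] for kk in kinds]), y, x,
                            d["genotypes"], components=comps)
            np.testing.assert_allclose(
                res.table["p"], gwas.table["p"], atol=1e-10
            )

    def test_exact_per_snp_close_to_fast_path(self):
        n, q = 80, 50
        local = np.random.default_rng(13)
        g = _geno(local.binomial(2, 0.35, size=(n, q)))
        from holowas.kernels import compute_grm, standardize_genotypes

        grm = compute_grm(standardize_genotypes(g), g.samples)
        v = 0.4 * grm.values + 0.6 * np.eye(n)
        y = np.linalg.cholesky(v) @ local.standard_normal(n)
        x = np.ones((n, 1))
        spec = ModelSpec("GWAS", [grm])
        fast = run_model(spec, y, x, g)
        exact = run_model(spec, y, x, g, exact_per_snp=True)
        pf, pe = fast.table["p"].to_numpy(), exact.table["p"].to_numpy()
        diff = np.abs(np.log10(pe) - np.log10(pf))
        # the fixed-components approximation is tight for the bulk of SNPs;
        # the exact path absorbs each SNP's own variance into the components,
        # so individual gaps grow with the SNP's effect at this small n
        assert np.median(diff) <= 0.01
        assert diff.max() <= 0.5
        assert np.corrcoef(-np.log10(pe), -np.log10(pf))[0, 1] > 0.998

    def test_wald_invariant_w_equals_effect_over_se_squared(self, tiny_dataset):
        d = tiny_dataset
        y = d["phenos"].data["y"].to_numpy()
        res = run_model(ModelSpec("M-GWAS", [d["kernels"]["MRM"]]), y,
                        np.ones((len(y), 1)), d["genotypes"])
        t = res.table.dropna(subset=["p"])
        np.testing.assert_allclose(
            t["wald"], (t["effect"] / t["se"]) ** 2, atol=1e-8
        )
        np.testing.assert_allclose(
            t["p"], stats.chi2.sf(t["wald"], 1), atol=1e-12
        )
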