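"""Linear mixed-model association scans with multiple variance components.

Four models are supported, differing only in their random-effect kernels:

========  =====================================  ==========================
model     random effects                         kernels
========  =====================================  ==========================
GWAS      polygenic                              [GRM]
M-GWAS    microbial                              [MRM]
HWAS-CG   polygenic + microbial + cross-cov.     [GRM, MRM, HRM_CG]
HWAS-H    polygenic + microbial + interaction    [GRM, MRM, HRM_H]
========  =====================================  ==========================

Each model is ``y = X beta + Z gamma + (random effects) + e`` with a single
SNP effect ``gamma`` tested at a time.  Variance components are estimated
once under the no-SNP null by AI-REML (with EM fallback) and held fixed
across SNPs; the fitted covariance ``V`` is eigendecomposed once so that
every per-SNP test is an ordinary least-squares fit in the whitened
coordinates.  The Wald statistic ``W = gamma^2 / var(gamma)`` is referred
to a chi-squared distribution with 1 degree of freedom, with ``var(gamma)``
taken from the generalized-least-squares information under the fitted
``V`` (the standard fixed-components approximation).

The HRM_CG kernel models a *covariance* between the genomic and microbial
effects, so its coefficient is left unconstrained in sign; all other
variance parameters are constrained non-negative.  If an unconstrained
coefficient drives the fitted ``V`` indefinite it is shrunk toward zero
until ``V`` is positive definite again.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.linalg import cho_factor, cho_solve

from .io import GenotypeMatrix
from .kernels import RelationshipMatrix

__all__ = [
    "MODEL_KERNELS",
    "ModelSpec",
    "VarianceComponents",
    "AssocResult",
    "fit_variance_components",
    "build_covariance",
    "whiten",
    "wald_scan",
    "run_model",
]

MODEL_KERNELS = {
    "GWAS": ("GRM",),
    "M-GWAS": ("MRM",),
    "HWAS-CG": ("GRM", "MRM", "HRM_CG"),
    "HWAS-H": ("GRM", "MRM", "HRM_H"),
}

CHI2_1_MEDIAN = float(stats.chi2.ppf(0.5, 1))  # ~0.4549


@dataclass
class ModelSpec:
    """Which model to run, on which trait, with which kernels."""

    name: str
    kernels: list[RelationshipMatrix]
    covariates: list[str] = field(default_factory=list)
    trait: str = "y"

    def __post_init__(self):
        if self.name not in MODEL_KERNELS:
            raise ValueError(f"unknown model {self.name!r}; use one of {list(MODEL_KERNELS)}")
        expected = MODEL_KERNELS[self.name]
        got = tuple(k.kind for k in self.kernels)
        if got != expected:
            raise ValueError(f"model {self.name} requires kernels {expected}, got {got}")
        base = self.kernels[0].samples if self.kernels else None
        for k in self.kernels:
            if k.samples != base:
                raise ValueError("kernels do not share a sample set/order")


@dataclass
class VarianceComponents:
    """REML estimates of the variance parameters of one model fit."""

    names: list[str]  # kernel kinds plus "residual"
    sigma2: np.ndarray
    reml_loglik: float
    n_iter: int
    converged: bool

    def as_dict(self) -> dict[str, float]:
        return {n: float(s) for n, s in zip(self.names, self.sigma2)}

    @property
    def total(self) -> float:
        return float(np.sum(self.sigma2))

    def fractions(self) -> dict[str, float]:
        t = self.total
        return {n: float(s) / t for n, s in zip(self.names, self.sigma2)}


@dataclass
class AssocResult:
    """Per-SNP association scan output plus scan-level diagnostics."""

    table: pd.DataFrame  # snp_id, chrom, pos, effect, se, wald, p, flag
    model: str
    trait: str
    n: int
    components: VarianceComponents
    lambda_gc: float = np.nan

    @property
    def q_tested(self) -> int:
        return len(self.table)

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# model={self.model}\ttrait={self.trait}\tn={self.n}\n")
            vc = "\t".join(f"{k}={v:.6g}" for k, v in self.components.as_dict().items())
            fh.write(f"# variance_components\t{vc}\n")
            fh.write(f"# lambda_gc={self.lambda_gc:.6g}\n")
            self.table.to_csv(fh, sep="\t", index=False, float_format="%.10g")


# ---------------------------------------------------------------------------
# REML


def _kernel_arrays(kernels) -> list[np.ndarray]:
    return [k.values if isinstance(k, RelationshipMatrix) else np.asarray(k) for k in kernels]


def build_covariance(kernels, sigma2: np.ndarray) -> np.ndarray:
    """``V = sum_k sigma2_k K_k + sigma2_e I`` (last entry = residual)."""
    mats = _kernel_arrays(kernels)
    n = mats[0].shape[0] if mats else None
    sigma2 = np.asarray(sigma2, dtype=float)
    if len(sigma2) != len(mats) + 1:
        raise ValueError("need one sigma^2 per kernel plus one residual")
    if n is None:
        raise ValueError("build_covariance needs at least the residual dimension")
    v = sigma2[-1] * np.eye(n)
    for s, k in zip(sigma2[:-1], mats):
        v += s * k
    return v


def _reml_pieces(y, x, v):
    """Cholesky-based REML log-likelihood and projection products.

    Returns (loglik, vi, py, vix, xtvix_cf) or None when V is not PD.
    """
    try:
        cf = cho_factor(v, lower=True)
    except np.linalg.LinAlgError:
        return None
    n = v.shape[0]
    logdet_v = 2.0 * np.sum(np.log(np.diag(cf[0])))
    vi = cho_solve(cf, np.eye(n))
    vix = vi @ x
    xtvix = x.T @ vix
    try:
        cf_x = cho_factor(xtvix, lower=True)
    except np.linalg.LinAlgError:
        return None
    logdet_x = 2.0 * np.sum(np.log(np.diag(cf_x[0])))
    viy = vi @ y
    beta = cho_solve(cf_x, x.T @ viy)
    py = viy - vix @ beta
    ypy = float(y @ py)
    ll = -0.5 * (logdet_v + logdet_x + ypy)
    return ll, vi, py, vix, cf_x


def _trace_pk(vi, vix, cf_x, k) -> float:
    # tr(P K) = tr(V^-1 K) - tr((X'V^-1X)^-1 X'V^-1 K V^-1 X)
    t1 = float(np.sum(vi * k))  # both symmetric
    a = vix.T @ (k @ vix)
    t2 = float(np.trace(cho_solve(cf_x, a)))
    return t1 - t2


def fit_variance_components(
    y: np.ndarray,
    x: np.ndarray,
    kernels,
    unconstrained: set[int] | None = None,
    tol: float = 1e-6,
    max_iter: int = 100,
) -> VarianceComponents:
    """Multi-kernel REML by average-information updates with EM fallback.

    ``kernels`` is an ordered list of RelationshipMatrix (or arrays); the
    residual identity component is implicit and always last in the output.
    Indices in ``unconstrained`` (e.g. the HRM_CG covariance coefficient)
    may go negative; every other parameter is projected to be >= 0.
    Convergence is declared when the restricted log-likelihood changes by
    less than ``tol``.
    """
    y = np.asarray(y, dtype=float).ravel()
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if x.shape[0] != y.shape[0]:
        x = x.T
    n, c = x.shape
    if np.linalg.matrix_rank(x) < c:
        raise ValueError("covariate matrix X is rank-deficient")
    mats = _kernel_arrays(kernels)
    names = [k.kind if isinstance(k, RelationshipMatrix) else f"K{i}" for i, k in enumerate(kernels)]
    names.append("residual")
    m = len(mats)
    unconstrained = set() if unconstrained is None else set(unconstrained)

    # residual-only closed form (ordinary REML variance)
    resid = y - x @ np.linalg.lstsq(x, y, rcond=None)[0]
    var_p = float(resid @ resid) / (n - c)
    if m == 0:
        ll = -0.5 * (
            n * np.log(var_p)
            + np.linalg.slogdet(x.T @ x)[1]
            + (n - c)
            - c * np.log(var_p)
        )
        return VarianceComponents(names, np.array([var_p]), float(ll), 0, True)

    theta = np.full(m + 1, var_p / (m + 1))
    for i in unconstrained:
        theta[i] = 0.0
    floor = 0.0

    def project(t):
        t = t.copy()
        for i in range(m + 1):
            if i not in unconstrained:
                t[i] = max(t[i], floor)
        # keep the residual strictly positive so the fitted V stays
        # invertible for whitening (GCTA-style boundary constraint)
        t[-1] = max(t[-1], 1e-6 * var_p)
        return t

    def make_pd(t):
        # shrink unconstrained coefficients toward 0 until V is PD
        for _ in range(60):
            pieces = _reml_pieces(y, x, build_covariance(mats, t))
            if pieces is not None:
                return t, pieces
            if unconstrained and any(t[i] != 0 for i in unconstrained):
                for i in unconstrained:
                    t[i] *= 0.5
                    if abs(t[i]) < 1e-12 * var_p:
                        t[i] = 0.0
            else:
                t = t.copy()
                t[-1] = max(t[-1] * 2.0, 1e-8 * var_p)
        raise np.linalg.LinAlgError("could not reach a positive-definite covariance")

    theta, pieces = make_pd(project(theta))
    ll, vi, py, vix, cf_x = pieces
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        kpy = [k @ py for k in mats] + [py]
        tr_pk = np.array(
            [_trace_pk(vi, vix, cf_x, k) for k in mats]
            + [float(np.trace(vi)) - _trace_eye_corr(vix, cf_x)]
        )
        ypkpy = np.array([float(py @ t) for t in kpy])
        score = -0.5 * (tr_pk - ypkpy)
        # P t_j for the average-information matrix
        pt = []
        for t in kpy:
            vit = vi @ t
            pt.append(vit - vix @ cho_solve(cf_x, x.T @ vit))
        ai = 0.5 * np.array([[float(a @ b) for b in kpy] for a in pt])
        step = 1.0
        accepted = False
        for _ in range(12):
            try:
                delta = np.linalg.solve(ai + 1e-9 * np.eye(m + 1) * np.trace(ai), score)
            except np.linalg.LinAlgError:
                break
            cand = project(theta + step * delta)
            try:
                cand, cand_pieces = make_pd(cand)
            except np.linalg.LinAlgError:
                step *= 0.5
                continue
            if cand_pieces[0] >= ll - 1e-10:
                theta, pieces = cand, cand_pieces
                accepted = True
                break
            step *= 0.5
        if not accepted:
            # EM-REML fallback step (guaranteed uphill for the constrained params)
            cand = theta + theta**2 * (ypkpy - tr_pk) / n
            cand = project(cand)
            try:
                cand, cand_pieces = make_pd(cand)
                if cand_pieces[0] >= ll - 1e-10:
                    theta, pieces = cand, cand_pieces
                    accepted = True
            except np.linalg.LinAlgError:
                pass
        if not accepted:
            break
        new_ll = pieces[0]
        ll_change = new_ll - ll
        ll, vi, py, vix, cf_x = pieces
        if abs(ll_change) < tol:
            converged = True
            break
    return VarianceComponents(names, theta.copy(), float(ll), it, converged)


def _trace_eye_corr(vix, cf_x) -> float:
    # correction term of tr(P I): tr((X'V^-1X)^-1 X'V^-2 X)
    return float(np.trace(cho_solve(cf_x, vix.T @ vix)))


# ---------------------------------------------------------------------------
# whitening + scan


@dataclass
class Whitening:
    """Eigendecomposition of a fitted V, applied as a rotation.

    With ``V = U diag(d) U'``, vectors are mapped through
    ``diag(d^-1/2) U'`` so that generalized least squares under ``V``
    becomes ordinary least squares in the rotated coordinates.
    """

    u: np.ndarray
    d: np.ndarray

    def transform(self, a: np.ndarray) -> np.ndarray:
        return (self.u.T @ a) / np.sqrt(self.d)[:, None] if a.ndim == 2 else (
            self.u.T @ a
        ) / np.sqrt(self.d)


def whiten(v: np.ndarray, y: np.ndarray, x: np.ndarray):
    """Rotate (y, X) into coordinates where the covariance is identity."""
    v = np.asarray(v, dtype=float)
    d, u = np.linalg.eigh((v + v.T) / 2.0)
    if d[0] <= 0:
        raise np.linalg.LinAlgError(
            f"fitted covariance is not positive definite (min eigenvalue {d[0]:.3e})"
        )
    rot = Whitening(u, d)
    return rot.transform(np.asarray(y, dtype=float)), rot.transform(np.atleast_2d(x)), rot


def _impute_dosages(g: GenotypeMatrix) -> np.ndarray:
    s = g.dosages.copy()
    miss = np.isnan(s)
    if miss.any():
        means = 2.0 * g.freqs
        s[miss] = means[np.nonzero(miss)[1]]
    return s


def wald_scan(
    y_star: np.ndarray,
    x_star: np.ndarray,
    genotypes: GenotypeMatrix,
    rotation: Whitening,
    model: str = "GWAS",
    trait: str = "y",
    components: VarianceComponents | None = None,
) -> AssocResult:
    """Per-SNP Wald tests in whitened coordinates.

    Each (mean-imputed) dosage column is rotated by the same whitening
    transform, residualized against the rotated covariates and tested:
    ``gamma = s'y / s's``, ``var(gamma) = 1 / s's`` (unit error variance
    after whitening), ``W = gamma^2 / var(gamma)`` referred to chi2(1).
    SNPs whose rotated column is numerically constant are flagged and
    reported with missing p-values.
    """
    n = y_star.shape[0]
    if genotypes.n != n:
        raise ValueError("genotype sample count differs from whitened data")
    raw = _impute_dosages(genotypes)
    s = rotation.transform(raw)
    q_mat, _ = np.linalg.qr(x_star)
    s_t = s - q_mat @ (q_mat.T @ s)
    y_t = y_star - q_mat @ (q_mat.T @ y_star)
    den = np.einsum("ij,ij->j", s_t, s_t)
    raw_norm = np.einsum("ij,ij->j", s, s)
    # a degenerate SNP is one that is constant in the raw data; the norm
    # ratio is only a numerical guard (whitening can amplify one direction
    # of V enormously without making the SNP untestable)
    degenerate = (np.ptp(raw, axis=0) == 0) | (
        den <= 1e-12 * np.maximum(raw_norm, 1.0)
    )
    den_safe = np.where(degenerate, 1.0, den)
    num = s_t.T @ y_t
    gamma = num / den_safe
    se = 1.0 / np.sqrt(den_safe)
    wald = num**2 / den_safe
    pvals = stats.chi2.sf(wald, 1)
    gamma[degenerate] = np.nan
    se[degenerate] = np.nan
    wald[degenerate] = np.nan
    pvals[degenerate] = np.nan
    table = pd.DataFrame(
        {
            "snp_id": genotypes.snps["id"].to_numpy(),
            "chrom": genotypes.snps["chrom"].to_numpy(),
            "pos": genotypes.snps["pos"].to_numpy(),
            "effect": gamma,
            "se": se,
            "wald": wald,
            "p": pvals,
            "flag": np.where(degenerate, "degenerate", ""),
        }
    )
    ok = ~np.isnan(wald)
    lam = float(np.median(wald[ok]) / CHI2_1_MEDIAN) if ok.sum() >= 10 else np.nan
    comps = components if components is not None else VarianceComponents(
        ["residual"], np.array([1.0]), np.nan, 0, True
    )
    res = AssocResult(table, model, trait, n, comps, lam)
    # context for permutation-based thresholds (not part of the public schema)
    res._scan_ctx = {
        "s_tilde": s_t,
        "y_tilde": y_t,
        "den": den_safe,
        "degenerate": degenerate,
        "q_mat": q_mat,
    }
    return res


def run_model(
    spec: ModelSpec,
    y: np.ndarray,
    x: np.ndarray,
    genotypes: GenotypeMatrix,
    exact_per_snp: bool = False,
    components: VarianceComponents | None = None,
) -> AssocResult:
    """Fit variance components under the null, whiten, scan.

    Components are estimated once without any SNP in the model and reused
    for every test (the standard fixed-components approximation); pass
    ``exact_per_snp=True`` to re-estimate them per SNP (slow verification
    path), or ``components`` to skip estimation entirely.
    """
    y = np.asarray(y, dtype=float).ravel()
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if x.shape[0] != y.shape[0]:
        x = x.T
    unconstrained = {i for i, k in enumerate(spec.kernels) if k.kind == "HRM_CG"}
    if components is None:
        components = fit_variance_components(y, x, spec.kernels, unconstrained)
    if exact_per_snp:
        return _exact_scan(spec, y, x, genotypes, unconstrained, components)
    v = build_covariance(spec.kernels, components.sigma2)
    y_star, x_star, rot = whiten(v, y, x)
    return wald_scan(y_star, x_star, genotypes, rot, spec.name, spec.trait, components)


def _exact_scan(spec, y, x, genotypes, unconstrained, null_components):
    s = _impute_dosages(genotypes)
    rows = []
    for j in range(genotypes.q):
        sj = s[:, j]
        if np.ptp(sj) == 0:
            rows.append((np.nan, np.nan, np.nan, np.nan, "degenerate"))
            continue
        xa = np.hstack([x, sj[:, None]])
        vc = fit_variance_components(y, xa, spec.kernels, unconstrained)
        v = build_covariance(spec.kernels, vc.sigma2)
        cf = cho_factor(v, lower=True)
        vix = cho_solve(cf, xa)
        xtvix_inv = np.linalg.inv(xa.T @ vix)
        beta = xtvix_inv @ (vix.T @ y)
        gamma = float(beta[-1])
        se = float(np.sqrt(xtvix_inv[-1, -1]))
        w = gamma**2 / se**2
        rows.append((gamma, se, w, float(stats.chi2.sf(w, 1)), ""))
    eff, se_, w_, p_, fl = zip(*rows)
    table = pd.DataFrame(
        {
            "snp_id": genotypes.snps["id"].to_numpy(),
            "chrom": genotypes.snps["chrom"].to_numpy(),
            "pos": genotypes.snps["pos"].to_numpy(),
            "effect": eff,
            "se": se_,
            "wald": w_,
            "p": p_,
            "flag": fl,
        }
    )
    w_arr = np.asarray(w_, dtype=float)
    ok = ~np.isnan(w_arr)
    lam = float(np.median(w_arr[ok]) / CHI2_1_MEDIAN) if ok.sum() >= 10 else np.nan
    return AssocResult(table, spec.name, spec.trait, len(y), null_components, lam)
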