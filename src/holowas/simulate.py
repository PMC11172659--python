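"""Synthetic hologenome datasets with a controllable variance architecture.

The generator emulates a livestock association panel after quality
control: HWE genotypes with uniform MAF in [0.05, 0.5], a logistic-normal
OTU table whose log-abundances are partly genotype-driven (creating
genuine genome-microbiome covariance), and phenotypes

    y = X beta + Z gamma + g + m + h + e

drawn from the exact multi-kernel covariance ``V = sigma_g^2 G +
sigma_m^2 M + sigma_h K_h + sigma_e^2 I`` implied by user-set variance
fractions.  Everything is a pure function of the configuration and its
seed.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .io import GenotypeMatrix, OTUTable, PhenotypeTable
from .kernels import (
    RelationshipMatrix,
    compute_grm,
    compute_hrm_cg,
    compute_hrm_h,
    compute_mrm,
    standardize_genotypes,
)
from .lmm import ModelSpec, build_covariance, run_model

__all__ = ["SimConfig", "sim_genotypes", "sim_microbiome", "sim_phenotype",
           "sim_dataset", "run_experiment", "ExperimentResult"]


@dataclass
class SimConfig:
    """Study-design parameters for one synthetic scenario.

    Variance fractions ``(h2_g, h2_m, h2_holo, residual)`` must sum to 1;
    ``rho_gm`` adds a genome-microbiome effect covariance on top (used by
    the cross-covariance scenario).  ``holo_kind`` selects which
    hologenome kernel carries the interaction variance.
    """

    n: int = 300
    q: int = 2000
    p: int = 200
    maf_range: tuple[float, float] = (0.05, 0.5)
    h2_g: float = 0.3
    h2_m: float = 0.2
    h2_holo: float = 0.0
    residual: float = 0.5
    rho_gm: float = 0.0
    holo_kind: str = "HRM_H"  # or "HRM_CG"
    n_causal_snps: int = 0
    causal_var: float = 0.05  # trait-variance fraction per causal SNP
    otu_heritable_frac: float = 0.3
    otu_baseline_sd: float = 2.0  # spread of OTU mean log-abundances
    ld_rho: float = 0.0  # AR(1) correlation between adjacent SNPs (0 = none)
    n_chrom: int = 10
    seed: int = 0

    def __post_init__(self):
        fr = np.array([self.h2_g, self.h2_m, self.h2_holo, self.residual])
        if (fr < 0).any():
            raise ValueError("variance fractions must be non-negative")
        if abs(fr.sum() - 1.0) > 1e-9:
            raise ValueError(f"variance fractions sum to {fr.sum():.6g}, expected 1")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must be within (0, 0.5]")
        if not 0 <= self.otu_heritable_frac <= 1:
            raise ValueError("otu_heritable_frac must lie in [0, 1]")


def _rng_for(cfg: SimConfig, stream: str) -> np.random.Generator:
    # stable per-stream key (hash() is salted per process)
    key = int.from_bytes(zlib.crc32(stream.encode()).to_bytes(4, "big"), "big")
    return np.random.default_rng(np.random.SeedSequence(cfg.seed, spawn_key=(key,)))


def sim_genotypes(cfg: SimConfig) -> GenotypeMatrix:
    """HWE genotypes: per-SNP MAF ~ Uniform(maf_range), dosage ~ Bin(2, MAF).

    With ``ld_rho > 0`` the two haplotypes per sample are drawn from an
    AR(1) Gaussian copula along each chromosome, giving adjacent SNPs
    correlated alleles (a simple stand-in for linkage disequilibrium);
    the default is independent SNPs.  SNPs are spread evenly over
    ``n_chrom`` chromosomes at 50 kb spacing so annotation and plotting
    have realistic coordinates.
    """
    rng = _rng_for(cfg, "genotypes")
    maf = rng.uniform(*cfg.maf_range, size=cfg.q)
    if cfg.ld_rho == 0.0:
        dosages = rng.binomial(2, maf, size=(cfg.n, cfg.q)).astype(float)
    else:
        from scipy import stats as _st

        thresh = _st.norm.ppf(maf)
        dosages = np.zeros((cfg.n, cfg.q))
        per_chrom = int(np.ceil(cfg.q / cfg.n_chrom))
        for _hap in range(2):
            z = rng.standard_normal((cfg.n, cfg.q))
            for j in range(1, cfg.q):
                if j % per_chrom == 0:
                    continue  # chromosomes are independent
                z[:, j] = cfg.ld_rho * z[:, j - 1] + np.sqrt(
                    1 - cfg.ld_rho**2
                ) * z[:, j]
            dosages += (z < thresh).astype(float)
    per_chrom = int(np.ceil(cfg.q / cfg.n_chrom))
    chroms = [str(1 + j // per_chrom) for j in range(cfg.q)]
    pos = [1 + 50_000 * (j % per_chrom) for j in range(cfg.q)]
    snps = pd.DataFrame(
        {
            "id": [f"snp{j:05d}" for j in range(cfg.q)],
            "chrom": chroms,
            "pos": pos,
            "ref": "A",
            "alt": "B",
        }
    )
    samples = [f"s{i:04d}" for i in range(cfg.n)]
    return GenotypeMatrix(samples, snps, dosages)


def sim_microbiome(cfg: SimConfig, genotypes: GenotypeMatrix) -> OTUTable:
    """Logistic-normal OTU table, partly driven by host genotype.

    Latent log-abundances are ``sqrt(f) * (X_s B)_unit + sqrt(1-f) * E``
    (f = ``otu_heritable_frac``; B, E standard normal; columns scaled to
    unit variance) plus per-OTU baseline offsets with standard deviation
    ``otu_baseline_sd`` that create the uneven abundance profile typical
    of 16S surveys.  A row-wise softmax maps the latent matrix to
    relative abundances summing to exactly 1.
    """
    rng = _rng_for(cfg, "microbiome")
    n, p, f = cfg.n, cfg.p, cfg.otu_heritable_frac
    e_part = rng.standard_normal((n, p))
    if f > 0:
        x_s = standardize_genotypes(genotypes)
        b = rng.standard_normal((genotypes.q, p))
        gen = x_s @ b
        sd = gen.std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        gen = gen / sd
        latent = np.sqrt(f) * gen + np.sqrt(1.0 - f) * e_part
    else:
        latent = e_part
    baseline = rng.normal(0.0, cfg.otu_baseline_sd, size=p)
    latent = latent + baseline
    latent -= latent.max(axis=1, keepdims=True)
    ex = np.exp(latent)
    rel = ex / ex.sum(axis=1, keepdims=True)
    otus = [f"otu{k:04d}" for k in range(p)]
    return OTUTable(list(genotypes.samples), otus, rel)


def true_covariance(
    cfg: SimConfig, kernels: dict[str, RelationshipMatrix]
) -> np.ndarray:
    """Phenotypic covariance implied by the configured variance fractions.

    With ``rho_gm`` non-zero the genomic and microbial effects are drawn
    jointly with cross-covariance ``rho_gm * L_G L_M'``, whose marginal
    contribution to Var(y) is exactly ``rho_gm * h_c``; the fraction is
    clamped (and recorded in the config) if it would break positive
    definiteness.
    """
    sig = np.array([cfg.h2_g, cfg.h2_m])
    mats = [kernels["GRM"].values, kernels["MRM"].values]
    v = sig @ np.array([m.ravel() for m in mats])
    v = v.reshape(mats[0].shape)
    if cfg.h2_holo > 0:
        v = v + cfg.h2_holo * kernels[cfg.holo_kind].values
    if cfg.rho_gm != 0:
        v = v + cfg.rho_gm * kernels["HRM_CG"].values
    v = v + cfg.residual * np.eye(cfg.n)
    return (v + v.T) / 2.0


def sim_phenotype(
    cfg: SimConfig,
    kernels: dict[str, RelationshipMatrix],
    genotypes: GenotypeMatrix,
    causal_snps: np.ndarray | None = None,
) -> tuple[PhenotypeTable, np.ndarray]:
    """Draw one trait from the exact model covariance.

    ``y = intercept + sum_j z_j gamma_j + u`` with ``u ~ N(0, V_true)``
    via Cholesky.  Each causal SNP's effect size is scaled so the SNP
    explains ``causal_var`` of trait variance.  Returns the phenotype
    table and the causal SNP indices used.
    """
    rng = _rng_for(cfg, "phenotype")
    v = true_covariance(cfg, kernels)
    w = np.linalg.eigvalsh(v)
    clamped_cfg = cfg
    while w[0] <= 1e-10 and clamped_cfg.rho_gm != 0:
        clamped_cfg = replace(clamped_cfg, rho_gm=clamped_cfg.rho_gm * 0.5)
        v = true_covariance(clamped_cfg, kernels)
        w = np.linalg.eigvalsh(v)
    if w[0] <= 0:
        raise np.linalg.LinAlgError(
            f"true covariance not positive definite (min eigenvalue {w[0]:.3e})"
        )
    u = np.linalg.cholesky(v) @ rng.standard_normal(cfg.n)
    if causal_snps is None:
        if cfg.n_causal_snps > 0:
            causal_snps = rng.choice(cfg.q, size=cfg.n_causal_snps, replace=False)
        else:
            causal_snps = np.array([], dtype=int)
    y = u.copy()
    for j in np.asarray(causal_snps, dtype=int):
        z = genotypes.dosages[:, j]
        var_z = z.var(ddof=0)
        if var_z == 0:
            continue
        gamma = np.sqrt(cfg.causal_var / var_z)
        y = y + z * gamma
    data = pd.DataFrame({"y": y}, index=genotypes.samples)
    return PhenotypeTable(data, traits=["y"]), np.asarray(causal_snps, dtype=int)


def build_kernels(
    genotypes: GenotypeMatrix, otu_log_abund: np.ndarray
) -> dict[str, RelationshipMatrix]:
    """All four kernels from one dataset."""
    x_s = standardize_genotypes(genotypes)
    g = compute_grm(x_s, genotypes.samples)
    m = compute_mrm(otu_log_abund, genotypes.samples)
    return {
        "GRM": g,
        "MRM": m,
        "HRM_CG": compute_hrm_cg(g, m),
        "HRM_H": compute_hrm_h(g, m),
    }


def sim_dataset(cfg: SimConfig):
    """Genotypes, OTU table, kernels and one phenotype for a scenario."""
    from .io import log_transform_otus

    genotypes = sim_genotypes(cfg)
    otus = sim_microbiome(cfg, genotypes)
    r = log_transform_otus(otus, pseudocount="auto", center=True)
    r = r / np.maximum(r.std(axis=0, ddof=0), 1e-12)  # unit-variance OTU features
    kernels = build_kernels(genotypes, r)
    phenos, causal = sim_phenotype(cfg, kernels, genotypes)
    return genotypes, otus, kernels, phenos, causal


@dataclass
class ExperimentResult:
    """Aggregated calibration/power/recovery metrics over replicates."""

    summary: pd.DataFrame  # one row per model x scenario
    per_replicate: pd.DataFrame
    config: SimConfig
    replicates: int


def _model_spec(name: str, kernels: dict[str, RelationshipMatrix]) -> ModelSpec:
    from .lmm import MODEL_KERNELS

    return ModelSpec(name, [kernels[k] for k in MODEL_KERNELS[name]])


def run_experiment(
    cfg: SimConfig,
    models: list[str],
    replicates: int,
    alpha_levels: tuple[float, ...] = (0.05,),
    null_per_model: bool = False,
) -> ExperimentResult:
    """Simulate, fit and scan ``replicates`` times; aggregate the metrics.

    Per replicate and model: type-I error on null SNPs at each alpha,
    power at causal SNPs, genomic inflation and variance-component
    fractions.  ``null_per_model=True`` redraws the phenotype under each
    model's own covariance structure (its null) instead of the shared
    configured one.  Fully deterministic given ``cfg.seed``.
    """
    if replicates < 1:
        raise ValueError("need at least 1 replicate")
    rows = []
    for rep in range(replicates):
        rep_cfg = replace(cfg, seed=cfg.seed + 100_003 * rep)
        genotypes = sim_genotypes(rep_cfg)
        otus = sim_microbiome(rep_cfg, genotypes)
        from .io import log_transform_otus

        r = log_transform_otus(otus, pseudocount="auto", center=True)
        r = r / np.maximum(r.std(axis=0, ddof=0), 1e-12)
        kernels = build_kernels(genotypes, r)
        shared_pheno = None
        if not null_per_model:
            shared_pheno, causal = sim_phenotype(rep_cfg, kernels, genotypes)
        for model in models:
            if null_per_model:
                null_cfg = _null_config_for(rep_cfg, model)
                pheno, causal = sim_phenotype(null_cfg, kernels, genotypes)
            else:
                pheno = shared_pheno
            spec = _model_spec(model, kernels)
            y = pheno.data["y"].to_numpy()
            x = np.ones((rep_cfg.n, 1))
            res = run_model(spec, y, x, genotypes)
            p = res.table["p"].to_numpy()
            ok = ~np.isnan(p)
            null_mask = ok.copy()
            null_mask[causal] = False
            row = {
                "replicate": rep,
                "model": model,
                "lambda_gc": res.lambda_gc,
                "converged": res.components.converged,
                "n_null": int(null_mask.sum()),
                "n_causal": len(causal),
            }
            for a in alpha_levels:
                row[f"type1_{a:g}"] = float(np.mean(p[null_mask] <= a)) if null_mask.any() else np.nan
                if len(causal):
                    pc = p[causal]
                    row[f"power_{a:g}"] = float(np.nanmean(pc <= a))
            for name, frac in res.components.fractions().items():
                row[f"frac_{name}"] = frac
            for name, s2 in res.components.as_dict().items():
                row[f"sigma2_{name}"] = s2
            rows.append(row)
    per_rep = pd.DataFrame(rows)
    summary = per_rep.drop(columns=["replicate"]).groupby("model").mean(numeric_only=True)
    return ExperimentResult(summary, per_rep, cfg, replicates)


def _null_config_for(cfg: SimConfig, model: str) -> SimConfig:
    """The variance structure of each model's own null (no SNP effects)."""
    base = dict(n_causal_snps=0)
    if model == "GWAS":
        return replace(cfg, h2_m=0.0, h2_holo=0.0, rho_gm=0.0,
                       residual=1.0 - cfg.h2_g, **base)
    if model == "M-GWAS":
        return replace(cfg, h2_g=0.0, h2_holo=0.0, rho_gm=0.0,
                       residual=1.0 - cfg.h2_m, **base)
    if model == "HWAS-CG":
        return replace(cfg, h2_holo=0.0, rho_gm=cfg.rho_gm if cfg.rho_gm else 0.1,
                       residual=1.0 - cfg.h2_g - cfg.h2_m, holo_kind="HRM_CG", **base)
    if model == "HWAS-H":
        return replace(cfg, h2_holo=cfg.h2_holo if cfg.h2_holo else 0.1, rho_gm=0.0,
                       residual=1.0 - cfg.h2_g - cfg.h2_m - (cfg.h2_holo if cfg.h2_holo else 0.1),
                       holo_kind="HRM_H", **base)
    raise ValueError(f"unknown model {model!r}")
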