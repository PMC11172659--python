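"""Input/output, quality control and trait derivation.

Genotypes are held as additive alt-allele dosages (0/1/2, NaN = missing),
microbiome data as compositional OTU relative-abundance tables, and
phenotypes/covariates as plain data frames keyed by sample ID.  Readers
cover PLINK1 bed/bim/fam, VCF and a simple dosage TSV; writers round-trip
the TSV formats exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeMatrix",
    "OTUTable",
    "PhenotypeTable",
    "read_genotypes",
    "read_otu_table",
    "read_phenotypes",
    "write_dosage_tsv",
    "write_otu_tsv",
    "write_phenotype_tsv",
    "qc_filter_genotypes",
    "qc_filter_otus",
    "log_transform_otus",
    "derive_performance_traits",
    "align_samples",
]


class DataValidationError(ValueError):
    """Raised when an input violates a structural invariant."""


def _check_unique(ids, what: str) -> None:
    ids = list(ids)
    if len(ids) != len(set(ids)):
        seen, dups = set(), []
        for i in ids:
            if i in seen:
                dups.append(i)
            seen.add(i)
        raise DataValidationError(f"duplicate {what} IDs: {sorted(set(dups))[:5]}")


@dataclass
class GenotypeMatrix:
    """n x q additive dosage matrix with a SNP map.

    ``dosages[i, j]`` counts copies of the alt allele of SNP ``j`` carried
    by sample ``i``; missing genotypes are ``NaN``.  ``snps`` is a frame
    with columns ``id, chrom, pos, ref, alt`` (1-based positions).
    """

    samples: list[str]
    snps: pd.DataFrame
    dosages: np.ndarray

    def __post_init__(self):
        _check_unique(self.samples, "sample")
        _check_unique(self.snps["id"], "SNP")
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.samples), len(self.snps)):
            raise DataValidationError(
                f"dosage shape {self.dosages.shape} does not match "
                f"{len(self.samples)} samples x {len(self.snps)} SNPs"
            )
        if (self.snps["pos"] < 1).any():
            raise DataValidationError("SNP positions must be >= 1")
        with np.errstate(invalid="ignore"):
            bad = np.nansum((self.dosages < 0) | (self.dosages > 2))
        if bad:
            raise DataValidationError("dosages must lie in [0, 2] or be NaN")
        self.snps = self.snps.reset_index(drop=True)

    @property
    def n(self) -> int:
        return len(self.samples)

    @property
    def q(self) -> int:
        return len(self.snps)

    @property
    def freqs(self) -> np.ndarray:
        """Alt-allele frequency per SNP, from non-missing dosages only."""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return np.nanmean(self.dosages, axis=0) / 2.0

    @property
    def call_rates(self) -> np.ndarray:
        return 1.0 - np.mean(np.isnan(self.dosages), axis=0)

    @property
    def maf(self) -> np.ndarray:
        f = self.freqs
        return np.minimum(f, 1.0 - f)

    def subset_samples(self, sample_ids: list[str]) -> "GenotypeMatrix":
        idx = [self.samples.index(s) for s in sample_ids]
        return GenotypeMatrix(list(sample_ids), self.snps.copy(), self.dosages[idx])

    def subset_snps(self, keep: np.ndarray) -> "GenotypeMatrix":
        keep = np.asarray(keep)
        return GenotypeMatrix(
            list(self.samples), self.snps.loc[keep].copy(), self.dosages[:, keep]
        )


@dataclass
class OTUTable:
    """n x p compositional relative-abundance table (rows sum to 1)."""

    samples: list[str]
    otus: list[str]
    rel_abund: np.ndarray

    def __post_init__(self):
        _check_unique(self.samples, "sample")
        _check_unique(self.otus, "OTU")
        self.rel_abund = np.asarray(self.rel_abund, dtype=float)
        if self.rel_abund.shape != (len(self.samples), len(self.otus)):
            raise DataValidationError("abundance shape mismatch")
        if (self.rel_abund < 0).any():
            raise DataValidationError("relative abundances must be >= 0")
        sums = self.rel_abund.sum(axis=1)
        if np.any(np.abs(sums - 1.0) > 1e-6):
            bad = np.argmax(np.abs(sums - 1.0))
            raise DataValidationError(
                f"row {self.samples[bad]} sums to {sums[bad]:.6g}, expected 1"
            )

    @property
    def n(self) -> int:
        return len(self.samples)

    @property
    def p(self) -> int:
        return len(self.otus)

    @property
    def prevalence(self) -> np.ndarray:
        """Fraction of samples in which each OTU is non-zero."""
        return np.mean(self.rel_abund > 0, axis=0)

    def subset_samples(self, sample_ids: list[str]) -> "OTUTable":
        idx = [self.samples.index(s) for s in sample_ids]
        return OTUTable(list(sample_ids), list(self.otus), self.rel_abund[idx])


@dataclass
class PhenotypeTable:
    """Traits plus covariates, keyed by sample ID.

    ``data`` holds one row per sample; ``traits`` and ``covariates`` name
    the columns playing each role.  Covariates may be numeric or
    categorical (categoricals are dummy-coded at design-matrix time).
    """

    data: pd.DataFrame
    traits: list[str] = field(default_factory=list)
    covariates: list[str] = field(default_factory=list)

    def __post_init__(self):
        _check_unique(self.data.index, "sample")
        for c in list(self.traits) + list(self.covariates):
            if c not in self.data.columns:
                raise DataValidationError(f"column {c!r} not in phenotype table")
        for t in self.traits:
            if self.data[t].isna().all():
                raise DataValidationError(f"trait {t!r} is entirely missing")

    @property
    def samples(self) -> list[str]:
        return [str(s) for s in self.data.index]

    def design_matrix(self, covariates: list[str] | None = None) -> np.ndarray:
        """Covariate design matrix with a leading intercept column.

        Categorical columns are expanded to treatment-coded dummies.
        """
        cols = self.covariates if covariates is None else covariates
        parts = [np.ones((len(self.data), 1))]
        for c in cols:
            col = self.data[c]
            if pd.api.types.is_numeric_dtype(col):
                parts.append(col.to_numpy(dtype=float)[:, None])
            else:
                dummies = pd.get_dummies(col, drop_first=True)
                parts.append(dummies.to_numpy(dtype=float))
        return np.hstack(parts)

    def subset_samples(self, sample_ids: list[str]) -> "PhenotypeTable":
        return PhenotypeTable(
            self.data.loc[list(sample_ids)].copy(),
            list(self.traits),
            list(self.covariates),
        )


# ---------------------------------------------------------------------------
# readers


_PLINK_MAGIC = b"\x6c\x1b\x01"


def _read_plink(prefix: str) -> GenotypeMatrix:
    prefix = str(prefix)
    fam = pd.read_csv(
        prefix + ".fam",
        sep=r"\s+",
        header=None,
        names=["fid", "iid", "father", "mother", "sex", "pheno"],
        dtype={"iid": str, "fid": str},
    )
    bim = pd.read_csv(
        prefix + ".bim",
        sep=r"\s+",
        header=None,
        names=["chrom", "id", "cm", "pos", "a1", "a2"],
        dtype={"chrom": str, "id": str},
    )
    snps = pd.DataFrame(
        {
            "id": bim["id"],
            "chrom": bim["chrom"],
            "pos": bim["pos"].astype(int),
            "ref": bim["a2"],
            "alt": bim["a1"],
        }
    )
    n, q = len(fam), len(bim)
    raw = np.fromfile(prefix + ".bed", dtype=np.uint8)
    if raw[:3].tobytes() != _PLINK_MAGIC:
        raise DataValidationError(f"{prefix}.bed: bad magic bytes (not SNP-major PLINK1)")
    body = raw[3:]
    per_snp = (n + 3) // 4
    if body.size != per_snp * q:
        raise DataValidationError(
            f"{prefix}.bed: expected {per_snp * q} data bytes, found {body.size}"
        )
    codes = body.reshape(q, per_snp)
    # 2-bit genotype codes, little-endian within each byte
    pairs = np.stack(
        [(codes >> shift) & 0b11 for shift in (0, 2, 4, 6)], axis=-1
    ).reshape(q, -1)[:, :n]
    # PLINK1: 00 = hom A1, 10 = het, 11 = hom A2, 01 = missing; A1 counted as alt
    lut = np.array([2.0, np.nan, 1.0, 0.0])
    dosages = lut[pairs].T
    return GenotypeMatrix(list(fam["iid"].astype(str)), snps, dosages)


def _read_vcf(path: str) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    ids, chroms, poss, refs, alts, rows = [], [], [], [], [], []
    for var in vcf:
        ids.append(var.ID if var.ID else f"{var.CHROM}:{var.POS}")
        chroms.append(var.CHROM)
        poss.append(var.POS)
        refs.append(var.REF)
        alts.append(var.ALT[0] if var.ALT else ".")
        gt = var.gt_types.astype(float)  # 0/1/2 alt dosage, 3 = missing
        gt[gt == 3] = np.nan
        rows.append(gt)
    snps = pd.DataFrame(
        {"id": ids, "chrom": chroms, "pos": poss, "ref": refs, "alt": alts}
    )
    dosages = np.array(rows).T if rows else np.empty((len(samples), 0))
    return GenotypeMatrix(samples, snps, dosages)


def _read_dosage_tsv(path: str) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    snps = pd.DataFrame(
        {
            "id": df.columns,
            "chrom": "0",
            "pos": np.arange(1, df.shape[1] + 1),
            "ref": "A",
            "alt": "B",
        }
    )
    return GenotypeMatrix(list(df.index), snps, df.to_numpy(dtype=float))


def read_genotypes(path: str | Path) -> GenotypeMatrix:
    """Read genotypes from a PLINK1 prefix, a VCF, or a dosage TSV.

    PLINK input is detected by the presence of ``<path>.bed``; ``.vcf``/
    ``.vcf.gz`` suffixes select the VCF reader; anything else is parsed as
    a dosage TSV (header row = SNP IDs, first column = sample IDs).
    """
    p = str(path)
    if Path(p + ".bed").exists():
        return _read_plink(p)
    if p.endswith((".vcf", ".vcf.gz")):
        return _read_vcf(p)
    if not Path(p).exists():
        raise FileNotFoundError(f"no genotype input at {p} (tried PLINK prefix and file)")
    return _read_dosage_tsv(p)


def read_otu_table(path: str | Path, renormalize: bool = False) -> OTUTable:
    """Read a samples x OTUs relative-abundance TSV."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    vals = df.to_numpy(dtype=float)
    if renormalize:
        vals = vals / vals.sum(axis=1, keepdims=True)
    return OTUTable(list(df.index), list(df.columns), vals)


def read_phenotypes(
    path: str | Path,
    traits: list[str] | None = None,
    covariates: list[str] | None = None,
) -> PhenotypeTable:
    """Read a phenotype/covariate TSV (first column = sample ID).

    When ``traits`` is omitted every numeric column is treated as a trait
    and there are no covariates.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    if traits is None:
        traits = [c for c in df.columns if pd.api.types.is_numeric_dtype(df[c])]
        covariates = []
    return PhenotypeTable(df, list(traits), list(covariates or []))


def write_dosage_tsv(g: GenotypeMatrix, path: str | Path) -> None:
    df = pd.DataFrame(g.dosages, index=g.samples, columns=g.snps["id"])
    df.to_csv(path, sep="\t", index_label="sample", float_format="%.17g")


def write_otu_tsv(t: OTUTable, path: str | Path) -> None:
    df = pd.DataFrame(t.rel_abund, index=t.samples, columns=t.otus)
    df.to_csv(path, sep="\t", index_label="sample", float_format="%.17g")


def write_phenotype_tsv(p: PhenotypeTable, path: str | Path) -> None:
    p.data.to_csv(path, sep="\t", index_label="sample", float_format="%.17g")


# ---------------------------------------------------------------------------
# quality control


def qc_filter_genotypes(
    g: GenotypeMatrix, maf_min: float = 0.05, cr_min: float = 0.95
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Drop SNPs failing MAF or call-rate thresholds.

    Comparisons are inclusive on the keep side (MAF >= ``maf_min``, call
    rate >= ``cr_min``).  Returns the filtered matrix plus a report frame
    listing each removed SNP with its reason(s).
    """
    if not (0 <= maf_min <= 1 and 0 <= cr_min <= 1):
        raise ValueError("maf_min and cr_min must lie in [0, 1]")
    maf, cr = g.maf, g.call_rates
    fail_maf = ~(maf >= maf_min)  # NaN-frequency SNPs fail too
    fail_cr = cr < cr_min
    keep = ~(fail_maf | fail_cr)
    reasons = []
    for j in np.flatnonzero(~keep):
        r = []
        if fail_maf[j]:
            r.append("MAF")
        if fail_cr[j]:
            r.append("call_rate")
        reasons.append(";".join(r))
    report = pd.DataFrame(
        {
            "snp_id": g.snps["id"].to_numpy()[~keep],
            "reason": reasons,
            "maf": maf[~keep],
            "call_rate": cr[~keep],
        }
    )
    if not keep.any():
        raise DataValidationError(
            "QC removed every SNP; relax maf_min/cr_min or check the input"
        )
    return g.subset_snps(keep), report


def qc_filter_otus(
    t: OTUTable, prevalence_min: float = 0.20, mode: str = "prevalence"
) -> tuple[OTUTable, pd.DataFrame]:
    """Drop rare OTUs and renormalize rows to sum 1.

    ``mode='prevalence'`` keeps OTUs non-zero in at least ``prevalence_min``
    of samples (inclusive); ``mode='abundance'`` keeps OTUs whose mean
    relative abundance is at least ``prevalence_min``.
    """
    if not 0 <= prevalence_min <= 1:
        raise ValueError("prevalence_min must lie in [0, 1]")
    if mode == "prevalence":
        stat = t.prevalence
    elif mode == "abundance":
        stat = t.rel_abund.mean(axis=0)
    else:
        raise ValueError(f"unknown OTU filter mode {mode!r}")
    keep = stat >= prevalence_min
    report = pd.DataFrame(
        {
            "otu_id": np.asarray(t.otus)[~keep],
            "reason": mode,
            "value": stat[~keep],
        }
    )
    if not keep.any():
        raise DataValidationError("OTU filter removed every OTU")
    vals = t.rel_abund[:, keep]
    sums = vals.sum(axis=1, keepdims=True)
    if (sums == 0).any():
        raise DataValidationError("a sample has zero total abundance after filtering")
    vals = vals / sums
    return OTUTable(list(t.samples), [o for o, k in zip(t.otus, keep) if k], vals), report


def log_transform_otus(
    t: OTUTable, pseudocount: float | str = "auto", center: bool = True
) -> np.ndarray:
    """Log-transform relative abundances into the real matrix R.

    ``R = log(rel_abund + pseudocount)``; the pseudocount keeps zero
    abundances finite, with ``"auto"`` = half the smallest non-zero entry
    of the table.  With ``center=True`` (default) each OTU column is
    mean-centered, so the downstream microbial kernel behaves like a
    covariance rather than being dominated by the compositional mean.
    """
    if pseudocount == "auto":
        nz = t.rel_abund[t.rel_abund > 0]
        if nz.size == 0:
            raise DataValidationError("table has no non-zero abundance")
        pc = float(nz.min()) / 2.0
    else:
        pc = float(pseudocount)
        if pc <= 0:
            raise ValueError("pseudocount must be positive")
    r = np.log(t.rel_abund + pc)
    if center:
        r = r - r.mean(axis=0, keepdims=True)
    return r


def derive_performance_traits(initial_wt, final_wt, days, feed_intake):
    """Daily gain (kg/day) and feed conversion ratio from raw records.

    DG = (final - initial) / days;  FC = feed intake / DG.
    Accepts scalars or aligned arrays.
    """
    initial_wt = np.asarray(initial_wt, dtype=float)
    final_wt = np.asarray(final_wt, dtype=float)
    days = np.asarray(days, dtype=float)
    feed_intake = np.asarray(feed_intake, dtype=float)
    if np.any(days <= 0):
        raise ValueError("days on test must be positive")
    dg = (final_wt - initial_wt) / days
    if np.any(dg == 0):
        raise ZeroDivisionError("daily gain of 0: feed conversion undefined")
    fc = feed_intake / dg
    if dg.ndim == 0:
        return float(dg), float(fc)
    return dg, fc


def align_samples(
    g: GenotypeMatrix, t: OTUTable, p: PhenotypeTable
) -> tuple[GenotypeMatrix, OTUTable, PhenotypeTable]:
    """Restrict all three tables to the common sample set, in a shared order.

    The order of the genotype matrix is used for the intersection.
    """
    sets = [set(g.samples), set(t.samples), set(p.samples)]
    common = sets[0] & sets[1] & sets[2]
    if not common:
        raise DataValidationError(
            "no samples shared between inputs; examples — genotypes: "
            f"{g.samples[:3]}, OTUs: {t.samples[:3]}, phenotypes: {p.samples[:3]}"
        )
    order = [s for s in g.samples if s in common]
    dropped = (set(g.samples) | set(t.samples) | set(p.samples)) - common
    if dropped:
        warnings.warn(f"dropped {len(dropped)} unshared sample(s)", stacklevel=2)
    return g.subset_samples(order), t.subset_samples(order), p.subset_samples(order)
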