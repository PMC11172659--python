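"""Significance regimes, count summaries and genomic-inflation diagnostics.

Four regimes are applied to every scan: an arbitrary per-test threshold
(p <= 0.05), Benjamini-Hochberg FDR control, Bonferroni correction
(alpha / number of tests), and a genome-wide significance threshold
(GWST) obtained by permutation of the whitened residuals, i.e. an
empirical family-wise error threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .lmm import CHI2_1_MEDIAN, AssocResult

__all__ = [
    "bonferroni_threshold",
    "bh_adjust",
    "gwst_threshold",
    "summarize_thresholds",
    "genomic_inflation",
    "ThresholdReport",
]


def bonferroni_threshold(alpha: float, n_tested: int) -> tuple[float, float]:
    """Bonferroni-corrected p-value threshold and its -log10.

    ``threshold = alpha / n_tested`` — e.g. 0.05 over 132,214 tests gives
    3.78e-7 (-log10 = 6.42).
    """
    if n_tested < 1:
        raise ValueError("n_tested must be >= 1")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    thr = alpha / n_tested
    return thr, float(-np.log10(thr))


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, original order kept."""
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1:
        p = p.ravel()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def gwst_threshold(
    result: AssocResult, t_perm: int = 1000, alpha: float = 0.05, seed: int = 0
) -> float:
    """Permutation-based genome-wide significance threshold.

    The whitened trait residuals from the scan are permuted ``t_perm``
    times with a seeded generator; each permutation re-runs the fast scan
    and records its minimum p-value.  The threshold is the empirical
    ``alpha``-quantile of that min-p distribution (the k-th smallest with
    ``k = floor(alpha * (t_perm + 1))``), so scan p-values at or below it
    have family-wise error ``alpha``.
    """
    if t_perm < 20:
        raise ValueError("need at least 20 permutations")
    k = int(np.floor(alpha * (t_perm + 1)))
    if k < 1:
        raise ValueError(
            f"t_perm = {t_perm} too small for the alpha = {alpha} quantile"
        )
    ctx = getattr(result, "_scan_ctx", None)
    if ctx is None:
        raise ValueError("result carries no scan context (was it run via wald_scan?)")
    s_t, y_t, den = ctx["s_tilde"], ctx["y_tilde"], ctx["den"]
    keep = ~ctx["degenerate"]
    rng = np.random.default_rng(seed)
    perms = np.stack([rng.permutation(y_t) for _ in range(t_perm)], axis=1)
    # permuting breaks the orthogonality to the design; re-project exactly
    q_mat = ctx["q_mat"]
    perms = perms - q_mat @ (q_mat.T @ perms)
    num = s_t[:, keep].T @ perms  # q x T
    w = num**2 / den[keep, None]
    min_p = stats.chi2.sf(w.max(axis=0), 1)
    return float(np.sort(min_p)[k - 1])


@dataclass
class ThresholdReport:
    """Per-model significance counts under the four regimes."""

    counts: pd.DataFrame  # index = model, columns = regimes
    passing: dict = field(default_factory=dict)  # (model, regime) -> list of SNP ids
    settings: dict = field(default_factory=dict)

    def write_tsv(self, path) -> None:
        self.counts.to_csv(path, sep="\t", index_label="model")


REGIMES = ("arbitrary", "FDR-BH", "BC", "GWST")


def summarize_thresholds(
    results: list[AssocResult],
    alpha: float = 0.05,
    arbitrary_p: float = 0.05,
    gwst_t: int = 1000,
    gwst_seed: int = 0,
    gwst_fixed: float | None = None,
) -> ThresholdReport:
    """Count significant SNPs per model under each regime.

    ``gwst_fixed`` substitutes a user-supplied threshold for the
    permutation-based GWST (useful when the scan context is unavailable).
    """
    if not results:
        raise ValueError("no scan results supplied")
    rows, passing = {}, {}
    for res in results:
        p = res.table["p"].to_numpy()
        ids = res.table["snp_id"].to_numpy()
        ok = ~np.isnan(p)
        n_tested = int(ok.sum())
        bc_thr, _ = bonferroni_threshold(alpha, max(n_tested, 1))
        adj = np.full_like(p, np.nan)
        adj[ok] = bh_adjust(p[ok])
        if gwst_fixed is not None:
            gw_thr = gwst_fixed
        else:
            try:
                gw_thr = gwst_threshold(res, gwst_t, alpha, gwst_seed)
            except ValueError:
                gw_thr = np.nan
        sets = {
            "arbitrary": ids[ok & (p <= arbitrary_p)],
            "FDR-BH": ids[ok & (adj <= alpha)],
            "BC": ids[ok & (p <= bc_thr)],
            "GWST": ids[ok & (p <= gw_thr)] if np.isfinite(gw_thr) else np.array([]),
        }
        rows[res.model] = {k: len(v) for k, v in sets.items()}
        for k, v in sets.items():
            passing[(res.model, k)] = list(v)
    counts = pd.DataFrame.from_dict(rows, orient="index")[list(REGIMES)]
    return ThresholdReport(
        counts,
        passing,
        {"alpha": alpha, "arbitrary_p": arbitrary_p, "gwst_t": gwst_t, "gwst_seed": gwst_seed},
    )


def genomic_inflation(result: AssocResult | np.ndarray) -> float:
    """Genomic-inflation factor: median Wald statistic / median of chi2(1).

    Values near 1 indicate a calibrated scan; > 1 suggests inflation from
    unmodeled structure (or true polygenicity).
    """
    w = result if isinstance(result, np.ndarray) else result.table["wald"].to_numpy()
    w = w[~np.isnan(w)]
    if w.size < 10:
        raise ValueError("need at least 10 non-missing test statistics")
    return float(np.median(w) / CHI2_1_MEDIAN)
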