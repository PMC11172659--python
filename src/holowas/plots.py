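"""Manhattan and QQ rendering.

Every figure also writes a TSV "sidecar" of the plotted coordinates so
that graphical content can be asserted in tests without pixel
comparisons.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .lmm import AssocResult
from .significance import bonferroni_threshold

__all__ = ["plot_manhattan_qq"]


def plot_manhattan_qq(
    result: AssocResult,
    out_prefix: str | Path,
    alpha: float = 0.05,
    bc_threshold: float | None = None,
) -> dict[str, Path]:
    """Write Manhattan + QQ PNGs and their data sidecars.

    The Manhattan plot alternates colors by chromosome and draws a dashed
    red line at the Bonferroni threshold; the QQ plot shows observed vs
    expected -log10 p with the genomic-inflation factor printed in the
    corner.  Returns the paths written.
    """
    tab = result.table.copy()
    tab = tab[~tab["p"].isna()]
    if tab.empty:
        raise ValueError("no usable p-values to plot")
    if bc_threshold is None:
        bc_threshold, _ = bonferroni_threshold(alpha, len(tab))
    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)

    # --- Manhattan ---
    chrom_order = list(dict.fromkeys(tab["chrom"]))
    offset, xs, colors, ticks = 0, [], [], []
    palette = ("#1f77b4", "#ff7f0e")
    for ci, ch in enumerate(chrom_order):
        sub = tab[tab["chrom"] == ch]
        xs.append(sub["pos"].to_numpy() + offset)
        colors.extend([palette[ci % 2]] * len(sub))
        ticks.append((ch, offset + sub["pos"].mean()))
        offset += sub["pos"].max() + 1
    x = np.concatenate(xs)
    logp = -np.log10(np.clip(tab["p"].to_numpy(), 1e-300, None))
    man_sidecar = pd.DataFrame(
        {
            "snp_id": tab["snp_id"].to_numpy(),
            "chrom": tab["chrom"].to_numpy(),
            "x": x,
            "neglog10p": logp,
            "above_bc": logp >= -np.log10(bc_threshold),
        }
    )
    fig, ax = plt.subplots(figsize=(9, 3.2))
    ax.scatter(x, logp, s=6, c=colors, linewidths=0)
    ax.axhline(-np.log10(bc_threshold), color="red", linestyle="--", linewidth=1)
    ax.set_xticks([t for _, t in ticks])
    ax.set_xticklabels([c for c, _ in ticks], fontsize=7)
    ax.set_xlabel("chromosome")
    ax.set_ylabel(r"$-\log_{10}\,p$")
    ax.set_title(f"{result.model} — {result.trait}")
    fig.tight_layout()
    man_png = out_prefix.with_suffix(".manhattan.png")
    fig.savefig(man_png, dpi=150)
    plt.close(fig)
    man_tsv = out_prefix.with_suffix(".manhattan.sidecar.tsv")
    man_sidecar.to_csv(man_tsv, sep="\t", index=False)

    # --- QQ ---
    p_sorted = np.sort(tab["p"].to_numpy())
    m = len(p_sorted)
    expected = -np.log10((np.arange(1, m + 1) - 0.5) / m)
    observed = -np.log10(np.clip(p_sorted, 1e-300, None))  # descending, like expected
    qq_sidecar = pd.DataFrame({"expected": expected, "observed": observed})
    fig, ax = plt.subplots(figsize=(3.4, 3.4))
    ax.scatter(expected, observed, s=6, c="#1f77b4", linewidths=0)
    lim = max(expected.max(), observed.max()) * 1.05
    ax.plot([0, lim], [0, lim], color="grey", linewidth=1)
    ax.text(
        0.05, 0.92, rf"$\lambda = {result.lambda_gc:.3f}$", transform=ax.transAxes
    )
    ax.set_xlabel(r"expected $-\log_{10} p$")
    ax.set_ylabel(r"observed $-\log_{10} p$")
    ax.set_title(f"{result.model} — {result.trait}", fontsize=9)
    fig.tight_layout()
    qq_png = out_prefix.with_suffix(".qq.png")
    fig.savefig(qq_png, dpi=150)
    plt.close(fig)
    qq_tsv = out_prefix.with_suffix(".qq.sidecar.tsv")
    qq_sidecar.to_csv(qq_tsv, sep="\t", index=False)

    return {
        "manhattan": man_png,
        "manhattan_sidecar": man_tsv,
        "qq": qq_png,
        "qq_sidecar": qq_tsv,
    }
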