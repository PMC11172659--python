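"""Relationship-matrix (kernel) construction.

Four n x n kernels drive the association models:

* GRM  — genomic relationship matrix, ``X_s X_s' / (q - 1)`` from
  standardized genotypes (VanRaden-style standardization).
* MRM  — microbial relationship matrix, ``R R' / p`` from log-transformed
  OTU relative abundances.
* HRM_CG — hologenome cross-covariance kernel, ``L_M L_G' + (L_M L_G')'``
  from the Cholesky factors of M and G.  May be indefinite; its variance
  parameter is interpreted as a genome-microbiome covariance.
* HRM_H — hologenome Hadamard kernel, the entrywise product ``G ∘ M``
  (positive semidefinite whenever G and M are, by the Schur product
  theorem).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import GenotypeMatrix

__all__ = [
    "RelationshipMatrix",
    "standardize_genotypes",
    "compute_grm",
    "compute_mrm",
    "compute_hrm_cg",
    "compute_hrm_h",
    "compute_pcs",
    "ensure_pd",
    "write_kernel_tsv",
    "read_kernel_tsv",
]

KERNEL_KINDS = ("GRM", "MRM", "HRM_CG", "HRM_H")


@dataclass
class RelationshipMatrix:
    """Symmetric n x n sample-similarity kernel tagged with its kind."""

    samples: list[str]
    values: np.ndarray
    kind: str
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.kind not in KERNEL_KINDS:
            raise ValueError(f"kernel kind must be one of {KERNEL_KINDS}")
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.samples)
        if self.values.shape != (n, n):
            raise ValueError(f"kernel shape {self.values.shape} != ({n}, {n})")
        if not np.isfinite(self.values).all():
            raise ValueError("kernel has non-finite entries")
        if np.max(np.abs(self.values - self.values.T)) > 1e-10:
            raise ValueError("kernel is not symmetric within 1e-10")
        # enforce exact symmetry for downstream eigendecompositions
        self.values = (self.values + self.values.T) / 2.0

    @property
    def n(self) -> int:
        return len(self.samples)

    def min_eigenvalue(self) -> float:
        return float(np.linalg.eigvalsh(self.values)[0])


def standardize_genotypes(g: GenotypeMatrix) -> np.ndarray:
    """Column-standardize dosages to the matrix X_s.

    Column j becomes ``(x - 2 p_j) / sqrt(2 p_j (1 - p_j))`` with ``p_j``
    the observed alt-allele frequency, the usual unit-variance scaling
    under Hardy-Weinberg proportions.  Missing dosages are mean-imputed
    (to ``2 p_j``) before centering, so they standardize to exactly 0.
    """
    f = g.freqs
    mono = np.flatnonzero(~((f > 0) & (f < 1)))
    if mono.size:
        names = list(g.snps["id"].iloc[mono[:5]])
        raise ValueError(
            f"monomorphic SNP(s) {names} cannot be standardized; run QC first"
        )
    x = g.dosages.copy()
    miss = np.isnan(x)
    if miss.any():
        x[miss] = (2.0 * f)[np.nonzero(miss)[1]]
    return (x - 2.0 * f) / np.sqrt(2.0 * f * (1.0 - f))


def compute_grm(x_s: np.ndarray, samples: list[str] | None = None) -> RelationshipMatrix:
    """Genomic relationship matrix ``G = X_s X_s' / (q - 1)``."""
    x_s = np.asarray(x_s, dtype=float)
    n, q = x_s.shape
    if q < 2:
        raise ValueError("need at least 2 SNPs (divisor q - 1)")
    g = x_s @ x_s.T / (q - 1)
    samples = samples if samples is not None else [str(i) for i in range(n)]
    return RelationshipMatrix(list(samples), g, "GRM", {"q": q})


def compute_mrm(r: np.ndarray, samples: list[str] | None = None) -> RelationshipMatrix:
    """Microbial relationship matrix ``M = R R' / p`` from log abundances."""
    r = np.asarray(r, dtype=float)
    n, p = r.shape
    if p < 1:
        raise ValueError("need at least 1 OTU")
    m = r @ r.T / p
    samples = samples if samples is not None else [str(i) for i in range(n)]
    return RelationshipMatrix(list(samples), m, "MRM", {"p": p})


def _check_same_samples(a: RelationshipMatrix, b: RelationshipMatrix) -> None:
    if a.samples != b.samples:
        raise ValueError("kernels were built on different sample sets/orders")


def compute_hrm_cg(
    g: RelationshipMatrix, m: RelationshipMatrix, jitter_tol: float = 1e-2
) -> RelationshipMatrix:
    """Cross-covariance hologenome kernel from Cholesky factors.

    ``h_c = L_M L_G' + (L_M L_G')'`` with ``L_G``, ``L_M`` the lower
    Cholesky factors of G and M (after minimal diagonal jitter when a
    factor does not exist).  The result is symmetric by construction but
    in general indefinite: it plays the role of a covariance term between
    the genomic and microbial effects, not of a variance.
    """
    _check_same_samples(g, m)
    gv, jit_g = _chol_with_jitter(g.values, jitter_tol)
    mv, jit_m = _chol_with_jitter(m.values, jitter_tol)
    cross = mv @ gv.T
    hc = cross + cross.T
    return RelationshipMatrix(
        list(g.samples), hc, "HRM_CG", {"jitter_g": jit_g, "jitter_m": jit_m}
    )


def compute_hrm_h(g: RelationshipMatrix, m: RelationshipMatrix) -> RelationshipMatrix:
    """Hadamard-product hologenome kernel ``(h)_ij = G_ij * M_ij``."""
    _check_same_samples(g, m)
    if g.values.shape != m.values.shape:
        raise ValueError("kernel dimension mismatch")
    return RelationshipMatrix(list(g.samples), g.values * m.values, "HRM_H", {})


def compute_pcs(g: RelationshipMatrix, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Top-k principal component scores of a kernel.

    Returns (scores, eigenvalues): scores are eigenvectors scaled by the
    square root of their (non-negative-clipped) eigenvalues, in descending
    eigenvalue order; each column's largest-magnitude loading is made
    positive to fix the sign.
    """
    if k > g.n:
        raise ValueError(f"k = {k} exceeds sample count {g.n}")
    w, u = np.linalg.eigh(g.values)
    w, u = w[::-1][:k], u[:, ::-1][:, :k]
    signs = np.sign(u[np.argmax(np.abs(u), axis=0), np.arange(k)])
    signs[signs == 0] = 1.0
    u = u * signs
    scores = u * np.sqrt(np.clip(w, 0.0, None))
    return scores, w


def _chol_with_jitter(k: np.ndarray, max_eps: float) -> tuple[np.ndarray, float]:
    """Lower Cholesky factor, escalating diagonal jitter x10 from 1e-8."""
    try:
        return np.linalg.cholesky(k), 0.0
    except np.linalg.LinAlgError:
        pass
    scale = float(np.mean(np.diag(k)))
    if scale <= 0:
        scale = 1.0
    eps = 1e-8
    while eps <= max_eps:
        try:
            l = np.linalg.cholesky(k + eps * scale * np.eye(k.shape[0]))
            return l, eps * scale
        except np.linalg.LinAlgError:
            eps *= 10.0
    w = np.linalg.eigvalsh(k)
    raise np.linalg.LinAlgError(
        f"Cholesky failed even with jitter {max_eps:g} x mean diag; "
        f"min eigenvalue = {w[0]:.3e}"
    )


def ensure_pd(
    k: np.ndarray, policy: str = "jitter", tol: float = 1e-8
) -> tuple[np.ndarray, dict]:
    """Return a positive-definite version of a symmetric matrix.

    ``policy='jitter'`` adds ``eps * mean(diag)`` to the diagonal with eps
    escalating x10 from 1e-8 until the Cholesky succeeds (error past
    1e-2); ``policy='clip-eigen'`` floors eigenvalues at ``tol`` and
    reconstructs.  The report records the modification applied.
    """
    k = np.asarray(k, dtype=float)
    if np.max(np.abs(k - k.T)) > 1e-8:
        raise ValueError("ensure_pd expects a symmetric matrix")
    if policy == "jitter":
        try:
            np.linalg.cholesky(k)
            return k, {"policy": policy, "modified": False, "jitter": 0.0}
        except np.linalg.LinAlgError:
            pass
        _, jit = _chol_with_jitter(k, 1e-2)
        out = k + jit * np.eye(k.shape[0])
        return out, {"policy": policy, "modified": True, "jitter": jit}
    if policy == "clip-eigen":
        w, u = np.linalg.eigh(k)
        if w[0] >= tol:
            return k, {"policy": policy, "modified": False, "min_eig": float(w[0])}
        w_clipped = np.clip(w, tol, None)
        out = (u * w_clipped) @ u.T
        out = (out + out.T) / 2.0
        return out, {
            "policy": policy,
            "modified": True,
            "min_eig": float(w[0]),
            "clipped_to": tol,
        }
    raise ValueError(f"unknown PD policy {policy!r}")


def rescale_unit_diag(k: RelationshipMatrix) -> RelationshipMatrix:
    """Rescale a kernel to mean diagonal 1 (off by default everywhere).

    Useful for cross-kernel comparability of variance components; no
    rescaling is applied automatically by the kernel builders.
    """
    scale = float(np.mean(np.diag(k.values)))
    if scale <= 0:
        raise ValueError("cannot rescale a kernel with non-positive mean diagonal")
    return RelationshipMatrix(
        list(k.samples), k.values / scale, k.kind,
        {**k.meta, "rescaled_by": scale},
    )


def write_kernel_tsv(k: RelationshipMatrix, path: str | Path) -> None:
    """Serialize a kernel as TSV plus a JSON metadata sidecar."""
    df = pd.DataFrame(k.values, index=k.samples, columns=k.samples)
    df.to_csv(path, sep="\t", index_label="sample", float_format="%.15g")
    meta = {"kind": k.kind, **k.meta}
    Path(str(path) + ".meta.json").write_text(json.dumps(meta, indent=1))


def read_kernel_tsv(path: str | Path) -> RelationshipMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    meta_path = Path(str(path) + ".meta.json")
    meta = json.loads(meta_path.read_text()) if meta_path.exists() else {"kind": "GRM"}
    kind = meta.pop("kind")
    vals = df.to_numpy(dtype=float)
    vals = (vals + vals.T) / 2.0
    return RelationshipMatrix([str(s) for s in df.index], vals, kind, meta)
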