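"""Tissue expression-matrix preprocessing.

Fixed pipeline order: RIN sample filter -> duplicate-gene aggregation ->
log2(E+1) scaling -> cross-tissue low-expression filter -> latent-covariate
(surrogate-variable style) PCA adjustment. Array-based matrices without RIN
annotations enter at the aggregation step.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "filter_rin",
    "aggregate_duplicates",
    "log2_scale",
    "filter_low_expression",
    "adjust_latent",
    "estimate_latent_components",
    "preprocess_tissues",
]


@dataclass
class ExpressionMatrix:
    """A genes x samples expression matrix for one tissue.

    ``values`` is a DataFrame indexed by gene symbol with sample columns;
    ``rin`` is an optional per-sample RNA integrity number Series aligned to
    the columns. ``scaled`` marks log2(E+1) scaling, ``adjusted`` marks
    latent-covariate residualization (after which values may be negative).
    """

    values: pd.DataFrame
    tissue_category: str | None = None
    rin: pd.Series | None = None
    scaled: bool = False
    adjusted: bool = False

    def __post_init__(self) -> None:
        if not np.isfinite(self.values.to_numpy(dtype=float)).all():
            raise ValueError("expression values must be finite")
        if self.rin is not None:
            missing = set(self.values.columns) - set(self.rin.index)
            if missing:
                raise ValueError(f"samples without RIN: {sorted(missing)[:5]}")
            self.rin = self.rin.loc[self.values.columns]

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)


def filter_rin(matrix: ExpressionMatrix, rin_min: float = 6.0) -> ExpressionMatrix:
    """Drop samples with RIN strictly below ``rin_min``.

    A matrix without RIN annotation (e.g. array data) passes through
    unchanged with a warning.
    """
    if matrix.rin is None:
        warnings.warn("no RIN annotation: RIN filter skipped", stacklevel=2)
        return matrix
    keep = matrix.rin[matrix.rin >= rin_min].index
    if len(keep) == 0:
        raise ValueError(f"all samples have RIN < {rin_min}: empty matrix")
    return replace(matrix, values=matrix.values[list(keep)], rin=matrix.rin.loc[keep])


def aggregate_duplicates(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Average rows sharing a gene symbol (per-sample arithmetic mean)."""
    if matrix.values.index.is_unique:
        return matrix
    values = matrix.values.groupby(level=0, sort=False).mean()
    return replace(matrix, values=values)


def log2_scale(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Elementwise log2(E + 1)."""
    if (matrix.values.to_numpy() < 0).any():
        raise ValueError("negative expression values cannot be log2(E+1)-scaled")
    return replace(matrix, values=np.log2(matrix.values + 1.0), scaled=True)


def filter_low_expression(
    matrices: Sequence[ExpressionMatrix],
    threshold: float = 1.0,
    fraction: float = 0.8,
    inclusive: bool = True,
) -> tuple[list[str], list[ExpressionMatrix]]:
    """Keep genes scaled above ``threshold`` in ``fraction`` of samples of at
    least one tissue; apply the shared keep-set to every matrix.

    The attained-fraction comparison is >= by default (``inclusive=False``
    makes it strict). Returns (keep list in first-matrix order, matrices).
    """
    if not matrices:
        raise ValueError("no matrices given")
    for m in matrices:
        if not m.scaled:
            raise ValueError("low-expression filter requires scaled matrices")
    keep: set[str] = set()
    for m in matrices:
        frac = (m.values > threshold).mean(axis=1)
        ok = frac >= fraction if inclusive else frac > fraction
        keep |= set(m.values.index[ok])
    if not keep:
        raise ValueError("low-expression filter removed every gene")
    out = []
    for m in matrices:
        rows = [g for g in m.values.index if g in keep]
        out.append(replace(m, values=m.values.loc[rows]))
    ordered = [g for g in matrices[0].values.index if g in keep]
    ordered += sorted(keep - set(ordered))
    return ordered, out


def adjust_latent(matrix: ExpressionMatrix, n_components: int = 10) -> ExpressionMatrix:
    """Residualize each gene on the top sample-space principal components.

    Genes are centered, the leading ``n_components`` right singular vectors of
    the centered matrix are removed, and the residuals (orthogonal to every
    removed component) are returned. ``n_components=0`` just centers.
    """
    X = matrix.values.to_numpy(dtype=float)
    n_genes, n_samples = X.shape
    if n_components < 0 or n_components >= min(n_genes, n_samples):
        raise ValueError(
            f"n_components must be in [0, {min(n_genes, n_samples) - 1}], got {n_components}"
        )
    Xc = X - X.mean(axis=1, keepdims=True)
    if n_components > 0:
        _, _, Vt = np.linalg.svd(Xc, full_matrices=False)
        V = Vt[:n_components].T  # samples x k
        Xc = Xc - (Xc @ V) @ V.T
    values = pd.DataFrame(Xc, index=matrix.values.index, columns=matrix.values.columns)
    return replace(matrix, values=values, adjusted=True)


def estimate_latent_components(
    matrix: ExpressionMatrix,
    n_perm: int = 20,
    quantile: float = 0.95,
    rng: np.random.Generator | None = None,
) -> int:
    """Permutation (parallel-analysis) estimate of the latent dimension.

    Compares observed singular values of the gene-centered matrix against the
    ``quantile`` of singular values obtained after independently permuting
    each gene row, and counts how many leading observed values exceed it.
    """
    rng = rng or np.random.default_rng(0)
    X = matrix.values.to_numpy(dtype=float)
    Xc = X - X.mean(axis=1, keepdims=True)
    obs = np.linalg.svd(Xc, compute_uv=False)
    null = np.empty((n_perm, obs.size))
    for i in range(n_perm):
        perm = rng.permuted(Xc, axis=1)
        null[i] = np.linalg.svd(perm, compute_uv=False)
    thresh = np.quantile(null, quantile, axis=0)
    above = obs > thresh
    k = 0
    while k < above.size and above[k]:
        k += 1
    return k


def preprocess_tissues(
    matrices: dict[str, ExpressionMatrix],
    rin_min: float = 6.0,
    threshold: float = 1.0,
    fraction: float = 0.8,
    n_components: int = 10,
) -> dict[str, ExpressionMatrix]:
    """Run the full fixed-order pipeline over a set of tissue matrices."""
    staged = {}
    for tissue, m in matrices.items():
        m = filter_rin(m, rin_min=rin_min) if m.rin is not None else m
        m = aggregate_duplicates(m)
        staged[tissue] = log2_scale(m)
    _, filtered = filter_low_expression(list(staged.values()), threshold, fraction)
    out = {}
    for tissue, m in zip(staged, filtered):
        out[tissue] = adjust_latent(m, n_components=n_components)
    return out
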