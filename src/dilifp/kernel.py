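"""Tanimoto similarity for binary and weighted fingerprints.

For 0/1 vectors the Tanimoto coefficient is the ratio of the intersecting
set to the union set.  For non-negative real vectors (weighted
fingerprints) the continuous generalization

    T(a, b) = (a . b) / (||a||^2 + ||b||^2 - a . b)

is used; it reduces exactly to the binary form on 0/1 input.  Both-zero
vector pairs are assigned similarity 0 (with a warning).  The continuous
form is invariant to one global scale factor applied to every bit (the
factor cancels), but NOT to non-uniform per-bit weights or to rescaling
a single vector — which is exactly why fingerprint weighting changes
the kernel.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)

VARIANTS = ("binary", "continuous")


@dataclass
class KernelMatrix:
    """Pairwise Tanimoto similarities plus the compound IDs they index."""

    K: np.ndarray
    row_ids: list[str] | None = None
    col_ids: list[str] | None = None
    variant: str = "continuous"


def _validate(X: np.ndarray, variant: str) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if (X < 0).any():
        raise ValueError("Tanimoto similarity requires non-negative entries")
    if variant not in VARIANTS:
        raise ValueError(f"variant must be one of {VARIANTS}, got {variant!r}")
    if variant == "binary" and X.size and not np.isin(X, (0.0, 1.0)).all():
        raise ValueError("binary variant requires 0/1 entries")
    return X


def tanimoto(a, b, variant: str = "binary") -> float:
    """Tanimoto similarity of two equal-length non-negative vectors."""
    a = _validate(np.atleast_1d(a), variant)
    b = _validate(np.atleast_1d(b), variant)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape[0]} vs {b.shape[0]}")
    dot = float(a @ b)
    denom = float(a @ a) + float(b @ b) - dot
    if denom == 0.0:
        logger.warning("tanimoto of two all-zero vectors defined as 0")
        return 0.0
    return dot / denom


def kernel_matrix(
    X_rows: np.ndarray,
    X_cols: np.ndarray | None = None,
    variant: str = "continuous",
    row_ids: list[str] | None = None,
    col_ids: list[str] | None = None,
) -> KernelMatrix:
    """All-pairs Tanimoto similarity between rows of two matrices.

    With ``X_cols=None`` the square self-kernel is computed; it is
    symmetric with unit diagonal for nonzero rows.  Binary and continuous
    variants share one arithmetic path, so they agree bit-for-bit on 0/1
    input.
    """
    X_rows = _validate(X_rows, variant)
    symmetric = X_cols is None
    X_cols = X_rows if symmetric else _validate(X_cols, variant)
    if X_rows.shape[1] != X_cols.shape[1]:
        raise ValueError(
            f"bit-dimension mismatch: {X_rows.shape[1]} vs {X_cols.shape[1]}"
        )
    dot = X_rows @ X_cols.T
    sq_r = np.einsum("ij,ij->i", X_rows, X_rows)
    sq_c = sq_r if symmetric else np.einsum("ij,ij->i", X_cols, X_cols)
    denom = sq_r[:, None] + sq_c[None, :] - dot
    if (sq_r == 0).any() or (sq_c == 0).any():
        logger.warning("all-zero fingerprint rows present; their similarities are 0")
    with np.errstate(invalid="ignore", divide="ignore"):
        K = np.where(denom > 0, dot / np.where(denom > 0, denom, 1.0), 0.0)
    if symmetric:
        col_ids = row_ids
    return KernelMatrix(K=K, row_ids=row_ids, col_ids=col_ids, variant=variant)


def write_kernel_csv(km: KernelMatrix, path) -> None:
    """Export a kernel as square CSV with ID header row/column."""
    import pandas as pd

    n_r, n_c = km.K.shape
    rows = km.row_ids or [str(i) for i in range(n_r)]
    cols = km.col_ids or [str(j) for j in range(n_c)]
    pd.DataFrame(km.K, index=rows, columns=cols).to_csv(path, index_label="id")
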