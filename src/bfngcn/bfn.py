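"""Brain functional network (BFN) estimation from ROI time series.

Three estimators of the n x n connectivity matrix:

* **PC** — Pearson's correlation between ROI time series,
  ``c_ij = (s_i - s̄_i)ᵀ(s_j - s̄_j) / (‖s_i - s̄_i‖ ‖s_j - s̄_j‖)``.
* **SR** — sparse representation: each ROI's series regressed on all the
  others with an L1 penalty (regional lasso); the coefficient matrix is
  symmetrized.
* **LR** — low-rank representation: nuclear-norm proximal denoising of the
  PC matrix, ``min_W ½‖C − W‖²_F + λ‖W‖_*``, solved in closed form by
  singular-value soft-thresholding.

All estimators produce an :class:`AdjacencyMatrix` holding the raw
symmetric zero-diagonal estimate and its symmetric degree-normalized form
``Â = D^{-1/2}(|A| + I)D^{-1/2}`` used by the spectral GCN.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from sklearn.linear_model import Lasso

__all__ = [
    "TimeSeriesMatrix",
    "AdjacencyMatrix",
    "estimate_pc",
    "estimate_sr",
    "estimate_lr",
    "normalize_adjacency",
    "binarize_adjacency",
]

_SYM_TOL = 1e-8


@dataclass
class TimeSeriesMatrix:
    """One subject's ROI signals: ``values`` is n ROIs x m time points."""

    values: np.ndarray
    roi_ids: list[str] = field(default_factory=list)
    subject_id: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError(f"{self.subject_id or 'time series'}: values must be 2-D")
        n, m = self.values.shape
        if n < 2 or m < 3:
            raise ValueError(
                f"{self.subject_id or 'time series'}: need >=2 ROIs and >=3 time "
                f"points, got {n}x{m}"
            )
        if not self.roi_ids:
            self.roi_ids = [f"ROI{i + 1:03d}" for i in range(n)]
        if len(self.roi_ids) != n:
            raise ValueError("roi_ids length does not match number of rows")

    @property
    def n_rois(self) -> int:
        return self.values.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[1]

    def constant_rows(self) -> list[int]:
        """Indices of zero-variance ROI rows (degenerate for correlation)."""
        return list(np.flatnonzero(np.ptp(self.values, axis=1) == 0))


@dataclass
class AdjacencyMatrix:
    """Symmetric connectivity estimate with estimator provenance.

    ``raw`` has zero diagonal; ``normalized`` is filled by
    :func:`normalize_adjacency` (done automatically by the estimators).
    """

    raw: np.ndarray
    estimator: str
    params: dict = field(default_factory=dict)
    roi_ids: list[str] = field(default_factory=list)
    normalized: Optional[np.ndarray] = None

    def __post_init__(self):
        self.raw = np.asarray(self.raw, dtype=float)
        if self.raw.ndim != 2 or self.raw.shape[0] != self.raw.shape[1]:
            raise ValueError("raw adjacency must be square")
        if not np.allclose(self.raw, self.raw.T, atol=_SYM_TOL):
            raise ValueError("raw adjacency must be symmetric")
        if not self.roi_ids:
            self.roi_ids = [f"ROI{i + 1:03d}" for i in range(self.n)]

    @property
    def n(self) -> int:
        return self.raw.shape[0]


def _check_constant_rows(ts: TimeSeriesMatrix) -> None:
    bad = ts.constant_rows()
    if bad:
        names = ", ".join(ts.roi_ids[i] for i in bad)
        raise ValueError(
            f"{ts.subject_id or 'subject'}: constant (zero-variance) ROI rows: {names}"
        )


def estimate_pc(ts: TimeSeriesMatrix) -> AdjacencyMatrix:
    """Pearson-correlation BFN; entries in [-1, 1], zero diagonal."""
    _check_constant_rows(ts)
    c = np.corrcoef(ts.values)
    c = np.clip((c + c.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(c, 0.0)
    adj = AdjacencyMatrix(raw=c, estimator="pc", roi_ids=list(ts.roi_ids))
    return normalize_adjacency(adj)


def estimate_sr(
    ts: TimeSeriesMatrix,
    lambda_l1: float,
    *,
    max_iter: int = 10_000,
    tol: float = 1e-6,
) -> AdjacencyMatrix:
    """Sparse-representation BFN via regional lasso.

    For each ROI i solves ``min_w ½‖s_i − S_{−i} w‖² + λ‖w‖₁`` over the
    other ROIs' z-scored series, then symmetrizes ``(|W| + |Wᵀ|)/2`` with a
    zeroed diagonal.  Larger λ gives sparser networks.
    """
    if lambda_l1 <= 0:
        raise ValueError("lambda_l1 must be positive")
    _check_constant_rows(ts)
    n, m = ts.values.shape
    # z-score each ROI series so the L1 penalty acts on comparable scales
    x = ts.values - ts.values.mean(axis=1, keepdims=True)
    x = x / x.std(axis=1, keepdims=True)
    w = np.zeros((n, n))
    # sklearn's lasso objective divides the fit term by m; rescale alpha to
    # match the unnormalized ½‖·‖² + λ‖·‖₁ objective
    model = Lasso(alpha=lambda_l1 / m, fit_intercept=False, max_iter=max_iter, tol=tol)
    for i in range(n):
        others = np.delete(np.arange(n), i)
        model.fit(x[others].T, x[i])
        if model.n_iter_ >= max_iter:
            resid = float(np.linalg.norm(x[i] - x[others].T @ model.coef_))
            raise RuntimeError(
                f"lasso for ROI {ts.roi_ids[i]} did not converge in {max_iter} "
                f"iterations (residual {resid:.3e}); increase max_iter or lambda"
            )
        w[i, others] = model.coef_
    raw = (np.abs(w) + np.abs(w.T)) / 2.0
    np.fill_diagonal(raw, 0.0)
    adj = AdjacencyMatrix(
        raw=raw, estimator="sr", params={"lambda": lambda_l1}, roi_ids=list(ts.roi_ids)
    )
    return normalize_adjacency(adj)


def estimate_lr(ts: TimeSeriesMatrix, lambda_nuc: float) -> AdjacencyMatrix:
    """Low-rank BFN: singular-value soft-thresholding of the PC matrix.

    Solves ``min_W ½‖C − W‖²_F + λ‖W‖_*`` where C is the Pearson matrix
    (unit diagonal); λ at or above C's largest singular value gives W = 0,
    and λ → 0 recovers C.
    """
    if lambda_nuc <= 0:
        raise ValueError("lambda_nuc must be positive")
    _check_constant_rows(ts)
    c = np.corrcoef(ts.values)
    c = (c + c.T) / 2.0
    u, s, vt = np.linalg.svd(c, hermitian=True)
    w = (u * np.maximum(s - lambda_nuc, 0.0)) @ vt
    raw = (np.abs(w) + np.abs(w.T)) / 2.0
    np.fill_diagonal(raw, 0.0)
    adj = AdjacencyMatrix(
        raw=raw, estimator="lr", params={"lambda": lambda_nuc}, roi_ids=list(ts.roi_ids)
    )
    return normalize_adjacency(adj)


def soft_threshold_matrix(c: np.ndarray, lam: float) -> np.ndarray:
    """Singular-value soft-thresholding (the proximal map of λ‖·‖_*)."""
    u, s, vt = np.linalg.svd(np.asarray(c, dtype=float))
    return (u * np.maximum(s - lam, 0.0)) @ vt


def binarize_adjacency(adj: AdjacencyMatrix, keep_fraction: float) -> AdjacencyMatrix:
    """Proportional thresholding: keep the top ``keep_fraction`` of |edges|.

    Returns a 0/1 adjacency with the strongest off-diagonal weights kept.
    ``keep_fraction=1`` keeps every nonzero edge.
    """
    if not 0 < keep_fraction <= 1:
        raise ValueError("keep_fraction must lie in (0, 1]")
    n = adj.n
    iu = np.triu_indices(n, k=1)
    mags = np.abs(adj.raw[iu])
    k = int(np.ceil(keep_fraction * len(mags)))
    order = np.argsort(-mags, kind="stable")
    keep = order[:k]
    keep = keep[mags[keep] > 0]
    binary = np.zeros((n, n))
    binary[iu[0][keep], iu[1][keep]] = 1.0
    binary = binary + binary.T
    out = AdjacencyMatrix(
        raw=binary,
        estimator=adj.estimator,
        params={**adj.params, "binarized": True, "keep_fraction": keep_fraction},
        roi_ids=list(adj.roi_ids),
    )
    return normalize_adjacency(out)


def normalize_adjacency(adj: AdjacencyMatrix) -> AdjacencyMatrix:
    """Fill ``adj.normalized`` with ``D^{-1/2}(|A| + I)D^{-1/2}``.

    Absolute values make the working matrix nonnegative so that every
    degree is positive and the normalized spectrum lies in [-1, 1];
    self-loops (the +I) guarantee D_ii >= 1.
    """
    working = np.abs(adj.raw) + np.eye(adj.n)
    d = working.sum(axis=1)
    if np.any(d <= 0):  # unreachable after +I, kept as a guard
        raise ValueError("zero degree encountered during normalization")
    d_inv_sqrt = 1.0 / np.sqrt(d)
    adj.normalized = working * np.outer(d_inv_sqrt, d_inv_sqrt)
    return adj
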