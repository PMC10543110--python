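"""Orthogonal projective NMF parcellation with split-half stability.

The decomposition approximates a non-negative vertices x subject-metrics
matrix X as C C^T X with C >= 0 and C^T C ~= I (k orthogonal, non-negative
spatial components).  C is initialised with non-negative double SVD and
refined with the Yang-Oja multiplicative update

    C <- C * (X X^T C) / (C C^T X X^T C),

monitored through the squared Frobenius objective ||X - C C^T X||^2.
Winner-take-all on the rows of C yields a hard parcellation; split-half
stability compares vertex-vertex cosine-similarity structure across
independent halves of the subjects.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "MetricStack",
    "OpnnmfDecomposition",
    "StabilityReport",
    "normalize_metrics",
    "nndsvd_init",
    "opnnmf_fit",
    "winner_take_all",
    "zscore_weights",
    "reconstruction_error",
    "error_gradient",
    "split_half_stability",
    "stability_analysis",
]

_EPS = 1e-12  # denominator floor in the multiplicative update


@dataclass
class MetricStack:
    """Non-negative vertices x (subject, metric) matrix with column metadata.

    columns is a DataFrame with one row per column of X carrying at least
    'subject' and 'metric' (and optionally 'hemisphere').
    """

    X: np.ndarray
    columns: pd.DataFrame
    hemisphere: str = ""

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2:
            raise ValueError("X must be 2-D (vertices x subject-metrics)")
        if len(self.columns) != self.X.shape[1]:
            raise ValueError("column metadata must match X's width")
        for col in ("subject", "metric"):
            if col not in self.columns:
                raise ValueError(f"column metadata needs a '{col}' field")
        if np.any(self.X < 0):
            raise ValueError("X must be non-negative (normalise first)")
        if np.any(~np.isfinite(self.X)):
            raise ValueError("X must be finite")
        if np.any(self.X.sum(axis=1) == 0):
            raise ValueError("X must not contain all-zero rows")

    @property
    def n_vertices(self) -> int:
        return self.X.shape[0]

    def subject_columns(self, subjects) -> np.ndarray:
        return self.columns["subject"].isin(list(subjects)).to_numpy()


def normalize_metrics(raw: np.ndarray, columns: pd.DataFrame, hemisphere: str = ""):
    """z-score each metric within each hemisphere, then shift everything by
    the single global minimum of the z-scored values so the result is >= 0
    with minimum exactly 0.

    z-scoring pools all vertices and subjects of a metric (per hemisphere),
    which puts metrics with different units on a common scale.
    """
    raw = np.asarray(raw, dtype=float)
    if raw.ndim != 2 or len(columns) != raw.shape[1]:
        raise ValueError("raw matrix and column metadata are inconsistent")
    hemi = (
        columns["hemisphere"]
        if "hemisphere" in columns
        else pd.Series([""] * len(columns))
    )
    z = np.empty_like(raw)
    for (metric, h), grp in columns.assign(_h=hemi.values).groupby(
        ["metric", "_h"], sort=False
    ):
        sel = grp.index.to_numpy()
        block = raw[:, sel]
        sd = block.std()
        if sd == 0:
            raise ValueError(f"metric '{metric}' has zero variance; cannot z-score")
        z[:, sel] = (block - block.mean()) / sd
    z = z - z.min()
    return MetricStack(X=z, columns=columns.reset_index(drop=True), hemisphere=hemisphere)


def nndsvd_init(X: np.ndarray, k: int) -> np.ndarray:
    """Deterministic non-negative double-SVD initialisation of C.

    Each rank-1 SVD term is split into its positive and negative parts and
    the dominant non-negative part is kept (Boutsidis-Gallopoulos).  Exact
    zeros are floored at a tiny positive value so the multiplicative update
    can move them; columns are returned unit-normalised.
    """
    X = np.asarray(X, dtype=float)
    if np.any(X < 0):
        raise ValueError("X must be non-negative")
    if not 1 <= k <= min(X.shape):
        raise ValueError(f"k must lie in [1, {min(X.shape)}]")
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    if S[k - 1] <= 0:
        raise ValueError(f"X has rank < {k}; cannot initialise {k} components")
    C0 = np.zeros((X.shape[0], k))
    C0[:, 0] = np.sqrt(S[0]) * np.abs(U[:, 0])
    for j in range(1, k):
        u, v = U[:, j], Vt[j]
        up, un = np.maximum(u, 0), np.maximum(-u, 0)
        vp, vn = np.maximum(v, 0), np.maximum(-v, 0)
        n_up, n_un = np.linalg.norm(up), np.linalg.norm(un)
        n_vp, n_vn = np.linalg.norm(vp), np.linalg.norm(vn)
        if n_up * n_vp >= n_un * n_vn:
            C0[:, j] = np.sqrt(S[j] * n_up * n_vp) * up / max(n_up, _EPS)
        else:
            C0[:, j] = np.sqrt(S[j] * n_un * n_vn) * un / max(n_un, _EPS)
    positive_mean = C0[C0 > 0].mean() if np.any(C0 > 0) else 1.0
    C0[C0 == 0] = 1e-6 * positive_mean
    return C0 / np.linalg.norm(C0, axis=0, keepdims=True)


@dataclass
class OpnnmfDecomposition:
    """Fitted decomposition: components C, weights W = C^T X, hard labels."""

    C: np.ndarray
    W: np.ndarray
    k: int
    labels: np.ndarray
    objective_trace: np.ndarray
    converged: bool
    n_iter: int
    ortho_error: float  # ||C^T C - I||_F at exit (reported, not enforced)


def _objective(tr_T, T_C, C):
    CtTC = C.T @ T_C
    CtC = C.T @ C
    return float(tr_T - 2.0 * np.trace(CtTC) + np.sum(CtC * CtTC.T))


def opnnmf_fit(
    X: np.ndarray,
    k: int,
    max_iter: int = 10000,
    tol: float = 1e-5,
) -> OpnnmfDecomposition:
    """Fit orthogonal projective NMF with k components.

    Iteration stops when the relative change of the objective
    ||X - C C^T X||_F^2 drops below tol, or at max_iter.  Components that
    die (all-zero columns) are re-seeded once from the vertex with the
    largest reconstruction residual.

    The raw multiplicative update is not scale-stable (the overall norm of
    C oscillates), so after every update C is rescaled by the global factor
    that minimises the objective; C is returned at that scale, where column
    norms approach 1 as the orthogonality constraint is met (the residual
    ||C^T C - I|| is reported as ortho_error).  W = C^T X.
    """
    X = np.asarray(X, dtype=float)
    if np.any(X < 0):
        raise ValueError("X must be non-negative")
    C = nndsvd_init(X, k)
    T = X @ X.T
    tr_T = float(np.trace(T))
    trace = []
    reseeded = False
    obj_prev = None
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        T_C = T @ C
        denom = C @ (C.T @ T_C)
        C = C * T_C / np.maximum(denom, _EPS)
        if not np.all(np.isfinite(C)):
            raise FloatingPointError(
                f"non-finite values in C at iteration {it}; aborting"
            )
        # re-seed dead components once
        dead = np.where(C.max(axis=0) <= _EPS)[0]
        if dead.size and not reseeded:
            resid = np.linalg.norm(X - C @ (C.T @ X), axis=1)
            for j in dead:
                C[np.argmax(resid), j] = 1.0
            reseeded = True
        # global rescale to the objective-optimal scale:
        # obj(g*C) = tr(T) - 2 g^2 A + g^4 B is minimal at g^2 = A/B
        T_C = T @ C
        CtTC = C.T @ T_C
        A = float(np.trace(CtTC))
        B = float(np.sum((C.T @ C) * CtTC.T))
        if B > 0 and A > 0:
            C = C * (A / B) ** 0.25
            obj = tr_T - A * A / B
        else:
            obj = _objective(tr_T, T_C, C)
        trace.append(obj)
        if obj_prev is not None:
            rel = abs(obj_prev - obj) / max(abs(obj_prev), _EPS)
            if rel < tol:
                converged = True
                break
        obj_prev = obj
    W = C.T @ X
    labels = winner_take_all(C)
    ortho = float(np.linalg.norm(C.T @ C - np.eye(k)))
    return OpnnmfDecomposition(
        C=C,
        W=W,
        k=k,
        labels=labels,
        objective_trace=np.asarray(trace),
        converged=converged,
        n_iter=it,
        ortho_error=ortho,
    )


def winner_take_all(C: np.ndarray) -> np.ndarray:
    """Hard labels 1..k from the largest component weight per vertex.

    Ties break to the lowest component index; all-zero rows get label 0
    (missing) with a warning.
    """
    C = np.asarray(C, dtype=float)
    if C.size == 0:
        raise ValueError("C must be non-empty")
    labels = np.argmax(C, axis=1) + 1
    dead = C.max(axis=1) == 0
    if np.any(dead):
        warnings.warn(f"{int(dead.sum())} vertices have all-zero component rows", stacklevel=2)
        labels[dead] = 0
    return labels


def zscore_weights(W: np.ndarray) -> np.ndarray:
    """z-score W within each component row (for plotting metric trends)."""
    W = np.asarray(W, dtype=float)
    sd = W.std(axis=1, keepdims=True)
    if np.any(sd == 0):
        bad = np.where(sd.ravel() == 0)[0]
        raise ValueError(f"constant weight row(s) {bad.tolist()}; cannot z-score")
    return (W - W.mean(axis=1, keepdims=True)) / sd


def reconstruction_error(X: np.ndarray, C: np.ndarray) -> float:
    """Frobenius norm ||X - C C^T X||_F."""
    X = np.asarray(X, dtype=float)
    C = np.asarray(C, dtype=float)
    return float(np.linalg.norm(X - C @ (C.T @ X)))


def error_gradient(errors_by_k) -> np.ndarray:
    """Consecutive differences of reconstruction error across the k sweep."""
    return np.diff(np.asarray(errors_by_k, dtype=float))


def split_half_stability(C1: np.ndarray, C2: np.ndarray) -> np.ndarray:
    """Per-vertex Pearson correlation between the rows of the two splits'
    vertex-by-vertex cosine-similarity matrices S = C_hat C_hat^T, where
    C_hat is the row-normalised component matrix.

    Invariant to column permutation of either C (S is unchanged).  Returns
    one correlation per vertex; vertices with a constant similarity row in
    either split are NaN.
    """
    def sim(C):
        C = np.asarray(C, dtype=float)
        norms = np.linalg.norm(C, axis=1, keepdims=True)
        Ch = np.divide(C, norms, out=np.zeros_like(C), where=norms > 0)
        return Ch @ Ch.T

    S1, S2 = sim(C1), sim(C2)
    if S1.shape != S2.shape:
        raise ValueError("component matrices must share the vertex count")
    A = S1 - S1.mean(axis=1, keepdims=True)
    B = S2 - S2.mean(axis=1, keepdims=True)
    num = np.sum(A * B, axis=1)
    den = np.sqrt(np.sum(A**2, axis=1) * np.sum(B**2, axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = num / den
    r[den == 0] = np.nan
    return r


@dataclass
class StabilityReport:
    """Per-k split-half stability and reconstruction-error summary."""

    table: pd.DataFrame  # k, stability_mean, stability_sd, recon_error, error_gradient
    n_splits: int
    per_vertex: dict = field(default_factory=dict)  # k -> (splits*V,) correlations


def stability_analysis(
    stack: MetricStack,
    k_range=range(2, 13),
    n_splits: int = 6,
    seed: int = 0,
    max_iter: int = 10000,
    tol: float = 1e-5,
) -> StabilityReport:
    """Split-half stability of the parcellation across a sweep of k.

    Subjects (the split unit: all metrics and hemispheres of a subject
    travel together) are repeatedly halved; OPNNMF is fitted to each half
    and the per-vertex correlation of the two halves' cosine-similarity
    structure is pooled over vertices and splits.  Reconstruction error on
    the full stack and its gradient across k are reported alongside.
    """
    subjects = list(pd.unique(stack.columns["subject"]))
    if len(subjects) < 4:
        raise ValueError("stability analysis needs at least 4 subjects")
    if len(subjects) % 2 == 1:
        warnings.warn(
            "odd subject count; dropping one subject per split for equal halves",
            stacklevel=2,
        )
    half = len(subjects) // 2
    rng = np.random.default_rng(seed)
    split_plans = []
    for _ in range(n_splits):
        order = rng.permutation(len(subjects))
        split_plans.append(
            ([subjects[i] for i in order[:half]], [subjects[i] for i in order[half : 2 * half]])
        )

    k_list = list(k_range)
    rows = []
    per_vertex = {}
    errors = []
    for k in k_list:
        full = opnnmf_fit(stack.X, k, max_iter=max_iter, tol=tol)
        errors.append(reconstruction_error(stack.X, full.C))
        corrs = []
        for ga, gb in split_plans:
            fa = opnnmf_fit(stack.X[:, stack.subject_columns(ga)], k, max_iter=max_iter, tol=tol)
            fb = opnnmf_fit(stack.X[:, stack.subject_columns(gb)], k, max_iter=max_iter, tol=tol)
            corrs.append(split_half_stability(fa.C, fb.C))
        pooled = np.concatenate(corrs)
        per_vertex[k] = pooled
        rows.append(
            {
                "k": k,
                "stability_mean": float(np.nanmean(pooled)),
                "stability_sd": float(np.nanstd(pooled)),
                "recon_error": errors[-1],
            }
        )
    table = pd.DataFrame(rows)
    grad = error_gradient(table["recon_error"].to_numpy())
    table["error_gradient"] = np.concatenate([[np.nan], grad])
    return StabilityReport(table=table, n_splits=n_splits, per_vertex=per_vertex)
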