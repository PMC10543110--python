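"""Laplace coordinate fields per hippocampal axis and their gradients.

For each axis the potential psi solves the discrete Laplace equation on the
masked voxels with Dirichlet conditions psi=0 on the source set, psi=1 on
the sink set, and no-flux (reflecting) conditions on the remaining mask
boundary.  Unit-normalised gradients of the three potentials give the
per-voxel axis vector fields G_AP, G_PD, G_IO.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import spsolve

from .domain import AXES, VoxelDomain

__all__ = [
    "LaplaceConvergenceError",
    "LaplaceCoordinates",
    "AxisVectorFields",
    "solve_laplace",
    "solve_all_axes",
    "gradient_fields",
]

_OFFSETS = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]


class LaplaceConvergenceError(RuntimeError):
    """Raised when the solver cannot reach the requested residual."""


@dataclass
class LaplaceCoordinates:
    """Solved potentials (NaN outside the mask), each in [0, 1]."""

    psi_AP: np.ndarray
    psi_PD: np.ndarray
    psi_IO: np.ndarray
    domain: VoxelDomain

    def psi(self, axis: str) -> np.ndarray:
        return getattr(self, f"psi_{axis}")


@dataclass
class AxisVectorFields:
    """Unit axis vectors per voxel (shape mask+(3,)); invalid voxels (zero
    gradient) are flagged, never silently zero-normalised."""

    G_AP: np.ndarray
    G_PD: np.ndarray
    G_IO: np.ndarray
    valid: np.ndarray  # true where all three axis vectors are defined

    def G(self, axis: str) -> np.ndarray:
        return getattr(self, f"G_{axis}")


def _laplacian_residual(psi, mask, free):
    """Max |discrete Laplacian| over non-Dirichlet mask voxels, where the
    Laplacian at a voxel uses only neighbours inside the mask (reflecting
    boundary)."""
    resid = np.zeros(mask.shape)
    deg = np.zeros(mask.shape)
    for off in _OFFSETS:
        nb = np.roll(psi, shift=[-o for o in off], axis=(0, 1, 2))
        nb_in = np.roll(mask, shift=[-o for o in off], axis=(0, 1, 2))
        # roll wraps; forbid wrap-around contributions
        edge = _wrap_edge(mask.shape, off)
        use = nb_in & ~edge & mask
        resid[use] += nb[use]
        deg[use] += 1
    resid = resid - deg * np.where(mask, psi, 0.0)
    return float(np.abs(resid[free]).max()) if free.any() else 0.0


def _wrap_edge(shape, off):
    """Boolean array marking voxels whose neighbour at -off wraps around."""
    edge = np.zeros(shape, dtype=bool)
    for ax, o in enumerate(off):
        if o == 1:
            sl = [slice(None)] * 3
            sl[ax] = slice(shape[ax] - 1, shape[ax])
            edge[tuple(sl)] = True
        elif o == -1:
            sl = [slice(None)] * 3
            sl[ax] = slice(0, 1)
            edge[tuple(sl)] = True
    return edge


def solve_laplace(
    domain: VoxelDomain,
    axis: str,
    tol: float = 1e-6,
    max_iter: int = 20000,
) -> np.ndarray:
    """Solve the per-axis Dirichlet problem; returns psi (NaN outside mask).

    Discretisation is the 6-connected finite-difference Laplacian; the
    sparse system over the free voxels is solved directly, then the residual
    is verified against tol.  max_iter bounds the iterative fallback used
    for very large systems.
    """
    if axis not in AXES:
        raise ValueError(f"axis must be one of {AXES}")
    if not tol > 0:
        raise ValueError("tol must be positive")
    mask = domain.mask
    source, sink = domain.boundary_labels[axis]
    free = mask & ~source & ~sink

    # index map over free voxels
    idx = -np.ones(mask.shape, dtype=np.int64)
    free_coords = np.argwhere(free)
    idx[free] = np.arange(len(free_coords))

    fixed_val = np.zeros(mask.shape)
    fixed_val[sink] = 1.0

    n = len(free_coords)
    rows, cols, vals = [], [], []
    rhs = np.zeros(n)
    deg = np.zeros(n)
    for off in _OFFSETS:
        nb = free_coords + np.array(off)
        inside = np.all((nb >= 0) & (nb < mask.shape), axis=1)
        nb_clip = np.clip(nb, 0, np.array(mask.shape) - 1)
        nb_t = tuple(nb_clip.T)
        in_mask = inside & mask[nb_t]
        deg[in_mask] += 1
        nb_free = in_mask & (idx[nb_t] >= 0)
        rows.append(np.nonzero(nb_free)[0])
        cols.append(idx[nb_t][nb_free])
        vals.append(-np.ones(nb_free.sum()))
        nb_fixed = in_mask & (idx[nb_t] < 0)
        np.add.at(rhs, np.nonzero(nb_fixed)[0], fixed_val[nb_t][nb_fixed])

    rows.append(np.arange(n))
    cols.append(np.arange(n))
    vals.append(deg)
    A = sparse.csr_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n, n),
    )

    if n > 0:
        if n <= 200_000:
            x = spsolve(A.tocsc(), rhs)
        else:
            x, info = sparse.linalg.cg(A, rhs, rtol=tol * 1e-3, maxiter=max_iter)
            if info != 0:
                raise LaplaceConvergenceError(
                    f"CG did not converge within {max_iter} iterations"
                )
    else:
        x = np.zeros(0)

    psi = np.full(mask.shape, np.nan)
    psi[source] = 0.0
    psi[sink] = 1.0
    psi[free] = x

    resid = _laplacian_residual(np.where(mask, psi, 0.0), mask, free)
    if resid > tol:
        raise LaplaceConvergenceError(
            f"solver residual {resid:.3e} exceeds tol {tol:.1e}"
        )
    # maximum principle (guards discretisation errors)
    vals_in = psi[mask]
    if np.nanmin(vals_in) < -1e-12 or np.nanmax(vals_in) > 1 + 1e-12:
        raise LaplaceConvergenceError("solution violates the maximum principle")
    return psi


def solve_all_axes(domain: VoxelDomain, tol: float = 1e-6, max_iter: int = 20000):
    return LaplaceCoordinates(
        psi_AP=solve_laplace(domain, "AP", tol, max_iter),
        psi_PD=solve_laplace(domain, "PD", tol, max_iter),
        psi_IO=solve_laplace(domain, "IO", tol, max_iter),
        domain=domain,
    )


def _masked_gradient(psi: np.ndarray, mask: np.ndarray, voxel_size) -> np.ndarray:
    """Per-axis derivative with central differences where both neighbours
    are in the mask, one-sided at mask edges, in physical (mm) units."""
    grad = np.zeros(mask.shape + (3,))
    psi0 = np.where(mask, psi, 0.0)
    for ax in range(3):
        h = voxel_size[ax]
        fwd_ok = np.zeros_like(mask)
        bwd_ok = np.zeros_like(mask)
        sl_f = [slice(None)] * 3
        sl_f[ax] = slice(0, mask.shape[ax] - 1)
        sl_fn = [slice(None)] * 3
        sl_fn[ax] = slice(1, mask.shape[ax])
        fwd_ok[tuple(sl_f)] = mask[tuple(sl_fn)]
        bwd_ok[tuple(sl_fn)] = mask[tuple(sl_f)]
        fwd_ok &= mask
        bwd_ok &= mask
        nxt = np.roll(psi0, -1, axis=ax)
        prv = np.roll(psi0, 1, axis=ax)
        g = np.zeros(mask.shape)
        central = fwd_ok & bwd_ok
        g[central] = (nxt[central] - prv[central]) / (2 * h)
        fonly = fwd_ok & ~bwd_ok
        g[fonly] = (nxt[fonly] - psi0[fonly]) / h
        bonly = bwd_ok & ~fwd_ok
        g[bonly] = (psi0[bonly] - prv[bonly]) / h
        grad[..., ax] = g
    return grad


def gradient_fields(
    coords: LaplaceCoordinates, voxel_size_mm=None
) -> AxisVectorFields:
    """Unit gradient vector fields of the three Laplace potentials.

    Gradients use central differences (one-sided at mask edges) divided by
    the voxel size, then unit normalisation; voxels with gradient magnitude
    below 1e-12 on any axis are flagged invalid.
    """
    domain = coords.domain
    mask = domain.mask
    vs = voxel_size_mm or domain.voxel_size_mm
    fields = {}
    valid = mask.copy()
    for axis in AXES:
        g = _masked_gradient(coords.psi(axis), mask, vs)
        norm = np.linalg.norm(g, axis=-1)
        ok = mask & (norm > 1e-12)
        unit = np.zeros_like(g)
        unit[ok] = g[ok] / norm[ok, None]
        unit[~ok] = np.nan
        fields[axis] = unit
        valid &= ok
    if not valid.any():
        warnings.warn("all voxels have degenerate gradients", stacklevel=2)
    return AxisVectorFields(
        G_AP=fields["AP"], G_PD=fields["PD"], G_IO=fields["IO"], valid=valid
    )
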