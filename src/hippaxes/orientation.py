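"""Cosine similarity between the NODDI orientation and hippocampal axes.

The per-voxel similarity is |a . u| / (|a| |u|): 1 when the primary
diffusion direction is parallel to an axis, 0 when perpendicular.  The
absolute value reflects the antipodal equivalence of diffusion orientations
(mu and -mu describe the same physical orientation).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .laplace import AxisVectorFields

__all__ = ["CosineSimilarityMaps", "cosine_similarity", "similarity_volumes"]


@dataclass
class CosineSimilarityMaps:
    """Per-voxel similarities to the AP, PD and IO axes, each in [0, 1];
    voxels invalid in either input are NaN and excluded from `valid`."""

    cs_AP: np.ndarray
    cs_PD: np.ndarray
    cs_IO: np.ndarray
    valid: np.ndarray

    def cs(self, axis: str) -> np.ndarray:
        return getattr(self, f"cs_{axis}")


def cosine_similarity(a, u) -> float:
    """|a . u| / (|a| |u|) for two non-zero 3-vectors; scale-invariant and
    symmetric, in [0, 1]."""
    a = np.asarray(a, dtype=float).ravel()
    u = np.asarray(u, dtype=float).ravel()
    if a.shape != (3,) or u.shape != (3,):
        raise ValueError("inputs must be 3-vectors")
    na, nu = np.linalg.norm(a), np.linalg.norm(u)
    if na == 0 or nu == 0:
        raise ValueError("cosine similarity is undefined for zero vectors")
    return float(min(1.0, abs(a @ u) / (na * nu)))


def similarity_volumes(
    mu_field: np.ndarray, axes: AxisVectorFields, mu_valid=None
) -> CosineSimilarityMaps:
    """Voxel-wise |cos| maps between a unit orientation field (shape
    grid+(3,)) and each axis vector field on the same grid."""
    mu_field = np.asarray(mu_field, dtype=float)
    if mu_field.shape != axes.G_AP.shape:
        raise ValueError("mu_field and axis fields must share a grid")
    norms = np.linalg.norm(mu_field, axis=-1)
    finite = np.all(np.isfinite(mu_field), axis=-1) & (norms > 1e-12)
    if mu_valid is not None:
        finite &= np.asarray(mu_valid, dtype=bool)
    valid = finite & axes.valid
    unit = np.zeros_like(mu_field)
    unit[valid] = mu_field[valid] / norms[valid, None]

    out = {}
    for axis in ("AP", "PD", "IO"):
        g = axes.G(axis)
        cs = np.full(valid.shape, np.nan)
        cs[valid] = np.clip(
            np.abs(np.einsum("...i,...i->...", unit, np.nan_to_num(g)))[valid],
            0.0,
            1.0,
        )
        out[axis] = cs
    return CosineSimilarityMaps(
        cs_AP=out["AP"], cs_PD=out["PD"], cs_IO=out["IO"], valid=valid
    )
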