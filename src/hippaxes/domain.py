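"""Voxelised hippocampus-like domains with labelled axis boundaries.

A VoxelDomain is the discrete geometry on which the per-axis Laplace
problems are posed: a connected boolean mask plus, for each intrinsic axis
(AP anterior-posterior, PD proximal-distal, IO inner-outer), a disjoint
pair of boundary voxel sets acting as the Dirichlet source (potential 0)
and sink (potential 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = ["VoxelDomain", "AXES"]

AXES = ("AP", "PD", "IO")


@dataclass
class VoxelDomain:
    """Connected voxel mask with per-axis (source, sink) boundary labels.

    boundary_labels maps axis name -> (source, sink), each a boolean array
    of mask shape selecting voxels inside the mask.
    """

    mask: np.ndarray
    voxel_size_mm: tuple
    boundary_labels: dict

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 3:
            raise ValueError("mask must be 3-D")
        vs = tuple(float(v) for v in self.voxel_size_mm)
        if len(vs) != 3 or any(v <= 0 for v in vs):
            raise ValueError("voxel_size_mm must be a positive triple")
        self.voxel_size_mm = vs
        _, n_comp = ndimage.label(self.mask)
        if n_comp != 1:
            raise ValueError(f"mask must be a single connected component (got {n_comp})")
        for axis in AXES:
            if axis not in self.boundary_labels:
                raise ValueError(f"missing boundary labels for axis {axis}")
            source, sink = self.boundary_labels[axis]
            source = np.asarray(source, dtype=bool)
            sink = np.asarray(sink, dtype=bool)
            if source.shape != self.mask.shape or sink.shape != self.mask.shape:
                raise ValueError("boundary label arrays must match mask shape")
            if not source.any() or not sink.any():
                raise ValueError(f"{axis}: source and sink must be non-empty")
            if np.any(source & sink):
                raise ValueError(f"{axis}: source and sink overlap")
            if np.any(source & ~self.mask) or np.any(sink & ~self.mask):
                raise ValueError(f"{axis}: boundary voxels must lie inside the mask")
            self.boundary_labels[axis] = (source, sink)

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())

    def voxel_centers_mm(self) -> np.ndarray:
        """Physical coordinates (mm) of masked voxel centres; voxel index i
        maps to i * voxel_size (0-based convention)."""
        idx = np.argwhere(self.mask).astype(float)
        return idx * np.asarray(self.voxel_size_mm)
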