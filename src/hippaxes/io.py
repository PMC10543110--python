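"""File I/O: NIfTI volumes, GIFTI surfaces/metrics, CSV tables.

Thin wrappers around nibabel with the package's coordinate convention
(voxel index i at physical position i * voxel_size, RAS-aligned diagonal
affine).
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .surface import HippocampalSurface, UnfoldedMetricMap

__all__ = [
    "save_nifti",
    "load_nifti",
    "save_surface_gifti",
    "save_metric_gifti",
    "save_map_csv",
    "load_map_csv",
]


def save_nifti(path, data: np.ndarray, voxel_size_mm=(1.0, 1.0, 1.0)) -> None:
    affine = np.diag(list(voxel_size_mm) + [1.0])
    nib.save(nib.Nifti1Image(np.asarray(data, dtype=np.float64), affine), str(path))


def load_nifti(path):
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata())
    voxel_size = tuple(float(z) for z in img.header.get_zooms()[:3])
    return data, voxel_size


def save_surface_gifti(path, surface: HippocampalSurface, sheet: str = "mid") -> None:
    """One sheet (inner/mid/outer) as a GIFTI surface file."""
    verts = getattr(surface, f"vertices_{sheet}").astype(np.float32)
    img = nib.gifti.GiftiImage(
        darrays=[
            nib.gifti.GiftiDataArray(verts, intent="NIFTI_INTENT_POINTSET"),
            nib.gifti.GiftiDataArray(
                surface.triangles.astype(np.int32), intent="NIFTI_INTENT_TRIANGLE"
            ),
        ]
    )
    nib.save(img, str(path))


def save_metric_gifti(path, metric_map: UnfoldedMetricMap) -> None:
    img = nib.gifti.GiftiImage(
        darrays=[
            nib.gifti.GiftiDataArray(
                metric_map.values.astype(np.float32), intent="NIFTI_INTENT_NONE"
            )
        ]
    )
    nib.save(img, str(path))


def save_map_csv(path, metric_map: UnfoldedMetricMap) -> None:
    pd.DataFrame(
        {"vertex": np.arange(metric_map.values.size), "value": metric_map.values}
    ).to_csv(path, index=False)


def load_map_csv(path, grid_shape, **kw) -> UnfoldedMetricMap:
    df = pd.read_csv(path)
    values = df.sort_values("vertex")["value"].to_numpy()
    return UnfoldedMetricMap(values=values, grid_shape=grid_shape, **kw)
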