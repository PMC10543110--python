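"""Diffusion acquisition schemes (b-values and gradient directions).

Schemes are stored as flat arrays matching the FSL bval/bvec convention:
one b-value (s/mm^2) and one unit direction per acquired volume.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["AcquisitionScheme", "fibonacci_directions", "multishell_scheme"]

#: b-values at or below this are treated as b=0 (no diffusion weighting)
B0_THRESHOLD = 10.0


@dataclass(frozen=True)
class AcquisitionScheme:
    """Multi-shell diffusion acquisition: b-values paired with unit directions.

    Parameters
    ----------
    bvals
        Array of shape (n,), b-values in s/mm^2, all >= 0.
    bvecs
        Array of shape (n, 3); rows with b > 0 must be unit vectors.
        Directions for b=0 entries are ignored.
    """

    bvals: np.ndarray
    bvecs: np.ndarray

    def __post_init__(self) -> None:
        bvals = np.asarray(self.bvals, dtype=float).ravel()
        bvecs = np.asarray(self.bvecs, dtype=float)
        if bvecs.ndim != 2 or bvecs.shape[1] != 3:
            raise ValueError("bvecs must have shape (n, 3)")
        if len(bvals) != len(bvecs):
            raise ValueError("bvals and bvecs must have the same length")
        if np.any(bvals < 0):
            raise ValueError("b-values must be non-negative")
        dw = bvals > B0_THRESHOLD
        if not np.any(~dw):
            raise ValueError("scheme must contain at least one b=0 volume")
        norms = np.linalg.norm(bvecs[dw], axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-3):
            raise ValueError("non-zero-b directions must be unit vectors")
        object.__setattr__(self, "bvals", bvals)
        object.__setattr__(self, "bvecs", bvecs)

    @property
    def n_volumes(self) -> int:
        return len(self.bvals)

    @property
    def b0_mask(self) -> np.ndarray:
        return self.bvals <= B0_THRESHOLD

    @property
    def shells(self) -> np.ndarray:
        """Distinct non-zero b-values, ascending."""
        return np.unique(self.bvals[~self.b0_mask])

    def subset(self, mask: np.ndarray) -> "AcquisitionScheme":
        return AcquisitionScheme(self.bvals[mask], self.bvecs[mask])

    def shell_subset(self, bvalues) -> "AcquisitionScheme":
        """Scheme restricted to b=0 plus the given shells."""
        keep = self.b0_mask.copy()
        for b in np.atleast_1d(bvalues):
            keep |= np.isclose(self.bvals, b)
        return self.subset(keep)

    # -- FSL-style text I/O ------------------------------------------------
    def save(self, bval_path, bvec_path) -> None:
        np.savetxt(bval_path, self.bvals[None, :], fmt="%.1f")
        np.savetxt(bvec_path, self.bvecs.T, fmt="%.8f")

    @classmethod
    def load(cls, bval_path, bvec_path) -> "AcquisitionScheme":
        bvals = np.loadtxt(bval_path).ravel()
        bvecs = np.loadtxt(bvec_path)
        if bvecs.shape[0] == 3 and bvecs.shape != (3, 3):
            bvecs = bvecs.T
        return cls(bvals, bvecs)


def fibonacci_directions(n: int) -> np.ndarray:
    """n roughly uniformly distributed unit vectors (Fibonacci sphere).

    Deterministic; antipodally asymmetric, which is fine for diffusion
    encoding where g and -g are equivalent.
    """
    i = np.arange(n, dtype=float) + 0.5
    phi = np.pi * (1.0 + np.sqrt(5.0)) * i
    z = 1.0 - 2.0 * i / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def multishell_scheme(
    shells=(1000.0, 2000.0, 3000.0),
    n_dirs: int = 90,
    n_b0: int = 18,
) -> AcquisitionScheme:
    """HCP-like multi-shell scheme: n_b0 b=0 volumes plus n_dirs directions
    per shell (same direction set on every shell)."""
    dirs = fibonacci_directions(n_dirs)
    bvals = [np.zeros(n_b0)]
    bvecs = [np.zeros((n_b0, 3))]
    for b in shells:
        bvals.append(np.full(n_dirs, float(b)))
        bvecs.append(dirs)
    return AcquisitionScheme(np.concatenate(bvals), np.vstack(bvecs))
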