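"""Synthetic inputs for every pipeline stage, with known ground truth.

This module generates the study's inputs at desk scale: voxel domains with
labelled axis boundaries, multi-shell diffusion signals drawn from the
Watson-NODDI forward model, unfolded multi-subject metric stacks with
planted parcels, correlated smooth map pairs for the spin test, and
subfield-averaged metric tables for the classifier.  Every generator is a
pure function of its arguments and seed.

The default unfolded grid is 64 x 32 = 2048 vertices, close to the ~1 mm
spaced real midthickness surfaces (2004 vertices) the generators emulate;
smoothness is imposed by Gaussian filtering of white noise with periodic
wrap, consistent with the torus geometry assumed by the spin test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .domain import VoxelDomain
from .acquisition import AcquisitionScheme
from .noddi import NoddiParameters, kappa_from_odi, noddi_forward
from .surface import SUBFIELDS, HippocampalSurface

__all__ = [
    "GroundTruthVoxelParams",
    "SyntheticUnfoldedDataset",
    "make_voxel_domain",
    "curved_shell_radial_directions",
    "make_ground_truth",
    "simulate_dwi",
    "make_unfolded_dataset",
    "make_correlated_map_pair",
    "make_subfield_table",
    "make_synthetic_surface",
    "make_smooth_volume",
    "DEFAULT_METRICS",
]

#: the metric panel the unfolded-stack generator emulates
DEFAULT_METRICS = (
    "odi",
    "ndi",
    "t1w_t2w",
    "fa",
    "md",
    "gyrification",
    "thickness",
    "curvature",
    "cs_ap",
    "cs_pd",
    "cs_io",
)


# --------------------------------------------------------------------------
# Voxel domains
# --------------------------------------------------------------------------
def make_voxel_domain(
    shape,
    geometry: str = "slab",
    seed: int = 0,
    bend_radius: float = 8.0,
    voxel_size_mm=(1.0, 1.0, 1.0),
) -> VoxelDomain:
    """Connected hippocampus-like mask with labelled axis boundary pairs.

    'slab' fills the whole box: AP runs along axis 0 (source x=0 face, sink
    x=-1 face), PD along axis 1 and IO along axis 2, so the three boundary
    pairs are mutually orthogonal planes.  'curved_shell' bends the slab
    into a half-cylindrical annulus (axis 0 still AP, PD angular, IO
    radial) so the axis fields are non-trivially oriented.  Deterministic
    for a given (shape, geometry, seed).
    """
    shape = tuple(int(s) for s in shape)
    if len(shape) != 3 or any(s < 8 for s in shape):
        raise ValueError(f"each dimension must be >= 8; got {shape}")
    nx, ny, nz = shape

    if geometry == "slab":
        mask = np.ones(shape, dtype=bool)

        def face(axis, first):
            m = np.zeros(shape, dtype=bool)
            sl = [slice(None)] * 3
            sl[axis] = 0 if first else -1
            m[tuple(sl)] = True
            return m

        labels = {
            "AP": (face(0, True), face(0, False)),
            "PD": (face(1, True), face(1, False)),
            "IO": (face(2, True), face(2, False)),
        }
        return VoxelDomain(mask, voxel_size_mm, labels)

    if geometry == "curved_shell":
        y0 = (ny - 1) / 2.0
        z0 = -0.5
        r_in = float(bend_radius)
        r_out = min((ny - 1) / 2.0, (nz - 1) - z0)
        if r_out - r_in < 2.0:
            raise ValueError(
                f"shape {shape} cannot host a shell of bend radius {r_in}; "
                "increase the last two dimensions or lower bend_radius"
            )
        x, y, z = np.meshgrid(
            np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij"
        )
        r = np.hypot(y - y0, z - z0)
        mask = (r >= r_in) & (r <= r_out)
        io_src = mask & (r < r_in + 1.0)
        io_snk = mask & (r > r_out - 1.0)
        ap_src = mask & (x == 0)
        ap_snk = mask & (x == nx - 1)
        pd_src = mask & (z == 0) & (y > y0)
        pd_snk = mask & (z == 0) & (y < y0)
        labels = {"AP": (ap_src, ap_snk), "PD": (pd_src, pd_snk), "IO": (io_src, io_snk)}
        return VoxelDomain(mask, voxel_size_mm, labels)

    raise ValueError(f"unknown geometry {geometry!r}")


def curved_shell_radial_directions(shape) -> np.ndarray:
    """Closed-form unit radial (IO) direction of the curved-shell geometry,
    per voxel (oracle for the Laplace gradient field)."""
    nx, ny, nz = (int(s) for s in shape)
    y0, z0 = (ny - 1) / 2.0, -0.5
    _, y, z = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij")
    r = np.hypot(y - y0, z - z0)
    out = np.zeros(tuple((nx, ny, nz)) + (3,))
    with np.errstate(invalid="ignore"):
        out[..., 1] = (y - y0) / r
        out[..., 2] = (z - z0) / r
    return out


# --------------------------------------------------------------------------
# Ground-truth microstructure and signal simulation
# --------------------------------------------------------------------------
@dataclass
class GroundTruthVoxelParams:
    """Per-voxel NODDI ground truth on a domain (simulation bookkeeping)."""

    domain: VoxelDomain
    f_iso: np.ndarray
    f_ic: np.ndarray
    f_ec: np.ndarray
    kappa: np.ndarray
    mu: np.ndarray  # shape mask + (3,)

    def __post_init__(self):
        m = self.domain.mask
        for name in ("f_iso", "f_ic", "f_ec", "kappa"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != m.shape:
                raise ValueError(f"{name} must match the domain grid")
            setattr(self, name, arr)
        self.mu = np.asarray(self.mu, dtype=float)
        if self.mu.shape != m.shape + (3,):
            raise ValueError("mu must have shape grid + (3,)")
        fr = np.stack([self.f_iso[m], self.f_ic[m], self.f_ec[m]])
        if np.any(fr < -1e-12) or np.any(fr > 1 + 1e-12):
            raise ValueError("fractions must lie in [0, 1]")
        if np.any(np.abs(fr.sum(axis=0) - 1) > 1e-9):
            raise ValueError("fractions must sum to 1 at every masked voxel")
        if np.any(np.abs(np.linalg.norm(self.mu[m], axis=-1) - 1) > 1e-6):
            raise ValueError("mu must be unit-norm at every masked voxel")

    def voxel_params(self, idx) -> NoddiParameters:
        return NoddiParameters(
            f_iso=float(self.f_iso[idx]),
            f_ic=float(self.f_ic[idx]),
            f_ec=float(self.f_ec[idx]),
            kappa=float(self.kappa[idx]),
            mu=self.mu[idx],
        )


def _smooth3d(shape, sigma, rng):
    f = ndimage.gaussian_filter(rng.standard_normal(shape), sigma, mode="nearest")
    sd = f.std()
    return f / sd if sd > 0 else f


def make_ground_truth(
    domain: VoxelDomain,
    seed: int = 0,
    f_iso_range=(0.02, 0.15),
    f_ic_range=(0.3, 0.65),
    odi_range=(0.15, 0.5),
    mu_field: np.ndarray | None = None,
    smoothness_vox: float = 2.0,
) -> GroundTruthVoxelParams:
    """Smooth, plausible grey-matter-like NODDI ground truth on a domain.

    Scalar fields are smooth spatial ramps of Gaussian noise mapped into the
    given ranges.  mu defaults to a smooth random unit field; pass mu_field
    (grid + (3,)) to align orientations with, e.g., Laplace axis vectors.
    """
    rng = np.random.default_rng(seed)
    m = domain.mask
    shape = m.shape

    def ranged(lo, hi):
        f = _smooth3d(shape, smoothness_vox, rng)
        u = 0.5 * (1 + np.tanh(f / 1.5))  # squash into (0,1), keep smoothness
        return lo + (hi - lo) * u

    f_iso = ranged(*f_iso_range)
    f_ic_tissue = ranged(*f_ic_range)  # fraction of the non-CSF tissue
    f_ic = (1 - f_iso) * f_ic_tissue
    f_ec = 1 - f_iso - f_ic
    odi = ranged(*odi_range)
    kappa = np.asarray(kappa_from_odi(np.clip(odi, 1e-3, 1.0)))

    if mu_field is None:
        comps = np.stack([_smooth3d(shape, smoothness_vox, rng) for _ in range(3)], -1)
        comps[..., 2] += 1.5  # bias away from degenerate zero vectors
        mu_field = comps
    norms = np.linalg.norm(mu_field, axis=-1, keepdims=True)
    mu = np.where(norms > 1e-12, mu_field / norms, [0.0, 0.0, 1.0])

    return GroundTruthVoxelParams(
        domain=domain, f_iso=f_iso, f_ic=f_ic, f_ec=f_ec, kappa=kappa, mu=mu
    )


def simulate_dwi(
    params: GroundTruthVoxelParams,
    scheme: AcquisitionScheme,
    snr: float | None = None,
    noise_model: str = "gaussian",
    seed: int = 0,
) -> np.ndarray:
    """4-D diffusion volume from the NODDI forward model, optionally noisy.

    The noiseless signal is the per-voxel forward model with b=0 normalised
    to 1; noise (Gaussian or Rician) is added with scale mean(b0)/snr = 1/snr.
    """
    if snr is not None and snr <= 0:
        raise ValueError("snr must be positive")
    if noise_model not in ("gaussian", "rician"):
        raise ValueError("noise_model must be 'gaussian' or 'rician'")
    mask = params.domain.mask
    vol = np.zeros(mask.shape + (scheme.n_volumes,))
    for idx in zip(*np.nonzero(mask)):
        vol[idx] = noddi_forward(params.voxel_params(idx), scheme)
    if snr is not None:
        rng = np.random.default_rng(seed)
        sigma = 1.0 / snr
        if noise_model == "gaussian":
            vol[mask] += rng.normal(0.0, sigma, vol[mask].shape)
        else:
            n1 = rng.normal(0.0, sigma, vol[mask].shape)
            n2 = rng.normal(0.0, sigma, vol[mask].shape)
            vol[mask] = np.sqrt((vol[mask] + n1) ** 2 + n2**2)
    return vol


# --------------------------------------------------------------------------
# Unfolded-space generators
# --------------------------------------------------------------------------
def _smooth_torus_field(grid_shape, sigma_px, rng) -> np.ndarray:
    """Standardised Gaussian-filtered white noise with periodic wrap."""
    f = ndimage.gaussian_filter(rng.standard_normal(grid_shape), sigma_px, mode="wrap")
    f -= f.mean()
    sd = f.std()
    return f / sd if sd > 0 else f


def _torus_voronoi_parcels(grid_shape, k, rng) -> np.ndarray:
    """k contiguous parcels from Voronoi seeds under torus distance; seeds
    are redrawn (deterministically) until every parcel is non-empty."""
    rows, cols = grid_shape
    rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    for _ in range(100):
        sr = rng.integers(rows, size=k)
        sc = rng.integers(cols, size=k)
        dr = np.abs(rr[..., None] - sr)
        dr = np.minimum(dr, rows - dr)
        dc = np.abs(cc[..., None] - sc)
        dc = np.minimum(dc, cols - dc)
        labels = np.argmin(dr**2 + dc**2, axis=-1)
        if len(np.unique(labels)) == k:
            return labels.ravel()
    raise RuntimeError("could not place non-empty Voronoi parcels")


@dataclass
class SyntheticUnfoldedDataset:
    """Multi-subject unfolded metric maps with planted parcel structure."""

    grid_shape: tuple
    n_subjects: int
    metric_names: tuple
    maps: np.ndarray  # (n_subjects, n_metrics, V)
    true_parcels: np.ndarray  # (V,) integer labels 0..true_rank-1
    true_rank: int

    def __post_init__(self):
        if not np.all(np.isfinite(self.maps)):
            raise ValueError("maps must be finite")
        if len(np.unique(self.true_parcels)) != self.true_rank:
            raise ValueError("distinct parcel labels must equal true_rank")

    def raw_matrix(self) -> tuple:
        """(V x n_subjects*n_metrics) matrix plus column metadata, the raw
        (pre-normalisation) input to OPNNMF."""
        s, m, v = self.maps.shape
        X = self.maps.reshape(s * m, v).T
        cols = pd.DataFrame(
            {
                "subject": np.repeat([f"sub-{i:03d}" for i in range(s)], m),
                "metric": list(self.metric_names) * s,
                "hemisphere": "L",
            }
        )
        return X, cols


def make_unfolded_dataset(
    grid_shape=(64, 32),
    n_subjects: int = 20,
    true_rank: int = 4,
    effect_size: float = 3.0,
    smoothness_mm: float = 2.0,
    seed: int = 0,
    metric_names=DEFAULT_METRICS,
    noise_sd: float = 1.0,
) -> SyntheticUnfoldedDataset:
    """Unfolded metric stack with planted parcels of known rank.

    maps[s, m] = loading[parcel(v), s, m] + smooth torus noise, with
    non-negative loadings scaled by effect_size (effect_size=0 gives pure
    smooth noise; the planted labels are still returned).  Vertex spacing
    is ~1 mm, so smoothness_mm doubles as the filter sigma in pixels.
    """
    grid_shape = tuple(int(g) for g in grid_shape)
    metric_names = tuple(metric_names)
    v = int(np.prod(grid_shape))
    n_metrics = len(metric_names)
    if true_rank > min(v, n_subjects * n_metrics):
        raise ValueError("true_rank exceeds the feasible rank of the stack")
    rng = np.random.default_rng(seed)
    parcels = _torus_voronoi_parcels(grid_shape, true_rank, rng)
    loadings = effect_size * rng.uniform(0.5, 1.5, size=(true_rank, n_subjects, n_metrics))
    maps = np.empty((n_subjects, n_metrics, v))
    for s in range(n_subjects):
        for m in range(n_metrics):
            noise = _smooth_torus_field(grid_shape, smoothness_mm, rng).ravel()
            maps[s, m] = loadings[parcels, s, m] + noise_sd * noise
    return SyntheticUnfoldedDataset(
        grid_shape=grid_shape,
        n_subjects=n_subjects,
        metric_names=metric_names,
        maps=maps,
        true_parcels=parcels,
        true_rank=true_rank,
    )


def make_correlated_map_pair(
    grid_shape=(64, 32),
    rho_target: float = 0.0,
    smoothness_mm: float = 2.0,
    seed: int = 0,
) -> tuple:
    """Two smooth torus maps whose population Spearman correlation is
    rho_target, built by mixing a shared latent field into one of two
    independent smooth Gaussian fields.

    For jointly Gaussian fields Spearman rho_s relates to the Pearson
    correlation by rho_s = (6/pi) arcsin(rho_p / 2); the mixing coefficient
    uses the inverse map so the *rank* correlation hits the target.
    rho_target=0 returns maps from independent latent fields.
    """
    if not -1 < rho_target < 1:
        raise ValueError("|rho_target| must be < 1")
    rng = np.random.default_rng(seed)
    z1 = _smooth_torus_field(grid_shape, smoothness_mm, rng)
    z2 = _smooth_torus_field(grid_shape, smoothness_mm, rng)
    rho_p = 2.0 * np.sin(np.pi * rho_target / 6.0)
    map_a = z1
    map_b = rho_p * z1 + np.sqrt(1.0 - rho_p**2) * z2
    return map_a.ravel(), map_b.ravel()


# --------------------------------------------------------------------------
# Subfield metric tables
# --------------------------------------------------------------------------
_DEFAULT_CLASS_MEANS = {
    # (ODI, NDI, T1w/T2w): grey-matter-plausible subfield profiles
    "Sub": (0.30, 0.52, 1.55),
    "CA1": (0.45, 0.35, 1.30),
    "CA2": (0.38, 0.44, 1.42),
    "CA3": (0.33, 0.47, 1.48),
    "DG/CA4": (0.30, 0.40, 1.38),
}
_DEFAULT_CLASS_COV = np.diag([0.04**2, 0.04**2, 0.06**2])


def make_subfield_table(
    n_subjects: int,
    class_means=None,
    class_cov=None,
    seed: int = 0,
    hemispheres=("L", "R"),
) -> pd.DataFrame:
    """Subject x hemisphere x subfield table of (ODI, NDI, T1w/T2w) draws.

    One row per subject-hemisphere-subfield, Gaussian around the class
    mean with shared covariance.  A zero covariance returns exact class
    means; a non-positive-semidefinite covariance is rejected.
    """
    means = dict(_DEFAULT_CLASS_MEANS)
    if class_means is not None:
        means.update(class_means)
    missing = [s for s in SUBFIELDS if s not in means]
    if missing:
        raise ValueError(f"class_means missing subfields {missing}")
    cov = np.asarray(
        _DEFAULT_CLASS_COV if class_cov is None else class_cov, dtype=float
    )
    if cov.shape != (3, 3):
        raise ValueError("class_cov must be 3x3")
    eigval, eigvec = np.linalg.eigh((cov + cov.T) / 2)
    if np.any(eigval < -1e-10):
        raise ValueError("class_cov must be positive semidefinite")
    A = eigvec @ np.diag(np.sqrt(np.clip(eigval, 0, None)))

    rng = np.random.default_rng(seed)
    rows = []
    for s in range(n_subjects):
        for h in hemispheres:
            for sf in SUBFIELDS:
                draw = np.asarray(means[sf], dtype=float) + A @ rng.standard_normal(3)
                rows.append(
                    {
                        "subject": f"sub-{s:03d}",
                        "hemisphere": h,
                        "subfield": sf,
                        "odi": draw[0],
                        "ndi": draw[1],
                        "t1w_t2w": draw[2],
                    }
                )
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# Synthetic surfaces and volumes
# --------------------------------------------------------------------------
def make_synthetic_surface(
    domain_shape,
    grid_shape=(64, 32),
    thickness_base: float | None = None,
    thickness_gradient: float = 0.0,
    voxel_size_mm=(1.0, 1.0, 1.0),
    margin: float = 1.0,
) -> HippocampalSurface:
    """Flat midthickness surface embedded in a slab volume.

    Unfolded rows run along AP (axis 0), columns along PD (axis 1) and the
    ribbon spans IO (axis 2) about the slab's mid-plane.  Subfield labels
    are five contiguous PD bands (Sub .. DG/CA4).  thickness_gradient
    linearly scales thickness across columns (for testing thickness-aware
    down-weighting).
    """
    nx, ny, nz = (int(s) for s in domain_shape)
    rows, cols = (int(g) for g in grid_shape)
    vs = np.asarray(voxel_size_mm, dtype=float)
    xs = np.linspace(margin, (nx - 1) * vs[0] - margin, rows)
    ys = np.linspace(margin, (ny - 1) * vs[1] - margin, cols)
    z_mid = (nz - 1) * vs[2] / 2.0
    if thickness_base is None:
        thickness_base = 0.6 * (nz - 1) * vs[2]

    xg, yg = np.meshgrid(xs, ys, indexing="ij")
    col_frac = np.tile(np.linspace(0, 1, cols), (rows, 1))
    thickness = thickness_base * (1.0 + thickness_gradient * (col_frac - 0.5))
    thickness = np.clip(thickness, 0.2, (nz - 1) * vs[2] - 0.2)

    mid = np.column_stack([xg.ravel(), yg.ravel(), np.full(rows * cols, z_mid)])
    half = (thickness / 2.0).ravel()
    inner = mid.copy()
    inner[:, 2] -= half
    outer = mid.copy()
    outer[:, 2] += half

    tris = []
    for r in range(rows - 1):
        for c in range(cols - 1):
            v00 = r * cols + c
            tris.append([v00, v00 + 1, v00 + cols])
            tris.append([v00 + 1, v00 + cols + 1, v00 + cols])
    unfolded = np.column_stack(
        [np.repeat(np.arange(rows), cols), np.tile(np.arange(cols), rows)]
    ).astype(float)

    band = np.array_split(np.arange(cols), len(SUBFIELDS))
    col_label = np.empty(cols, dtype=object)
    for lbl, idxs in zip(SUBFIELDS, band):
        col_label[idxs] = lbl
    labels = np.tile(col_label, rows)

    return HippocampalSurface(
        vertices_inner=inner,
        vertices_mid=mid,
        vertices_outer=outer,
        triangles=np.asarray(tris, dtype=int),
        unfolded_coords=unfolded,
        thickness_mm=thickness.ravel(),
        subfield_label=labels,
        grid_shape=(rows, cols),
    )


def make_smooth_volume(
    shape, mean: float = 1.4, sd: float = 0.15, smoothness_vox: float = 2.0, seed: int = 0
) -> np.ndarray:
    """Smooth scalar volume (e.g. a T1w/T2w-like myelin proxy map)."""
    rng = np.random.default_rng(seed)
    return mean + sd * _smooth3d(tuple(int(s) for s in shape), smoothness_vox, rng)
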