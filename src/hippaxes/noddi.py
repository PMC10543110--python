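"""Watson-NODDI forward model and per-voxel fitting, plus DTI.

The three-compartment model describes the normalised diffusion signal as

    E = f_iso * E_iso + f_ec * E_ec + f_ic * E_ic,

where the intra-cellular compartment is a set of "sticks" (diffusion only
along the neurite axis, axial diffusivity d_par), the extra-cellular
compartment is a cylindrically symmetric Gaussian ("zeppelin") whose radial
diffusivity follows a tortuosity rule, and the CSF compartment is free
isotropic diffusion (d_iso).  Stick and zeppelin orientations are dispersed
by a Watson distribution with mean orientation mu and concentration kappa;
dispersion is summarised by ODI = (2/pi) * arctan(1/kappa).

Diffusivities are fixed at grey-matter-appropriate values: the axial
diffusivity d_par = 1.1e-3 mm^2/s (grey-matter optimised, rather than the
white-matter 1.7e-3) and d_iso = 3.0e-3 mm^2/s.

Watson spherical means are evaluated with an even-order Legendre series
whose 1-D moments come from fixed-order Gauss-Legendre quadrature; this is
deterministic and accurate to well below 1e-6 for kappa <= ~200 at the
b-values used here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy.optimize import least_squares
from scipy.special import expit, logit

from .acquisition import AcquisitionScheme

__all__ = [
    "D_PAR_GM",
    "D_ISO",
    "NoddiParameters",
    "NoddiFit",
    "TensorFit",
    "odi_from_kappa",
    "kappa_from_odi",
    "noddi_forward",
    "fit_noddi",
    "fit_noddi_volume",
    "fit_dti",
    "watson_mean_sq_cos",
]

#: grey-matter optimised intra/extra-cellular axial diffusivity, mm^2/s
D_PAR_GM = 1.1e-3
#: free-water (CSF) diffusivity, mm^2/s
D_ISO = 3.0e-3

_KAPPA_MIN = 1e-6
_KAPPA_MAX = 1e4


# --------------------------------------------------------------------------
# ODI <-> kappa
# --------------------------------------------------------------------------
def odi_from_kappa(kappa):
    """Orientation dispersion index ODI = (2/pi) * arctan(1/kappa)."""
    kappa = np.asarray(kappa, dtype=float)
    if np.any(kappa <= 0):
        raise ValueError("kappa must be positive")
    return (2.0 / np.pi) * np.arctan(1.0 / kappa)


def kappa_from_odi(odi):
    """Inverse of odi_from_kappa: kappa = 1 / tan(pi * odi / 2)."""
    odi = np.asarray(odi, dtype=float)
    if np.any(odi <= 0) or np.any(odi > 1):
        raise ValueError("odi must lie in (0, 1]")
    return 1.0 / np.tan(np.pi * odi / 2.0)


# --------------------------------------------------------------------------
# Watson spherical means via an even Legendre series
# --------------------------------------------------------------------------
_LMAX = 24  # even orders 0..24
_EVEN_L = np.arange(0, _LMAX + 1, 2)
_GL_T, _GL_W = np.polynomial.legendre.leggauss(128)
# P_l(t) at the quadrature nodes, one row per even order
_P_EVEN = np.polynomial.legendre.legvander(_GL_T, _LMAX)[:, ::2].T


def _watson_moments(kappa: float) -> np.ndarray:
    """Normalised even Legendre moments a_l of the Watson density on [-1, 1]:
    a_l = int exp(kappa t^2) P_l(t) dt / int exp(kappa t^2) dt."""
    # subtract the max exponent for stability at large kappa
    w = _GL_W * np.exp(kappa * (_GL_T**2 - 1.0))
    z = w.sum()
    return (_P_EVEN @ w) / z


@lru_cache(maxsize=256)
def _stick_kernel_coeffs(x: float) -> np.ndarray:
    """c_l = int_{-1}^{1} exp(-x t^2) P_l(t) dt for even l."""
    w = _GL_W * np.exp(-x * _GL_T**2)
    return _P_EVEN @ w


def watson_mean_sq_cos(kappa: float) -> float:
    """tau = E[(n . mu)^2] under Watson(mu, kappa); 1/3 at kappa -> 0,
    -> 1 as kappa -> inf."""
    w = _GL_W * np.exp(kappa * (_GL_T**2 - 1.0))
    return float((w * _GL_T**2).sum() / w.sum())


def _watson_stick_signal(bvals, cos_ang, kappa, d_par):
    """Watson-dispersed stick signal for each (b, g) pair.

    E(g) = sum_l (2l+1)/2 * a_l(kappa) * c_l(b d_par) * P_l(g . mu)
    (Funk-Hecke applied to the axially symmetric Watson ODF and the
    stick kernel exp(-b d_par t^2))."""
    bvals = np.asarray(bvals, dtype=float)
    cos_ang = np.asarray(cos_ang, dtype=float)
    a_l = _watson_moments(kappa)
    out = np.empty_like(cos_ang)
    p_at = np.polynomial.legendre.legvander(cos_ang, _LMAX)[:, ::2]
    for b in np.unique(bvals):
        sel = bvals == b
        c_l = _stick_kernel_coeffs(float(b * d_par))
        coeff = 0.5 * (2 * _EVEN_L + 1) * a_l * c_l
        out[sel] = p_at[sel] @ coeff
    return out


# --------------------------------------------------------------------------
# Parameter containers
# --------------------------------------------------------------------------
@dataclass(frozen=True)
class NoddiParameters:
    """Per-voxel Watson-NODDI parameters.

    f_iso + f_ic + f_ec must sum to 1; f_ic is the neurite density index
    (NDI).  mu carries an antipodal sign ambiguity: mu and -mu are
    equivalent.
    """

    f_iso: float
    f_ic: float
    f_ec: float
    kappa: float
    mu: np.ndarray
    d_par: float = D_PAR_GM
    d_iso: float = D_ISO

    def __post_init__(self):
        fractions = np.array([self.f_iso, self.f_ic, self.f_ec], dtype=float)
        if np.any(fractions < -1e-12) or np.any(fractions > 1 + 1e-12):
            raise ValueError("compartment fractions must lie in [0, 1]")
        if abs(fractions.sum() - 1.0) > 1e-9:
            raise ValueError("f_iso + f_ic + f_ec must sum to 1")
        if not (self.kappa > 0):
            raise ValueError("kappa must be positive")
        mu = np.asarray(self.mu, dtype=float).ravel()
        n = np.linalg.norm(mu)
        if mu.shape != (3,) or n < 1e-12:
            raise ValueError("mu must be a non-zero 3-vector")
        object.__setattr__(self, "mu", mu / n)

    @property
    def odi(self) -> float:
        return float(odi_from_kappa(self.kappa))

    @property
    def ndi(self) -> float:
        return self.f_ic

    @property
    def nu_ic(self) -> float:
        """Intra-cellular fraction of the tissue (non-CSF) compartment."""
        tissue = self.f_ic + self.f_ec
        return self.f_ic / tissue if tissue > 0 else 0.0

    @property
    def d_perp(self) -> float:
        """Tortuosity rule: d_perp = d_par * (1 - nu_ic)."""
        return self.d_par * (1.0 - self.nu_ic)

    @classmethod
    def from_odi(cls, f_iso, f_ic, odi, mu, **kw) -> "NoddiParameters":
        f_ec = 1.0 - f_iso - f_ic
        return cls(f_iso, f_ic, f_ec, float(kappa_from_odi(odi)), mu, **kw)


# --------------------------------------------------------------------------
# Forward model
# --------------------------------------------------------------------------
def noddi_forward(params: NoddiParameters, scheme: AcquisitionScheme) -> np.ndarray:
    """Normalised NODDI signal E for every volume of the scheme.

    E_iso is free isotropic diffusion; E_ic is the Watson spherical mean of
    the stick signal; E_ec is the Gaussian signal of the Watson-averaged
    zeppelin tensor (axial d_par, radial d_perp from the tortuosity rule).
    E = 1 exactly at b = 0.
    """
    b = scheme.bvals
    g = scheme.bvecs
    cos_ang = g @ params.mu

    e_iso = np.exp(-b * params.d_iso)

    kappa = float(np.clip(params.kappa, _KAPPA_MIN, _KAPPA_MAX))
    e_ic = _watson_stick_signal(b, cos_ang, kappa, params.d_par)

    # Watson-averaged zeppelin: average the tensor, then take the Gaussian
    # signal.  tau interpolates the axial/radial diffusivities between the
    # aligned (tau=1) and fully dispersed (tau=1/3) limits.
    d_perp = params.d_perp
    tau = watson_mean_sq_cos(kappa)
    d_ax = d_perp + (params.d_par - d_perp) * tau
    d_rad = d_perp + (params.d_par - d_perp) * (1.0 - tau) / 2.0
    e_ec = np.exp(-b * (d_rad + (d_ax - d_rad) * cos_ang**2))

    e = params.f_iso * e_iso + params.f_ic * e_ic + params.f_ec * e_ec
    e[scheme.b0_mask] = 1.0
    return e


# --------------------------------------------------------------------------
# NODDI fitting
# --------------------------------------------------------------------------
@dataclass
class NoddiFit:
    """Result of a per-voxel NODDI fit."""

    params: NoddiParameters | None
    residual_norm: float = np.nan
    n_iter: int = 0
    success: bool = False
    flagged: bool = False  # voxel not fittable (all-zero / non-finite signal)


def _theta_to_params(theta) -> NoddiParameters:
    a_iso, a_nu, log_kappa, polar, azim = theta
    f_iso = float(expit(a_iso))
    nu = float(expit(a_nu))
    f_ic = (1.0 - f_iso) * nu
    f_ec = (1.0 - f_iso) * (1.0 - nu)
    kappa = float(np.clip(np.exp(log_kappa), _KAPPA_MIN, _KAPPA_MAX))
    st = np.sin(polar)
    mu = np.array([st * np.cos(azim), st * np.sin(azim), np.cos(polar)])
    if np.linalg.norm(mu) < 1e-12:
        mu = np.array([0.0, 0.0, 1.0])
    return NoddiParameters(f_iso, f_ic, f_ec, kappa, mu)


def _params_to_theta(f_iso, nu_ic, kappa, mu) -> np.ndarray:
    clip = lambda p: float(np.clip(p, 1e-4, 1 - 1e-4))
    mu = np.asarray(mu, float)
    mu = mu / np.linalg.norm(mu)
    polar = float(np.arccos(np.clip(mu[2], -1.0, 1.0)))
    azim = float(np.arctan2(mu[1], mu[0]))
    return np.array(
        [logit(clip(f_iso)), logit(clip(nu_ic)), np.log(kappa), polar, azim]
    )


_INIT_FISO = (0.02, 0.2, 0.5, 0.9)
_INIT_NU = (0.2, 0.4, 0.6, 0.8)
_INIT_ODI = (0.04, 0.15, 0.35, 0.7)


def _grid_init(y, scheme, mu0, init_grid=None):
    """Best starting point from a coarse (f_iso, nu_ic, odi) grid with mu
    fixed at mu0; shares the Watson moments across grid points for speed."""
    if init_grid is None:
        init_grid = [
            (fi, nu, odi) for fi in _INIT_FISO for nu in _INIT_NU for odi in _INIT_ODI
        ]
    b = scheme.bvals
    cos_ang = scheme.bvecs @ mu0
    e_iso = np.exp(-b * D_ISO)
    odis = sorted({odi for _, _, odi in init_grid})
    e_ic_by_odi, tau_by_odi = {}, {}
    for odi in odis:
        kappa = float(kappa_from_odi(odi))
        e_ic_by_odi[odi] = _watson_stick_signal(b, cos_ang, kappa, D_PAR_GM)
        tau_by_odi[odi] = watson_mean_sq_cos(kappa)
    best_sse, best = np.inf, init_grid[0]
    for fi, nu, odi in init_grid:
        d_perp = D_PAR_GM * (1.0 - nu)
        tau = tau_by_odi[odi]
        d_ax = d_perp + (D_PAR_GM - d_perp) * tau
        d_rad = d_perp + (D_PAR_GM - d_perp) * (1.0 - tau) / 2.0
        e_ec = np.exp(-b * (d_rad + (d_ax - d_rad) * cos_ang**2))
        e = fi * e_iso + (1 - fi) * (nu * e_ic_by_odi[odi] + (1 - nu) * e_ec)
        e[scheme.b0_mask] = 1.0
        sse = float(np.sum((e - y) ** 2))
        if sse < best_sse:
            best_sse, best = sse, (fi, nu, odi)
    fi, nu, odi = best
    return _params_to_theta(fi, nu, float(kappa_from_odi(odi)), mu0)


def fit_noddi(
    signal: np.ndarray,
    scheme: AcquisitionScheme,
    max_iter: int = 200,
    tol: float = 1e-10,
    init_grid=None,
) -> NoddiFit:
    """Fit the Watson-NODDI model to one voxel's signal vector.

    The signal is normalised by the mean b=0 value.  Bounded nonlinear least
    squares over (f_iso, f_ic, kappa, mu) with d_par and d_iso fixed;
    bounds enforced through logistic/log transforms.  Initialisation scans a
    coarse grid over (f_iso, nu_ic, odi) with mu taken from the principal
    eigenvector of a DTI fit (when a b~1000 shell is present).  Fully
    deterministic.
    """
    signal = np.asarray(signal, dtype=float).ravel()
    if signal.shape != (scheme.n_volumes,):
        raise ValueError("signal length must match the scheme")
    if not np.all(np.isfinite(signal)) or np.all(signal == 0):
        return NoddiFit(params=None, flagged=True)

    b0 = signal[scheme.b0_mask].mean()
    if not np.isfinite(b0) or b0 <= 0:
        return NoddiFit(params=None, flagged=True)
    y = signal / b0

    if len(scheme.shells) < 2:
        warnings.warn(
            "fitting NODDI on fewer than 2 shells; parameters are poorly "
            "conditioned",
            stacklevel=2,
        )

    # orientation initialisation from DTI when possible
    mu0 = np.array([0.0, 0.0, 1.0])
    try:
        dti = fit_dti(y, scheme)
        if np.isfinite(dti.fa):
            mu0 = dti.e1
    except ValueError:
        pass

    best_theta = _grid_init(y, scheme, mu0, init_grid)

    def residuals(theta):
        return noddi_forward(_theta_to_params(theta), scheme) - y

    res = least_squares(
        residuals,
        best_theta,
        method="lm",
        ftol=tol,
        xtol=tol,
        gtol=tol,
        max_nfev=max_iter * 6,
    )
    params = _theta_to_params(res.x)
    return NoddiFit(
        params=params,
        residual_norm=float(np.linalg.norm(res.fun)),
        n_iter=int(res.nfev),
        success=bool(res.success),
    )


def fit_noddi_volume(
    data: np.ndarray, mask: np.ndarray, scheme: AcquisitionScheme, **kw
) -> dict:
    """Fit NODDI voxel-wise inside a mask of a 4-D volume.

    Returns a dict of 3-D maps: noddi_ndi, noddi_odi, noddi_fiso, noddi_mu
    (last axis 3) and a boolean 'valid' map.  Unfittable voxels are NaN and
    invalid.
    """
    data = np.asarray(data, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if data.shape[:3] != mask.shape or data.shape[3] != scheme.n_volumes:
        raise ValueError("data / mask / scheme shapes are inconsistent")
    shape = mask.shape
    maps = {
        "noddi_ndi": np.full(shape, np.nan),
        "noddi_odi": np.full(shape, np.nan),
        "noddi_fiso": np.full(shape, np.nan),
        "noddi_mu": np.full(shape + (3,), np.nan),
        "valid": np.zeros(shape, dtype=bool),
    }
    for idx in zip(*np.nonzero(mask)):
        fit = fit_noddi(data[idx], scheme, **kw)
        if fit.flagged or fit.params is None:
            continue
        p = fit.params
        maps["noddi_ndi"][idx] = p.f_ic
        maps["noddi_odi"][idx] = p.odi
        maps["noddi_fiso"][idx] = p.f_iso
        maps["noddi_mu"][idx] = p.mu
        maps["valid"][idx] = True
    return maps


# --------------------------------------------------------------------------
# DTI
# --------------------------------------------------------------------------
@dataclass(frozen=True)
class TensorFit:
    """Diffusion tensor fit: tensor, eigensystem, FA and MD."""

    D: np.ndarray  # 3x3 symmetric, mm^2/s
    eigenvalues: np.ndarray  # descending
    eigenvectors: np.ndarray  # columns matched to eigenvalues
    s0: float
    clamped: bool = False  # negative eigenvalues were clamped to 0

    @property
    def md(self) -> float:
        return float(self.eigenvalues.mean())

    @property
    def fa(self) -> float:
        lam = self.eigenvalues
        mean = lam.mean()
        denom = np.sqrt((lam**2).sum())
        if denom == 0:
            return 0.0
        return float(np.sqrt(1.5 * ((lam - mean) ** 2).sum()) / denom)

    @property
    def e1(self) -> np.ndarray:
        return self.eigenvectors[:, 0]


def fit_dti(
    signal: np.ndarray, scheme: AcquisitionScheme, shell_b: float = 1000.0
) -> TensorFit:
    """Log-linear least-squares tensor fit on the b=0 and b~shell_b volumes.

    Requires >= 6 unique diffusion directions on the shell.  Negative
    eigenvalues are clamped to zero and the fit is flagged.
    """
    signal = np.asarray(signal, dtype=float).ravel()
    if signal.shape != (scheme.n_volumes,):
        raise ValueError("signal length must match the scheme")
    use = scheme.b0_mask | np.isclose(scheme.bvals, shell_b, rtol=0.05)
    b = scheme.bvals[use]
    g = scheme.bvecs[use]
    s = np.clip(signal[use], 1e-10, None)
    dw = b > 10.0
    n_dirs = len(np.unique(np.round(g[dw], 6), axis=0))
    if n_dirs < 6:
        raise ValueError(
            f"DTI needs >= 6 unique directions at b={shell_b:g}; got {n_dirs}"
        )
    # design: ln S = ln S0 - b g^T D g
    gx, gy, gz = g.T
    X = np.column_stack(
        [
            np.ones_like(b),
            -b * gx**2,
            -b * gy**2,
            -b * gz**2,
            -2 * b * gx * gy,
            -2 * b * gx * gz,
            -2 * b * gy * gz,
        ]
    )
    beta, *_ = np.linalg.lstsq(X, np.log(s), rcond=None)
    s0 = float(np.exp(beta[0]))
    dxx, dyy, dzz, dxy, dxz, dyz = beta[1:]
    D = np.array([[dxx, dxy, dxz], [dxy, dyy, dyz], [dxz, dyz, dzz]])
    lam, vec = np.linalg.eigh(D)
    order = np.argsort(lam)[::-1]
    lam, vec = lam[order], vec[:, order]
    clamped = bool(np.any(lam < 0))
    lam = np.clip(lam, 0.0, None)
    return TensorFit(D=D, eigenvalues=lam, eigenvectors=vec, s0=s0, clamped=clamped)
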