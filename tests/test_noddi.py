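"""Watson-NODDI forward model, parameter fitting and DTI."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from hippaxes.acquisition import AcquisitionScheme, fibonacci_directions, multishell_scheme
from hippaxes.noddi import (
    D_ISO,
    D_PAR_GM,
    NoddiParameters,
    fit_dti,
    fit_noddi,
    kappa_from_odi,
    noddi_forward,
    odi_from_kappa,
    watson_mean_sq_cos,
)


class TestOdiKappa:
    @pytest.mark.parametrize(
        "kappa,odi",
        [(1.0, 0.5), (1e9, 2 / np.pi * np.arctan(1e-9))],
    )
    def test_known_values(self, kappa, odi):
        assert odi_from_kappa(kappa) == pytest.approx(odi, abs=1e-12)

    def test_large_kappa_limit(self):
        assert odi_from_kappa(1e9) < 1e-8

    @given(st.floats(0.05, 20.0))
    def test_round_trip(self, kappa):
        assert kappa_from_odi(odi_from_kappa(kappa)) == pytest.approx(kappa, abs=1e-10)

    @pytest.mark.parametrize("bad", [0.0, -1.0])
    def test_rejects_nonpositive(self, bad):
        with pytest.raises(ValueError):
            odi_from_kappa(bad)
        with pytest.raises(ValueError):
            kappa_from_odi(bad)


class TestForwardModel:
    def test_b0_is_one(self, small_scheme):
        p = NoddiParameters.from_odi(0.2, 0.5, 0.3, [0, 0, 1])
        e = noddi_forward(p, small_scheme)
        assert np.all(e[small_scheme.b0_mask] == 1.0)

    def test_pure_isotropic_single_compartment(self, small_scheme):
        p = NoddiParameters(1.0, 0.0, 0.0, 1.0, [0, 0, 1])
        e = noddi_forward(p, small_scheme)
        for b in (1000.0, 3000.0):
            sel = np.isclose(small_scheme.bvals, b)
            assert e[sel] == pytest.approx(np.exp(-b * D_ISO), rel=1e-12)

    def test_parallel_sticks_no_perpendicular_attenuation(self):
        # kappa=64: nearly parallel sticks; perpendicular gradient sees ~no decay
        scheme = AcquisitionScheme([0.0, 2000.0], [[0, 0, 0], [1.0, 0, 0]])
        p = NoddiParameters(0.0, 1.0, 0.0, 64.0, [0, 0, 1])
        assert noddi_forward(p, scheme)[1] == pytest.approx(1.0, rel=0.02)

    def test_antipodal_symmetry_exact(self, small_scheme):
        mu = np.array([0.4, -0.5, 0.76])
        pa = NoddiParameters.from_odi(0.1, 0.5, 0.3, mu)
        pb = NoddiParameters.from_odi(0.1, 0.5, 0.3, -mu)
        assert np.array_equal(noddi_forward(pa, small_scheme), noddi_forward(pb, small_scheme))

    def test_monotone_in_b_and_bounded(self):
        dirs = fibonacci_directions(12)
        p = NoddiParameters.from_odi(0.15, 0.55, 0.25, [0.2, 0.3, 0.93])
        prev = np.ones(12)
        for b in (0.0, 500.0, 1000.0, 2000.0, 3000.0):
            scheme = AcquisitionScheme(
                np.concatenate([[0.0], np.full(12, b)]),
                np.vstack([[0, 0, 0], dirs]),
            )
            e = noddi_forward(p, scheme)[1:]
            assert np.all(e > 0) and np.all(e <= 1)
            assert np.all(e <= prev + 1e-12)
            prev = e

    def test_matches_spherical_quadrature_oracle(self):
        """Independent oracle: Watson-weighted kernels integrated over a
        dense sphere point set (signal average for the sticks, tensor
        average for the zeppelin)."""
        pts = fibonacci_directions(12000)
        scheme = multishell_scheme(n_dirs=20, n_b0=2)
        mu = np.array([0.3, -0.2, 0.93])
        mu /= np.linalg.norm(mu)
        for f_iso, f_ic_t, odi in [(0.1, 0.6, 0.2), (0.3, 0.4, 0.6), (0.0, 0.9, 0.05)]:
            f_ic = (1 - f_iso) * f_ic_t
            p = NoddiParameters(f_iso, f_ic, 1 - f_iso - f_ic, float(kappa_from_odi(odi)), mu)
            w = np.exp(p.kappa * ((pts @ mu) ** 2 - 1.0))
            w /= w.sum()
            b, g = scheme.bvals, scheme.bvecs
            cos2 = (g @ pts.T) ** 2
            e_ic = (np.exp(-b[:, None] * D_PAR_GM * cos2) * w).sum(axis=1)
            tau = float((w * (pts @ mu) ** 2).sum())
            d_perp = p.d_perp
            d_ax = d_perp + (D_PAR_GM - d_perp) * tau
            d_rad = d_perp + (D_PAR_GM - d_perp) * (1 - tau) / 2
            e_ec = np.exp(-b * (d_rad + (d_ax - d_rad) * (g @ mu) ** 2))
            e_oracle = f_iso * np.exp(-b * D_ISO) + p.f_ic * e_ic + p.f_ec * e_ec
            e_oracle[scheme.b0_mask] = 1.0
            assert np.abs(noddi_forward(p, scheme) - e_oracle).max() < 1e-3

    def test_mean_sq_cos_limits(self):
        assert watson_mean_sq_cos(1e-6) == pytest.approx(1 / 3, abs=1e-5)
        assert watson_mean_sq_cos(500.0) > 0.99


class TestNoddiParameters:
    def test_fraction_sum_enforced(self):
        with pytest.raises(ValueError):
            NoddiParameters(0.5, 0.5, 0.5, 1.0, [0, 0, 1])

    def test_mu_normalised(self):
        p = NoddiParameters(0.2, 0.3, 0.5, 1.0, [0, 0, 2.0])
        assert np.linalg.norm(p.mu) == pytest.approx(1.0)

    def test_tortuosity_rule(self):
        p = NoddiParameters.from_odi(0.2, 0.4, 0.3, [0, 0, 1])
        nu = 0.4 / 0.8
        assert p.d_perp == pytest.approx(D_PAR_GM * (1 - nu))


class TestFitNoddi:
    def test_noiseless_recovery(self, full_scheme):
        truth = NoddiParameters.from_odi(0.1, 0.6, 0.3, [0, 0, 1])
        fit = fit_noddi(noddi_forward(truth, full_scheme), full_scheme)
        p = fit.params
        assert abs(p.f_ic - 0.6) < 0.02
        assert abs(p.odi - 0.3) < 0.02
        angle = np.degrees(np.arccos(min(1.0, abs(p.mu @ truth.mu))))
        assert angle < 3.0
        assert p.f_iso + p.f_ic + p.f_ec == pytest.approx(1.0, abs=1e-9)

    def test_pure_isotropic_recovery(self, small_scheme):
        truth = NoddiParameters(1.0, 0.0, 0.0, 1.0, [0, 0, 1])
        fit = fit_noddi(noddi_forward(truth, small_scheme), small_scheme)
        assert fit.params.f_iso > 0.95

    def test_bad_voxel_flagged_not_fitted(self, small_scheme):
        fit = fit_noddi(np.zeros(small_scheme.n_volumes), small_scheme)
        assert fit.flagged and fit.params is None
        sig = np.ones(small_scheme.n_volumes)
        sig[3] = np.nan
        assert fit_noddi(sig, small_scheme).flagged

    def test_single_shell_warns(self):
        scheme = multishell_scheme(shells=(1000.0,), n_dirs=12, n_b0=2)
        truth = NoddiParameters.from_odi(0.1, 0.5, 0.3, [0, 0, 1])
        with pytest.warns(UserWarning, match="fewer than 2 shells"):
            fit_noddi(noddi_forward(truth, scheme), scheme)

    def test_deterministic(self, small_scheme, rng):
        truth = NoddiParameters.from_odi(0.15, 0.5, 0.25, [0.3, 0.1, 0.95])
        y = noddi_forward(truth, small_scheme) + rng.normal(0, 1 / 30, small_scheme.n_volumes)
        a, b = fit_noddi(y, small_scheme), fit_noddi(y, small_scheme)
        assert np.array_equal(a.params.mu, b.params.mu)
        assert a.params.f_ic == b.params.f_ic


class TestFitDti:
    def test_isotropic_decay(self, small_scheme):
        sig = np.exp(-small_scheme.bvals * 1e-3)
        tf = fit_dti(sig, small_scheme)
        assert tf.fa == pytest.approx(0.0, abs=1e-9)
        assert tf.md == pytest.approx(1e-3, abs=1e-9)

    def test_known_tensor_recovery(self, small_scheme):
        lam = np.diag([1.7e-3, 0.3e-3, 0.3e-3])
        b, g = small_scheme.bvals, small_scheme.bvecs
        sig = np.exp(-b * np.einsum("ij,jk,ik->i", g, lam, g))
        tf = fit_dti(sig, small_scheme)
        assert np.abs(tf.D - lam).max() < 1e-9
        assert abs(tf.e1 @ np.array([1.0, 0, 0])) == pytest.approx(1.0, abs=1e-6)
        assert tf.md == pytest.approx(np.trace(tf.D) / 3)

    def test_uses_only_b1000_shell(self, full_scheme):
        # corrupt the b=2000/3000 volumes; the tensor fit must not change
        lam = np.diag([1.2e-3, 0.5e-3, 0.4e-3])
        b, g = full_scheme.bvals, full_scheme.bvecs
        sig = np.exp(-b * np.einsum("ij,jk,ik->i", g, lam, g))
        corrupted = sig.copy()
        corrupted[full_scheme.bvals > 1500] = 0.123
        assert np.array_equal(
            fit_dti(sig, full_scheme).D, fit_dti(corrupted, full_scheme).D
        )

    def test_too_few_directions_rejected(self):
        scheme = multishell_scheme(shells=(1000.0,), n_dirs=5, n_b0=2)
        with pytest.raises(ValueError, match="6 unique directions"):
            fit_dti(np.ones(scheme.n_volumes), scheme)

    def test_negative_eigenvalues_clamped_and_flagged(self, small_scheme, rng):
        sig = 1.0 + 0.5 * rng.standard_normal(small_scheme.n_volumes)
        sig = np.clip(sig, 0.05, None)
        tf = fit_dti(sig, small_scheme)
        assert np.all(tf.eigenvalues >= 0)
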