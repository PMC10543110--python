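"""Synthetic-data generators: domains, signals, unfolded maps, tables."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from hippaxes.noddi import NoddiParameters, noddi_forward
from hippaxes.acquisition import multishell_scheme
from hippaxes.spatial_stats import spearman_rho
from hippaxes.synthetic import (
    make_correlated_map_pair,
    make_ground_truth,
    make_subfield_table,
    make_synthetic_surface,
    make_unfolded_dataset,
    make_voxel_domain,
    simulate_dwi,
)
from hippaxes.surface import SUBFIELDS


class TestMakeVoxelDomain:
    def test_slab_is_full_box_with_ap_faces(self):
        d = make_voxel_domain((16, 16, 8), "slab")
        assert d.mask.all()
        src, snk = d.boundary_labels["AP"]
        assert src[0].all() and src.sum() == 16 * 8
        assert snk[15].all() and snk.sum() == 16 * 8

    def test_slab_axes_are_orthogonal_planes(self):
        d = make_voxel_domain((16, 16, 8), "slab")
        normals = []
        for axis in ("AP", "PD", "IO"):
            src, _ = d.boundary_labels[axis]
            idx = np.argwhere(src)
            # a boundary plane is constant along exactly one axis
            const_axes = [a for a in range(3) if np.ptp(idx[:, a]) == 0]
            assert len(const_axes) == 1
            normals.append(const_axes[0])
        assert sorted(normals) == [0, 1, 2]

    def test_curved_shell_deterministic(self):
        a = make_voxel_domain((10, 28, 14), "curved_shell", seed=3)
        b = make_voxel_domain((10, 28, 14), "curved_shell", seed=3)
        assert np.array_equal(a.mask, b.mask)

    @pytest.mark.parametrize("shape", [(7, 16, 8), (16, 7, 8), (8, 8, 7)])
    def test_degenerate_shape_rejected(self, shape):
        with pytest.raises(ValueError, match=">= 8"):
            make_voxel_domain(shape, "slab")

    def test_unknown_geometry_rejected(self):
        with pytest.raises(ValueError, match="geometry"):
            make_voxel_domain((8, 8, 8), "sphere")


class TestSimulateDwi:
    @pytest.fixture()
    def iso_truth(self):
        domain = make_voxel_domain((8, 8, 8), "slab")
        shape = domain.mask.shape
        mu = np.zeros(shape + (3,))
        mu[..., 2] = 1.0
        return make_voxel_domain((8, 8, 8), "slab"), shape, mu

    def test_pure_isotropic_signal(self, iso_truth):
        domain, shape, mu = iso_truth
        truth = type("GT", (), {})
        from hippaxes.synthetic import GroundTruthVoxelParams

        gt = GroundTruthVoxelParams(
            domain=domain,
            f_iso=np.ones(shape),
            f_ic=np.zeros(shape),
            f_ec=np.zeros(shape),
            kappa=np.ones(shape),
            mu=mu,
        )
        scheme = multishell_scheme(shells=(1000.0,), n_dirs=6, n_b0=2)
        vol = simulate_dwi(gt, scheme)
        dw = ~scheme.b0_mask
        assert np.allclose(vol[domain.mask][:, dw], np.exp(-1000 * 3.0e-3), rtol=1e-12)
        assert np.all(vol[domain.mask][:, scheme.b0_mask] == 1.0)

    def test_noiseless_matches_forward_model(self, small_scheme):
        domain = make_voxel_domain((8, 8, 8), "slab")
        gt = make_ground_truth(domain, seed=5)
        vol = simulate_dwi(gt, small_scheme)
        idx = (4, 3, 2)
        expected = noddi_forward(gt.voxel_params(idx), small_scheme)
        assert np.abs(vol[idx] - expected).max() < 1e-12

    def test_gaussian_noise_scale(self, rng):
        """Empirical SD of the b=0 replicates matches 1/snr within 10%."""
        domain = make_voxel_domain((8, 8, 8), "slab")
        gt = make_ground_truth(domain, seed=2)
        scheme = multishell_scheme(shells=(1000.0,), n_dirs=6, n_b0=4)
        vol = simulate_dwi(gt, scheme, snr=30.0, noise_model="gaussian", seed=7)
        b0 = vol[domain.mask][:, scheme.b0_mask]  # 512 voxels x 4 replicates
        resid = b0 - 1.0
        assert resid.size >= 100
        assert np.std(resid) == pytest.approx(1 / 30, rel=0.10)

    def test_rician_biases_positive(self):
        domain = make_voxel_domain((8, 8, 8), "slab")
        gt = make_ground_truth(domain, seed=2)
        scheme = multishell_scheme(shells=(1000.0,), n_dirs=6, n_b0=4)
        g = simulate_dwi(gt, scheme, snr=10.0, noise_model="rician", seed=7)
        assert np.all(g[domain.mask] >= 0)
        assert g[domain.mask][:, scheme.b0_mask].mean() > 1.0

    def test_bad_snr_rejected(self, small_scheme):
        domain = make_voxel_domain((8, 8, 8), "slab")
        gt = make_ground_truth(domain, seed=0)
        with pytest.raises(ValueError, match="snr"):
            simulate_dwi(gt, small_scheme, snr=0.0)

    def test_deterministic_given_seed(self, small_scheme):
        domain = make_voxel_domain((8, 8, 8), "slab")
        gt = make_ground_truth(domain, seed=1)
        a = simulate_dwi(gt, small_scheme, snr=20.0, seed=9)
        b = simulate_dwi(gt, small_scheme, snr=20.0, seed=9)
        assert np.array_equal(a, b)


class TestMakeUnfoldedDataset:
    def test_deterministic(self):
        a = make_unfolded_dataset((16, 8), n_subjects=3, true_rank=3, seed=11)
        b = make_unfolded_dataset((16, 8), n_subjects=3, true_rank=3, seed=11)
        assert np.array_equal(a.maps, b.maps)
        assert np.array_equal(a.true_parcels, b.true_parcels)

    def test_zero_effect_is_pure_noise_with_labels(self):
        ds = make_unfolded_dataset((16, 8), n_subjects=4, true_rank=3, effect_size=0.0, seed=2)
        assert len(np.unique(ds.true_parcels)) == 3
        # zero planted effect: parcel means indistinguishable from noise
        v0 = ds.maps[:, 0, :]
        assert abs(v0.mean()) < 0.2

    def test_intersubject_mean_shrinks_with_n(self):
        """With no planted effect the vertex-wise inter-subject mean is
        within 3 standard errors of zero almost everywhere."""
        ds = make_unfolded_dataset(
            (16, 8), n_subjects=40, true_rank=2, effect_size=0.0, seed=3,
            metric_names=("m1",),
        )
        vals = ds.maps[:, 0, :]  # subjects x vertices
        mean = vals.mean(axis=0)
        se = vals.std(axis=0, ddof=1) / np.sqrt(vals.shape[0])
        assert np.mean(np.abs(mean) < 3 * se) > 0.95

    def test_rank_bound_enforced(self):
        with pytest.raises(ValueError, match="true_rank"):
            make_unfolded_dataset((4, 4), n_subjects=1, true_rank=20, metric_names=("a",))

    def test_raw_matrix_layout(self):
        ds = make_unfolded_dataset((8, 8), n_subjects=3, true_rank=2, seed=0)
        X, cols = ds.raw_matrix()
        assert X.shape == (64, 3 * len(ds.metric_names))
        assert list(cols.columns) >= ["subject", "metric"]
        assert cols["subject"].nunique() == 3


class TestMakeCorrelatedMapPair:
    def test_high_rho_sample_band(self):
        """Sample Spearman rho stays in a band around the 0.9 target
        (Monte-Carlo over 100 seeds of the generator)."""
        rhos = [
            spearman_rho(*make_correlated_map_pair((64, 32), 0.9, seed=s))
            for s in range(100)
        ]
        rhos = np.array(rhos)
        assert rhos.min() > 0.8 and rhos.max() < 0.97
        assert abs(np.median(rhos) - 0.9) < 0.03

    def test_negative_rho_mostly_negative(self):
        signs = [
            spearman_rho(*make_correlated_map_pair((64, 32), -0.5, seed=s)) < 0
            for s in range(100)
        ]
        assert sum(signs) >= 95

    def test_zero_rho_independent_fields(self):
        a, b = make_correlated_map_pair((64, 32), 0.0, seed=4)
        assert abs(spearman_rho(a, b)) < 0.5  # loose: smooth fields, small n_eff

    def test_target_validation(self):
        with pytest.raises(ValueError):
            make_correlated_map_pair((8, 8), 1.0)


class TestMakeSubfieldTable:
    def test_zero_covariance_returns_class_means(self):
        t = make_subfield_table(3, class_cov=np.zeros((3, 3)), seed=0)
        sub = t[(t.subfield == "CA1")]
        assert sub["odi"].nunique() == 1
        assert len(t) == 3 * 2 * 5

    def test_nonpsd_covariance_rejected(self):
        bad = np.diag([1.0, 1.0, -0.1])
        with pytest.raises(ValueError, match="positive semidefinite"):
            make_subfield_table(2, class_cov=bad)

    def test_all_subfields_present_and_deterministic(self):
        a = make_subfield_table(4, seed=6)
        b = make_subfield_table(4, seed=6)
        assert set(a["subfield"]) == set(SUBFIELDS)
        pd.testing.assert_frame_equal(a, b)


class TestMakeSyntheticSurface:
    def test_grid_layout_and_invariants(self):
        s = make_synthetic_surface((12, 8, 8), grid_shape=(16, 10))
        assert s.n_vertices == 160
        assert s.grid_shape == (16, 10)
        assert np.all(s.thickness_mm > 0)
        assert set(s.subfield_label) == set(SUBFIELDS)
        # sheets are ordered inner < mid < outer along IO
        assert np.all(s.vertices_inner[:, 2] < s.vertices_mid[:, 2])
        assert np.all(s.vertices_mid[:, 2] < s.vertices_outer[:, 2])

    def test_thickness_gradient_varies_across_columns(self):
        s = make_synthetic_surface((12, 8, 8), (8, 10), thickness_gradient=0.5)
        grid = s.thickness_mm.reshape(8, 10)
        assert grid[0, -1] > grid[0, 0]
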