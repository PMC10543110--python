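"""Orthogonal projective NMF: normalisation, fitting, labels, stability."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from hippaxes.opnnmf import (
    error_gradient,
    nndsvd_init,
    normalize_metrics,
    opnnmf_fit,
    reconstruction_error,
    split_half_stability,
    stability_analysis,
    winner_take_all,
    zscore_weights,
)
from hippaxes.synthetic import make_unfolded_dataset


def planted_stack(
    grid=(16, 12), n_subjects=8, rank=4, effect=6.0, seed=0,
    metrics=("a", "b", "c"), noise_sd=1.0,
):
    ds = make_unfolded_dataset(
        grid, n_subjects=n_subjects, true_rank=rank, effect_size=effect,
        seed=seed, metric_names=metrics, noise_sd=noise_sd,
    )
    X, cols = ds.raw_matrix()
    return normalize_metrics(X, cols), ds


class TestNormalizeMetrics:
    def _raw(self, rng):
        cols = pd.DataFrame(
            {"subject": ["s0", "s0", "s1", "s1"], "metric": ["a", "b", "a", "b"]}
        )
        raw = rng.uniform(1, 5, (20, 4))
        raw[:, cols.metric == "b"] *= 100  # wildly different scale
        return raw, cols

    def test_global_minimum_exactly_zero(self, rng):
        raw, cols = self._raw(rng)
        stack = normalize_metrics(raw, cols)
        assert stack.X.min() == 0.0
        assert np.all(stack.X >= 0)

    def test_per_metric_zscore_before_shift(self, rng):
        raw, cols = self._raw(rng)
        stack = normalize_metrics(raw, cols)
        shift = stack.X.min() - (stack.X - stack.X.mean()).min()  # recover z via stats
        for metric in ("a", "b"):
            block = stack.X[:, (cols.metric == metric).to_numpy()]
            assert block.std() == pytest.approx(1.0, abs=1e-9)

    def test_affine_invariance_of_one_metric(self, rng):
        raw, cols = self._raw(rng)
        scaled = raw.copy()
        sel = (cols.metric == "a").to_numpy()
        scaled[:, sel] = 3.7 * scaled[:, sel] - 11.0
        a = normalize_metrics(raw, cols)
        b = normalize_metrics(scaled, cols)
        assert np.allclose(a.X, b.X, atol=1e-9)

    def test_zero_variance_metric_rejected(self):
        cols = pd.DataFrame({"subject": ["s0", "s0"], "metric": ["a", "b"]})
        raw = np.ones((10, 2))
        raw[:, 0] = np.arange(10)
        with pytest.raises(ValueError, match="'b'"):
            normalize_metrics(raw, cols)


class TestNndsvdInit:
    def test_rank_one_matrix_recovers_direction(self, rng):
        u = rng.uniform(0.1, 1.0, 15)
        v = rng.uniform(0.1, 1.0, 8)
        X = 4.0 * np.outer(u, v)
        C0 = nndsvd_init(X, 1)
        cos = C0[:, 0] @ u / (np.linalg.norm(C0) * np.linalg.norm(u))
        assert cos == pytest.approx(1.0, abs=1e-9)

    def test_nonnegative_and_deterministic(self, rng):
        X = rng.uniform(0, 1, (30, 12))
        a, b = nndsvd_init(X, 5), nndsvd_init(X, 5)
        assert np.all(a >= 0)
        assert np.array_equal(a, b)

    def test_excessive_k_rejected(self, rng):
        X = rng.uniform(0, 1, (10, 4))
        with pytest.raises(ValueError):
            nndsvd_init(X, 5)


class TestOpnnmfFit:
    def test_planted_orthogonal_blocks_low_error(self):
        # structure dominates noise, so rank-4 components explain ~all of X
        stack, ds = planted_stack(effect=8.0, noise_sd=0.2)
        fit = opnnmf_fit(stack.X, 4)
        rel = reconstruction_error(stack.X, fit.C) / np.linalg.norm(stack.X)
        assert rel < 0.05

    def test_objective_monotone_nonincreasing(self, rng):
        X = rng.uniform(0, 1, (40, 15))
        fit = opnnmf_fit(X, 3, max_iter=300)
        diffs = np.diff(fit.objective_trace)
        assert np.all(diffs <= 1e-10 * np.abs(fit.objective_trace[:-1]) + 1e-10)

    def test_components_stay_nonnegative_near_unit_norm(self, rng):
        X = rng.uniform(0, 1, (40, 15))
        fit = opnnmf_fit(X, 3, max_iter=500)
        assert np.all(fit.C >= 0)
        # orthogonality is approached, not enforced: column norms near 1
        assert np.all(np.linalg.norm(fit.C, axis=0) < 1.2)
        assert np.all(np.linalg.norm(fit.C, axis=0) > 0.5)
        assert np.allclose(fit.W, fit.C.T @ X)

    def test_scaling_x_leaves_component_direction_unchanged(self, rng):
        X = rng.uniform(0, 1, (30, 10))
        c1 = opnnmf_fit(X, 2).C
        c2 = opnnmf_fit(5.0 * X, 2).C
        assert np.allclose(c1, c2, atol=1e-6)

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError):
            opnnmf_fit(-np.ones((5, 5)), 2)


class TestWinnerTakeAll:
    def test_one_hot_rows(self):
        C = np.eye(4)[[2, 0, 3, 1]]
        assert np.array_equal(winner_take_all(C), [3, 1, 4, 2])

    def test_tie_breaks_to_lowest_index(self):
        assert winner_take_all(np.array([[0.2, 0.2]]))[0] == 1

    def test_zero_row_flagged(self):
        C = np.array([[0.0, 0.0], [1.0, 0.0]])
        with pytest.warns(UserWarning, match="all-zero"):
            labels = winner_take_all(C)
        assert labels[0] == 0 and labels[1] == 1

    def test_planted_parcels_recovered(self):
        stack, ds = planted_stack(effect=8.0, seed=3)
        fit = opnnmf_fit(stack.X, ds.true_rank)
        ari = adjusted_rand_score(ds.true_parcels, fit.labels)
        assert ari > 0.9


class TestWeightsAndError:
    def test_zscore_rows(self, rng):
        W = rng.uniform(0, 2, (3, 20))
        Z = zscore_weights(W)
        assert np.allclose(Z.mean(axis=1), 0, atol=1e-12)
        assert np.allclose(Z.std(axis=1), 1, atol=1e-12)
        with pytest.raises(ValueError, match="constant"):
            zscore_weights(np.ones((2, 5)))

    def test_planted_loading_positive_z(self):
        stack, ds = planted_stack(effect=8.0, seed=1)
        fit = opnnmf_fit(stack.X, ds.true_rank)
        Z = zscore_weights(fit.W)
        # each component's top-weighted columns are above its row mean
        for j in range(ds.true_rank):
            assert Z[j].max() > 0

    def test_perfect_basis_zero_error(self, rng):
        X = rng.uniform(0, 1, (8, 8))
        Q, _ = np.linalg.qr(X)
        assert reconstruction_error(X, Q) == pytest.approx(0.0, abs=1e-9)

    def test_zero_components_full_error(self, rng):
        X = rng.uniform(0, 1, (8, 5))
        assert reconstruction_error(X, np.zeros((8, 3))) == pytest.approx(
            np.linalg.norm(X)
        )

    def test_matches_bruteforce_frobenius(self, rng):
        X = rng.uniform(0, 1, (12, 9))
        C = rng.uniform(0, 1, (12, 3))
        brute = np.sqrt(((X - C @ C.T @ X) ** 2).sum())
        assert reconstruction_error(X, C) == pytest.approx(brute, abs=1e-12)

    def test_error_nonincreasing_in_k(self):
        stack, _ = planted_stack(effect=4.0, seed=2)
        errs = [reconstruction_error(stack.X, opnnmf_fit(stack.X, k).C) for k in range(2, 7)]
        grad = error_gradient(errs)
        assert np.all(grad <= 1e-8)


class TestStability:
    def test_identical_splits_perfect_stability(self, rng):
        C = rng.uniform(0, 1, (30, 4))
        r = split_half_stability(C, C)
        assert np.nanmean(r) == pytest.approx(1.0, abs=1e-9)

    def test_invariant_to_component_permutation(self, rng):
        C1 = rng.uniform(0, 1, (25, 4))
        C2 = rng.uniform(0, 1, (25, 4))
        base = split_half_stability(C1, C2)
        perm = split_half_stability(C1[:, [2, 0, 3, 1]], C2)
        assert np.allclose(base, perm, equal_nan=True)

    def test_planted_structure_more_stable_than_noise(self):
        stack_sig, ds = planted_stack(grid=(12, 8), n_subjects=8, rank=3, effect=8.0, seed=4)
        stack_noise, _ = planted_stack(grid=(12, 8), n_subjects=8, rank=3, effect=0.0, seed=4)
        rep_sig = stability_analysis(stack_sig, k_range=[3], n_splits=2, seed=0)
        rep_noise = stability_analysis(stack_noise, k_range=[3], n_splits=2, seed=0)
        s_sig = rep_sig.table.stability_mean.iloc[0]
        s_noise = rep_noise.table.stability_mean.iloc[0]
        assert s_sig > 0.9
        assert s_sig > s_noise

    def test_stability_higher_at_true_k_than_double(self):
        stack, ds = planted_stack(grid=(12, 8), n_subjects=8, rank=3, effect=8.0, seed=5)
        rep = stability_analysis(stack, k_range=[3, 6], n_splits=2, seed=1)
        t = rep.table.set_index("k")
        assert t.loc[3, "stability_mean"] > t.loc[6, "stability_mean"]

    def test_too_few_subjects_rejected(self):
        stack, _ = planted_stack(n_subjects=3)
        with pytest.raises(ValueError, match="4 subjects"):
            stability_analysis(stack, k_range=[2], n_splits=1, seed=0)
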