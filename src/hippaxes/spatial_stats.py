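"""Map-to-map correlations with torus spin-test significance.

Unfolded hippocampal maps live on a rectangular grid whose opposite edges
are treated as wrapping (a torus).  Significance of a Spearman correlation
between two maps is assessed by permuting one map with random torus
isometries — cyclic 2-D shifts optionally composed with a 180-degree
rotation — which preserve the spatial autocorrelation structure, then
comparing the observed |rho| with the permuted null.  p-values across many
map pairs are corrected with Benjamini-Hochberg FDR.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "SpinTestResult",
    "spearman_rho",
    "torus_permutations",
    "spin_test",
    "fdr_bh",
    "all_pairs_report",
]


def _as_values(m) -> np.ndarray:
    return np.asarray(getattr(m, "values", m), dtype=float).ravel()


def spearman_rho(map_a, map_b) -> float:
    """Spearman rank correlation with average ranks for ties; missing
    vertices are pairwise-deleted.  Constant input is undefined and raises."""
    a, b = _as_values(map_a), _as_values(map_b)
    if a.shape != b.shape:
        raise ValueError("maps must share a vertex set")
    ok = np.isfinite(a) & np.isfinite(b)
    if ok.sum() < 3:
        raise ValueError("need at least 3 paired non-missing values")
    a, b = a[ok], b[ok]
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("Spearman correlation is undefined for a constant map")
    rho = stats.spearmanr(a, b).statistic
    return float(rho)


def torus_permutations(grid_shape, n_perm: int, seed: int) -> np.ndarray:
    """Vertex-index permutations from random torus isometries.

    Each permutation is a cyclic shift by uniform (dr, dc) composed, with
    probability 1/2, with a 180-degree rotation; the identity transform is
    excluded and resampled.  Returns an (n_perm, V) integer array P such
    that map.ravel()[P[i]] is the i-th permuted map.
    """
    rows, cols = (int(s) for s in grid_shape)
    n_transforms = rows * cols * 2 - 1  # minus identity
    if n_perm > n_transforms:
        raise ValueError(
            f"n_perm={n_perm} exceeds the {n_transforms} distinct non-identity "
            "transforms of this grid"
        )
    rng = np.random.default_rng(seed)
    base = np.arange(rows * cols).reshape(rows, cols)
    perms = np.empty((n_perm, rows * cols), dtype=np.int64)
    i = 0
    while i < n_perm:
        dr = int(rng.integers(rows))
        dc = int(rng.integers(cols))
        rot = bool(rng.integers(2))
        if dr == 0 and dc == 0 and not rot:
            continue
        g = np.roll(base, (dr, dc), axis=(0, 1))
        if rot:
            g = g[::-1, ::-1]
        perms[i] = g.ravel()
        i += 1
    return perms


@dataclass
class SpinTestResult:
    """Observed Spearman rho, its torus-permutation null and two-sided p."""

    rho_observed: float
    null_rhos: np.ndarray
    p_value: float
    n_perm: int


def _rank_standardised(x: np.ndarray) -> np.ndarray:
    r = stats.rankdata(x)
    r = r - r.mean()
    sd = r.std()
    if sd == 0:
        raise ValueError("constant map in spin test")
    return r / (sd * np.sqrt(len(r)))


def spin_test(map_a, map_b, grid_shape=None, n_perm: int = 2500, seed: int = 0):
    """Torus spin test of the Spearman correlation between two grid maps.

    map_a is permuted over random torus isometries while map_b stays fixed;
    the two-sided p-value uses the +1 correction
    p = (1 + #{|null| >= |observed|}) / (1 + n_perm).
    Maps must be complete (no missing vertices) on a common grid.
    """
    if grid_shape is None:
        grid_shape = getattr(map_a, "grid_shape", None)
        if grid_shape is None:
            raise ValueError("grid_shape required for array inputs")
    a, b = _as_values(map_a), _as_values(map_b)
    if a.shape != b.shape or a.size != int(np.prod(grid_shape)):
        raise ValueError("maps must share the full grid")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("spin test requires complete maps (no missing vertices)")
    rho_obs = spearman_rho(a, b)
    # ranks of a permuted map are the permuted ranks, so rank once
    ra = _rank_standardised(a)
    rb = _rank_standardised(b)
    perms = torus_permutations(grid_shape, n_perm, seed)
    null = ra[perms] @ rb
    p = float((1 + np.sum(np.abs(null) >= abs(rho_obs))) / (1 + n_perm))
    return SpinTestResult(
        rho_observed=rho_obs, null_rhos=null, p_value=p, n_perm=n_perm
    )


def fdr_bh(p_values, alpha: float = 0.05) -> tuple:
    """Benjamini-Hochberg step-up FDR: returns (q_values, rejected)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    if np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    rejected, q, *_ = multipletests(p, alpha=alpha, method="fdr_bh")
    return q, rejected


def _pair_seed(root_seed: int, name_a: str, name_b: str) -> int:
    """Deterministic per-pair seed, invariant to map ordering."""
    key = "|".join(sorted([name_a, name_b]))
    h = hashlib.blake2b(key.encode(), digest_size=4).digest()
    return (root_seed * 0x9E3779B1 + int.from_bytes(h, "little")) % (2**31)


def all_pairs_report(
    maps: list,
    n_perm: int = 2500,
    seed: int = 0,
    alpha: float = 0.05,
    run_spin: bool = True,
) -> pd.DataFrame:
    """Spearman rho, spin-test p and joint BH-FDR q for every map pair.

    The FDR family is all pairs in one report.  Per-pair permutation seeds
    are derived from the metric names so the result is invariant to the
    order in which maps are supplied.
    """
    if len(maps) < 2:
        raise ValueError("need at least 2 maps")
    names = [m.metric_name or f"map{i}" for i, m in enumerate(maps)]
    if len(set(names)) != len(names):
        names = [f"{n}#{i}" for i, n in enumerate(names)]
    rows = []
    for (i, a), (j, b) in combinations(enumerate(maps), 2):
        if run_spin:
            # canonical orientation (permute the lexically first map) so the
            # result is independent of input order
            if names[j] < names[i]:
                a, b = b, a
            res = spin_test(
                a, b, n_perm=n_perm, seed=_pair_seed(seed, names[i], names[j])
            )
            rho, p = res.rho_observed, res.p_value
        else:
            rho, p = spearman_rho(a, b), np.nan
        rows.append({"metric_a": names[i], "metric_b": names[j], "rho": rho, "p": p})
    report = pd.DataFrame(rows)
    if run_spin:
        q, rej = fdr_bh(report["p"].to_numpy(), alpha=alpha)
        report["q"] = q
        report["significant"] = rej
    else:
        report["q"] = np.nan
        report["significant"] = pd.NA
    return report


def report_matrix(report: pd.DataFrame) -> pd.DataFrame:
    """Square matrix with rho below the diagonal and FDR q above it."""
    names = sorted(set(report["metric_a"]) | set(report["metric_b"]))
    order = {n: i for i, n in enumerate(names)}
    mat = pd.DataFrame(np.nan, index=names, columns=names)
    for _, r in report.iterrows():
        i, j = order[r["metric_a"]], order[r["metric_b"]]
        lo, hi = (r["metric_a"], r["metric_b"]) if i < j else (r["metric_b"], r["metric_a"])
        mat.loc[hi, lo] = r["rho"]
        mat.loc[lo, hi] = r["q"]
    return mat
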