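"""Alpha/beta diversity, ordination and permutation tests.

Hand-written implementations of the standard community-ecology toolkit:
Shannon index and richness, Bray–Curtis dissimilarity, classical principal
coordinate analysis (Gower centering, negative eigenvalues reported rather
than corrected), PERMANOVA with a label-permutation null, and the
homogeneity-of-dispersion (betadisper) test of Anderson based on distances to
group centroids in PCoA space.

Permutation p-values use the "+1" convention
``p = (1 + #{permuted stat >= observed}) / (1 + n_perm)`` so that the minimum
attainable p at 999 permutations is 1.00e-03 and p can never be zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .profiles import CohortProfile


@dataclass
class DistanceMatrix:
    sample_ids: list
    d: np.ndarray  # square symmetric, zero diagonal, values in [0, 1]

    def __post_init__(self) -> None:
        d = np.asarray(self.d, dtype=float)
        if d.ndim != 2 or d.shape[0] != d.shape[1]:
            raise ValueError("distance matrix must be square")
        if len(self.sample_ids) != d.shape[0]:
            raise ValueError("sample_ids length mismatch")
        if not np.allclose(d, d.T, atol=1e-10):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(d), 0.0, atol=1e-10):
            raise ValueError("distance matrix diagonal must be zero")
        self.d = d

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.d, index=self.sample_ids, columns=self.sample_ids)


@dataclass
class PermutationTestResult:
    statistic: float
    p_value: float
    n_permutations: int
    seed: int


@dataclass
class PCoAResult:
    coordinates: np.ndarray  # samples x k (positive axes only)
    eigenvalues: np.ndarray  # all eigenvalues, descending (negatives included)
    proportion_explained: np.ndarray  # per retained axis, over positive eigs
    sample_ids: list


# ---------------------------------------------------------------------------
# Alpha diversity
# ---------------------------------------------------------------------------


def shannon(abundance_vector) -> float:
    """Shannon index H = -sum p_i ln p_i (nats) after renormalizing."""
    v = np.asarray(abundance_vector, dtype=float)
    if (v < 0).any():
        raise ValueError("negative abundances")
    total = v.sum()
    if total <= 0:
        raise ValueError("all-zero abundance vector")
    p = v[v > 0] / total
    return float(-(p * np.log(p)).sum())


def richness(abundance_vector, threshold: float = 0.0) -> int:
    """Number of features with abundance strictly above ``threshold``."""
    v = np.asarray(abundance_vector, dtype=float)
    if (v < 0).any():
        raise ValueError("negative abundances")
    return int((v > threshold).sum())


def kruskal_wallis(*groups) -> tuple[float, float]:
    """Tie-corrected Kruskal–Wallis H and its chi-square p (g-1 df).

    All-identical data yields (0, 1) by convention rather than an error.
    """
    if len(groups) < 2:
        raise ValueError("need >=2 groups")
    for g in groups:
        if len(g) < 1:
            raise ValueError("empty group")
    pooled = np.concatenate([np.asarray(g, dtype=float) for g in groups])
    if np.allclose(pooled, pooled[0]):
        return 0.0, 1.0
    h, p = stats.kruskal(*groups)
    return float(h), float(p)


# ---------------------------------------------------------------------------
# Beta diversity
# ---------------------------------------------------------------------------


def bray_curtis(profile: CohortProfile | pd.DataFrame | np.ndarray) -> DistanceMatrix:
    """Pairwise Bray–Curtis dissimilarity d = sum|x - y| / sum(x + y)."""
    if isinstance(profile, CohortProfile):
        x, ids = profile.values(), profile.sample_ids
    elif isinstance(profile, pd.DataFrame):
        x, ids = profile.to_numpy(dtype=float), list(profile.index)
    else:
        x = np.asarray(profile, dtype=float)
        ids = list(range(x.shape[0]))
    if (x < 0).any():
        raise ValueError("negative abundances")
    sums = x.sum(axis=1)
    if (sums <= 0).any():
        bad = [ids[i] for i in np.flatnonzero(sums <= 0)]
        raise ValueError(f"zero-sum sample(s) make Bray-Curtis undefined: {bad}")
    n = x.shape[0]
    d = np.zeros((n, n))
    for i in range(n):
        num = np.abs(x[i] - x).sum(axis=1)
        den = sums[i] + sums
        d[i] = num / den
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(ids, (d + d.T) / 2)


def _gower_center(d: np.ndarray) -> np.ndarray:
    a = -0.5 * d**2
    row = a.mean(axis=1, keepdims=True)
    col = a.mean(axis=0, keepdims=True)
    return a - row - col + a.mean()


def pcoa(dm: DistanceMatrix, k: int | None = None) -> PCoAResult:
    """Classical scaling of the Gower-centered matrix.

    Axes are ordered by descending eigenvalue; coordinates are returned only
    for positive-eigenvalue axes (up to ``k``); negative eigenvalues are
    reported but excluded from the proportion-explained denominator.
    """
    n = dm.d.shape[0]
    if k is not None and k <= 0:
        raise ValueError("k must be positive")
    b = _gower_center(dm.d)
    eigvals, eigvecs = np.linalg.eigh(b)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    tol = max(1e-10, abs(eigvals).max() * 1e-10)
    pos = eigvals > tol
    coords = eigvecs[:, pos] * np.sqrt(eigvals[pos])
    if k is not None:
        coords = coords[:, :k]
    denom = eigvals[pos].sum()
    prop = (eigvals[pos][: coords.shape[1]] / denom) if denom > 0 else np.zeros(coords.shape[1])
    return PCoAResult(coords, eigvals, prop, list(dm.sample_ids))


# ---------------------------------------------------------------------------
# Permutation tests
# ---------------------------------------------------------------------------


def _group_indices(labels) -> list[np.ndarray]:
    labels = np.asarray(labels)
    return [np.flatnonzero(labels == g) for g in pd.unique(labels)]


def _permanova_f(d2: np.ndarray, groups: list[np.ndarray], n: int) -> float:
    ss_total = d2.sum() / (2 * n)
    ss_within = 0.0
    for idx in groups:
        ss_within += d2[np.ix_(idx, idx)].sum() / (2 * len(idx))
    g = len(groups)
    ss_between = ss_total - ss_within
    if ss_within <= 0:
        raise ValueError("all within-group distances are zero; pseudo-F undefined")
    return (ss_between / (g - 1)) / (ss_within / (n - g))


def permanova(
    dm: DistanceMatrix, labels, n_perm: int = 999, seed: int = 0
) -> PermutationTestResult:
    """PERMANOVA pseudo-F with a uniform label-permutation null.

    pseudo-F = (SS_between/(g-1)) / (SS_within/(n-g)) from squared
    distances; p = (1 + #{perm F >= observed}) / (1 + n_perm).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    labels = np.asarray(labels)
    n = dm.d.shape[0]
    if len(labels) != n:
        raise ValueError("labels length mismatch")
    groups = _group_indices(labels)
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("need >=2 groups with >=2 samples each")
    d2 = dm.d**2
    f_obs = _permanova_f(d2, groups, n)
    rng = np.random.default_rng(seed)
    sizes = [len(g) for g in groups]
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        start = 0
        pgroups = []
        for s in sizes:
            pgroups.append(perm[start : start + s])
            start += s
        if _permanova_f(d2, pgroups, n) >= f_obs:
            count += 1
    p = (1 + count) / (1 + n_perm)
    return PermutationTestResult(float(f_obs), float(p), n_perm, seed)


def _centroid_distances(dm: DistanceMatrix, labels) -> tuple[np.ndarray, np.ndarray]:
    """Per-sample distance to own-group centroid in full PCoA space.

    Negative-eigenvalue ("imaginary") axes contribute with a minus sign in
    squared form, per Anderson's formulation; groups of size 1 are excluded.
    """
    labels = np.asarray(labels)
    b = _gower_center(dm.d)
    eigvals, eigvecs = np.linalg.eigh(b)
    tol = max(1e-10, abs(eigvals).max() * 1e-10) if eigvals.size else 1e-10
    pos, neg = eigvals > tol, eigvals < -tol
    xr = eigvecs[:, pos] * np.sqrt(eigvals[pos])
    xi = eigvecs[:, neg] * np.sqrt(-eigvals[neg])
    keep = np.ones(len(labels), dtype=bool)
    for g in pd.unique(labels):
        idx = np.flatnonzero(labels == g)
        if len(idx) < 2:
            warnings.warn(f"betadisper: group {g!r} has one sample, excluded")
            keep[idx] = False
    labels, xr, xi = labels[keep], xr[keep], xi[keep]
    dist = np.empty(len(labels))
    for g in pd.unique(labels):
        idx = np.flatnonzero(labels == g)
        cr = xr[idx].mean(axis=0)
        ci = xi[idx].mean(axis=0)
        d2 = ((xr[idx] - cr) ** 2).sum(axis=1) - ((xi[idx] - ci) ** 2).sum(axis=1)
        dist[idx] = np.sqrt(np.clip(d2, 0.0, None))
    return dist, labels


def _anova_f(values: np.ndarray, labels: np.ndarray) -> float:
    grand = values.mean()
    ss_between = ss_within = 0.0
    for g in pd.unique(labels):
        v = values[labels == g]
        ss_between += len(v) * (v.mean() - grand) ** 2
        ss_within += ((v - v.mean()) ** 2).sum()
    g, n = len(pd.unique(labels)), len(values)
    if ss_within <= 0:
        raise ValueError("all within-group centroid distances are zero; F undefined")
    return (ss_between / (g - 1)) / (ss_within / (n - g))


def betadisper(
    dm: DistanceMatrix, labels, n_perm: int = 999, seed: int = 0
) -> PermutationTestResult:
    """Homogeneity-of-dispersions test: one-way ANOVA F on distances to group
    centroids, with a permutation p obtained by shuffling the (fixed)
    distances across groups."""
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    dist, lab = _centroid_distances(dm, labels)
    if len(pd.unique(lab)) < 2:
        raise ValueError("need >=2 groups of size >=2")
    f_obs = _anova_f(dist, lab)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        if _anova_f(rng.permutation(dist), lab) >= f_obs:
            count += 1
    p = (1 + count) / (1 + n_perm)
    return PermutationTestResult(float(f_obs), float(p), n_perm, seed)


def write_distance_matrix(dm: DistanceMatrix, path) -> None:
    dm.to_frame().to_csv(path, sep="\t", index_label="sample_id")
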