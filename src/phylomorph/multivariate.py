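"""Ordination and group discrimination for Procrustes shape coordinates.

Implements PCA of tangent-space shape coordinates (relative warps with
uniform weighting), per-group total variance, equal-frequency ellipses of
fitted bivariate normals, canonical variate analysis with Mahalanobis and
Procrustes distances between feeding-type means, and pairwise two-group
permutation tests of those distances.

Rank control
------------
With 50 2D semi-landmarks the shape space has at most 2k-4 = 96
dimensions and the pooled within-group covariance of a desk-scale sample
is near-singular.  CVA therefore operates in the subspace of leading
principal components whose eigenvalue exceeds ``1e-9`` times the largest,
additionally capped at ``n - g - 1`` so the pooled within-group
covariance stays invertible; ``retained_dims`` overrides the rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, stats

from .procrustes import AlignedSample, mean_shape, procrustes_distance

__all__ = [
    "PcaResult",
    "CvaResult",
    "EllipseSpec",
    "PermutationResult",
    "pca",
    "group_total_variance",
    "equal_frequency_ellipse",
    "ellipse_contains",
    "cva",
    "permutation_test",
]

EIGENVALUE_RTOL = 1e-9  # relative eigenvalue threshold of the auto rank rule


@dataclass
class PcaResult:
    eigenvalues: np.ndarray          # (m,) nonincreasing, >= 0
    axes: np.ndarray                 # (m, d) orthonormal rows
    scores: np.ndarray               # (n, m) centered
    variance_proportions: np.ndarray # (m,) sums to 1
    mean: np.ndarray                 # (d,) grand mean of the input rows

    def project(self, flat: np.ndarray) -> np.ndarray:
        """Scores of arbitrary tangent-space vectors on the fitted axes."""
        return (np.atleast_2d(flat) - self.mean) @ self.axes.T


def pca(sample: AlignedSample | np.ndarray) -> PcaResult:
    """Principal components of the tangent-space covariance (divisor n-1).

    Retains ``m = min(n - 1, d)`` components, which always captures the
    full rank of the centered data, so the variance proportions sum to 1.
    """
    x = sample.tangent_coords if isinstance(sample, AlignedSample) else np.asarray(sample, float)
    n, d = x.shape
    if n < 3:
        raise ValueError(f"PCA needs n >= 3 specimens, got {n}")
    mean = x.mean(axis=0)
    xc = x - mean
    m = min(n - 1, d)
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    eig = s ** 2 / (n - 1)
    eig, vt, u, s = eig[:m], vt[:m], u[:, :m], s[:m]
    scores = u * s
    total = eig.sum()
    props = eig / total if total > 0 else np.zeros_like(eig)
    return PcaResult(eigenvalues=eig, axes=vt, scores=scores,
                     variance_proportions=props, mean=mean)


def group_total_variance(sample: AlignedSample | np.ndarray,
                         members: np.ndarray | list) -> float:
    """Trace of the subset's tangent-coordinate covariance (divisor n-1).

    Equals the sum of the eigenvalues of a PCA restricted to the subset;
    the per-group "total variance" statistic.
    """
    x = sample.tangent_coords if isinstance(sample, AlignedSample) else np.asarray(sample, float)
    sub = x[np.asarray(members)]
    if sub.shape[0] < 2:
        raise ValueError("group_total_variance needs >= 2 members")
    xc = sub - sub.mean(axis=0)
    return float(np.sum(xc * xc) / (sub.shape[0] - 1))


@dataclass
class EllipseSpec:
    """Equal-frequency contour of a fitted bivariate normal."""

    center: np.ndarray      # (2,)
    semi_axes: np.ndarray   # (2,) major, minor
    angle: float            # radians, orientation of the major axis
    coverage: float = 0.90


def equal_frequency_ellipse(scores: np.ndarray, coverage: float = 0.90) -> EllipseSpec:
    """Fit the equal-frequency ellipse containing ``coverage`` of a
    bivariate normal: center at the mean, axes from the covariance
    eigendecomposition scaled by sqrt(chi2.ppf(coverage, df=2))."""
    pts = np.asarray(scores, float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
        raise ValueError("need an (n >= 3, 2) score matrix")
    if not 0 < coverage < 1:
        raise ValueError("coverage must be in (0, 1)")
    center = pts.mean(axis=0)
    cov = np.cov(pts, rowvar=False, ddof=1)
    eigval, eigvec = np.linalg.eigh(cov)
    if eigval[0] <= 1e-12 * max(eigval[1], 1e-300):
        raise ValueError("degenerate (singular) score covariance")
    q = stats.chi2.ppf(coverage, df=2)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    semi = np.sqrt(eigval * q)
    angle = float(np.arctan2(eigvec[1, 0], eigvec[0, 0]))
    return EllipseSpec(center=center, semi_axes=semi, angle=angle,
                       coverage=coverage)


def ellipse_contains(spec: EllipseSpec, pts: np.ndarray) -> np.ndarray:
    """Boolean mask: which points fall inside the ellipse."""
    c, s = np.cos(spec.angle), np.sin(spec.angle)
    rot = np.array([[c, s], [-s, c]])
    local = (np.atleast_2d(pts) - spec.center) @ rot.T
    return np.sum((local / spec.semi_axes) ** 2, axis=1) <= 1.0


# ---------------------------------------------------------------------------
# CVA

@dataclass
class CvaResult:
    group_labels: list
    canonical_axes: np.ndarray            # (n_axes, d) in tangent space
    mahalanobis: np.ndarray               # (g, g) symmetric, zero diagonal
    procrustes_d: np.ndarray | None       # (g, g) or None for matrix input
    retained_dims: int
    pc_basis: np.ndarray                  # (r, d) reduction basis
    grand_mean: np.ndarray                # (d,)
    group_means_reduced: np.ndarray       # (g, r)
    pooled_cov: np.ndarray                # (r, r) within-group, divisor n-g
    p_mahalanobis: np.ndarray | None = None
    p_procrustes: np.ndarray | None = None
    n_permutations: int = 0

    def mahalanobis_to_groups(self, flat: np.ndarray) -> np.ndarray:
        """Mahalanobis distances of out-of-sample tangent vectors to each
        group mean, in the retained subspace with the pooled covariance."""
        z = (np.atleast_2d(flat) - self.grand_mean) @ self.pc_basis.T
        diffs = z[:, None, :] - self.group_means_reduced[None, :, :]
        sol = np.linalg.solve(self.pooled_cov,
                              diffs.reshape(-1, diffs.shape[-1]).T).T
        d2 = np.sum(sol.reshape(diffs.shape) * diffs, axis=-1)
        return np.sqrt(np.maximum(d2, 0.0))


def _resolve_groups(labels) -> tuple[list, list[np.ndarray]]:
    labels = list(labels)
    order: list = []
    for l in labels:
        if l not in order:
            order.append(l)
    idx = [np.array([i for i, l in enumerate(labels) if l == g]) for g in order]
    return order, idx


def _auto_rank(eigenvalues: np.ndarray, n: int, g: int) -> int:
    r = int(np.sum(eigenvalues > EIGENVALUE_RTOL * eigenvalues[0]))
    return max(1, min(r, n - g - 1))


def _pooled_cov(z: np.ndarray, group_idx: list[np.ndarray]) -> np.ndarray:
    n, g = z.shape[0], len(group_idx)
    scatter = np.zeros((z.shape[1], z.shape[1]))
    for idx in group_idx:
        zc = z[idx] - z[idx].mean(axis=0)
        scatter += zc.T @ zc
    return scatter / (n - g)


def cva(sample: AlignedSample | np.ndarray, labels,
        retained_dims: int | str = "auto") -> CvaResult:
    """Canonical variate analysis of shape coordinates grouped by label.

    The tangent coordinates are reduced to the leading principal
    components (see module docstring for the rank rule); canonical axes
    solve the generalized eigenproblem of between-group versus pooled
    within-group covariance; Mahalanobis distances between group means use
    the pooled within-group covariance in the reduced space.  When
    ``sample`` is an :class:`AlignedSample`, Procrustes distances between
    the group mean shapes are computed in full shape space as well.
    """
    is_aligned = isinstance(sample, AlignedSample)
    x = sample.tangent_coords if is_aligned else np.asarray(sample, float)
    order, group_idx = _resolve_groups(labels)
    g, n = len(order), x.shape[0]
    if g < 2:
        raise ValueError("CVA needs at least 2 groups")
    for lab, idx in zip(order, group_idx):
        if len(idx) < 2:
            raise ValueError(f"group {lab!r} has fewer than 2 members")

    mean = x.mean(axis=0)
    xc = x - mean
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    eig = s ** 2 / max(n - 1, 1)
    if retained_dims == "auto":
        r = _auto_rank(eig, n, g)
    else:
        r = int(retained_dims)
        rank = int(np.sum(s > 1e-12 * s[0]))
        if not 1 <= r <= rank:
            raise ValueError(f"retained_dims={r} outside [1, rank={rank}]")
        if n <= r + g:
            raise ValueError(f"need n > retained_dims + groups ({n} <= {r}+{g})")
    basis = vt[:r]                      # (r, d)
    z = xc @ basis.T                    # (n, r)

    mu = np.stack([z[idx].mean(axis=0) for idx in group_idx])
    w = _pooled_cov(z, group_idx)

    # Mahalanobis distances between group means
    maha = np.zeros((g, g))
    for i in range(g):
        for j in range(i + 1, g):
            diff = mu[i] - mu[j]
            d2 = diff @ linalg.solve(w, diff, assume_a="pos")
            maha[i, j] = maha[j, i] = np.sqrt(max(d2, 0.0))

    # canonical axes: generalized eigenproblem B v = lambda W v
    zbar = z.mean(axis=0)
    b = np.zeros_like(w)
    for idx in group_idx:
        dm = z[idx].mean(axis=0) - zbar
        b += len(idx) * np.outer(dm, dm)
    b /= max(g - 1, 1)
    evals, evecs = linalg.eigh(b, w)
    take = np.argsort(evals)[::-1][: min(g - 1, r)]
    canon = (basis.T @ evecs[:, take]).T  # back-projected to tangent space

    proc = None
    if is_aligned:
        means = [mean_shape([sample.configs[i] for i in idx],
                            specimen_id=str(lab))
                 for lab, idx in zip(order, group_idx)]
        proc = np.zeros((g, g))
        for i in range(g):
            for j in range(i + 1, g):
                proc[i, j] = proc[j, i] = procrustes_distance(means[i], means[j])

    return CvaResult(group_labels=order, canonical_axes=canon,
                     mahalanobis=maha, procrustes_d=proc, retained_dims=r,
                     pc_basis=basis, grand_mean=mean,
                     group_means_reduced=mu, pooled_cov=w)


# ---------------------------------------------------------------------------
# Permutation tests

@dataclass
class PermutationResult:
    group_labels: list
    statistic: str
    observed: np.ndarray   # (g, g)
    p_values: np.ndarray   # (g, g); 1.0 on the diagonal by convention
    n_permutations: int


def _pair_mahalanobis(za: np.ndarray, zb: np.ndarray) -> float:
    na, nb = len(za), len(zb)
    da = za - za.mean(axis=0)
    db = zb - zb.mean(axis=0)
    w = (da.T @ da + db.T @ db) / (na + nb - 2)
    diff = za.mean(axis=0) - zb.mean(axis=0)
    d2 = diff @ linalg.solve(w, diff, assume_a="pos")
    return float(np.sqrt(max(d2, 0.0)))


def _pair_procrustes(ca: np.ndarray, cb: np.ndarray) -> float:
    from .procrustes import procrustes_distance_coords
    return procrustes_distance_coords(ca.mean(axis=0), cb.mean(axis=0))


def permutation_test(sample: AlignedSample | np.ndarray, labels,
                     statistic: str = "mahalanobis", n_perm: int = 10000,
                     seed: int | None = None,
                     retained_dims: int | str = "auto") -> PermutationResult:
    """Pairwise two-group permutation tests of between-group distance.

    For each group pair the pooled labels are randomly reassigned with
    group sizes preserved, ``n_perm`` times; the p-value is
    ``(#{permuted statistic >= observed} + 1) / (n_perm + 1)``, so p is
    never 0 and ties count toward p.  The Mahalanobis statistic is fully
    recomputed per permutation (two-group means and pooled covariance) in
    a principal-component subspace of the pair's pooled data, capped so
    the covariance stays invertible; the Procrustes statistic is the
    distance between the permuted group mean shapes.
    """
    if statistic not in {"mahalanobis", "procrustes"}:
        raise ValueError(f"unknown statistic {statistic!r}")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    is_aligned = isinstance(sample, AlignedSample)
    if statistic == "procrustes" and not is_aligned:
        raise ValueError("procrustes statistic needs an AlignedSample")
    x = sample.tangent_coords if is_aligned else np.asarray(sample, float)
    order, group_idx = _resolve_groups(labels)
    g = len(order)
    rng = np.random.default_rng(seed)
    observed = np.zeros((g, g))
    pvals = np.eye(g)

    coords = (np.stack([c.coords for c in sample.configs])
              if is_aligned else None)

    for i in range(g):
        for j in range(i + 1, g):
            pool = np.concatenate([group_idx[i], group_idx[j]])
            na = len(group_idx[i])
            npool = len(pool)
            if statistic == "mahalanobis":
                xp = x[pool]
                xp = xp - xp.mean(axis=0)
                u, s, vt = np.linalg.svd(xp, full_matrices=False)
                if retained_dims == "auto":
                    # keep >= 2 within-group dof per retained dimension so the
                    # permuted pooled covariance stays well conditioned
                    r = min(_auto_rank(s ** 2 / max(npool - 1, 1), npool, 2),
                            max(npool // 2 - 1, 1))
                else:
                    r = min(int(retained_dims), npool - 3)
                z = xp @ vt[:r].T
                obs = _pair_mahalanobis(z[:na], z[na:])
                count = 0
                for _ in range(n_perm):
                    perm = rng.permutation(npool)
                    stat = _pair_mahalanobis(z[perm[:na]], z[perm[na:]])
                    if stat >= obs:
                        count += 1
            else:
                cp = coords[pool]
                obs = _pair_procrustes(cp[:na], cp[na:])
                count = 0
                for _ in range(n_perm):
                    perm = rng.permutation(npool)
                    stat = _pair_procrustes(cp[perm[:na]], cp[perm[na:]])
                    if stat >= obs:
                        count += 1
            observed[i, j] = observed[j, i] = obs
            p = (count + 1) / (n_perm + 1)
            pvals[i, j] = pvals[j, i] = p
    return PermutationResult(group_labels=order, statistic=statistic,
                             observed=observed, p_values=pvals,
                             n_permutations=n_perm)
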