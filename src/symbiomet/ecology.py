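"""Distance-matrix ecology on the presence/absence matrix.

These routines are implemented here in full (rather than wrapping an
ecology package) so that every statistic is an auditable formula:

* Jaccard distance between family sets,
* non-metric multidimensional scaling (NMDS) minimising Kruskal stress-1
  with isotonic (pool-adjacent-violators) disparities and Guttman updates,
* ANOSIM: R = (mean between-group rank - mean within-group rank) / (M/2),
  with midranks for ties and a label-permutation p-value,
* one-way PERMANOVA: pseudo-F from the partition of squared distances,
  R^2 = SS_between / SS_total, label-permutation p-value.

Permutation p-values use the (count + 1) / (permutations + 1) estimator.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.isotonic import IsotonicRegression

__all__ = [
    "jaccard_distance",
    "OrdinationResult",
    "nmds",
    "AnosimResult",
    "anosim",
    "PermanovaResult",
    "permanova",
]


# ---------------------------------------------------------------------------
# Jaccard
# ---------------------------------------------------------------------------

def jaccard_distance(matrix: pd.DataFrame) -> pd.DataFrame:
    """1 - |intersection| / |union| over family sets, per sample pair.

    Two all-zero samples have no defined Jaccard similarity; their distance
    is set to 0 with a warning (they are identical in content).
    """
    if len(matrix) < 2:
        raise ValueError("need at least two samples")
    x = matrix.to_numpy(dtype=float)
    inter = x @ x.T
    sums = x.sum(axis=1)
    union = sums[:, None] + sums[None, :] - inter
    with np.errstate(divide="ignore", invalid="ignore"):
        d = 1.0 - inter / union
    if np.any(union == 0):
        warnings.warn("all-zero sample pair(s): distance set to 0", stacklevel=2)
        d[union == 0] = 0.0
    np.fill_diagonal(d, 0.0)
    return pd.DataFrame(d, index=matrix.index, columns=matrix.index)


def _as_square(dist: pd.DataFrame | np.ndarray) -> tuple[np.ndarray, list[str]]:
    if isinstance(dist, pd.DataFrame):
        labels = [str(x) for x in dist.index]
        m = dist.to_numpy(dtype=float)
    else:
        m = np.asarray(dist, dtype=float)
        labels = [str(i) for i in range(len(m))]
    if m.shape[0] != m.shape[1] or not np.allclose(m, m.T) or not np.allclose(np.diag(m), 0):
        raise ValueError("expected a symmetric distance matrix with zero diagonal")
    return m, labels


# ---------------------------------------------------------------------------
# NMDS
# ---------------------------------------------------------------------------

@dataclass
class OrdinationResult:
    coordinates: pd.DataFrame  # samples x k, centred at the origin
    stress: float              # Kruskal stress-1
    n_restarts: int
    seed: int


def _config_distances(x: np.ndarray) -> np.ndarray:
    diff = x[:, None, :] - x[None, :, :]
    return np.sqrt((diff**2).sum(axis=-1))


def _classical_mds(d: np.ndarray, k: int) -> np.ndarray:
    n = len(d)
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    vals, vecs = np.linalg.eigh(b)
    order = np.argsort(vals)[::-1][:k]
    lam = np.clip(vals[order], 0.0, None)
    return vecs[:, order] * np.sqrt(lam)


def nmds(
    dist: pd.DataFrame | np.ndarray,
    k: int = 2,
    n_restarts: int = 20,
    max_iter: int = 500,
    tol: float = 1e-7,
    seed: int = 0,
) -> OrdinationResult:
    """Non-metric MDS minimising Kruskal stress-1.

    Each restart starts from the classical (metric) MDS solution plus seeded
    jitter and alternates isotonic regression of the configuration distances
    on the dissimilarity ranks with Guttman-transform updates.  The best
    configuration over restarts is returned, centred at the origin.
    """
    d, labels = _as_square(dist)
    n = len(d)
    if k >= n:
        raise ValueError("k must be below the number of samples")
    iu = np.triu_indices(n, 1)
    diss = d[iu]
    order = np.argsort(diss, kind="stable")
    rng = np.random.default_rng(seed)
    base = _classical_mds(d, k)
    scale = np.abs(base).max() or 1.0
    best_x, best_stress = None, np.inf
    iso = IsotonicRegression(increasing=True)
    for restart in range(n_restarts):
        x = base + (0.0 if restart == 0 else rng.normal(0, 0.1 * scale, size=base.shape))
        prev = np.inf
        for _ in range(max_iter):
            dhat = _config_distances(x)
            dh = dhat[iu]
            # disparities: isotonic fit of configuration distances vs rank order
            disp = np.empty_like(dh)
            disp[order] = iso.fit_transform(np.arange(len(dh)), dh[order])
            denom = float((dh**2).sum())
            stress = math.sqrt(((dh - disp) ** 2).sum() / denom) if denom > 0 else 0.0
            if prev - stress < tol:
                break
            prev = stress
            # Guttman transform towards the disparities
            full = np.zeros_like(dhat)
            full[iu] = disp
            full = full + full.T
            with np.errstate(divide="ignore", invalid="ignore"):
                ratio = np.where(dhat > 0, full / dhat, 0.0)
            b = -ratio
            np.fill_diagonal(b, ratio.sum(axis=1))
            x = (b @ x) / n
            x -= x.mean(axis=0)
        if stress < best_stress:
            best_stress, best_x = stress, x.copy()
    best_x -= best_x.mean(axis=0)
    coords = pd.DataFrame(best_x, index=labels, columns=[f"NMDS{i + 1}" for i in range(k)])
    return OrdinationResult(
        coordinates=coords, stress=float(best_stress), n_restarts=n_restarts, seed=seed
    )


# ---------------------------------------------------------------------------
# group machinery shared by ANOSIM / PERMANOVA
# ---------------------------------------------------------------------------

def _check_groups(labels: list[str], groups) -> np.ndarray:
    g = np.asarray([groups[lab] if isinstance(groups, dict) else groups[i]
                    for i, lab in enumerate(labels)])
    values, counts = np.unique(g, return_counts=True)
    if len(values) < 2:
        raise ValueError("need at least two groups")
    if counts.min() < 2:
        small = values[counts < 2].tolist()
        raise ValueError(f"groups of size 1 not allowed: {small}")
    return g


def _permutations(n: int, n_permutations: int, rng: np.random.Generator) -> np.ndarray:
    return np.array([rng.permutation(n) for _ in range(n_permutations)])


def _exhaustive_label_orders(g: np.ndarray) -> np.ndarray | None:
    """All distinct arrangements of the label multiset (None when too many)."""
    n = len(g)
    values, counts = np.unique(g, return_counts=True)
    total = math.factorial(n)
    for c in counts:
        total //= math.factorial(int(c))
    if total > 200_000:
        return None
    seen = sorted(set(itertools.permutations(g.tolist())))
    idx = {v: k for k, v in enumerate(values.tolist())}
    return np.array([[idx[v] for v in perm] for perm in seen])


# ---------------------------------------------------------------------------
# ANOSIM
# ---------------------------------------------------------------------------

@dataclass
class AnosimResult:
    r: float
    p_value: float
    n_permutations: int
    exhaustive: bool = False


def _anosim_r(within: np.ndarray, ranks: np.ndarray, m: int) -> float:
    rw = ranks[within].mean()
    rb = ranks[~within].mean()
    return float((rb - rw) / (m / 2.0))


def anosim(
    dist: pd.DataFrame | np.ndarray,
    groups,
    n_permutations: int = 999,
    seed: int = 0,
    exhaustive: bool = False,
) -> AnosimResult:
    """Clarke's analysis of similarities with a label-permutation test.

    ``groups`` maps sample label -> group (dict) or is a sequence aligned
    with the matrix order.  ``exhaustive=True`` enumerates every distinct
    label assignment instead of sampling (small n only).
    """
    d, labels = _as_square(dist)
    g = _check_groups(labels, groups)
    n = len(d)
    iu = np.triu_indices(n, 1)
    ranks = rankdata(d[iu])  # midranks for ties
    m = len(ranks)
    same = (g[iu[0]] == g[iu[1]])
    observed = _anosim_r(same, ranks, m)

    if exhaustive:
        orders = _exhaustive_label_orders(g)
        if orders is None:
            raise ValueError("too many distinct label assignments for exhaustive mode")
        count = 0
        for row in orders:
            same_p = row[iu[0]] == row[iu[1]]
            if _anosim_r(same_p, ranks, m) >= observed - 1e-12:
                count += 1
        return AnosimResult(
            r=observed, p_value=count / len(orders), n_permutations=len(orders), exhaustive=True
        )

    rng = np.random.default_rng(seed)
    perms = _permutations(n, n_permutations, rng)
    gp = g[perms]  # (n_permutations, n)
    same_p = gp[:, iu[0]] == gp[:, iu[1]]  # (n_permutations, m)
    rw = np.where(same_p, ranks, 0.0).sum(axis=1) / same_p.sum(axis=1)
    rb = np.where(~same_p, ranks, 0.0).sum(axis=1) / (~same_p).sum(axis=1)
    r_perm = (rb - rw) / (m / 2.0)
    count = int(np.sum(r_perm >= observed - 1e-12))
    p = (count + 1) / (n_permutations + 1)
    return AnosimResult(r=observed, p_value=p, n_permutations=n_permutations)


# ---------------------------------------------------------------------------
# PERMANOVA
# ---------------------------------------------------------------------------

@dataclass
class PermanovaResult:
    pseudo_f: float
    r_squared: float
    p_value: float
    n_permutations: int


def _permanova_stats(d2: np.ndarray, g: np.ndarray) -> tuple[float, float]:
    """(pseudo-F, R^2) from squared distances and group labels."""
    n = len(d2)
    iu = np.triu_indices(n, 1)
    ss_total = d2[iu].sum() / n
    values = np.unique(g)
    ss_within = 0.0
    for v in values:
        members = np.where(g == v)[0]
        if len(members) > 1:
            sub = d2[np.ix_(members, members)]
            ss_within += sub[np.triu_indices(len(members), 1)].sum() / len(members)
    ss_between = ss_total - ss_within
    a = len(values)
    if ss_total == 0:
        return float("nan"), float("nan")
    f = (ss_between / (a - 1)) / (ss_within / (n - a)) if ss_within > 0 else float("inf")
    return float(f), float(ss_between / ss_total)


def permanova(
    dist: pd.DataFrame | np.ndarray,
    groups,
    n_permutations: int = 999,
    seed: int = 0,
) -> PermanovaResult:
    """One-way permutational multivariate ANOVA on a distance matrix.

    A degenerate all-identical input (SS_total = 0) yields NaN statistics and
    p-value 1.0.  Composite designs (e.g. a genus x host interaction) are
    expressed by passing the composite label as the grouping factor.
    """
    d, labels = _as_square(dist)
    g = _check_groups(labels, groups)
    d2 = d**2
    observed, r2 = _permanova_stats(d2, g)
    if math.isnan(observed):
        warnings.warn("all distances are zero: PERMANOVA undefined", stacklevel=2)
        return PermanovaResult(
            pseudo_f=float("nan"), r_squared=float("nan"), p_value=1.0,
            n_permutations=n_permutations,
        )
    rng = np.random.default_rng(seed)
    n = len(d)
    perms = _permutations(n, n_permutations, rng)
    gp = g[perms]  # (P, n) permuted labels
    iu = np.triu_indices(n, 1)
    ss_total = d2[iu].sum() / n
    values = np.unique(g)
    a = len(values)
    ss_within = np.zeros(n_permutations)
    for v in values:
        m_v = (gp == v).astype(float)  # (P, n)
        n_v = m_v.sum(axis=1)
        pair_sum = np.einsum("pi,ij,pj->p", m_v, d2, m_v) / 2.0
        ss_within += np.where(n_v > 0, pair_sum / np.maximum(n_v, 1), 0.0)
    ss_between = ss_total - ss_within
    with np.errstate(divide="ignore", invalid="ignore"):
        f_perm = (ss_between / (a - 1)) / (ss_within / (n - a))
    count = int(np.sum(f_perm >= observed - 1e-12))
    p = (count + 1) / (n_permutations + 1)
    return PermanovaResult(
        pseudo_f=observed, r_squared=r2, p_value=p, n_permutations=n_permutations
    )
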