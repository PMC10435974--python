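"""Statistical surface: ln(x+1), one-way ANOVA, Duncan's MRT, PCoA, Mantel.

The treatment-comparison workflow is: ln(x+1)-transform abundances, one-way
ANOVA per variable, then Duncan's new multiple range test at P < 0.05 to
assign letter groups to treatment means.  Community structure is compared by
principal coordinates analysis (PCoA) of a Bray-Curtis dissimilarity matrix,
and community-environment association by the permutation Mantel test between
distance matrices.

Duncan's test compares the range of every stretch of p ordered means against
the least significant range

    R_p = q(1 - alpha_p; p, df_within) * sqrt(MS_within / n),

where q is the studentized-range quantile and alpha_p = 1 - (1-alpha)^(p-1)
is Duncan's protection level (so for p = 2 the decision coincides with
Fisher's LSD).  Quantiles come from ``scipy.stats.studentized_range`` rather
than printed tables; for unequal group sizes n is the harmonic mean.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Mapping, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats as sps

from .community import CommunityTable

__all__ = [
    "ln_transform",
    "AnovaResult",
    "one_way_anova",
    "duncan_mrt",
    "bray_curtis",
    "euclidean_distance",
    "OrdinationResult",
    "pcoa",
    "MantelResult",
    "mantel_test",
]

ArrayLike = Union[np.ndarray, pd.DataFrame]


def ln_transform(x):
    """ln(x + 1), the variance-stabilising transform for count-like abundances."""
    arr = np.asarray(x, dtype=float)
    if np.any(arr < 0):
        raise ValueError("ln(x+1) transform expects non-negative abundances")
    out = np.log1p(arr)
    return float(out) if np.isscalar(x) or arr.ndim == 0 else out


# ---------------------------------------------------------------------------
# ANOVA + Duncan

@dataclass
class AnovaResult:
    F: float
    df_between: int
    df_within: int
    p: float
    group_means: dict[str, float]
    group_sizes: dict[str, int]
    ms_within: float


def one_way_anova(groups: Mapping[str, Sequence[float]]) -> AnovaResult:
    """Classical fixed-effects one-way ANOVA, F = MS_between / MS_within."""
    labels = list(groups)
    if len(labels) < 2:
        raise ValueError("need >= 2 groups")
    arrs = {g: np.asarray(groups[g], dtype=float) for g in labels}
    if any(a.size < 2 for a in arrs.values()):
        raise ValueError("every group needs >= 2 values")
    if any(np.isnan(a).any() for a in arrs.values()):
        raise ValueError("NaN values in ANOVA input; drop undefined entries first")
    N = sum(a.size for a in arrs.values())
    k = len(labels)
    grand = sum(a.sum() for a in arrs.values()) / N
    ssb = sum(a.size * (a.mean() - grand) ** 2 for a in arrs.values())
    ssw = sum(((a - a.mean()) ** 2).sum() for a in arrs.values())
    df_b, df_w = k - 1, N - k
    msw = ssw / df_w
    if msw == 0:
        raise ValueError("zero within-group variance everywhere; F undefined")
    F = (ssb / df_b) / msw
    return AnovaResult(
        F=float(F),
        df_between=df_b,
        df_within=df_w,
        p=float(sps.f.sf(F, df_b, df_w)),
        group_means={g: float(a.mean()) for g, a in arrs.items()},
        group_sizes={g: int(a.size) for g, a in arrs.items()},
        ms_within=float(msw),
    )


@lru_cache(maxsize=1024)
def _duncan_q(p: int, df: int, alpha: float) -> float:
    alpha_p = 1.0 - (1.0 - alpha) ** (p - 1)
    return float(sps.studentized_range.ppf(1.0 - alpha_p, p, df))


def duncan_mrt(
    groups: Mapping[str, Sequence[float]],
    alpha: float = 0.05,
    anova: AnovaResult | None = None,
) -> dict[str, str]:
    """Duncan's multiple range test: letter display over group means.

    Groups sharing a letter do not differ significantly at *alpha*; letters
    run 'a', 'b', ... down the descending-mean order.  A stretch of means
    whose range falls below its least significant range R_p is declared
    homogeneous, and (protection rule) no pair inside a homogeneous stretch
    is ever declared different.
    """
    res = anova if anova is not None else one_way_anova(groups)
    labels = sorted(res.group_means, key=lambda g: -res.group_means[g])
    means = [res.group_means[g] for g in labels]
    k = len(labels)
    sizes = list(res.group_sizes.values())
    n_h = len(sizes) / sum(1.0 / n for n in sizes)  # harmonic mean
    se = math.sqrt(res.ms_within / n_h)

    # pairs inside any stretch whose range is below R_p are non-significant
    nonsig: set[tuple[int, int]] = set()
    for span in range(k - 1, 0, -1):
        for i in range(0, k - span):
            j = i + span
            if (i, j) in nonsig:
                continue
            if means[i] - means[j] <= _duncan_q(span + 1, res.df_within, alpha) * se:
                for a in range(i, j + 1):
                    for b in range(a + 1, j + 1):
                        nonsig.add((a, b))

    # maximal homogeneous stretches -> letters
    intervals: list[tuple[int, int]] = []
    for i in range(k):
        j = i
        while j + 1 < k and (i, j + 1) in nonsig:
            j += 1
        if not any(a <= i and j <= b for a, b in intervals):
            intervals.append((i, j))
    letters = {g: "" for g in labels}
    for idx, (a, b) in enumerate(intervals):
        ch = chr(ord("a") + idx)
        for pos in range(a, b + 1):
            letters[labels[pos]] += ch
    return letters


# ---------------------------------------------------------------------------
# Distances & ordination

def _sample_matrix(data: Union[CommunityTable, ArrayLike]) -> tuple[np.ndarray, list[str]]:
    if isinstance(data, CommunityTable):
        df = data.to_frame().T  # samples x genera
        return df.to_numpy(dtype=float), list(df.index)
    if isinstance(data, pd.DataFrame):
        return data.to_numpy(dtype=float), [str(i) for i in data.index]
    arr = np.asarray(data, dtype=float)
    return arr, [str(i) for i in range(arr.shape[0])]


def bray_curtis(data: Union[CommunityTable, ArrayLike]) -> pd.DataFrame:
    """Bray-Curtis dissimilarity d(i,j) = sum|x_i - x_j| / sum(x_i + x_j).

    *data* is a :class:`CommunityTable` or a samples x variables matrix.
    A pair of all-zero samples has an undefined distance (NaN).
    """
    X, ids = _sample_matrix(data)
    if X.shape[0] < 2:
        raise ValueError("need >= 2 samples")
    if np.any(X < 0):
        raise ValueError("Bray-Curtis requires non-negative data")
    num = np.abs(X[:, None, :] - X[None, :, :]).sum(axis=2)
    den = (X[:, None, :] + X[None, :, :]).sum(axis=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        D = np.where(den > 0, num / np.where(den > 0, den, 1.0), np.nan)
    np.fill_diagonal(D, 0.0)
    return pd.DataFrame(D, index=ids, columns=ids)


def euclidean_distance(
    data: ArrayLike, standardize: bool = True
) -> pd.DataFrame:
    """Euclidean distances between samples (rows), optionally on z-scored columns.

    The standard way to turn a covariate table (soil chemistry, plant biomass)
    into a distance matrix for the Mantel test.
    """
    X, ids = _sample_matrix(data)
    if standardize:
        sd = X.std(axis=0, ddof=1)
        X = (X - X.mean(axis=0)) / np.where(sd > 0, sd, 1.0)
    diff = X[:, None, :] - X[None, :, :]
    D = np.sqrt((diff**2).sum(axis=2))
    return pd.DataFrame(D, index=ids, columns=ids)


def _check_distance(D: ArrayLike, name: str) -> tuple[np.ndarray, list[str]]:
    ids = list(map(str, D.index)) if isinstance(D, pd.DataFrame) else None
    M = np.asarray(D, dtype=float)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise ValueError(f"{name} must be square")
    if not np.allclose(M, M.T, equal_nan=True):
        raise ValueError(f"{name} must be symmetric")
    if not np.allclose(np.diag(M), 0.0):
        raise ValueError(f"{name} must have a zero diagonal")
    if ids is None:
        ids = [str(i) for i in range(M.shape[0])]
    return M, ids


@dataclass
class OrdinationResult:
    coordinates: pd.DataFrame  # samples x retained axes
    eigenvalues: np.ndarray  # all eigenvalues, descending
    explained: np.ndarray  # fraction of positive-eigenvalue variation per axis


def pcoa(D: ArrayLike, n_axes: int | None = None, lingoes: bool = False) -> OrdinationResult:
    """Principal coordinates analysis (classical metric MDS).

    The squared distance matrix is Gower double-centered,
    B = -0.5 * J D^2 J with J = I - 11'/n, and eigendecomposed.  Coordinates
    are eigenvectors scaled by sqrt of their (positive) eigenvalues; negative
    eigenvalues — possible for semimetric dissimilarities like Bray-Curtis —
    are reported but excluded from coordinates, and explained fractions are
    taken over the positive eigenvalues only.  ``lingoes=True`` applies the
    Lingoes correction (adds -2*lambda_min to off-diagonal squared distances)
    to remove negative eigenvalues first.
    """
    M, ids = _check_distance(D, "distance matrix")
    if np.isnan(M).any():
        raise ValueError("distance matrix contains NaN")
    n = M.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n

    def decompose(sq):
        B = -0.5 * J @ sq @ J
        vals, vecs = np.linalg.eigh((B + B.T) / 2)
        order = np.argsort(vals)[::-1]
        return vals[order], vecs[:, order]

    vals, vecs = decompose(M**2)
    if lingoes and vals[-1] < -1e-12:
        c = -vals[-1]
        sq = M**2 + 2.0 * c
        np.fill_diagonal(sq, 0.0)
        vals, vecs = decompose(sq)
    pos = vals > max(1e-12, 1e-10 * abs(vals[0]))
    lam = vals[pos]
    coords = vecs[:, pos] * np.sqrt(lam)
    explained = lam / lam.sum() if lam.sum() > 0 else lam
    if n_axes is not None:
        coords = coords[:, :n_axes]
        explained = explained[:n_axes]
    axes = [f"PCo{i + 1}" for i in range(coords.shape[1])]
    return OrdinationResult(
        coordinates=pd.DataFrame(coords, index=ids, columns=axes),
        eigenvalues=vals,
        explained=explained,
    )


# ---------------------------------------------------------------------------
# Mantel test

@dataclass
class MantelResult:
    r: float
    p: float
    n_perm: int
    method: str


def _triangle_ranks(vals: np.ndarray, method: str) -> np.ndarray:
    if method == "spearman":
        return sps.rankdata(vals, axis=-1)
    return vals


def mantel_test(
    D1: ArrayLike,
    D2: ArrayLike,
    method: str = "spearman",
    n_perm: int = 999,
    seed: int | np.random.Generator | None = None,
) -> MantelResult:
    """Permutation Mantel test of association between two distance matrices.

    r correlates the lower-triangle entries (Spearman by default, Pearson
    optional); the p-value permutes the object labels of the second matrix:
    p = (1 + #{r_perm >= r_obs}) / (n_perm + 1), so its floor is
    1/(n_perm+1).
    """
    if method not in ("spearman", "pearson"):
        raise ValueError(f"unsupported method: {method}")
    M1, _ = _check_distance(D1, "D1")
    M2, _ = _check_distance(D2, "D2")
    n = M1.shape[0]
    if M2.shape[0] != n:
        raise ValueError("distance matrices are not conformable")
    if n < 4:
        raise ValueError("need >= 4 objects for a meaningful Mantel test")
    iu = np.triu_indices(n, k=1)
    t1 = _triangle_ranks(M1[iu], method)
    t2 = M2[iu]

    def corr(y: np.ndarray) -> np.ndarray:
        yr = _triangle_ranks(y, method)
        xc = t1 - t1.mean()
        yc = yr - yr.mean(axis=-1, keepdims=True)
        denom = np.sqrt((xc**2).sum() * (yc**2).sum(axis=-1))
        return (yc @ xc) / np.where(denom > 0, denom, np.nan)

    r_obs = float(corr(t2))
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    perms = np.array([rng.permutation(n) for _ in range(n_perm)])
    permuted = M2[perms[:, iu[0]], perms[:, iu[1]]]  # (n_perm, n*(n-1)/2)
    r_perm = corr(permuted)
    p = (1.0 + np.sum(r_perm >= r_obs)) / (n_perm + 1.0)
    return MantelResult(r=r_obs, p=float(p), n_perm=n_perm, method=method)
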