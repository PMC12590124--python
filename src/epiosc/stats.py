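"""Inferential statistics: rank-sum with FDR, the time-frequency
cluster-based permutation test, Spearman correlation, and multiple linear
regression.

The cluster test compares two groups of time-frequency maps: pixelwise
independent-samples t statistics, clusters of suprathreshold neighbours
(4-connected by default), cluster mass as the sum of t values, and a Monte
Carlo reference distribution of the maximum absolute cluster mass under
subject-label permutation.  A cluster is significant when its absolute mass
exceeds the configured percentile of that distribution (99th by default);
permutation p values use (1 + #{null >= observed}) / (n_perm + 1).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import ndimage, stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ranksum",
    "fdr_bh",
    "ClusterTestResult",
    "cluster_permutation_test",
    "spearman",
    "multiple_regression",
]


def ranksum(group_a, group_b) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Exact enumeration when the pooled sample is small (n <= 12) and tie-free;
    otherwise the normal approximation with tie and continuity corrections.
    Returns ``(U statistic of group_a, two-sided p)``.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    no_ties = np.unique(pooled).size == pooled.size
    method = "exact" if (pooled.size <= 12 and no_ties) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method, use_continuity=True)
    return float(res.statistic), float(res.pvalue)


def fdr_bh(p_values, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up FDR.

    Returns ``(adjusted p, rejection mask)`` at level ``q``.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy(), np.zeros(0, dtype=bool)
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p values must lie in [0, 1]")
    reject, p_adj, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return p_adj, reject


@dataclass
class ClusterTestResult:
    t_map: np.ndarray
    clusters: list
    null_max_mass: np.ndarray
    mask: np.ndarray
    frequencies: np.ndarray
    times: np.ndarray
    params: dict = field(default_factory=dict)

    @property
    def significant_clusters(self) -> list:
        return [c for c in self.clusters if c["significant"]]


def _t_map(x: np.ndarray, is_a: np.ndarray) -> np.ndarray:
    """Pooled-variance independent-samples t over the last axes."""
    a = x[is_a]
    b = x[~is_a]
    na, nb = a.shape[0], b.shape[0]
    ma, mb = a.mean(axis=0), b.mean(axis=0)
    va = a.var(axis=0, ddof=1)
    vb = b.var(axis=0, ddof=1)
    sp = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
    denom = np.sqrt(sp * (1.0 / na + 1.0 / nb))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (ma - mb) / denom
    return np.where(denom > 0, t, 0.0)


def _clusters_and_masses(t: np.ndarray, crit: float, structure: np.ndarray, usable: np.ndarray):
    """Positive and negative suprathreshold clusters with signed masses."""
    out = []
    for sign in (1.0, -1.0):
        supra = (sign * t > crit) & usable
        labels, n = ndimage.label(supra, structure=structure)
        for lab in range(1, n + 1):
            members = labels == lab
            out.append((members, float(t[members].sum())))
    return out


def cluster_permutation_test(
    maps_a,
    maps_b,
    frequencies=None,
    times=None,
    n_perm: int = 1000,
    pixel_alpha: float = 0.05,
    cluster_percentile: float = 99.0,
    adjacency: str = "4",
    time_window: tuple[float, float] | None = (10.0, 500.0),
    valid: np.ndarray | None = None,
    seed: int | None = None,
) -> ClusterTestResult:
    """Cluster-based Monte Carlo permutation test between two groups of maps.

    Parameters
    ----------
    maps_a, maps_b
        Sequences of (frequencies x times) arrays (or :class:`~epiosc.tfr.TFRMap`),
        one per subject, on a shared grid.
    n_perm
        Number of random subject-label permutations (the observed labelling
        is additionally included in the reference distribution).
    pixel_alpha
        Two-sided pixelwise threshold used to form clusters.
    cluster_percentile
        A cluster is significant when its absolute mass exceeds this
        percentile of the max-|mass| reference distribution.
    adjacency
        ``"4"`` (orthogonal neighbours) or ``"8"`` (including diagonals).
    time_window
        Restrict the test to this post-stimulus window (ms); ``None`` uses
        all times.
    valid
        Optional boolean (frequencies x times) mask of pixels eligible for
        cluster formation (e.g. the joint wavelet-validity mask).
    """
    def _unpack(m):
        if hasattr(m, "values") and hasattr(m, "frequencies"):
            return np.asarray(m.values, dtype=float), m.frequencies, m.times, m.valid
        return np.asarray(m, dtype=float), None, None, None

    arrs_a, arrs_b = [], []
    for m in maps_a:
        v, f, t, vmask = _unpack(m)
        arrs_a.append(v)
        if frequencies is None and f is not None:
            frequencies, times = f, t
        if valid is None and vmask is not None:
            valid = vmask.copy()
        elif vmask is not None:
            valid = valid & vmask
    for m in maps_b:
        v, _, _, vmask = _unpack(m)
        arrs_b.append(v)
        if vmask is not None and valid is not None:
            valid = valid & vmask

    if len(arrs_a) < 2 or len(arrs_b) < 2:
        raise ValueError("need at least 2 subjects per group")
    shape = arrs_a[0].shape
    if any(a.shape != shape for a in arrs_a + arrs_b):
        raise ValueError("all maps must share the same grid")
    if frequencies is None:
        frequencies = np.arange(shape[0], dtype=float)
    if times is None:
        times = np.arange(shape[1], dtype=float)

    usable = np.ones(shape, dtype=bool) if valid is None else valid.copy()
    if time_window is not None:
        tsel = (times >= time_window[0]) & (times <= time_window[1])
        usable &= tsel[None, :]

    x = np.stack(arrs_a + arrs_b)
    na = len(arrs_a)
    n = x.shape[0]
    is_a_obs = np.zeros(n, dtype=bool)
    is_a_obs[:na] = True

    df = n - 2
    crit = sps.t.ppf(1.0 - pixel_alpha / 2.0, df)
    structure = (
        np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])
        if adjacency == "4"
        else np.ones((3, 3), dtype=int)
    )

    t_obs = _t_map(x, is_a_obs)
    obs_clusters = _clusters_and_masses(t_obs, crit, structure, usable)

    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for i in range(n_perm):
        perm = rng.permutation(n)
        is_a = np.zeros(n, dtype=bool)
        is_a[perm[:na]] = True
        t_p = _t_map(x, is_a)
        cl = _clusters_and_masses(t_p, crit, structure, usable)
        null[i] = max((abs(m) for _, m in cl), default=0.0)

    obs_max = max((abs(m) for _, m in obs_clusters), default=0.0)
    reference = np.concatenate([null, [obs_max]])  # observed partition included
    thresh = np.percentile(reference, cluster_percentile)

    clusters = []
    mask = np.zeros(shape, dtype=bool)
    for members, mass in obs_clusters:
        p = (1.0 + np.sum(null >= abs(mass))) / (n_perm + 1.0)
        significant = abs(mass) > thresh
        if significant:
            mask |= members
        clusters.append(
            {
                "pixels": members,
                "mass": mass,
                "p": p,
                "significant": significant,
                "n_pixels": int(members.sum()),
            }
        )
    clusters.sort(key=lambda c: -abs(c["mass"]))
    return ClusterTestResult(
        t_map=t_obs,
        clusters=clusters,
        null_max_mass=null,
        mask=mask,
        frequencies=np.asarray(frequencies, dtype=float),
        times=np.asarray(times, dtype=float),
        params={
            "n_perm": n_perm,
            "pixel_alpha": pixel_alpha,
            "cluster_percentile": cluster_percentile,
            "adjacency": adjacency,
            "time_window": time_window,
            "mass_threshold": float(thresh),
            "seed": seed,
        },
    )


@lru_cache(maxsize=8)
def _exact_spearman_null(n: int) -> np.ndarray:
    """|r| values of all rank permutations of size n (tie-free case)."""
    base = np.arange(1, n + 1, dtype=float)
    base = (base - base.mean()) / base.std()
    rs = []
    for perm in itertools.permutations(range(n)):
        rs.append(abs(np.mean(base * base[list(perm)])))
    return np.array(rs)


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation with midranks for ties.

    p is exact (permutation enumeration) for n <= 9 without ties, otherwise
    the t approximation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need paired samples with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance input")
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    r = float(np.corrcoef(rx, ry)[0, 1])
    n = x.size
    no_ties = np.unique(x).size == n and np.unique(y).size == n
    if n <= 9 and no_ties:
        null = _exact_spearman_null(n)
        p = float(np.mean(null >= abs(r) - 1e-12))
    else:
        if abs(r) >= 1.0:
            p = 0.0
        else:
            t = r * np.sqrt((n - 2) / (1.0 - r * r))
            p = float(2.0 * sps.t.sf(abs(t), n - 2))
    return r, p


def multiple_regression(y, predictors: pd.DataFrame) -> pd.DataFrame:
    """Ordinary least squares with intercept and per-coefficient t tests.

    ``predictors`` columns are used as given (encode categorical subtype as
    a binary indicator beforehand).  Rank deficiency raises an error naming
    the collinear columns.
    """
    import statsmodels.api as sm

    y = np.asarray(y, dtype=float)
    X = predictors.astype(float)
    if len(X) != y.size:
        raise ValueError("y and predictors disagree in length")
    if y.size <= X.shape[1] + 1:
        raise ValueError("need n > number of predictors + 1")
    Xc = sm.add_constant(X, has_constant="add")
    rank = np.linalg.matrix_rank(Xc.to_numpy())
    if rank < Xc.shape[1]:
        offenders = []
        cols = list(Xc.columns)
        kept = np.empty((len(Xc), 0))
        for c in cols:
            trial = np.column_stack([kept, Xc[c].to_numpy()])
            if np.linalg.matrix_rank(trial) > kept.shape[1]:
                kept = trial
            else:
                offenders.append(c)
        raise ValueError(f"rank-deficient design; collinear columns: {offenders}")
    fit = sm.OLS(y, Xc).fit()
    return pd.DataFrame(
        {
            "coefficient": fit.params,
            "std_error": fit.bse,
            "t": fit.tvalues,
            "p": fit.pvalues,
        }
    )
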