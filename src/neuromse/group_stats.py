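"""Group-level statistics for multiscale-entropy profiles.

The screening test is a split-plot (repeated-measures) ANCOVA per region
and band: group, medication use and sex as between-subject factors (main
effects), age as a covariate, and scale factor (20 levels) as the within
factor, with Greenhouse-Geisser degree-of-freedom adjustment and
Bonferroni correction across regions.  Significant screens are followed
by per-scale-factor independent t-tests under Benjamini-Hochberg FDR,
correlation maps between component entropies, and entropy-cognition
Pearson correlations.  Demographic tables use pooled-variance t and
Pearson chi-square tests.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "AncovaResult",
    "PosthocResult",
    "rm_ancova",
    "posthoc_ttests",
    "bh_fdr",
    "correlation_map",
    "cognition_correlation",
    "two_sample_t",
    "chi_square_2x2",
]

logger = logging.getLogger(__name__)


@dataclass
class AncovaResult:
    region: str
    band: str
    p_group: float            # GG-adjusted between p, Bonferroni-corrected
    p_interaction: float      # GG-adjusted group x SF p, Bonferroni-corrected
    p_group_raw: float        # before Bonferroni
    p_interaction_raw: float  # GG-adjusted, before Bonferroni
    p_interaction_sphericity: float  # unadjusted within-subject F p
    f_group: float
    f_interaction: float
    gg_epsilon: float
    bonferroni_factor: int
    n_subjects: int
    dropped_factors: tuple[str, ...] = ()


@dataclass
class PosthocResult:
    scale_factors: tuple[int, ...]
    t: np.ndarray
    p: np.ndarray
    rejected: np.ndarray
    direction: tuple[str, ...]  # 'HC>AD' or 'HC<AD' per SF
    q: float


def _design_matrix(design: pd.DataFrame, factors: list[str],
                   covariates: list[str]) -> tuple[np.ndarray, dict[str, list[int]],
                                                   tuple[str, ...]]:
    """Intercept + dummy-coded factors + centered covariates.

    Single-level factors are dropped with a warning (singular design).
    Returns the matrix, a map factor -> column indices, and the dropped
    factor names.
    """
    n = len(design)
    cols: list[np.ndarray] = [np.ones(n)]
    col_map: dict[str, list[int]] = {}
    dropped: list[str] = []
    for f in factors:
        levels = sorted(pd.unique(design[f].astype(str)))
        if len(levels) < 2:
            logger.warning("factor %r has a single level; dropped", f)
            dropped.append(f)
            continue
        idx = []
        for lev in levels[1:]:
            idx.append(len(cols))
            cols.append((design[f].astype(str) == lev).to_numpy(float))
        col_map[f] = idx
    for c in covariates:
        v = design[c].to_numpy(float)
        col_map[c] = [len(cols)]
        cols.append(v - v.mean())
    return np.column_stack(cols), col_map, tuple(dropped)


def _rss(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Residual sum of squares of OLS per response column."""
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    return (resid ** 2).sum(axis=0)


def rm_ancova(profiles: np.ndarray, design: pd.DataFrame,
              region: str = "", band: str = "",
              factors: tuple[str, ...] = ("group", "dz_use", "sex"),
              covariates: tuple[str, ...] = ("age",),
              bonferroni_factor: int = 7) -> AncovaResult:
    """Split-plot ANCOVA of subject x scale-factor entropy profiles.

    ``profiles`` is (n_subjects, k) with k repeated measures; subjects
    with any undefined (NaN) cell are excluded listwise.  The between
    stratum tests the group main effect on the subject means; the within
    stratum tests the group x SF interaction on orthonormal-contrast
    scores, with the Greenhouse-Geisser epsilon estimated from the
    residual covariance of those scores.  Reported p-values are
    Bonferroni-multiplied by ``bonferroni_factor`` (capped at 1).
    """
    Y = np.asarray(profiles, dtype=float)
    keep = np.all(np.isfinite(Y), axis=1)
    if not np.all(keep):
        logger.info("rm_ancova: excluding %d subjects with undefined cells",
                    int((~keep).sum()))
    Y = Y[keep]
    design = design.loc[keep].reset_index(drop=True)
    n, k = Y.shape
    counts = design["group"].value_counts()
    if len(counts) < 2 or counts.min() < 2:
        raise ValueError("need >= 2 subjects per group")

    X, col_map, dropped = _design_matrix(design, [f for f in factors],
                                         list(covariates))
    p_cols = X.shape[1]
    if "group" not in col_map:
        raise ValueError("group factor is singular after exclusions")
    group_cols = col_map["group"]
    X_red = np.delete(X, group_cols, axis=1)
    df_group = len(group_cols)
    df_res = n - p_cols

    # between stratum: subject means
    y_bar = Y.mean(axis=1, keepdims=True)
    rss_full = float(_rss(X, y_bar)[0])
    rss_red = float(_rss(X_red, y_bar)[0])
    f_group = ((rss_red - rss_full) / df_group) / (rss_full / df_res)
    p_group_raw = float(sps.f.sf(f_group, df_group, df_res))

    # within stratum: orthonormal contrasts of the k repeated measures
    C = np.linalg.qr(np.vstack([np.ones(k), np.eye(k)[:-1]]).T)[0][:, 1:]
    Z = Y @ C  # (n, k-1)
    rss_full_z = _rss(X, Z)
    rss_red_z = _rss(X_red, Z)
    ss_int = float((rss_red_z - rss_full_z).sum())
    ss_err = float(rss_full_z.sum())
    df_int = df_group * (k - 1)
    df_err = df_res * (k - 1)
    f_int = (ss_int / df_int) / (ss_err / df_err)

    beta, *_ = np.linalg.lstsq(X, Z, rcond=None)
    R = Z - X @ beta
    sigma = (R.T @ R) / df_res
    tr = float(np.trace(sigma))
    tr2 = float(np.sum(sigma * sigma))  # trace of sigma @ sigma (symmetric)
    eps = tr ** 2 / ((k - 1) * tr2) if tr2 > 0 else 1.0
    eps = float(np.clip(eps, 1.0 / (k - 1), 1.0))

    p_int_sph = float(sps.f.sf(f_int, df_int, df_err))
    p_int_raw = float(sps.f.sf(f_int, eps * df_int, eps * df_err))

    return AncovaResult(
        region=region, band=band,
        p_group=min(1.0, p_group_raw * bonferroni_factor),
        p_interaction=min(1.0, p_int_raw * bonferroni_factor),
        p_group_raw=p_group_raw, p_interaction_raw=p_int_raw,
        p_interaction_sphericity=p_int_sph,
        f_group=float(f_group), f_interaction=float(f_int),
        gg_epsilon=eps, bonferroni_factor=bonferroni_factor,
        n_subjects=n, dropped_factors=dropped)


def bh_fdr(pvals: np.ndarray, q: float) -> np.ndarray:
    """Benjamini-Hochberg step-up: reject the largest prefix of sorted p
    with p_(i) <= q*i/m.  NaN p-values are never rejected and do not
    count toward the family size."""
    p = np.asarray(pvals, dtype=float)
    out = np.zeros(p.shape, dtype=bool)
    finite = np.isfinite(p)
    pf = p[finite]
    m = pf.size
    if m == 0:
        return out
    order = np.argsort(pf, kind="stable")
    thresh = q * (np.arange(1, m + 1) / m)
    below = pf[order] <= thresh
    if below.any():
        cutoff = np.max(np.nonzero(below)[0])
        rej = np.zeros(m, dtype=bool)
        rej[order[:cutoff + 1]] = True
        out[np.nonzero(finite)[0]] = rej
    return out


def two_sample_t(a, b) -> float:
    """Pooled-variance two-sample t statistic, ``(mean_a - mean_b) / SE``.

    Each argument is either a 1-D sample (list/array) or a ``(mean, sd,
    n)`` summary *tuple* — tuples are reserved for summaries so a
    three-observation sample is never misread.  Returns NaN when the
    pooled variance is zero.
    """
    def _summ(x):
        if isinstance(x, tuple):
            if len(x) != 3:
                raise ValueError("summary input must be (mean, sd, n)")
            return float(x[0]), float(x[1]), int(x[2])
        arr = np.asarray(x, dtype=float)
        return float(arr.mean()), float(arr.std(ddof=1)), arr.size

    m1, s1, n1 = _summ(a)
    m2, s2, n2 = _summ(b)
    if n1 < 2 or n2 < 2:
        raise ValueError("need n >= 2 per group")
    sp2 = ((n1 - 1) * s1 ** 2 + (n2 - 1) * s2 ** 2) / (n1 + n2 - 2)
    if sp2 == 0:
        return float("nan")
    return (m1 - m2) / math.sqrt(sp2 * (1 / n1 + 1 / n2))


def chi_square_2x2(counts) -> float:
    """Pearson chi-square of a 2x2 table, without continuity correction."""
    t = np.asarray(counts, dtype=float)
    if t.shape != (2, 2) or np.any(t < 0) or not np.allclose(t, np.round(t)):
        raise ValueError("counts must be a 2x2 non-negative integer table")
    row = t.sum(axis=1)
    col = t.sum(axis=0)
    if np.any(row == 0) or np.any(col == 0):
        raise ValueError("table has a zero margin")
    n = t.sum()
    return float(n * (t[0, 0] * t[1, 1] - t[0, 1] * t[1, 0]) ** 2
                 / (row[0] * row[1] * col[0] * col[1]))


def posthoc_ttests(profiles_hc: np.ndarray, profiles_ad: np.ndarray,
                   scale_factors, q: float = 0.1) -> PosthocResult:
    """Per-scale-factor pooled t-tests (HC - AD) with BH FDR across SFs.

    SFs where either group has fewer than 2 defined values, or where the
    pooled variance is zero, are undefined (NaN) and excluded from the
    FDR family.
    """
    H = np.asarray(profiles_hc, dtype=float)
    A = np.asarray(profiles_ad, dtype=float)
    k = H.shape[1]
    if A.shape[1] != k:
        raise ValueError("group profile matrices disagree in SF count")
    ts = np.full(k, np.nan)
    ps = np.full(k, np.nan)
    for j in range(k):
        h = H[np.isfinite(H[:, j]), j]
        a = A[np.isfinite(A[:, j]), j]
        if h.size < 2 or a.size < 2:
            logger.warning("posthoc: SF index %d underpopulated; skipped", j)
            continue
        t = two_sample_t(h, a)
        if not np.isfinite(t):
            logger.warning("posthoc: SF index %d has zero variance; skipped", j)
            continue
        df = h.size + a.size - 2
        ts[j] = t
        ps[j] = 2 * sps.t.sf(abs(t), df)
    rejected = bh_fdr(ps, q)
    direction = tuple("HC>AD" if t > 0 else "HC<AD" if t < 0 else "none"
                      for t in np.nan_to_num(ts))
    return PosthocResult(scale_factors=tuple(scale_factors), t=ts, p=ps,
                         rejected=rejected, direction=direction, q=q)


def correlation_map(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pearson r between component-a SF_i and component-b SF_j across subjects.

    Zero-variance columns yield NaN entries.
    """
    A = np.asarray(a, dtype=float)
    B = np.asarray(b, dtype=float)
    if A.shape[0] != B.shape[0]:
        raise ValueError("both matrices must hold the same subjects")
    ka, kb = A.shape[1], B.shape[1]
    out = np.full((ka, kb), np.nan)
    for i in range(ka):
        x = A[:, i]
        if np.std(x) == 0 or not np.all(np.isfinite(x)):
            continue
        for j in range(kb):
            y = B[:, j]
            if np.std(y) == 0 or not np.all(np.isfinite(y)):
                continue
            out[i, j] = float(np.corrcoef(x, y)[0, 1])
    return out


def cognition_correlation(entropy_values, scores) -> tuple[float, float]:
    """Pearson r and two-sided p (t transform) between entropy and score."""
    x = np.asarray(entropy_values, dtype=float)
    y = np.asarray(scores, dtype=float)
    mask = np.isfinite(x) & np.isfinite(y)
    x, y = x[mask], y[mask]
    if x.size < 3:
        raise ValueError("need >= 3 paired finite values")
    if np.std(x) == 0 or np.std(y) == 0:
        return float("nan"), float("nan")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)
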