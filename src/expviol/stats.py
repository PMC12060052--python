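"""Inference engines: paired t, repeated-measures ANOVA, cluster-mass
permutation test, skipped (robust) Pearson correlation.

The cluster test controls the familywise error of time-resolved paired
comparisons with the max-statistic approach: paired t at every sample,
contiguous runs of pointwise-significant same-sign samples scored by their
summed t ("mass"), and the observed masses compared against the 95th
percentile of the permutation null of the *maximum* mass, built by
sign-flipping each observer's difference series (equivalent to swapping
condition labels within observer).

The skipped correlation removes bivariate outliers by the projection
method: the cloud is centred on a robust centre, every point is projected
onto the line through the centre and each data point in turn, and a point
is flagged if it exceeds boxplot-rule fences (ideal-fourths quartiles
+- 1.5 IQR) on any projection.  Pearson's r is then computed on the
retained points.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "paired_t",
    "rm_anova_2way",
    "cluster_permutation_test",
    "skipped_pearson",
    "ClusterResult",
    "SkippedCorrEstimate",
]


# ---------------------------------------------------------------------------
# paired t

def paired_t(x, y, tail="two"):
    """Classical paired t-test.

    tail: "two" (difference != 0) or "greater" (mean(x - y) > 0).
    Returns dict with t, df, p.  Zero-variance differences give a signed
    infinite t (or t=0 if the differences are identically zero) with a
    warning.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D samples")
    n = len(x)
    if n < 2:
        raise ValueError("need at least 2 pairs")
    if tail not in ("two", "greater"):
        raise ValueError("tail must be 'two' or 'greater'")
    d = x - y
    df = n - 1
    sd = d.std(ddof=1)
    if sd == 0:
        warnings.warn("zero-variance differences: t is degenerate")
        m = d.mean()
        t = 0.0 if m == 0 else np.inf * np.sign(m)
        if tail == "two":
            p = 1.0 if m == 0 else 0.0
        else:
            p = 1.0 if m <= 0 else 0.0
        return {"t": float(t), "df": df, "p": float(p)}
    alternative = "two-sided" if tail == "two" else "greater"
    res = sps.ttest_rel(x, y, alternative=alternative)
    return {"t": float(res.statistic), "df": df, "p": float(res.pvalue)}


# ---------------------------------------------------------------------------
# repeated-measures ANOVA

def _rm_effect(ss_eff, df_eff, ss_err, df_err):
    if ss_eff <= 0:
        return {"F": 0.0, "df1": float(df_eff), "df2": float(df_err), "p": 1.0}
    if ss_err <= 0:
        warnings.warn("zero error variance: F is infinite")
        return {"F": float("inf"), "df1": float(df_eff),
                "df2": float(df_err), "p": 0.0}
    f = (ss_eff / df_eff) / (ss_err / df_err)
    return {"F": float(f), "df1": float(df_eff), "df2": float(df_err),
            "p": float(sps.f.sf(f, df_eff, df_err))}


def rm_anova_2way(data: pd.DataFrame, dv, subject, within):
    """Two-way fully within-subjects ANOVA (classical SS partition).

    ``within`` is a pair of factor column names (e.g. condition with 2
    levels and violation bin with 8).  Cell replicates are averaged first;
    subjects missing any cell are dropped listwise with a warning.  Each
    effect is tested against its own effect-by-subject error term:

        F_A  = MS_A  / MS_{A x S},   F_B = MS_B / MS_{B x S},
        F_AB = MS_AB / MS_{A x B x S}

    Returns ``{effect: {"F", "df1", "df2", "p"}}`` keyed "A", "B", "A:B"
    by the order given.  A zero effect sum of squares yields F = 0.
    """
    fa, fb = within
    cells = (data.groupby([subject, fa, fb], observed=True)[dv]
             .mean().reset_index())
    n_levels = cells[fa].nunique() * cells[fb].nunique()
    counts = cells.groupby(subject, observed=True).size()
    complete = counts[counts == n_levels].index
    dropped = counts.index.difference(complete)
    if len(dropped):
        warnings.warn(f"listwise deletion of {len(dropped)} subject(s) "
                      "with incomplete cells")
    cells = cells[cells[subject].isin(complete)]
    if cells[subject].nunique() < 2:
        raise ValueError("fewer than 2 complete subjects")

    wide = cells.pivot_table(index=subject, columns=[fa, fb], values=dv,
                             observed=True)
    n = wide.shape[0]
    a = cells[fa].nunique()
    b = cells[fb].nunique()
    y = wide.to_numpy(float).reshape(n, a, b)

    grand = y.mean()
    m_s = y.mean(axis=(1, 2))           # subject means
    m_a = y.mean(axis=(0, 2))           # factor-A level means
    m_b = y.mean(axis=(0, 1))
    m_as = y.mean(axis=2)               # (n, a)
    m_bs = y.mean(axis=1)               # (n, b)
    m_ab = y.mean(axis=0)               # (a, b)

    ss_a = n * b * np.sum((m_a - grand) ** 2)
    ss_b = n * a * np.sum((m_b - grand) ** 2)
    ss_ab = n * np.sum((m_ab - m_a[:, None] - m_b[None, :] + grand) ** 2)
    ss_as = b * np.sum((m_as - m_a[None, :] - m_s[:, None] + grand) ** 2)
    ss_bs = a * np.sum((m_bs - m_b[None, :] - m_s[:, None] + grand) ** 2)
    resid = (y - m_as[:, :, None] - m_bs[:, None, :] - m_ab[None, :, :]
             + m_a[None, :, None] + m_b[None, None, :] + m_s[:, None, None]
             - grand)
    ss_abs = np.sum(resid ** 2)

    return {
        "A": _rm_effect(ss_a, a - 1, ss_as, (a - 1) * (n - 1)),
        "B": _rm_effect(ss_b, b - 1, ss_bs, (b - 1) * (n - 1)),
        "A:B": _rm_effect(ss_ab, (a - 1) * (b - 1), ss_abs,
                          (a - 1) * (b - 1) * (n - 1)),
    }


# ---------------------------------------------------------------------------
# cluster-mass permutation test

@dataclass
class ClusterResult:
    clusters: list                      # dicts: start_ms, end_ms, mass, sign, significant
    pointwise_t: np.ndarray
    times: np.ndarray
    threshold_mass: float               # 95th percentile of null max masses
    null_masses: np.ndarray
    n_perm: int
    tail: str
    seed: Optional[int] = None
    alpha_pointwise: float = 0.05

    @property
    def significant_clusters(self):
        return [c for c in self.clusters if c["significant"]]


def _run_masses_rowwise(values, mask):
    """Max run-sum of `values` over True-runs of `mask`, per row (vectorised).

    values, mask: (n_rows, n_cols).  Returns (n_rows,) of max run sums
    (0 where a row has no runs).  Used on |t| so masses are nonnegative.
    """
    n_rows, n_cols = mask.shape
    padded = np.zeros((n_rows, n_cols + 1), dtype=bool)
    padded[:, :n_cols] = mask
    flat = padded.ravel()
    vals = np.zeros((n_rows, n_cols + 1), dtype=float)
    vals[:, :n_cols] = np.where(mask, values, 0.0)
    cs = np.concatenate([[0.0], np.cumsum(vals.ravel())])
    prev = np.concatenate([[False], flat[:-1]])
    starts = np.flatnonzero(flat & ~prev)
    nxt = np.concatenate([flat[1:], [False]])
    ends = np.flatnonzero(flat & ~nxt)
    sums = cs[ends + 1] - cs[starts]
    rows = starts // (n_cols + 1)
    out = np.zeros(n_rows, dtype=float)
    np.maximum.at(out, rows, sums)
    return out


def _find_clusters(t_vals, sig_mask):
    """Maximal contiguous runs of pointwise-significant same-sign samples."""
    clusters = []
    sign = np.sign(t_vals)
    boundary = np.concatenate([[True], (sign[1:] != sign[:-1])])
    group = np.cumsum(boundary)
    group = np.where(sig_mask, group, 0)
    for g in np.unique(group):
        if g == 0:
            continue
        idx = np.flatnonzero(group == g)
        # runs within a sign group can still be broken by non-significant gaps
        breaks = np.flatnonzero(np.diff(idx) > 1)
        for chunk in np.split(idx, breaks + 1):
            clusters.append((chunk[0], chunk[-1],
                             float(t_vals[chunk].sum()),
                             int(sign[chunk[0]])))
    return clusters


def _t_rows(diffs_flipped, sumsq):
    """Paired-t per column given sign-flipped differences.

    Sign flips leave per-observer squares unchanged, so the column variance
    is recoverable from the flipped mean and the fixed sum of squares.
    """
    n = diffs_flipped.shape[-2] if diffs_flipped.ndim == 3 else diffs_flipped.shape[0]
    mean = diffs_flipped.mean(axis=-2)
    var = (sumsq - n * mean ** 2) / (n - 1)
    var = np.maximum(var, 1e-300)
    return mean / np.sqrt(var / n)


def cluster_permutation_test(cond_a, cond_b=None, times=None,
                             alpha_pointwise=0.05, n_perm=1000, tail="two",
                             seed=None, rng=None, method="montecarlo"):
    """Cluster-mass permutation test on paired time series.

    Parameters
    ----------
    cond_a, cond_b : (n_observers, n_times) arrays
        Paired condition time courses; alternatively pass the difference
        series as ``cond_a`` with ``cond_b=None``.
    times : array, optional
        Sample times in ms (defaults to sample indices).
    alpha_pointwise : float
        Alpha for forming clusters at each sample (same tail as the test).
    tail : {"two", "greater"}
        "greater" tests for cond_a > cond_b only (positive clusters).
    method : {"montecarlo", "exhaustive"}
        Exhaustive enumerates all 2^n sign-flip assignments (small n only).

    The null distribution records, per permutation, the maximum cluster
    mass (|summed t|; positive and negative runs scored separately), and
    clusters whose mass does not exceed its 95th percentile are marked
    non-significant.
    """
    diffs = np.asarray(cond_a, float)
    if cond_b is not None:
        diffs = diffs - np.asarray(cond_b, float)
    if diffs.ndim != 2:
        raise ValueError("expected (n_observers, n_times) input")
    n_obs, n_times = diffs.shape
    if n_obs < 2:
        raise ValueError("need at least 2 observers")
    if tail not in ("two", "greater"):
        raise ValueError("tail must be 'two' or 'greater'")
    if n_perm < 100:
        warnings.warn("n_perm < 100 gives a very coarse null")
    times = np.arange(n_times, dtype=float) if times is None else np.asarray(times, float)

    df = n_obs - 1
    if tail == "two":
        t_crit = sps.t.ppf(1.0 - alpha_pointwise / 2.0, df)
    else:
        t_crit = sps.t.ppf(1.0 - alpha_pointwise, df)

    sumsq = np.sum(diffs ** 2, axis=0)
    sd = diffs.std(axis=0, ddof=1)
    mean = diffs.mean(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_obs = np.where(sd > 0, mean / (sd / np.sqrt(n_obs)), 0.0)

    if tail == "two":
        sig = np.abs(t_obs) > t_crit
    else:
        sig = t_obs > t_crit
    observed = _find_clusters(t_obs, sig)

    # permutation null of the maximum cluster mass
    if method == "exhaustive":
        if n_obs > 16:
            raise ValueError("exhaustive enumeration limited to n <= 16")
        signs = np.array(
            [[1 if (i >> k) & 1 else -1 for k in range(n_obs)]
             for i in range(2 ** n_obs)], dtype=float)
        n_perm = signs.shape[0]
    else:
        if rng is None:
            rng = np.random.default_rng(seed)
        signs = rng.choice([-1.0, 1.0], size=(n_perm, n_obs))

    null_masses = np.empty(n_perm)
    batch = max(1, int(5e7 // (n_obs * n_times)))
    for lo in range(0, n_perm, batch):
        s = signs[lo:lo + batch]
        flipped = s[:, :, None] * diffs[None, :, :]
        t_perm = _t_rows(flipped, sumsq[None, :])
        # sign-homogeneous runs, like the observed clusters
        masses = _run_masses_rowwise(t_perm, t_perm > t_crit)
        if tail == "two":
            masses = np.maximum(
                masses, _run_masses_rowwise(-t_perm, t_perm < -t_crit))
        null_masses[lo:lo + len(s)] = masses
    threshold = float(np.percentile(null_masses, 95))

    clusters = []
    for start, end, mass, sgn in observed:
        if tail == "greater" and sgn < 0:
            continue
        clusters.append({
            "start_ms": float(times[start]), "end_ms": float(times[end]),
            "start_idx": int(start), "end_idx": int(end),
            "mass": mass, "sign": sgn,
            "significant": bool(abs(mass) > threshold),
        })
    return ClusterResult(clusters=clusters, pointwise_t=t_obs, times=times,
                         threshold_mass=threshold, null_masses=null_masses,
                         n_perm=n_perm, tail=tail, seed=seed,
                         alpha_pointwise=alpha_pointwise)


# ---------------------------------------------------------------------------
# skipped correlation

@dataclass
class SkippedCorrEstimate:
    r: float
    p_value: float
    n_used: int
    outlier_ids: np.ndarray = field(default_factory=lambda: np.array([], int))
    method: str = "skipped-pearson/median-center/boxplot-rule"

    @property
    def n_outliers(self):
        return len(self.outlier_ids)


def _ideal_fourths(x):
    """Ideal-fourths (interpolated) quartile estimates."""
    xs = np.sort(np.asarray(x, float))
    n = len(xs)
    j = int(np.floor(n / 4 + 5 / 12))
    h = n / 4 + 5 / 12 - j
    q1 = (1 - h) * xs[j - 1] + h * xs[j]
    k = n - j + 1
    q3 = (1 - h) * xs[k - 1] + h * xs[k - 2]
    return q1, q3


def _mcd_center(xy):
    from sklearn.covariance import MinCovDet
    return MinCovDet(random_state=0).fit(xy).location_


def skipped_pearson(x, y, center="median"):
    """Skipped Pearson correlation with projection-method outlier removal.

    A point is a bivariate outlier if, on the projection of the cloud onto
    the line through the robust centre and *any* data point, it falls
    outside the boxplot fences (ideal-fourths quartiles -+ 1.5 IQR).
    Pearson's r and its t-based p-value are then computed on the retained
    points.

    ``center``: "median" (coordinatewise, deterministic default) or "mcd"
    (minimum covariance determinant, via scikit-learn).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D samples")
    n = len(x)
    if n < 10:
        raise ValueError("need at least 10 paired observations")
    xy = np.column_stack([x, y])
    if center == "median":
        c = np.median(xy, axis=0)
    elif center == "mcd":
        c = _mcd_center(xy)
    else:
        raise ValueError("center must be 'median' or 'mcd'")

    centered = xy - c
    norms = np.linalg.norm(centered, axis=1)
    flagged = np.zeros(n, dtype=bool)
    for i in range(n):
        if norms[i] == 0:
            continue
        u = centered[i] / norms[i]
        proj = centered @ u
        q1, q3 = _ideal_fourths(proj)
        iqr = q3 - q1
        flagged |= (proj < q1 - 1.5 * iqr) | (proj > q3 + 1.5 * iqr)
    if flagged.sum() > n / 2:
        raise ValueError(
            f"{flagged.sum()}/{n} points flagged as outliers; the cloud is "
            "not predominantly regular — skipped correlation refused")
    keep = ~flagged
    r, p = sps.pearsonr(x[keep], y[keep])
    return SkippedCorrEstimate(
        r=float(r), p_value=float(p), n_used=int(keep.sum()),
        outlier_ids=np.flatnonzero(flagged),
        method=f"skipped-pearson/{center}-center/boxplot-rule")
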