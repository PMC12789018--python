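"""Gradient-ordered nestedness, directional turnover and meta-analysis.

Site-by-species matrices are ordered by an external stressor gradient
(increasing hazard quotient or decreasing semi-natural habitat).  Weighted
nestedness based on overlap and decreasing fill (WNODF) is computed on the
matrix as ordered and z-scored against a quantitative swap null model that
preserves row sums, column sums and fill; z-scores averaged within studies
feed a one-sample t-test against 0, and the two gradients are compared per
study with a paired Wilcoxon signed-rank test.  Occurrence matrices are
decomposed into directional (losing vs gaining) turnover and nestedness
components over site pairs shifted by three gradient positions, summarized
per matrix as paired Hedges' g and pooled across matrices by a
DerSimonian-Laird random-effects meta-analysis with an optional moderator
omnibus screen and leave-one-out Cook's distances.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

try:  # the swap chain is hot: burn-in and thinning scale with matrix size
    from numba import njit as _njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def _njit(*a, **k):
        def deco(f):
            return f

        return deco if not (len(a) == 1 and callable(a[0])) else a[0]


__all__ = [
    "OrderedMatrix",
    "NestednessResult",
    "MetaResult",
    "order_by_gradient",
    "wnodf",
    "quantitative_swap_null",
    "null_zscore",
    "nestedness_zscore",
    "study_nestedness_test",
    "paired_wilcoxon",
    "directional_decomposition",
    "hedges_g_paired",
    "random_effects_meta",
    "meta_influence",
    "t_from_summary",
    "ci_upper_from_t",
]


# ---------------------------------------------------------------------------
# Gradient ordering


@dataclass
class OrderedMatrix:
    """Site x species matrix with rows ordered along a stressor gradient."""

    matrix: pd.DataFrame
    gradient: pd.Series  # aligned with the row order
    direction: str  # 'increasing' or 'decreasing'
    tie_break: str = "site_id"


def order_by_gradient(matrix: pd.DataFrame, gradient: pd.Series, direction: str = "increasing") -> OrderedMatrix:
    """Stable sort of the rows by the gradient; ties broken by site id.

    Sites without a gradient value are dropped with a warning.
    """
    if direction not in ("increasing", "decreasing"):
        raise ValueError("direction must be 'increasing' or 'decreasing'")
    g = gradient.reindex(matrix.index)
    missing = g.isna()
    if missing.any():
        warnings.warn(f"dropping {int(missing.sum())} site(s) without a gradient value")
        matrix = matrix.loc[~missing]
        g = g[~missing]
    key = pd.DataFrame({"g": g if direction == "increasing" else -g, "site": matrix.index})
    order = key.sort_values(["g", "site"], kind="stable").index
    return OrderedMatrix(matrix.loc[order], g.loc[order], direction)


# ---------------------------------------------------------------------------
# WNODF


def _pair_scores(X: np.ndarray) -> tuple[float, int]:
    """Sum of WNODF row-pair scores (i above j) and the number of pairs.

    A pair scores only under decreasing fill -- the upper row must occupy
    strictly more cells than the (nonempty) lower row; the score is the
    fraction of the lower row's occupied cells that are strictly smaller
    than the corresponding upper cell.
    """
    n = X.shape[0]
    nz = (X > 0).sum(axis=1)
    # less[i, j] = #columns with 0 < X[j, k] < X[i, k]
    less = ((X[None, :, :] > 0) & (X[None, :, :] < X[:, None, :])).sum(axis=2)
    nzmat = np.broadcast_to(nz[None, :], (n, n))
    valid = (nz[:, None] > nzmat) & (nzmat > 0)
    score = np.where(valid, 100.0 * less / np.maximum(nzmat, 1), 0.0)
    iu = np.triu_indices(n, k=1)
    return float(score[iu].sum()), len(iu[0])


def wnodf(matrix, component: str = "combined") -> float:
    """Weighted NODF of the matrix in its given order (no internal sorting).

    For each row pair (i above j) with strictly decreasing fill (i occupies
    more cells than the nonempty j), the pair score is 100 x the fraction of
    j's nonzero cells that are strictly smaller than the corresponding cell
    of i; otherwise 0.  Column pairs (left vs right) are scored analogously.
    ``component`` selects the mean over row pairs, column pairs, or their
    combination.
    """
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError("WNODF needs at least 2 rows and 2 columns")
    rsum, rpairs = _pair_scores(X)
    csum, cpairs = _pair_scores(X.T)
    if component == "rows":
        return rsum / rpairs
    if component == "columns":
        return csum / cpairs
    if component == "combined":
        return (rsum + csum) / (rpairs + cpairs)
    raise ValueError(f"unknown component {component!r}")


# ---------------------------------------------------------------------------
# Quantitative swap null model


@_njit(cache=False)
def _swap_chain(mat, n_samples, burn_accepts, thin_proposals, seed, max_stale):  # pragma: no cover
    np.random.seed(seed)
    r, c = mat.shape
    work = mat.copy()
    out = np.zeros((n_samples, r, c), dtype=mat.dtype)
    filled = 0
    accepted = 0
    proposals = 0
    in_burn = True
    stale = 0
    degenerate = False
    while filled < n_samples:
        i1 = np.random.randint(0, r)
        i2 = np.random.randint(0, r)
        j1 = np.random.randint(0, c)
        j2 = np.random.randint(0, c)
        if i1 == i2 or j1 == j2:
            continue
        proposals += 1
        a = work[i1, j1]
        d = work[i2, j2]
        moved = False
        if a > 0 and d > 0:
            delta = 0
            if a == 1:
                delta -= 1
            if d == 1:
                delta -= 1
            if work[i1, j2] == 0:
                delta += 1
            if work[i2, j1] == 0:
                delta += 1
            if delta == 0:
                work[i1, j1] -= 1
                work[i2, j2] -= 1
                work[i1, j2] += 1
                work[i2, j1] += 1
                accepted += 1
                stale = 0
                moved = True
        if not moved:
            stale += 1
            if stale >= max_stale:
                degenerate = True
                break
        if in_burn:
            if accepted >= burn_accepts:
                in_burn = False
                proposals = 0
                out[filled] = work
                filled += 1
        elif proposals >= thin_proposals:
            proposals = 0
            out[filled] = work
            filled += 1
    for f in range(filled, n_samples):
        out[f] = work
    return out, degenerate


def quantitative_swap_null(
    matrix,
    n_nulls: int = 999,
    seed: int = 0,
    burn_factor: int = 10,
    thin_factor: int = 5,
    max_stale: int = 200_000,
) -> tuple[np.ndarray, bool]:
    """Seeded null ensemble preserving row sums, column sums and fill.

    A Markov chain of constrained 2x2 quantitative swap moves (one unit moved
    from a diagonal to the anti-diagonal of a random 2x2 submatrix, rejecting
    moves that change the number of zero cells) is burned in for 10 x #cells
    accepted moves and then sampled every 5 x #cells proposals.  A matrix
    admitting no valid move (or with < 2 rows/columns) yields an ensemble of
    input copies flagged degenerate.
    """
    X = np.asarray(matrix, dtype=np.int64)
    if n_nulls < 1:
        raise ValueError("n_nulls must be >= 1")
    if X.ndim != 2 or X.shape[0] < 2 or X.shape[1] < 2 or (X > 0).sum() == 0:
        return np.repeat(X[None, :, :], n_nulls, axis=0), True
    cells = X.shape[0] * X.shape[1]
    out, degenerate = _swap_chain(
        X, n_nulls, burn_factor * cells, thin_factor * cells, int(seed) % (2**31), max_stale
    )
    return out, bool(degenerate)


def null_zscore(observed: float, ensemble) -> float:
    """(observed - null mean) / null sd; sd of 0 yields NaN with a warning."""
    vals = np.asarray(ensemble, dtype=float)
    if vals.size < 2:
        raise ValueError("null ensemble needs at least 2 values")
    sd = vals.std(ddof=1)
    if sd == 0:
        warnings.warn("null ensemble has zero spread; z-score undefined")
        return float("nan")
    return float((observed - vals.mean()) / sd)


@dataclass
class NestednessResult:
    dataset_id: object
    gradient: str
    component: str
    wnodf_observed: float
    null_mean: float
    null_sd: float
    z: float
    n_nulls: int
    degenerate: bool = False


def nestedness_zscore(
    ordered: OrderedMatrix,
    dataset_id,
    gradient_name: str,
    n_nulls: int = 999,
    seed: int = 0,
    component: str = "combined",
) -> NestednessResult:
    """Observed WNODF of an ordered matrix against its swap-null ensemble.

    Year-averaged matrices can carry fractional cells; they are rounded to
    integers here so the quantitative swap moves (which transfer single
    individuals) are well defined, and the observed statistic is computed on
    the same rounded matrix.
    """
    X = np.rint(np.asarray(ordered.matrix, dtype=float)).astype(np.int64)
    obs = wnodf(X, component)
    nulls, degenerate = quantitative_swap_null(X, n_nulls=n_nulls, seed=seed)
    null_vals = np.array([wnodf(m, component) for m in nulls])
    sd = null_vals.std(ddof=1)
    z = (obs - null_vals.mean()) / sd if sd > 0 else float("nan")
    return NestednessResult(
        dataset_id, gradient_name, component, obs, float(null_vals.mean()), float(sd),
        float(z), n_nulls, degenerate,
    )


# ---------------------------------------------------------------------------
# Study-level tests


def study_nestedness_test(z_by_dataset: pd.Series, study_of: pd.Series) -> dict:
    """Average z within studies, then a two-sided one-sample t-test vs 0."""
    frame = pd.DataFrame({"z": z_by_dataset, "study": study_of.reindex(z_by_dataset.index)})
    frame = frame.dropna()
    per_study = frame.groupby("study")["z"].mean()
    k = len(per_study)
    if k < 2:
        raise ValueError("need z-scores from at least 2 studies")
    sd = per_study.std(ddof=1)
    if sd == 0:
        raise ValueError("all study-level z-scores identical; t-test undefined")
    res = stats.ttest_1samp(per_study, 0.0)
    tcrit = stats.t.ppf(0.975, k - 1)
    mean = float(per_study.mean())
    se = float(sd / np.sqrt(k))
    return {
        "mean": mean,
        "ci": (mean - tcrit * se, mean + tcrit * se),
        "t": float(res.statistic),
        "df": k - 1,
        "p": float(res.pvalue),
        "n_studies": k,
        "per_study": per_study,
    }


def paired_wilcoxon(x, y) -> tuple[float, float]:
    """Two-sided paired Wilcoxon signed-rank test on within-study pairs.

    Zero differences are dropped; the exact distribution is used for up to 25
    nonzero differences (falling back to the normal approximation when ties
    make the exact distribution unavailable), the continuity-corrected normal
    approximation above that.
    """
    d = np.asarray(x, dtype=float) - np.asarray(y, dtype=float)
    d = d[d != 0]
    if d.size == 0:
        warnings.warn("all paired differences are zero; p = 1")
        return 0.0, 1.0
    if d.size <= 25:
        try:
            res = stats.wilcoxon(d, alternative="two-sided", method="exact")
        except Exception:
            res = stats.wilcoxon(d, alternative="two-sided", method="approx", correction=True)
    else:
        res = stats.wilcoxon(d, alternative="two-sided", method="approx", correction=True)
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# Directional beta-diversity decomposition


def directional_decomposition(ordered: OrderedMatrix, shift: int = 3) -> tuple[pd.DataFrame, dict]:
    """Jaccard-denominator turnover/nestedness over site pairs shifted by *shift*.

    For each pair (r, r + shift) along the gradient: a = shared species,
    b = species of the earlier site only (lost), c = later site only
    (gained); D = (b + c)/(a + b + c), turnover T = 2 min(b, c)/(a + b + c),
    nestedness component Nc = |b - c|/(a + b + c), so T + Nc = D.  Each
    pair's T and Nc are attributed wholly to its net direction (losing if
    b > c, gaining if c > b); balanced pairs contribute to neither.  The
    per-matrix means average the attributed values over all pairs.
    """
    occ = (np.asarray(ordered.matrix) > 0)
    n = occ.shape[0]
    if n <= shift:
        raise ValueError(f"need more than {shift} sites for a shift-{shift} decomposition")
    rows = []
    sites = list(ordered.matrix.index)
    for r in range(n - shift):
        early, late = occ[r], occ[r + shift]
        a = int((early & late).sum())
        b = int((early & ~late).sum())
        c = int((~early & late).sum())
        tot = a + b + c
        D = (b + c) / tot if tot else 0.0
        T = 2 * min(b, c) / tot if tot else 0.0
        Nc = abs(b - c) / tot if tot else 0.0
        direction = "losing" if b > c else ("gaining" if c > b else "balanced")
        rows.append(
            {"row_a": sites[r], "row_b": sites[r + shift], "a": a, "b": b, "c": c,
             "D": D, "T": T, "Nc": Nc, "direction": direction}
        )
    pairs = pd.DataFrame(rows)
    losing = pairs["direction"] == "losing"
    gaining = pairs["direction"] == "gaining"
    means = {
        "losing_turnover": float((pairs["T"] * losing).mean()),
        "gaining_turnover": float((pairs["T"] * gaining).mean()),
        "losing_nestedness": float((pairs["Nc"] * losing).mean()),
        "gaining_nestedness": float((pairs["Nc"] * gaining).mean()),
    }
    return pairs, means


def hedges_g_paired(losing, gaining) -> tuple[float, float]:
    """Small-sample-corrected paired standardized mean difference.

    g = J * mean(d) / sd(d) with d = losing - gaining and
    J = 1 - 3 / (4(n - 1) - 1); sampling variance 1/n + g^2 / (2n).
    """
    losing = np.asarray(losing, dtype=float)
    gaining = np.asarray(gaining, dtype=float)
    if losing.shape != gaining.shape:
        raise ValueError("paired vectors must have equal length")
    n = losing.size
    if n < 3:
        raise ValueError("need at least 3 pairs")
    d = losing - gaining
    sd = d.std(ddof=1)
    if sd == 0:
        if np.all(d == 0):  # identical vectors: no effect, by convention g = 0
            return 0.0, 1.0 / n
        raise ValueError("zero variance of paired differences; g undefined")
    J = 1.0 - 3.0 / (4.0 * (n - 1) - 1.0)
    g = J * d.mean() / sd
    return float(g), float(1.0 / n + g**2 / (2.0 * n))


# ---------------------------------------------------------------------------
# Random-effects meta-analysis (DerSimonian-Laird)


@dataclass
class MetaResult:
    pooled: float
    se: float
    ci: tuple
    tau2: float
    i2: float  # percent
    h2: float
    q: float
    q_df: int
    q_p: float
    p: float  # test of the pooled effect (t reference, df = k - 1)
    k: int
    qm: float | None = None
    qm_df: int | None = None
    qm_p: float | None = None
    moderator_retained: bool = False
    cooks: pd.Series | None = None


def _dl_tau2(effects: np.ndarray, variances: np.ndarray, X: np.ndarray) -> tuple[float, float, int]:
    """Generalized DerSimonian-Laird tau^2 for a (weighted) design X."""
    W = np.diag(1.0 / variances)
    XtW = X.T @ W
    H = X @ np.linalg.solve(XtW @ X, XtW)
    resid = effects - H @ effects
    Q = float(resid @ W @ resid)
    df = len(effects) - X.shape[1]
    P = W - W @ X @ np.linalg.solve(XtW @ X, XtW)
    trP = float(np.trace(P))
    tau2 = max(0.0, (Q - df) / trP) if trP > 0 else 0.0
    return tau2, Q, df


def random_effects_meta(effects, variances, moderator=None, alpha: float = 0.05) -> MetaResult:
    """DerSimonian-Laird pooled standardized mean difference.

    tau^2 = max(0, (Q - df)/C); the pooled effect is the inverse-variance
    weighted mean with weights 1/(v_i + tau^2); I2 = max(0, (Q - df)/Q) * 100
    and H2 = Q/df.  The pooled-effect test uses a t reference with k - 1
    degrees of freedom.  With a moderator, its omnibus QM test (Wald chi2 on
    the mixed-effects fit) runs first and the moderator is dropped when
    p > alpha, leaving the random-effects model.
    """
    y = np.asarray(effects, dtype=float)
    v = np.asarray(variances, dtype=float)
    k = y.size
    if k == 0:
        raise ValueError("no effects to pool")
    if (v <= 0).any():
        raise ValueError("sampling variances must be positive")
    if k == 1:
        se = float(np.sqrt(v[0]))
        return MetaResult(float(y[0]), se, (y[0] - 1.96 * se, y[0] + 1.96 * se),
                          0.0, 0.0, 1.0, 0.0, 0, 1.0, float("nan"), 1)

    qm = qm_df = qm_p = None
    retained = False
    if moderator is not None:
        x = np.asarray(moderator, dtype=float)
        if np.std(x) > 0:
            Xm = np.column_stack([np.ones(k), x])
            tau2_m, _, _ = _dl_tau2(y, v, Xm)
            Wm = np.diag(1.0 / (v + tau2_m))
            cov = np.linalg.inv(Xm.T @ Wm @ Xm)
            beta = cov @ Xm.T @ Wm @ y
            qm = float(beta[1] ** 2 / cov[1, 1])
            qm_df = 1
            qm_p = float(stats.chi2.sf(qm, qm_df))
            retained = qm_p <= alpha

    X0 = np.ones((k, 1))
    tau2, Q, df = _dl_tau2(y, v, X0)
    w = 1.0 / (v + tau2)
    pooled = float((w * y).sum() / w.sum())
    se = float(np.sqrt(1.0 / w.sum()))
    tcrit = stats.t.ppf(0.975, k - 1)
    tstat = pooled / se
    p = float(2 * stats.t.sf(abs(tstat), k - 1))
    i2 = float(max(0.0, (Q - df) / Q) * 100) if Q > 0 else 0.0
    h2 = float(max(1.0, Q / df)) if df > 0 else 1.0
    return MetaResult(
        pooled=pooled, se=se, ci=(pooled - tcrit * se, pooled + tcrit * se),
        tau2=float(tau2), i2=i2, h2=h2, q=float(Q), q_df=df,
        q_p=float(stats.chi2.sf(Q, df)) if df > 0 else 1.0,
        p=p, k=k, qm=qm, qm_df=qm_df, qm_p=qm_p, moderator_retained=retained,
    )


def meta_influence(effects, variances) -> pd.Series:
    """Leave-one-out Cook's distance of each study on the pooled effect."""
    y = np.asarray(effects, dtype=float)
    v = np.asarray(variances, dtype=float)
    k = y.size
    if k < 3:
        raise ValueError("influence needs at least 3 studies")
    full = random_effects_meta(y, v)
    cooks = np.zeros(k)
    for i in range(k):
        keep = np.arange(k) != i
        sub = random_effects_meta(y[keep], v[keep])
        cooks[i] = (full.pooled - sub.pooled) ** 2 / full.se**2
    idx = effects.index if isinstance(effects, pd.Series) else pd.RangeIndex(k)
    return pd.Series(cooks, index=idx)


# ---------------------------------------------------------------------------
# Consistency helpers for reported one-sample t summaries


def t_from_summary(mean: float, ci_low: float, ci_high: float, n: int) -> float:
    """Back-compute the t statistic from a reported mean and 95% CI."""
    tcrit = stats.t.ppf(0.975, n - 1)
    se = (ci_high - ci_low) / (2.0 * tcrit)
    return mean / se


def ci_upper_from_t(mean: float, t: float, n: int) -> float:
    """Back-compute the upper 95% CI bound from a reported mean and t."""
    se = mean / t
    return mean + stats.t.ppf(0.975, n - 1) * se
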