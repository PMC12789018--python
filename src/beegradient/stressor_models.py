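"""Standardized random-slope models of hazard and habitat effects.

Community descriptors are z-transformed within datasets (square-root first
for abundance and species richness) and modelled with linear mixed models
carrying a per-dataset random intercept and independent random slopes for the
continuous predictors, fitted by maximum likelihood so that likelihood-ratio
tests between nested fits are valid.  Pesticide hazard enters either as the
continuous (standardized) hazard quotient or as the binary use-intensity
class (0 = low / organic, 1 = high / conventional, unstandardized); the two
are never placed in the same model.  An interaction screen fits the
HQ x SNH product first and reports the additive model as final whenever the
interaction fails its likelihood-ratio test at the 0.05 level.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "within_dataset_standardize",
    "ModelFit",
    "fit_random_slope_lmm",
    "likelihood_ratio_test",
    "interaction_screen",
    "vif",
]


def within_dataset_standardize(values, dataset_ids, sqrt_first: bool = False) -> pd.Series:
    """z-scores computed within each dataset (optional sqrt transform first).

    Datasets with fewer than 3 non-missing values or zero variance are
    flagged with a warning and their values set to NaN (dropped downstream).
    """
    x = pd.Series(np.asarray(values, dtype=float))
    if sqrt_first:
        if (x.dropna() < 0).any():
            raise ValueError("sqrt transform requires nonnegative values")
        x = np.sqrt(x)
    groups = pd.Series(np.asarray(dataset_ids), index=x.index)
    out = pd.Series(np.nan, index=x.index)
    for ds, idx in groups.groupby(groups).groups.items():
        vals = x.loc[idx]
        ok = vals.notna()
        if ok.sum() < 3 or vals[ok].std(ddof=1) == 0:
            warnings.warn(f"dataset {ds!r}: <3 values or zero variance; dropped from standardization")
            continue
        out.loc[idx[ok]] = (vals[ok] - vals[ok].mean()) / vals[ok].std(ddof=1)
    return out


@dataclass
class ModelFit:
    """Fixed estimates (standardized scale), random variances and ML metadata."""

    params: pd.Series
    se: pd.Series
    conf_int: pd.DataFrame  # columns lower, upper
    loglike: float
    n_sites: int
    n_datasets: int
    random_variances: dict = field(default_factory=dict)
    lrt_p: dict = field(default_factory=dict)
    vif: dict = field(default_factory=dict)
    converged: bool = True
    singular: bool = False
    method: str = "mixedlm"


def _fit_mixed(data: pd.DataFrame, response: str, predictors, group: str) -> ModelFit:
    import statsmodels.api as sm
    from statsmodels.regression.mixed_linear_model import MixedLM

    continuous = [p for p in predictors if data[p].nunique() > 2 or ":" in p]
    formula = f"{response} ~ " + (" + ".join(predictors) if predictors else "1")
    vc = {p: f"0 + {p}" for p in continuous}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = MixedLM.from_formula(
            formula, groups=group, re_formula="1", vc_formula=vc or None, data=data
        )
        res = None
        converged_ok = False
        last_exc = None
        for method in ("lbfgs", "powell", "bfgs"):
            try:
                kwargs = {"gtol": 1e-12, "ftol": 1e-14} if method == "lbfgs" else {}
                cand = model.fit(reml=False, method=method, maxiter=2000, **kwargs)
                # warm-start polish until the likelihood stabilizes: the
                # variance surface can be flat enough that a single pass
                # stops short of a reproducible optimum
                stable = False
                for _ in range(4):
                    polished = model.fit(
                        reml=False, method=method, maxiter=2000,
                        start_params=cand.params_object, **kwargs,
                    )
                    stable = abs(polished.llf - cand.llf) < 1e-9
                    if polished.llf >= cand.llf - 1e-10:
                        cand = polished
                    if stable:
                        break
                fe_var = np.diag(cand.cov_params())[: len(cand.fe_params)]
                if not np.all(np.isfinite(fe_var)) or np.any(fe_var < 0):
                    raise np.linalg.LinAlgError("unusable fixed-effect covariance")
                res = cand
                converged_ok = bool(cand.converged) or stable
                if converged_ok:
                    break
            except Exception as exc:  # singular Hessian at a variance boundary
                last_exc = exc
        if res is None:
            # all random variances at the zero boundary: ML coincides with OLS
            fit = _fit_ols(data, response, predictors)
            fit.n_datasets = int(data[group].nunique())
            fit.singular = True
            fit.method = "ols_boundary"
            if fit.n_datasets < 2:
                raise RuntimeError(f"mixed model failed to converge: {last_exc}") from last_exc
            return fit
    names = list(res.fe_params.index)
    params = pd.Series(res.fe_params.values, index=names)
    se = pd.Series(np.sqrt(np.diag(res.cov_params())[: len(names)]), index=names)
    zcrit = stats.norm.ppf(0.975)
    ci = pd.DataFrame({"lower": params - zcrit * se, "upper": params + zcrit * se})
    rv = {"intercept": float(res.cov_re.iloc[0, 0])} if res.cov_re.size else {}
    for name, v in zip(vc, np.atleast_1d(getattr(res, "vcomp", []))):
        rv[name] = float(v)
    singular = any(v < 1e-8 for v in rv.values())
    return ModelFit(
        params=params,
        se=se,
        conf_int=ci,
        loglike=float(res.llf),
        n_sites=int(res.nobs),
        n_datasets=int(data[group].nunique()),
        random_variances=rv,
        converged=converged_ok,
        singular=singular,
    )


def _fit_ols(data: pd.DataFrame, response: str, predictors) -> ModelFit:
    import statsmodels.formula.api as smf

    formula = f"{response} ~ " + (" + ".join(predictors) if predictors else "1")
    res = smf.ols(formula, data=data).fit()
    ci = res.conf_int()
    ci.columns = ["lower", "upper"]
    return ModelFit(
        params=res.params,
        se=res.bse,
        conf_int=ci,
        loglike=float(res.llf),
        n_sites=int(res.nobs),
        n_datasets=1,
        method="ols",
    )


def fit_random_slope_lmm(
    data: pd.DataFrame,
    response: str,
    predictors,
    group: str = "dataset_id",
    compute_lrt: bool = True,
) -> ModelFit:
    """ML fit with per-dataset random intercept and independent random slopes.

    Rows with a missing response or predictor are dropped listwise.  A single
    dataset degenerates to ordinary least squares (where, with standardized
    inputs and one predictor, the slope equals the Pearson correlation).
    Likelihood-ratio p-values per fixed term are obtained by refitting
    without that term under the unchanged random structure.
    """
    predictors = list(predictors)
    cols = [response] + [p for p in predictors if ":" not in p] + [group]
    frame = data[list(dict.fromkeys(cols))].dropna().copy()
    for p in predictors:
        if ":" in p:
            a, b = p.split(":")
            frame[p.replace(":", "_x_")] = frame[a] * frame[b]
    predictors = [p.replace(":", "_x_") for p in predictors]

    if frame[group].nunique() < 2:
        fit = _fit_ols(frame, response, predictors)
    else:
        fit = _fit_mixed(frame, response, predictors, group)
        if compute_lrt:
            for term in predictors:
                reduced = _fit_mixed(frame, response, [p for p in predictors if p != term], group)
                _, _, p = likelihood_ratio_test(fit, reduced)
                fit.lrt_p[term] = p
    if len(predictors) >= 2:
        fit.vif = vif(frame[predictors])
    return fit


def likelihood_ratio_test(full: ModelFit, reduced: ModelFit) -> tuple[float, int, float]:
    """chi2 = 2 * (ll_full - ll_reduced), floored at 0; p from the upper tail."""
    df = len(full.params) - len(reduced.params)
    if df < 0:
        raise ValueError("reduced model has more parameters than the full model")
    if full.n_sites != reduced.n_sites:
        raise ValueError("LRT requires both fits on identical rows")
    chi2 = max(0.0, 2.0 * (full.loglike - reduced.loglike))
    if df == 0:
        return chi2, 0, 1.0
    return chi2, df, float(stats.chi2.sf(chi2, df))


def interaction_screen(
    data: pd.DataFrame,
    response: str,
    hazard: str,
    snh: str = "zsnh",
    group: str = "dataset_id",
    alpha: float = 0.05,
    compute_lrt: bool = True,
) -> dict:
    """Fit hazard x SNH interaction first; keep it only if its LRT p <= alpha.

    Returns the final (additive or interaction) fit together with both fits,
    the interaction LRT and whether the interaction was retained.  A constant
    interaction column (e.g. all sites organic) skips the screen.
    """
    frame = data[[response, hazard, snh, group]].dropna()
    inter = frame[hazard] * frame[snh]
    if inter.nunique() <= 1:
        warnings.warn("interaction column is constant; screen skipped")
        keep = [p for p in (hazard, snh) if frame[p].nunique() > 1]
        additive = fit_random_slope_lmm(frame, response, keep, group,
                                        compute_lrt=compute_lrt)
        return {"final": additive, "additive": additive, "interaction_fit": None,
                "interaction_p": None, "interaction_retained": False}
    full = fit_random_slope_lmm(frame, response, [hazard, snh, f"{hazard}:{snh}"], group,
                                compute_lrt=False)
    additive = fit_random_slope_lmm(frame, response, [hazard, snh], group,
                                    compute_lrt=compute_lrt)
    chi2, df, p = likelihood_ratio_test(full, additive)
    retained = p <= alpha
    return {
        "final": full if retained else additive,
        "additive": additive,
        "interaction_fit": full,
        "interaction_p": p,
        "interaction_chi2": chi2,
        "interaction_retained": retained,
    }


def vif(design: pd.DataFrame) -> dict:
    """Variance inflation factors: VIF_j = 1 / (1 - R2_j) against the others."""
    X = design.to_numpy(dtype=float)
    if X.shape[1] < 2:
        raise ValueError("VIF needs at least 2 predictors")
    if np.linalg.matrix_rank(np.column_stack([np.ones(len(X)), X])) <= X.shape[1]:
        raise ValueError("rank-deficient design (collinear predictors)")
    out = {}
    for j, name in enumerate(design.columns):
        y = X[:, j]
        others = np.column_stack([np.ones(len(X)), np.delete(X, j, axis=1)])
        beta, *_ = np.linalg.lstsq(others, y, rcond=None)
        resid = y - others @ beta
        ss_res = float(resid @ resid)
        ss_tot = float(((y - y.mean()) ** 2).sum())
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
        out[name] = float(1.0 / (1.0 - r2)) if r2 < 1 else float("inf")
    return out
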