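"""Per-site pesticide hazard quotients (HQ) from application records.

The hazard quotient of a site sums, over its N pesticide applications, the log
ratio of the application rate (g active ingredient / ha) to the honey-bee
LD50 (ug/bee) of the active ingredient::

    HQ = sum_{n=1}^{N} log(application_rate_n / LD50_n)

Toxicity resolution follows a fixed cascade: unbounded ('>') limit-test LD50s
enter at their bound value; a missing oral LD50 falls back to the contact
LD50 as a proxy (and vice versa for the contact pathway); applications whose
ingredient cannot be resolved at all -- or that carry only a pesticide type --
receive the mean per-application contribution of the same pesticide type and
production system within the same study, falling back to the cross-study mean
of that type and system, and finally to zero with a warning.

Negative contributions (rate below LD50) are retained; the sum has no floor.
The log base is configurable (natural log by default); a base change rescales
every HQ by the same positive constant and therefore leaves within-dataset
z-scores untouched.
"""

from __future__ import annotations

import math
import warnings

import numpy as np
import pandas as pd

__all__ = [
    "PATHWAYS",
    "PESTICIDE_TYPES",
    "resolve_ld50",
    "application_log_ratio",
    "site_hq",
    "compute_hazard",
    "classify_use_intensity",
    "select_hq_variant",
]

PATHWAYS = ("oral", "contact", "both")
PESTICIDE_TYPES = ("insecticide", "fungicide", "herbicide", "seed_treatment")

#: preference order used to break ties between exposure-pathway variants
_VARIANT_PREFERENCE = ("oral", "contact", "both")


def _validate_toxicity(toxicity: pd.DataFrame) -> pd.DataFrame:
    """Index the toxicity table by ingredient, rejecting nonpositive LD50s."""
    for col in ("oral_ld50_ug_bee", "contact_ld50_ug_bee"):
        bad = toxicity[col].notna() & (toxicity[col] <= 0)
        if bad.any():
            names = toxicity.loc[bad, "active_ingredient"].tolist()
            raise ValueError(f"nonpositive {col} for ingredient(s): {names}")
    dup = toxicity["active_ingredient"].duplicated()
    if dup.any():
        names = toxicity.loc[dup, "active_ingredient"].unique().tolist()
        raise ValueError(f"duplicate toxicity records for: {names}")
    return toxicity.set_index("active_ingredient")


def resolve_ld50(ingredient: str, toxicity: pd.DataFrame, pathway: str = "oral"):
    """Resolve the LD50 (ug/bee) of *ingredient* for an exposure pathway.

    Returns ``None`` when no LD50 is obtainable (the imputation path).
    Unbounded ('>') records resolve to their bound value: a limit-test
    minimum is the most hazard-conservative number available.
    """
    if pathway not in PATHWAYS:
        raise ValueError(f"unknown pathway {pathway!r}")
    tox = toxicity if toxicity.index.name == "active_ingredient" else _validate_toxicity(toxicity)
    if ingredient not in tox.index:
        return None
    row = tox.loc[ingredient]
    oral = row["oral_ld50_ug_bee"]
    contact = row["contact_ld50_ug_bee"]
    oral = None if pd.isna(oral) else float(oral)
    contact = None if pd.isna(contact) else float(contact)
    if pathway == "oral":
        return oral if oral is not None else contact
    if pathway == "contact":
        return contact if contact is not None else oral
    avail = [v for v in (oral, contact) if v is not None]
    return min(avail) if avail else None


def application_log_ratio(rate: float, ld50: float, log_base: float | None = None) -> float:
    """log(rate / LD50) in the configured base (natural log by default)."""
    if rate is None or ld50 is None or rate <= 0 or ld50 <= 0:
        raise ValueError(f"rate and LD50 must be positive, got rate={rate}, ld50={ld50}")
    value = math.log(rate / ld50)
    if log_base is not None:
        value /= math.log(log_base)
    return value


def site_hq(contributions) -> float:
    """Sum per-application contributions for one site; empty -> 0."""
    return float(np.sum(contributions)) if len(contributions) else 0.0


def classify_use_intensity(production_system) -> str | None:
    """conventional -> 'high', organic -> 'low', unknown -> None."""
    if production_system == "conventional":
        return "high"
    if production_system == "organic":
        return "low"
    return None


def compute_hazard(
    applications: pd.DataFrame,
    toxicity: pd.DataFrame,
    sites: pd.DataFrame,
    pathways=PATHWAYS,
    log_base: float | None = None,
) -> pd.DataFrame:
    """Per-site HQ under each exposure pathway, with imputation.

    Parameters
    ----------
    applications
        site_id, pesticide_type, active_ingredient (may be missing),
        application_rate_g_ha (may be missing), source.
    toxicity
        active_ingredient, oral_ld50_ug_bee, oral_bounded,
        contact_ld50_ug_bee, contact_bounded and, optionally,
        label_rate_g_ha (the national-label default rate used when a
        farmer reported the product but not the rate).
    sites
        site_id, dataset_id, study_id, production_system.

    Returns
    -------
    DataFrame with one row per site: hq_<pathway> columns, n_applications,
    n_imputed and intensity_class.  Sites without applications get HQ 0.
    """
    tox = _validate_toxicity(toxicity)
    has_label = "label_rate_g_ha" in tox.columns

    site_info = sites.set_index("site_id")
    apps = applications.copy()
    apps["study_id"] = apps["site_id"].map(site_info["study_id"])
    apps["production_system"] = apps["site_id"].map(site_info["production_system"])

    out = pd.DataFrame(index=site_info.index)
    for pathway in pathways:
        if pathway not in PATHWAYS:
            raise ValueError(f"unknown pathway {pathway!r}")
        contrib = np.full(len(apps), np.nan)
        for k, row in enumerate(apps.itertuples(index=False)):
            ingredient = row.active_ingredient
            if pd.isna(ingredient):
                continue  # type-only record: imputed below
            ld50 = resolve_ld50(ingredient, tox, pathway)
            if ld50 is None:
                continue
            rate = row.application_rate_g_ha
            if pd.isna(rate) and has_label:
                rate = tox["label_rate_g_ha"].get(ingredient, np.nan)
            if pd.isna(rate):
                continue
            contrib[k] = application_log_ratio(float(rate), ld50, log_base)

        imputed = np.isnan(contrib)
        if imputed.any():
            contrib = _impute_contributions(apps, contrib)
        per_site = pd.Series(contrib, index=apps["site_id"].to_numpy())
        out[f"hq_{pathway}"] = per_site.groupby(level=0).sum().reindex(out.index).fillna(0.0)
        if "n_imputed" not in out.columns:
            imp = pd.Series(imputed.astype(int), index=apps["site_id"].to_numpy())
            out["n_imputed"] = imp.groupby(level=0).sum().reindex(out.index).fillna(0).astype(int)

    napp = apps.groupby("site_id").size().reindex(out.index).fillna(0).astype(int)
    out["n_applications"] = napp
    out["intensity_class"] = site_info["production_system"].map(
        {"conventional": "high", "organic": "low"}
    )
    return out.reset_index().rename(columns={"index": "site_id"})


def impute_type_only(
    pesticide_type: str,
    production_system: str,
    study_id,
    resolved: pd.DataFrame,
) -> float:
    """Mean contribution of (type, system) within the study, then across studies.

    *resolved* carries columns pesticide_type, production_system, study_id and
    contribution for every application whose HQ term could be computed
    directly.  No matching stratum at all -> 0 with a warning.
    """
    same_type = resolved[
        (resolved["pesticide_type"] == pesticide_type)
        & (resolved["production_system"] == production_system)
    ]
    in_study = same_type[same_type["study_id"] == study_id]
    if len(in_study):
        return float(in_study["contribution"].mean())
    if len(same_type):
        return float(same_type["contribution"].mean())
    warnings.warn(
        f"no contributions of type={pesticide_type!r} system={production_system!r} "
        "anywhere; imputing 0",
        stacklevel=2,
    )
    return 0.0


def _impute_contributions(apps: pd.DataFrame, contrib: np.ndarray) -> np.ndarray:
    resolved = apps.loc[~np.isnan(contrib), ["pesticide_type", "production_system", "study_id"]].copy()
    resolved["contribution"] = contrib[~np.isnan(contrib)]
    filled = contrib.copy()
    for k in np.flatnonzero(np.isnan(contrib)):
        row = apps.iloc[k]
        filled[k] = impute_type_only(
            row["pesticide_type"], row["production_system"], row["study_id"], resolved
        )
    return filled


def select_hq_variant(
    hazard: pd.DataFrame,
    metrics: pd.DataFrame,
    sites: pd.DataFrame,
    responses=("abundance", "richness", "fd", "pd"),
    sqrt_responses=("abundance", "richness"),
) -> tuple[str, pd.DataFrame]:
    """Pick the exposure pathway that best predicts the community descriptors.

    For every computed hq_<pathway> column, the mean absolute Pearson
    correlation against the within-dataset-standardized responses is
    evaluated (square-root transform first for abundance-like responses,
    mirroring the model stage); the pathway with the largest mean |r| wins,
    ties broken in the fixed preference order oral > contact > both.
    """
    from .stressor_models import within_dataset_standardize

    variants = [p for p in _VARIANT_PREFERENCE if f"hq_{p}" in hazard.columns]
    if not variants:
        raise ValueError("hazard table contains no hq_<pathway> columns")

    frame = hazard.merge(sites[["site_id", "dataset_id"]], on="site_id").merge(
        metrics[["site_id", *[r for r in responses if r in metrics.columns]]], on="site_id"
    )
    rows = []
    for pathway in variants:
        zhq = within_dataset_standardize(frame[f"hq_{pathway}"], frame["dataset_id"])
        rs = {}
        for resp in responses:
            if resp not in frame.columns:
                continue
            z = within_dataset_standardize(
                frame[resp], frame["dataset_id"], sqrt_first=resp in sqrt_responses
            )
            ok = zhq.notna() & z.notna()
            if ok.sum() >= 3 and zhq[ok].std() > 0 and z[ok].std() > 0:
                rs[resp] = float(np.corrcoef(zhq[ok], z[ok])[0, 1])
        if not rs:
            raise ValueError(f"all correlations undefined for pathway {pathway!r}")
        rows.append({"pathway": pathway, "mean_abs_r": float(np.mean(np.abs(list(rs.values())))), **{f"r_{k}": v for k, v in rs.items()}})
    report = pd.DataFrame(rows)
    best = report.loc[report["mean_abs_r"].idxmax(), "pathway"]
    # ties resolved by preference order (report rows are already in that order)
    top = report["mean_abs_r"].max()
    for pathway in variants:
        if report.loc[report["pathway"] == pathway, "mean_abs_r"].iloc[0] >= top - 1e-12:
            best = pathway
            break
    return best, report
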