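"""Configuration, I/O, validation and the end-to-end pipeline.

Stage order follows the analysis: hazard quotients -> per-site community
descriptors -> standardized random-slope models -> gradient-ordered
nestedness / directional turnover with meta-analysis.  Dataset-level filters
are applied between stages: datasets whose sites carry fewer than three
distinct HQ values are removed (several downstream analyses require a hazard
gradient), and sites averaging ten or fewer bees are excluded from the
models.  Identical configuration and seed reproduce every output byte.
"""

from __future__ import annotations

import json
import time
import warnings
from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path

import numpy as np
import pandas as pd

from . import beta_structure as beta
from . import community_metrics as cm
from . import pesticide_hazard as ph
from . import stressor_models as sm
from .synthetic_data import GroundTruth, SimulationConfig, StudyCollection, degrade_collection, generate_collection

__all__ = [
    "PipelineConfig",
    "validate_inputs",
    "run_pipeline",
    "write_collection",
    "read_collection",
]

EXCLUDED_TAXA = ("Apis_mellifera",)
RESPONSES = ("abundance", "richness", "rarefied_richness", "fd", "pd", "fmpd", "pmpd", "feve", "fspe")
SQRT_RESPONSES = ("abundance", "richness", "rarefied_richness")


@dataclass
class PipelineConfig:
    """All knobs of a pipeline run; defaults are the analysis defaults."""

    input_dir: str | None = None  # read the five CSV tables from here, or ...
    simulation: SimulationConfig | None = None  # ... simulate a collection
    degrade: bool = True  # apply real-data pathologies to simulated input
    hazard_pathway: str = "auto"  # 'oral', 'contact', 'both' or 'auto'
    log_base: float | None = None  # None = natural log
    inclusion_threshold: float = 10.0  # mean bees per site, strict >
    min_distinct_hq: int = 3
    n_nulls: int = 999
    shift: int = 3
    n_axes: int = 4
    balance_traits: bool = True
    exclude_trait_cols: tuple = ()
    responses: tuple = RESPONSES
    seed: int = 0
    out_dir: str | None = None

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        known = {f.name for f in dc_fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        raw = dict(raw)
        if isinstance(raw.get("simulation"), dict):
            sim_known = {f.name for f in dc_fields(SimulationConfig)}
            sim_unknown = set(raw["simulation"]) - sim_known
            if sim_unknown:
                raise ValueError(f"unknown simulation keys: {sorted(sim_unknown)}")
            raw["simulation"] = SimulationConfig(**raw["simulation"])
        for key in ("exclude_trait_cols", "responses"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


# ---------------------------------------------------------------------------
# Collection I/O (CSV, UTF-8, comma, '.' decimal)

_TABLES = ("sites", "applications", "toxicity", "communities", "traits")


def write_collection(collection: StudyCollection, out_dir, truth: GroundTruth | None = None) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name in _TABLES:
        getattr(collection, name).to_csv(out / f"{name}.csv", index=False)
    if truth is not None:
        payload = {
            "beta_hq": truth.beta_hq,
            "beta_snh": truth.beta_snh,
            "beta_interaction": truth.beta_interaction,
            "species_sensitivity": truth.species_sensitivity.to_dict(),
            "species_baseline": truth.species_baseline.to_dict(),
        }
        (out / "ground_truth.json").write_text(json.dumps(payload, indent=1))


def read_collection(in_dir) -> StudyCollection:
    path = Path(in_dir)
    frames = {}
    for name in _TABLES:
        f = path / f"{name}.csv"
        if not f.exists():
            raise FileNotFoundError(f"missing input table: {f}")
        frames[name] = pd.read_csv(f)
    return StudyCollection(**frames)


# ---------------------------------------------------------------------------
# Validation


def validate_inputs(collection: StudyCollection) -> pd.DataFrame:
    """Referential-integrity and range checks; returns a violation table."""
    rows = []

    def flag(table, row, column, message):
        rows.append({"table": table, "row": row, "column": column, "message": message})

    sites = collection.sites
    if sites.empty:
        flag("sites", None, None, "site table is empty")
    dup = sites["site_id"].duplicated() if "site_id" in sites else pd.Series(dtype=bool)
    for i in sites.index[dup]:
        flag("sites", int(i), "site_id", f"duplicate site id {sites.at[i, 'site_id']!r}")
    if "snh" in sites:
        bad = sites["snh"].notna() & ((sites["snh"] < 0) | (sites["snh"] > 1))
        for i in sites.index[bad]:
            flag("sites", int(i), "snh", f"SNH {sites.at[i, 'snh']} outside [0, 1]")
    known_sites = set(sites.get("site_id", pd.Series(dtype=object)))

    apps = collection.applications
    for i in apps.index[~apps["site_id"].isin(known_sites)]:
        flag("applications", int(i), "site_id", f"unknown site {apps.at[i, 'site_id']!r}")
    bad_rate = apps["application_rate_g_ha"].notna() & (apps["application_rate_g_ha"] <= 0)
    for i in apps.index[bad_rate]:
        flag("applications", int(i), "application_rate_g_ha", "rate must be positive")
    bad_type = ~apps["pesticide_type"].isin(ph.PESTICIDE_TYPES)
    for i in apps.index[bad_type]:
        flag("applications", int(i), "pesticide_type", f"unknown type {apps.at[i, 'pesticide_type']!r}")

    tox = collection.toxicity
    for col in ("oral_ld50_ug_bee", "contact_ld50_ug_bee"):
        bad = tox[col].notna() & (tox[col] <= 0)
        for i in tox.index[bad]:
            flag("toxicity", int(i), col, "LD50 must be positive")
    for i in tox.index[tox["active_ingredient"].duplicated()]:
        flag("toxicity", int(i), "active_ingredient", "duplicate ingredient")

    comm = collection.communities
    for i in comm.index[~comm["site_id"].isin(known_sites)]:
        flag("communities", int(i), "site_id", f"unknown site {comm.at[i, 'site_id']!r}")
    bad_ab = (comm["abundance"] < 0) | (comm["abundance"] % 1 != 0)
    for i in comm.index[bad_ab]:
        flag("communities", int(i), "abundance", "abundance must be a nonnegative integer")
    for i in comm.index[comm["effort"] <= 0]:
        flag("communities", int(i), "effort", "effort must be positive")
    known_species = set(collection.traits["species_id"])
    for i in comm.index[~comm["species_id"].isin(known_species)]:
        flag("communities", int(i), "species_id", f"unknown species {comm.at[i, 'species_id']!r}")

    for i in collection.traits.index[collection.traits["species_id"].duplicated()]:
        flag("traits", int(i), "species_id", "duplicate species id")
    return pd.DataFrame(rows, columns=["table", "row", "column", "message"])


# ---------------------------------------------------------------------------
# Stage runners


def _metrics_stage(collection: StudyCollection, config: PipelineConfig) -> pd.DataFrame:
    """Per-site descriptors: per (year, method) panel, then averaged."""
    all_metrics = []
    for dataset_id in collection.dataset_ids():
        sub = collection.communities[collection.communities["dataset_id"] == dataset_id]
        if sub.empty:
            continue
        species = sorted(set(sub["species_id"]) - set(EXCLUDED_TAXA))
        if len(species) < 3:
            warnings.warn(f"dataset {dataset_id}: fewer than 3 species; metrics skipped")
            continue
        ctx = cm.build_dataset_context(
            collection.traits, species, n_axes=config.n_axes,
            balance=config.balance_traits, exclude_trait_cols=config.exclude_trait_cols,
        )
        # dataset-wide rarefaction reference: smallest positive site total
        full_mat, _ = collection.community_matrix(dataset_id)
        full_mat = cm.exclude_taxa(full_mat, EXCLUDED_TAXA)
        totals = full_mat.sum(axis=1)
        m_ref = int(max(1, totals[totals > 0].min())) if (totals > 0).any() else 1

        panels = []
        for (year, method), panel in sub.groupby(["year", "method"]):
            mat = panel.pivot_table(index="site_id", columns="species_id", values="abundance",
                                    aggfunc="sum", fill_value=0)
            mat = cm.exclude_taxa(mat, EXCLUDED_TAXA)
            if mat.empty or mat.shape[1] == 0:
                continue
            effort = panel.groupby("site_id")["effort"].mean()
            met = cm.compute_site_metrics(mat, effort, ctx, rarefaction_m=m_ref)
            met["year"] = year
            met["method"] = method
            met["raw_total"] = met["site_id"].map(mat.sum(axis=1))
            panels.append(met)
        if not panels:
            continue
        agg = cm.aggregate_site_metrics(pd.concat(panels, ignore_index=True),
                                        inclusion_threshold=config.inclusion_threshold)
        agg.insert(0, "dataset_id", dataset_id)
        all_metrics.append(agg)
    if not all_metrics:
        raise ValueError("no dataset produced community metrics")
    return pd.concat(all_metrics, ignore_index=True)


def _models_stage(frame: pd.DataFrame, config: PipelineConfig) -> dict:
    """Interaction-screened HQ models and intensity models per response."""
    out = {}
    for response in config.responses:
        col = f"z_{response}"
        if col not in frame.columns:
            continue
        entry = {}
        data = frame[[col, "zhq", "zsnh", "dataset_id"]].dropna()
        if data["dataset_id"].nunique() >= 2 and len(data) >= 10:
            screen = sm.interaction_screen(data, col, "zhq", "zsnh", "dataset_id")
            entry["hq"] = _fit_to_dict(screen["final"])
            entry["hq"]["interaction_p"] = screen["interaction_p"]
            entry["hq"]["interaction_retained"] = screen["interaction_retained"]
        idata = frame[[col, "intensity", "zsnh", "dataset_id"]].dropna()
        if idata["dataset_id"].nunique() >= 2 and idata["intensity"].nunique() > 1 and len(idata) >= 10:
            fit = sm.fit_random_slope_lmm(idata, col, ["intensity", "zsnh"], "dataset_id")
            entry["intensity"] = _fit_to_dict(fit)
        if entry:
            out[response] = entry
    return out


def _fit_to_dict(fit: sm.ModelFit) -> dict:
    return {
        "estimates": fit.params.to_dict(),
        "se": fit.se.to_dict(),
        "ci": {k: [fit.conf_int.at[k, "lower"], fit.conf_int.at[k, "upper"]] for k in fit.conf_int.index},
        "lrt_p": fit.lrt_p,
        "random_variances": fit.random_variances,
        "loglike": fit.loglike,
        "n_sites": fit.n_sites,
        "n_datasets": fit.n_datasets,
        "vif": fit.vif,
        "converged": fit.converged,
        "singular": fit.singular,
        "method": fit.method,
    }


def _beta_stage(collection: StudyCollection, hazard: pd.DataFrame, hq_col: str,
                config: PipelineConfig, datasets: list) -> dict:
    """Nestedness z-scores, study tests, directional decomposition, meta."""
    sites = collection.sites.set_index("site_id")
    hq = hazard.set_index("site_id")[hq_col]
    nest_rows, pair_rows = [], []
    gmeans: dict = {}
    for d_idx, dataset_id in enumerate(datasets):
        mat, _ = collection.community_matrix(dataset_id, average_years=True)
        mat = cm.exclude_taxa(mat, EXCLUDED_TAXA)
        mat = mat.loc[:, mat.sum(axis=0) > 0]
        if mat.shape[0] < max(4, config.shift + 1) or mat.shape[1] < 2:
            continue
        snh = sites.loc[mat.index, "snh"]
        for gradient, values, direction in (
            ("hq", hq.reindex(mat.index), "increasing"),
            ("snh", snh, "decreasing"),
        ):
            ordered = beta.order_by_gradient(mat, values, direction)
            seed = int(np.random.SeedSequence(entropy=config.seed, spawn_key=(3, d_idx)).generate_state(1)[0] % (2**31))
            res = beta.nestedness_zscore(ordered, dataset_id, gradient,
                                         n_nulls=config.n_nulls, seed=seed)
            nest_rows.append(res)
            pairs, means = beta.directional_decomposition(ordered, shift=config.shift)
            pairs.insert(0, "gradient", gradient)
            pairs.insert(0, "dataset_id", dataset_id)
            pair_rows.append(pairs)
            gmeans.setdefault(gradient, {})[dataset_id] = (pairs, means)

    nest = pd.DataFrame(
        [
            {"dataset_id": r.dataset_id, "gradient": r.gradient, "component": r.component,
             "wnodf": r.wnodf_observed, "null_mean": r.null_mean, "null_sd": r.null_sd,
             "z": r.z, "n_nulls": r.n_nulls, "degenerate": r.degenerate}
            for r in nest_rows
        ]
    )
    study_of = collection.sites.drop_duplicates("dataset_id").set_index("dataset_id")["study_id"]
    attractive = collection.sites.drop_duplicates("dataset_id").set_index("dataset_id")["crop_attractive"] \
        if "crop_attractive" in collection.sites else None

    tests, meta_out = {}, {}
    for gradient in ("hq", "snh"):
        zs = nest[(nest["gradient"] == gradient)].set_index("dataset_id")["z"].dropna()
        if len(zs) >= 2 and study_of.reindex(zs.index).nunique() >= 2:
            try:
                tests[gradient] = {
                    k: v for k, v in beta.study_nestedness_test(zs, study_of).items() if k != "per_study"
                }
            except ValueError as exc:
                warnings.warn(f"nestedness t-test ({gradient}): {exc}")

    # paired Wilcoxon: study-averaged z under the two gradients
    wide = nest.pivot_table(index="dataset_id", columns="gradient", values="z")
    if {"hq", "snh"} <= set(wide.columns):
        wide["study"] = study_of.reindex(wide.index)
        per_study = wide.dropna().groupby("study")[["hq", "snh"]].mean()
        if len(per_study) >= 2:
            stat, p = beta.paired_wilcoxon(per_study["hq"], per_study["snh"])
            tests["paired_wilcoxon_hq_vs_snh"] = {"statistic": stat, "p": p, "n_pairs": len(per_study)}

    for gradient, by_ds in gmeans.items():
        for component in ("Nc", "T"):
            effects, variances, mods, ids = [], [], [], []
            for dataset_id, (pairs, _) in by_ds.items():
                losing = np.where(pairs["direction"] == "losing", pairs[component], 0.0)
                gaining = np.where(pairs["direction"] == "gaining", pairs[component], 0.0)
                try:
                    g, var = beta.hedges_g_paired(losing, gaining)
                except ValueError:
                    continue
                effects.append(g)
                variances.append(var)
                ids.append(dataset_id)
                if attractive is not None:
                    mods.append(float(bool(attractive.get(dataset_id, False))))
            if len(effects) < 2:
                continue
            mod = np.asarray(mods) if attractive is not None else None
            res = beta.random_effects_meta(np.asarray(effects), np.asarray(variances), moderator=mod)
            cooks = beta.meta_influence(pd.Series(effects, index=ids), np.asarray(variances)) \
                if len(effects) >= 3 else None
            name = {"Nc": "nestedness", "T": "turnover"}[component]
            meta_out[f"{gradient}_{name}"] = {
                "pooled": res.pooled, "se": res.se, "ci": list(res.ci), "tau2": res.tau2,
                "I2": res.i2, "H2": res.h2, "Q": res.q, "Q_df": res.q_df, "Q_p": res.q_p,
                "p": res.p, "k": res.k, "QM": res.qm, "QM_p": res.qm_p,
                "moderator_retained": res.moderator_retained,
                "cooks": cooks.to_dict() if cooks is not None else None,
            }

    return {
        "nestedness": nest,
        "beta_pairs": pd.concat(pair_rows, ignore_index=True) if pair_rows else pd.DataFrame(),
        "tests": tests,
        "meta": meta_out,
    }


# ---------------------------------------------------------------------------
# The pipeline


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage; returns all stage outputs plus a run report."""
    t0 = time.time()
    import statsmodels

    from . import __version__

    report: dict = {
        "seed": config.seed,
        "exclusions": [],
        "counts": {},
        "versions": {
            "beegradient": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "statsmodels": statsmodels.__version__,
        },
    }

    truth = None
    if config.input_dir is not None:
        collection = read_collection(config.input_dir)
    else:
        sim = config.simulation or SimulationConfig(seed=config.seed)
        collection, truth = generate_collection(sim)
        if config.degrade:
            collection = degrade_collection(collection, sim)

    violations = validate_inputs(collection)
    if len(violations):
        raise ValueError(
            "input validation failed:\n" + violations.to_string(index=False)
        )

    report["counts"]["sites"] = len(collection.sites)
    report["counts"]["applications"] = len(collection.applications)
    report["counts"]["datasets"] = len(collection.dataset_ids())

    hazard = ph.compute_hazard(
        collection.applications, collection.toxicity, collection.sites, log_base=config.log_base
    )

    metrics = _metrics_stage(collection, config)

    if config.hazard_pathway == "auto":
        pathway, variant_report = ph.select_hq_variant(hazard, metrics, collection.sites)
    else:
        pathway, variant_report = config.hazard_pathway, None
    hq_col = f"hq_{pathway}"

    # dataset filter: a hazard gradient needs >= min_distinct_hq distinct values
    hq_by_ds = hazard.merge(collection.sites[["site_id", "dataset_id"]], on="site_id")
    distinct = hq_by_ds.groupby("dataset_id")[hq_col].nunique()
    dropped = sorted(distinct.index[distinct < config.min_distinct_hq])
    for ds in dropped:
        report["exclusions"].append({"dataset_id": ds, "reason": "hq_gradient"})
    hq_datasets = sorted(distinct.index[distinct >= config.min_distinct_hq])

    excluded_sites = metrics.loc[metrics["excluded"], "site_id"].tolist()
    for s in excluded_sites:
        report["exclusions"].append({"site_id": s, "reason": "inclusion_threshold"})

    frame = (
        metrics[~metrics["excluded"]]
        .merge(hazard, on="site_id")
        .merge(collection.sites[["site_id", "study_id", "snh", "production_system"]], on="site_id")
    )
    frame = frame[frame["dataset_id"].isin(hq_datasets)]
    frame["zhq"] = sm.within_dataset_standardize(frame[hq_col], frame["dataset_id"])
    frame["zsnh"] = sm.within_dataset_standardize(frame["snh"], frame["dataset_id"])
    frame["intensity"] = frame["intensity_class"].map({"high": 1.0, "low": 0.0})
    for response in config.responses:
        if response in frame.columns:
            frame[f"z_{response}"] = sm.within_dataset_standardize(
                frame[response], frame["dataset_id"], sqrt_first=response in SQRT_RESPONSES
            )

    models = _models_stage(frame, config)
    beta_out = _beta_stage(collection, hazard, hq_col, config, hq_datasets)

    report["hazard_pathway"] = pathway
    report["counts"]["modelled_sites"] = int(len(frame))
    report["counts"]["modelled_datasets"] = int(frame["dataset_id"].nunique())
    report["wall_time_s"] = round(time.time() - t0, 2)

    result = {
        "collection": collection,
        "truth": truth,
        "hazard": hazard,
        "metrics": metrics,
        "analysis_frame": frame,
        "variant_report": variant_report,
        "models": models,
        "beta": beta_out,
        "report": report,
    }
    if config.out_dir is not None:
        _write_outputs(result, config)
    return result


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating, float)):
        f = float(obj)
        return f if np.isfinite(f) else None
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def _write_outputs(result: dict, config: PipelineConfig) -> None:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_collection(result["collection"], out / "inputs", result["truth"])
    result["hazard"].to_csv(out / "hazard.csv", index=False)
    result["metrics"].to_csv(out / "metrics.csv", index=False)
    result["beta"]["nestedness"].to_csv(out / "nestedness.csv", index=False)
    result["beta"]["beta_pairs"].to_csv(out / "beta_pairs.csv", index=False)
    (out / "models.json").write_text(json.dumps(_jsonable(result["models"]), indent=1))
    (out / "meta.json").write_text(
        json.dumps(_jsonable({"tests": result["beta"]["tests"], "meta": result["beta"]["meta"]}), indent=1)
    )
    (out / "report.json").write_text(json.dumps(_jsonable(result["report"]), indent=1))
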