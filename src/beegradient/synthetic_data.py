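"""Synthetic multi-study collections of wild-bee survey data.

The generator emulates the structure of a global synthesis of field studies:
studies contain datasets, datasets contain crop-field sites with a proportion
of semi-natural habitat (SNH) in the surrounding landscape and an organic or
conventional production system; conventional sites carry pesticide
application records (active ingredient, rate) whose hazard quotient
HQ = sum log(rate / LD50) forms the stressor gradient; each dataset holds a
site x species abundance matrix over a regional subset of a global species
pool with six traits and a family/genus taxonomy.

Effects are planted on the standardized scale: the requested ``beta_hq`` and
``beta_snh`` are the slopes a within-dataset-standardized regression of
z(sqrt total abundance) on z(HQ) and z(SNH) should recover.  Internally the
log-linear coefficients are calibrated against a delta-method estimate of the
sampling noise of sqrt(total) under negative-binomial counts, so that
corr(z(sqrt T), zHQ) = beta_hq in expectation.  Species-level sensitivity to
hazard is an ordered sequence (rarer species more sensitive) applied through
a composition reweighting that leaves the expected total unchanged; this is
what makes high-hazard communities nested subsets of low-hazard ones.

``degrade_collection`` then layers on the messiness of real compilations:
unbounded ('>') LD50s, missing oral LD50s, type-only application records,
missing application rates, and per-trait missing values.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "StudyCollection",
    "generate_collection",
    "degrade_collection",
]

FAMILIES = ("Andrenidae", "Apidae", "Colletidae", "Halictidae", "Megachilidae", "Melittidae")

_DEFAULT_TRAIT_MISSINGNESS = {
    "body_size_mm": 0.24,
    "lecty": 0.28,
    "sociality": 0.04,
    "nest_location": 0.04,
    "nesting_strategy": 0.04,
    "kleptoparasitism": 0.04,
}


@dataclass(frozen=True)
class SimulationConfig:
    """Conditions of a simulated multi-study synthesis.

    Defaults mirror the structure of the synthesis being emulated: 36
    datasets nested in 26 studies (10 studies contribute two datasets),
    SNH uniform on [0, 0.8], roughly a third organic sites, negative
    standardized hazard effect and positive SNH effect on abundance with no
    interaction, negative-binomial counts with dispersion 1.
    """

    n_studies: int = 26
    datasets_per_study: int = 1
    studies_with_extra_dataset: int = 10
    sites_per_dataset: int = 18
    species_pool_size: int = 120
    species_per_dataset: int = 30
    snh_range: tuple = (0.0, 0.8)
    frac_organic: float = 0.3
    apps_per_site_range: tuple = (2, 10)
    beta_hq: float = -0.3
    beta_snh: float = 0.3
    beta_interaction: float = 0.0
    sensitivity_sd: float = 0.3
    abundance_dispersion: float = 1.0
    mean_site_total: float = 60.0
    effort: float = 4.0
    trait_missingness: object = field(default_factory=lambda: dict(_DEFAULT_TRAIT_MISSINGNESS))
    ld50_unbounded_frac: float = 0.64
    oral_missing_frac: float = 0.06
    type_only_frac: float = 0.03
    rate_missing_frac: float = 0.10
    include_honeybee: bool = True
    seed: int = 0

    def missingness(self) -> dict:
        if isinstance(self.trait_missingness, dict):
            return dict(self.trait_missingness)
        return {c: float(self.trait_missingness) for c in _DEFAULT_TRAIT_MISSINGNESS}

    def validate(self) -> None:
        for name in ("frac_organic", "ld50_unbounded_frac", "oral_missing_frac",
                     "type_only_frac", "rate_missing_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name, v in self.missingness().items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"trait_missingness[{name}] must be in [0, 1]")
        for name in ("n_studies", "datasets_per_study", "sites_per_dataset",
                     "species_pool_size", "species_per_dataset"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.sites_per_dataset < 4:
            raise ValueError("sites_per_dataset must be >= 4 (shift-3 site pairs)")
        if self.species_pool_size < 10:
            raise ValueError("species_pool_size must be >= 10")
        lo, hi = self.snh_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValueError("snh_range must be an interval within [0, 1]")
        if self.species_per_dataset > self.species_pool_size:
            raise ValueError("species_per_dataset cannot exceed the pool size")
        total_beta2 = self.beta_hq**2 + self.beta_snh**2 + self.beta_interaction**2
        if total_beta2 >= 0.9:
            raise ValueError("planted standardized effects too large (sum of squares >= 0.9)")
        if self.abundance_dispersion <= 0:
            raise ValueError("abundance_dispersion must be positive")


@dataclass
class GroundTruth:
    """Planted parameters, recorded for parameter-recovery checks."""

    beta_hq: float
    beta_snh: float
    beta_interaction: float
    species_sensitivity: pd.Series  # per pool species, hazard tolerance score
    species_baseline: pd.Series  # per pool species, log mean abundance
    site_latent: pd.DataFrame  # site_id, hq_latent, zhq, zsnh


@dataclass
class StudyCollection:
    """A full multi-study bundle of survey tables.

    sites: site_id, dataset_id, study_id, snh, production_system,
    landscape_radius_km, crop_attractive, field_size_ha.
    applications / toxicity / communities (long form) / traits follow the CSV
    schemas written by the pipeline; traits carries the taxonomy columns.
    """

    sites: pd.DataFrame
    applications: pd.DataFrame
    toxicity: pd.DataFrame
    communities: pd.DataFrame
    traits: pd.DataFrame

    @property
    def taxonomy(self) -> pd.DataFrame:
        return self.traits[["species_id", "family", "genus"]]

    def dataset_ids(self) -> list:
        return sorted(self.sites["dataset_id"].unique())

    def community_matrix(
        self, dataset_id, year=None, method=None, average_years: bool = False
    ) -> tuple[pd.DataFrame, pd.Series]:
        """Site x species abundance matrix and per-site effort.

        Cells are summed over panels; with ``average_years`` per-year
        matrices are averaged instead (repeat surveys do not inflate
        abundances).
        """
        sub = self.communities[self.communities["dataset_id"] == dataset_id]
        if year is not None:
            sub = sub[sub["year"] == year]
        if method is not None:
            sub = sub[sub["method"] == method]
        if average_years and sub["year"].nunique() > 1:
            yearly = [
                y.pivot_table(index="site_id", columns="species_id", values="abundance",
                              aggfunc="sum", fill_value=0)
                for _, y in sub.groupby("year")
            ]
            all_sites = sorted(set().union(*[m.index for m in yearly]))
            all_species = sorted(set().union(*[m.columns for m in yearly]))
            stacked = [m.reindex(index=all_sites, columns=all_species, fill_value=0) for m in yearly]
            mat = sum(stacked) / len(stacked)
        else:
            mat = sub.pivot_table(
                index="site_id", columns="species_id", values="abundance", aggfunc="sum", fill_value=0
            )
        sites = self.sites.loc[self.sites["dataset_id"] == dataset_id, "site_id"]
        mat = mat.reindex(sorted(sites), fill_value=0)
        effort = sub.groupby("site_id")["effort"].mean().reindex(mat.index)
        effort = effort.fillna(float(sub["effort"].mean()) if len(sub) else 1.0)
        return mat, effort

    def copy(self) -> "StudyCollection":
        return StudyCollection(
            self.sites.copy(), self.applications.copy(), self.toxicity.copy(),
            self.communities.copy(), self.traits.copy(),
        )


# ---------------------------------------------------------------------------
# Generation


def _rng(seed: int, *key) -> np.random.Generator:
    """Child stream keyed by purpose so adding datasets never perturbs others."""
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=key))


def _make_toxicity(rng: np.random.Generator, n_ingredients: int = 40) -> pd.DataFrame:
    types = (["insecticide"] * 14 + ["fungicide"] * 13 + ["herbicide"] * 11 + ["seed_treatment"] * 2)
    types = (types * (n_ingredients // len(types) + 1))[:n_ingredients]
    median_ld50 = {"insecticide": 1.0, "fungicide": 100.0, "herbicide": 200.0, "seed_treatment": 0.01}
    median_rate = {"insecticide": 60.0, "fungicide": 500.0, "herbicide": 700.0, "seed_treatment": 10.0}
    rows = []
    for k, ptype in enumerate(types):
        oral = float(np.exp(np.log(median_ld50[ptype]) + rng.normal(0, 1.2)))
        contact = float(oral * np.exp(rng.normal(0, 0.6)))
        rate = float(np.exp(np.log(median_rate[ptype]) + rng.normal(0, 0.4)))
        rows.append(
            {
                "active_ingredient": f"ai_{k:03d}",
                "pesticide_type": ptype,
                "oral_ld50_ug_bee": oral,
                "oral_bounded": False,
                "contact_ld50_ug_bee": contact,
                "contact_bounded": False,
                "label_rate_g_ha": rate,
            }
        )
    return pd.DataFrame(rows)


def _make_species_pool(rng: np.random.Generator, config: SimulationConfig) -> pd.DataFrame:
    S = config.species_pool_size
    fam_p = 0.55 ** np.arange(len(FAMILIES))
    fam_p /= fam_p.sum()
    fams = rng.choice(len(FAMILIES), size=S, p=fam_p)
    genus_idx = rng.geometric(0.35, size=S)  # geometric clade sizes within family
    rows = []
    for i in range(S):
        fam = FAMILIES[fams[i]]
        rows.append(
            {
                "species_id": f"sp_{i:03d}",
                "family": fam,
                "genus": f"{fam[:4]}_g{genus_idx[i]:02d}",
                "body_size_mm": float(np.round(np.exp(rng.normal(np.log(10.0), 0.35)), 2)),
                "lecty": rng.choice(["polylectic", "oligolectic"], p=[0.7, 0.3]),
                "sociality": rng.choice(["solitary", "eusocial", "facultative"], p=[0.65, 0.2, 0.15]),
                "nest_location": rng.choice(["ground", "cavity", "stem"], p=[0.6, 0.25, 0.15]),
                "nesting_strategy": rng.choice(["excavator", "renter"], p=[0.7, 0.3]),
                "kleptoparasitism": int(rng.random() < 0.13),
            }
        )
    pool = pd.DataFrame(rows)
    # abundance propensity: lognormal, induces few common / many rare species
    pool["propensity"] = np.exp(rng.normal(0.0, 1.0, size=S))
    return pool


def _honeybee_row() -> dict:
    return {
        "species_id": "Apis_mellifera",
        "family": "Apidae",
        "genus": "Apis",
        "body_size_mm": 12.0,
        "lecty": "polylectic",
        "sociality": "eusocial",
        "nest_location": "cavity",
        "nesting_strategy": "renter",
        "kleptoparasitism": 0,
        "propensity": np.nan,
    }


def _calibrated_log_coefficients(config: SimulationConfig, shares: np.ndarray) -> tuple[float, float, float]:
    """Log-scale slopes such that standardized recovery returns the betas.

    Delta method: sd of sqrt(T) under NB counts with total mean M and shares w
    is ~ 0.5 * sqrt(1 + M * sum(w^2) / k); the planted signal sd on that scale
    must be beta * total sd, with total sd inflated so the betas are
    correlations: sd_tot = sd_noise / sqrt(1 - sum beta^2).
    """
    M = config.mean_site_total
    k = config.abundance_dispersion
    sd_noise = 0.5 * np.sqrt(1.0 + M * float((shares**2).sum()) / k)
    beta2 = config.beta_hq**2 + config.beta_snh**2 + config.beta_interaction**2
    sd_tot = sd_noise / np.sqrt(1.0 - beta2)
    scale = 2.0 * sd_tot / np.sqrt(M)
    return (config.beta_hq * scale, config.beta_snh * scale, config.beta_interaction * scale)


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    return (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)


def generate_collection(config: SimulationConfig) -> tuple[StudyCollection, GroundTruth]:
    """Simulate a clean multi-study collection with planted effects.

    Deterministic for a fixed config (the seed lives in the config); the
    returned collection carries no missingness -- pass it through
    ``degrade_collection`` to add the real-data pathologies.
    """
    config.validate()
    pool_rng = _rng(config.seed, 0)
    toxicity = _make_toxicity(pool_rng)
    pool = _make_species_pool(pool_rng, config)

    # ordered sensitivities: rarer species respond more negatively to hazard
    rarity_rank = pool["propensity"].rank(ascending=False, method="first") - 1
    rank_norm = rarity_rank / max(1, len(pool) - 1)
    sens = -config.sensitivity_sd * ((rank_norm - rank_norm.mean()) / rank_norm.std(ddof=0))
    sens.index = pool["species_id"]
    baseline = pd.Series(
        np.log(config.mean_site_total * pool["propensity"].to_numpy() / pool["propensity"].sum()),
        index=pool["species_id"],
    )

    tox_idx = toxicity.set_index("active_ingredient")
    dataset_studies = []
    for s in range(config.n_studies):
        n_ds = config.datasets_per_study + (1 if s < config.studies_with_extra_dataset else 0)
        dataset_studies.extend([s] * n_ds)

    sites_rows, app_rows, comm_rows, latent_rows = [], [], [], []
    for d, study in enumerate(dataset_studies):
        rng = _rng(config.seed, 1, d)
        dataset_id = f"ds_{d:02d}"
        study_id = f"study_{study:02d}"
        radius = float(rng.choice([0.5, 1.0]))
        crop_attractive = bool(rng.random() < 0.5)

        chosen = rng.choice(
            pool.index,
            size=config.species_per_dataset,
            replace=False,
            p=pool["propensity"] / pool["propensity"].sum(),
        )
        sub = pool.loc[chosen]
        shares = sub["propensity"].to_numpy() / sub["propensity"].sum()
        s_i = sens[sub["species_id"]].to_numpy()
        g_hq, g_snh, g_int = _calibrated_log_coefficients(config, shares)

        n_sites = config.sites_per_dataset
        snh = rng.uniform(config.snh_range[0], config.snh_range[1], size=n_sites)
        organic = rng.random(n_sites) < config.frac_organic
        site_ids = [f"{dataset_id}_s{j:02d}" for j in range(n_sites)]

        hq_latent = np.zeros(n_sites)
        for j, site in enumerate(site_ids):
            if organic[j]:
                n_apps = int(rng.binomial(2, 0.3))
            else:
                lo, hi = config.apps_per_site_range
                n_apps = int(rng.integers(lo, hi + 1))
            for _ in range(n_apps):
                ing = toxicity["active_ingredient"].iloc[int(rng.integers(len(toxicity)))]
                label = float(tox_idx.loc[ing, "label_rate_g_ha"])
                rate = label * float(np.exp(rng.normal(0, 0.4)))
                if organic[j]:
                    rate *= 0.3
                app_rows.append(
                    {
                        "site_id": site,
                        "pesticide_type": tox_idx.loc[ing, "pesticide_type"],
                        "active_ingredient": ing,
                        "application_rate_g_ha": rate,
                        "source": "recorded",
                    }
                )
                hq_latent[j] += np.log(rate / float(tox_idx.loc[ing, "oral_ld50_ug_bee"]))

        zhq = _zscore(hq_latent)
        zsnh = _zscore(snh)
        total_mean = config.mean_site_total * np.exp(
            g_hq * zhq + g_snh * zsnh + g_int * zhq * zsnh
        )
        # composition reweighting: expected total is untouched by sensitivities
        logw = np.log(shares)[None, :] + np.outer(zhq, s_i)
        w = np.exp(logw - logw.max(axis=1, keepdims=True))
        w /= w.sum(axis=1, keepdims=True)
        mu = total_mean[:, None] * w
        k = config.abundance_dispersion
        counts = rng.negative_binomial(k, k / (k + mu))

        for j, site in enumerate(site_ids):
            sites_rows.append(
                {
                    "site_id": site,
                    "dataset_id": dataset_id,
                    "study_id": study_id,
                    "snh": float(snh[j]),
                    "production_system": "organic" if organic[j] else "conventional",
                    "landscape_radius_km": radius,
                    "crop_attractive": crop_attractive,
                    "field_size_ha": float(np.round(np.exp(rng.normal(1.0, 0.6)), 2)),
                }
            )
            latent_rows.append(
                {"site_id": site, "dataset_id": dataset_id, "hq_latent": float(hq_latent[j]),
                 "zhq": float(zhq[j]), "zsnh": float(zsnh[j])}
            )
            for i, sp in enumerate(sub["species_id"]):
                if counts[j, i] > 0:
                    comm_rows.append(
                        {
                            "dataset_id": dataset_id,
                            "site_id": site,
                            "year": 2020,
                            "method": "pan_trap",
                            "species_id": sp,
                            "abundance": int(counts[j, i]),
                            "effort": config.effort,
                        }
                    )
            if config.include_honeybee:
                apis = int(rng.negative_binomial(1.0, 1.0 / (1.0 + 15.0)))
                if apis > 0:
                    comm_rows.append(
                        {
                            "dataset_id": dataset_id,
                            "site_id": site,
                            "year": 2020,
                            "method": "pan_trap",
                            "species_id": "Apis_mellifera",
                            "abundance": apis,
                            "effort": config.effort,
                        }
                    )

    traits = pool.copy()
    if config.include_honeybee:
        traits = pd.concat([traits, pd.DataFrame([_honeybee_row()])], ignore_index=True)
    traits = traits.drop(columns=["propensity"])

    collection = StudyCollection(
        sites=pd.DataFrame(sites_rows),
        applications=pd.DataFrame(
            app_rows,
            columns=["site_id", "pesticide_type", "active_ingredient", "application_rate_g_ha", "source"],
        ),
        toxicity=toxicity.drop(columns=["pesticide_type"]),
        communities=pd.DataFrame(
            comm_rows,
            columns=["dataset_id", "site_id", "year", "method", "species_id", "abundance", "effort"],
        ),
        traits=traits,
    )
    truth = GroundTruth(
        beta_hq=config.beta_hq,
        beta_snh=config.beta_snh,
        beta_interaction=config.beta_interaction,
        species_sensitivity=sens,
        species_baseline=baseline,
        site_latent=pd.DataFrame(latent_rows),
    )
    return collection, truth


def degrade_collection(collection: StudyCollection, config: SimulationConfig) -> StudyCollection:
    """Overlay real-data pathologies; the input collection is left untouched.

    Marks a fraction of LD50s as unbounded ('>'), blanks a fraction of oral
    LD50s (forcing the contact proxy), strips the active ingredient from a
    fraction of applications (type-only records routed to imputation), blanks
    application rates (label-default fallback), and deletes trait values per
    trait at the configured missingness.
    """
    config.validate()
    out = collection.copy()
    rng = _rng(config.seed, 2)

    tox = out.toxicity
    unbounded = rng.random(len(tox)) < config.ld50_unbounded_frac
    tox.loc[unbounded, "oral_bounded"] = True
    missing_oral = rng.random(len(tox)) < config.oral_missing_frac
    tox.loc[missing_oral, "oral_ld50_ug_bee"] = np.nan
    tox.loc[missing_oral, "oral_bounded"] = False

    apps = out.applications
    if len(apps):
        type_only = rng.random(len(apps)) < config.type_only_frac
        apps.loc[type_only, "active_ingredient"] = np.nan
        apps.loc[type_only, "application_rate_g_ha"] = np.nan
        no_rate = (rng.random(len(apps)) < config.rate_missing_frac) & ~type_only
        apps.loc[no_rate, "application_rate_g_ha"] = np.nan
        apps.loc[no_rate, "source"] = "label_default"

    traits = out.traits
    for col, frac in config.missingness().items():
        if col in traits.columns and frac > 0:
            drop = rng.random(len(traits)) < frac
            traits.loc[drop, col] = np.nan
    return out
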