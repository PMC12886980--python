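"""Synthetic cohort generator with stored ground truth.

The generative model mirrors the causal diagram the structural models are
built to recover: latent SES and BCAA factors and an exogenous hemoglobin
driver feed a continuous HAZ equation; SES, HAZ and a microbiota diversity
driver feed a latent neurodevelopment factor; each latent projects onto its
observed indicators, which are then discretized to their declared scales
(ASQ-3 domains on a 0-60 grid in steps of 5, ordinal socioeconomic
indicators, binary asset flags, biomarkers in clinical units).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from stuntsem.config import GeneratorConfig
from stuntsem.derived_scores import DEFAULT_POLICY, categorize_haz_array

#: columns a cohort table must always carry
REQUIRED_COHORT_COLUMNS = (
    "child_id",
    "age_months",
    "sex",
    "haz",
    "stunting_category",
    "comm",
    "ps",
    "pes",
    "fm",
    "gm",
    "overall_score",
    "ses_score",
    "maternal_education",
    "maternal_age_first_pregnancy",
    "treated_water",
    "rooms",
    "running_water",
    "hemoglobin",
    "anemia",
    "ferritin",
    "crp",
    "alanine",
    "citrulline",
    "valine",
    "leucine",
    "isoleucine",
    "aat_class",
    "birth_size",
)

DOMAIN_COLUMNS = ("comm", "ps", "pes", "fm", "gm")
SES_INDICATOR_COLUMNS = (
    "ses_score",
    "maternal_education",
    "maternal_age_first_pregnancy",
    "treated_water",
    "rooms",
)
BCAA_COLUMNS = ("alanine", "citrulline", "valine", "leucine", "isoleucine")
PARASITE_COLUMNS = ("ascaris", "trichuris", "giardia", "blastocystis", "enterobius", "hymenolepis")
FOOD_GROUP_COLUMNS = (
    "fg_grains",
    "fg_pulses",
    "fg_dairy",
    "fg_flesh",
    "fg_eggs",
    "fg_vit_a",
    "fg_other_fruit_veg",
)

# columns eligible for MCAR missingness injection
_MISSINGNESS_COLUMNS = (
    "hemoglobin",
    "ferritin",
    "crp",
    "maternal_age_first_pregnancy",
) + BCAA_COLUMNS

_BCAA_MEANS = (350.0, 25.0, 220.0, 120.0, 60.0)  # umol/L
_BCAA_SCALES = (60.0, 7.0, 40.0, 25.0, 14.0)

_PARASITE_PREVALENCE = (0.493, 0.618, 0.224, 0.30, 0.05, 0.03)
_FOOD_GROUP_PREVALENCE = (0.97, 0.55, 0.45, 0.80, 0.30, 0.55, 0.70)


@dataclass(frozen=True)
class GroundTruth:
    """Realized latent scores and the coefficients that generated a cohort.

    ``latents`` holds one row per child (ses, bcaa, hb_z, diversity_driver,
    neuro); ``coefficients`` is the edge->value mapping actually used.
    """

    latents: pd.DataFrame
    coefficients: dict[str, float]
    config: GeneratorConfig


def _ordinal_from_projection(z: np.ndarray, sd: float, probs: tuple[float, ...]) -> np.ndarray:
    """Cut a zero-mean projection with theoretical SD ``sd`` into ordered levels."""
    cuts = sd * stats.norm.ppf(np.cumsum(probs)[:-1])
    return np.digitize(z, cuts)


def _round_to_grid(x: np.ndarray, step: int = 5, lo: int = 0, hi: int = 60) -> np.ndarray:
    return np.clip(np.round(x / step) * step, lo, hi).astype(int)


def generate_cohort(config: GeneratorConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Generate a per-child cohort table and its ground truth.

    Deterministic given ``config.seed``. Latent SES and BCAA are standard
    normal; HAZ, the diversity driver and latent neurodevelopment follow the
    linear structural equations in ``config.path_coefficients``; every
    indicator is loading x latent + noise, discretized to its declared scale.
    """
    cfg = config
    n = cfg.n_children
    rng = np.random.default_rng(cfg.seed)

    child_id = np.array([f"c{i:04d}" for i in range(1, n + 1)])
    age = rng.integers(24, 61, size=n)
    sex = rng.integers(0, 2, size=n)  # 1 = female

    ses = rng.standard_normal(n)
    bcaa = rng.standard_normal(n)
    hb_z = rng.standard_normal(n)

    driver = (
        cfg.path("SES->Microbiota") * ses
        + cfg.path("BCAA->Microbiota") * bcaa
        + cfg.noise_sd["Microbiota"] * rng.standard_normal(n)
    )

    if cfg.haz_mode == "continuous":
        haz = (
            cfg.haz_mean
            + cfg.path("SES->HAZ") * ses
            + cfg.path("Hb->HAZ") * hb_z
            + cfg.path("BCAA->HAZ") * bcaa
            + cfg.path("Microbiota->HAZ") * driver
            + cfg.noise_sd["HAZ"] * rng.standard_normal(n)
        )
        haz = np.round(haz, 2)  # categorize the value that is actually stored
        category = categorize_haz_array(haz)
    else:
        category = rng.choice(
            np.array(["normal", "moderate", "severe"]), size=n, p=cfg.category_probs
        )
        haz = np.empty(n)
        mu, sd = cfg.haz_mean, 1.1
        bounds = {"severe": (-np.inf, -3.0), "moderate": (-3.0, -2.0), "normal": (-2.0, np.inf)}
        u = rng.uniform(size=n)
        clip_to = {"severe": (None, -3.0), "moderate": (-2.99, -2.0), "normal": (-1.99, None)}
        for cat, (lo, hi) in bounds.items():
            mask = category == cat
            a, b = (lo - mu) / sd, (hi - mu) / sd
            vals = np.round(stats.truncnorm.ppf(u[mask], a, b, loc=mu, scale=sd), 2)
            haz[mask] = np.clip(vals, *clip_to[cat])

    neuro = (
        cfg.path("SES->Neuro") * ses
        + cfg.path("HAZ->Neuro") * (haz - cfg.haz_mean)
        + cfg.path("Shannon->Neuro") * driver
        + cfg.noise_sd["Neuro"] * rng.standard_normal(n)
    )

    # ASQ-3 domains on the 0-60 grid in steps of 5
    domains = {}
    for name, lam in zip(DOMAIN_COLUMNS, cfg.loadings_neuro):
        cont = 45.0 + 7.0 * (lam * neuro + cfg.noise_sd["neuro_ind"] * rng.standard_normal(n))
        domains[name] = _round_to_grid(cont)
    overall = sum(domains.values())

    # SES indicators
    sd_ind = cfg.noise_sd["ses_ind"]
    proj = {
        name: lam * ses + sd_ind * rng.standard_normal(n)
        for name, lam in zip(SES_INDICATOR_COLUMNS, cfg.loadings_ses)
    }

    def _proj_sd(lam: float) -> float:
        return float(np.hypot(lam, sd_ind))

    ses_score = 1 + _ordinal_from_projection(
        proj["ses_score"], _proj_sd(cfg.loadings_ses[0]), (0.30, 0.45, 0.25)
    )
    maternal_education = _ordinal_from_projection(
        proj["maternal_education"], _proj_sd(cfg.loadings_ses[1]), (0.25, 0.35, 0.30, 0.10)
    )
    z3 = proj["maternal_age_first_pregnancy"] / _proj_sd(cfg.loadings_ses[2])
    maternal_age = np.round(19.0 + 3.5 * z3, 1)
    treated_water = (
        proj["treated_water"] > _proj_sd(cfg.loadings_ses[3]) * stats.norm.ppf(1 - 0.45)
    ).astype(int)
    rooms = np.clip(np.round(2.5 + proj["rooms"] / _proj_sd(cfg.loadings_ses[4])), 1, 8).astype(int)

    running_z = 0.6 * ses + 0.8 * rng.standard_normal(n)
    running_water = (running_z > np.hypot(0.6, 0.8) * stats.norm.ppf(1 - 0.35)).astype(int)

    hemoglobin = np.round(11.9 + 1.4 * hb_z, 1)
    anemia = (hemoglobin < DEFAULT_POLICY.anemia_hb).astype(int)
    ferritin = np.round(np.exp(rng.normal(3.2, 0.6, size=n)), 1)
    crp = np.round(np.exp(rng.normal(0.3, 1.0, size=n)), 2)

    bcaa_vals = {}
    sd_b = cfg.noise_sd["bcaa_ind"]
    for name, lam, mean, scale in zip(BCAA_COLUMNS, cfg.loadings_bcaa, _BCAA_MEANS, _BCAA_SCALES):
        z = (lam * bcaa + sd_b * rng.standard_normal(n)) / np.hypot(lam, sd_b)
        bcaa_vals[name] = np.round(np.maximum(mean + scale * z, 0.5), 1)

    aat_class = np.where(rng.uniform(size=n) < 0.35, "elevated", "normal")
    birth_size = rng.choice(np.array(["smaller", "same", "bigger"]), size=n, p=(0.2, 0.6, 0.2))

    parasites = {
        name: rng.binomial(1, p, size=n)
        for name, p in zip(PARASITE_COLUMNS, _PARASITE_PREVALENCE)
    }
    enteropathogen_genes = rng.poisson(1.8, size=n)
    food_groups = {
        name: rng.binomial(1, p, size=n)
        for name, p in zip(FOOD_GROUP_COLUMNS, _FOOD_GROUP_PREVALENCE)
    }
    dds = sum(food_groups.values())
    ldd = (dds < DEFAULT_POLICY.ldd_cut).astype(int)

    age_solid_food = np.clip(np.round(rng.normal(5.0, 1.5, size=n)), 2, 12).astype(int)
    breastfeeding_months = np.clip(np.round(rng.normal(24.0, 4.0, size=n)), 6, 36).astype(int)
    currently_breastfed = rng.binomial(1, 0.083, size=n)
    exclusive_bf_6m = rng.binomial(1, 0.665, size=n)

    cohort = pd.DataFrame(
        {
            "child_id": child_id,
            "age_months": age,
            "sex": sex,
            "haz": np.round(haz, 2),
            "stunting_category": category,
            **domains,
            "overall_score": overall,
            "ses_score": ses_score,
            "maternal_education": maternal_education,
            "maternal_age_first_pregnancy": maternal_age,
            "treated_water": treated_water,
            "rooms": rooms,
            "running_water": running_water,
            "hemoglobin": hemoglobin,
            "anemia": anemia,
            "ferritin": ferritin,
            "crp": crp,
            **bcaa_vals,
            "aat_class": aat_class,
            "birth_size": birth_size,
            **parasites,
            "enteropathogen_genes": enteropathogen_genes,
            **food_groups,
            "dds": dds,
            "ldd": ldd,
            "age_solid_food_months": age_solid_food,
            "breastfeeding_months": breastfeeding_months,
            "currently_breastfed": currently_breastfed,
            "exclusive_bf_6m": exclusive_bf_6m,
        }
    )

    if cfg.missing_rate > 0:
        mask = rng.uniform(size=(n, len(_MISSINGNESS_COLUMNS))) < cfg.missing_rate
        for j, col in enumerate(_MISSINGNESS_COLUMNS):
            cohort.loc[mask[:, j], col] = np.nan

    latents = pd.DataFrame(
        {
            "child_id": child_id,
            "ses": ses,
            "bcaa": bcaa,
            "hb_z": hb_z,
            "diversity_driver": driver,
            "neuro": neuro,
        }
    )
    truth = GroundTruth(
        latents=latents, coefficients=dict(cfg.path_coefficients), config=cfg
    )
    return cohort, truth
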