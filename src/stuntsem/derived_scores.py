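"""Classification and composite-score rules for anthropometry, diet and biomarkers.

Every rule is a pure function of its inputs plus a :class:`ThresholdPolicy`
holding the clinical cut-offs (WHO stunting thresholds, anemia and
inflammation cut-offs, the inflammation correction factor for ferritin, the
qPCR detection threshold, and the fecal alpha-1-antitrypsin limits).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

STUNTING_CATEGORIES = ("normal", "moderate", "severe")


@dataclass(frozen=True)
class ThresholdPolicy:
    """Clinical cut-offs used by the derived-score rules.

    Defaults follow standard practice for child cohorts in low-resource
    settings: stunting at HAZ <= -2 SD (severe at <= -3 SD), anemia at
    hemoglobin < 11 g/dL (altitude-adjusted values expected as input),
    ferritin corrected by a factor 0.67 when CRP > 6 mg/L and considered low
    below 12 ug/L, CRP elevated above 10 mg/L, citrulline low below 7 and
    elevated above 43 umol/L, qPCR gene presence at Ct < 37, and fecal
    alpha-1-antitrypsin normal below 1.25 mg/g dry weight or 0.15 wet weight.
    """

    haz_stunted: float = -2.0
    haz_severe: float = -3.0
    anemia_hb: float = 11.0
    ferritin_low: float = 12.0
    crp_correction: float = 6.0
    crp_elevated: float = 10.0
    ferritin_factor: float = 0.67
    citrulline_low: float = 7.0
    citrulline_high: float = 43.0
    ct_presence: float = 37.0
    aat_dry: float = 1.25
    aat_wet: float = 0.15
    ldd_cut: int = 4

    def __post_init__(self) -> None:
        if not self.haz_severe < self.haz_stunted:
            raise ValueError("haz_severe must be below haz_stunted")
        if not self.citrulline_low < self.citrulline_high:
            raise ValueError("citrulline_low must be below citrulline_high")


DEFAULT_POLICY = ThresholdPolicy()


def categorize_haz(haz: float, policy: ThresholdPolicy = DEFAULT_POLICY) -> str:
    """Classify a height-for-age Z-score as normal / moderate / severe stunting.

    Boundaries are inclusive downward: ``haz <= -3`` is severe, ``-3 < haz <= -2``
    is moderate, anything above is normal growth.
    """
    if not math.isfinite(haz):
        raise ValueError(f"HAZ must be finite, got {haz!r}")
    if haz <= policy.haz_severe:
        return "severe"
    if haz <= policy.haz_stunted:
        return "moderate"
    return "normal"


def categorize_haz_array(haz, policy: ThresholdPolicy = DEFAULT_POLICY) -> np.ndarray:
    """Vectorized :func:`categorize_haz` over an array of HAZ values."""
    haz = np.asarray(haz, dtype=float)
    if not np.all(np.isfinite(haz)):
        raise ValueError("HAZ values must be finite")
    return np.select(
        [haz <= policy.haz_severe, haz <= policy.haz_stunted],
        ["severe", "moderate"],
        default="normal",
    )


def dietary_diversity(
    food_groups: Sequence[int], policy: ThresholdPolicy = DEFAULT_POLICY
) -> tuple[int, bool]:
    """Dietary diversity score (sum of 7 food-group indicators) and low-diversity flag.

    The score counts food groups consumed in the last 24 h; low dietary
    diversity (LDD) means a score strictly below ``policy.ldd_cut`` (4).
    """
    if len(food_groups) != 7:
        raise ValueError(f"expected exactly 7 food-group indicators, got {len(food_groups)}")
    vals = [int(v) for v in food_groups]
    if any(v not in (0, 1) for v in vals):
        raise ValueError("food-group indicators must be binary")
    dds = sum(vals)
    return dds, dds < policy.ldd_cut


def correct_ferritin(
    ferritin: float, crp: float, policy: ThresholdPolicy = DEFAULT_POLICY
) -> tuple[float, bool]:
    """Inflammation-corrected ferritin and low-ferritin flag.

    Ferritin is an acute-phase reactant; when CRP is strictly above
    ``crp_correction`` (6 mg/L) the measured value is multiplied by
    ``ferritin_factor`` (0.67) before applying the low cut-off (12 ug/L).
    """
    if ferritin < 0 or crp < 0:
        raise ValueError("ferritin and CRP must be non-negative")
    corrected = policy.ferritin_factor * ferritin if crp > policy.crp_correction else ferritin
    return corrected, corrected < policy.ferritin_low


def classify_biomarkers(
    hb: float,
    crp: float,
    citrulline: float,
    aat_value: float,
    aat_basis: str,
    ct_values: Iterable[float],
    policy: ThresholdPolicy = DEFAULT_POLICY,
) -> dict:
    """Binary/ordinal classes for the blood and stool biomarker panel.

    Returns a dict with ``anemia`` (hb < 11 g/dL), ``crp_elevated``
    (> 10 mg/L), ``citrulline_class`` in {low, normal, elevated},
    ``aat_class`` in {normal, elevated} (basis-specific threshold on dry or
    wet fecal weight), and ``pathogen_gene_count`` (# qPCR targets with
    Ct < 37).
    """
    if aat_basis not in ("dry", "wet"):
        raise ValueError(f"unknown aat_basis {aat_basis!r}; expected 'dry' or 'wet'")
    aat_cut = policy.aat_dry if aat_basis == "dry" else policy.aat_wet
    if citrulline < policy.citrulline_low:
        cit = "low"
    elif citrulline > policy.citrulline_high:
        cit = "elevated"
    else:
        cit = "normal"
    return {
        "anemia": hb < policy.anemia_hb,
        "crp_elevated": crp > policy.crp_elevated,
        "citrulline_class": cit,
        "aat_class": "normal" if aat_value < aat_cut else "elevated",
        "pathogen_gene_count": int(sum(1 for ct in ct_values if ct < policy.ct_presence)),
    }


_SES_KEYS = ("telephone", "floor", "internal_shower", "internal_kitchen")


def socioeconomic_category(assets: Mapping) -> int:
    """Three-level socioeconomic category from a minimal household asset set.

    Category 1 (lowest): no telephone, or a house floor of pounded earth.
    Category 3 (highest): telephone and solid floor, plus either an internal
    shower or an internal kitchen in a separate room. Category 2: everything
    in between. ``assets['floor']`` is one of ``pounded_earth``, ``wood``,
    ``concrete``.
    """
    missing = [k for k in _SES_KEYS if k not in assets]
    if missing:
        raise KeyError(f"missing asset keys: {missing}")
    if not assets["telephone"] or assets["floor"] == "pounded_earth":
        return 1
    if assets["internal_shower"] or assets["internal_kitchen"]:
        return 3
    return 2


def overall_asq(domains: Sequence[float]) -> int:
    """Overall development score: the exact sum of the five ASQ-3 domain scores."""
    if len(domains) != 5:
        raise ValueError(f"expected 5 domain scores, got {len(domains)}")
    for d in domains:
        if not 0 <= d <= 60:
            raise ValueError(f"domain score {d} outside [0, 60]")
    return int(sum(domains))


def _pct_half_up(count: int, total: int) -> float:
    frac = Decimal(count) * Decimal(100) / Decimal(total)
    return float(frac.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def cohort_summary(cohort: pd.DataFrame) -> pd.DataFrame:
    """Counts and half-up-rounded percentages of each stunting category.

    Returns a frame indexed by category (normal, moderate, severe) with
    columns ``count`` and ``percent`` (one decimal, round-half-up).
    """
    if len(cohort) == 0:
        raise ValueError("empty cohort")
    if "stunting_category" not in cohort.columns:
        raise ValueError("cohort lacks a stunting_category column")
    counts = cohort["stunting_category"].value_counts()
    total = int(counts.sum())
    rows = []
    for cat in STUNTING_CATEGORIES:
        c = int(counts.get(cat, 0))
        rows.append({"stunting_category": cat, "count": c, "percent": _pct_half_up(c, total)})
    return pd.DataFrame(rows).set_index("stunting_category")
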