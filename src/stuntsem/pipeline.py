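"""End-to-end orchestration: scores -> regressions -> constructs -> SEM fits.

``run_pipeline`` runs the full analysis either on files (cohort CSV plus
count-table TSVs) or in simulation mode from a generator configuration, and
emits report tables mirroring the analysis outputs: adjusted stunting
contrasts, diversity/score regressions, a family-level taxon screen, the
block-eligibility matrix, and — for every selected topology x microbiota
construct — parameter tables, fit statistics and effect decompositions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

import stuntsem
from stuntsem.association import adjusted_contrast, ols_fit, screen_block
from stuntsem.catalog import CONSTRUCTS, TOPOLOGIES, build_model_catalog
from stuntsem.cohort import (
    BCAA_COLUMNS,
    DOMAIN_COLUMNS,
    PARASITE_COLUMNS,
    SES_INDICATOR_COLUMNS,
    generate_cohort,
)
from stuntsem.config import GeneratorConfig
from stuntsem.derived_scores import cohort_summary
from stuntsem.io import read_cohort, read_counts
from stuntsem.microbiome import aggregate_taxa, build_constructs, relative_abundance, screen_taxa
from stuntsem.sem.effects import effects
from stuntsem.sem.estimate import estimate
from stuntsem.sem.fitstats import fit_statistics
from stuntsem.taxa import generate_taxa_counts

ADJUSTMENT_COVARIATES = (
    "ses_score",
    "running_water",
    "sex",
    "age_months",
    "anemia",
    "maternal_age_first_pregnancy",
    "maternal_education",
)

_BIRTH_SIZE_NUM = {"smaller": 1, "same": 2, "bigger": 3}

DEFAULT_BLOCKS: dict[str, dict[str, str]] = {
    "neurodevelopment": {c: "continuous" for c in DOMAIN_COLUMNS},
    "ses_maternal": {
        "ses_score": "categorical",
        "maternal_education": "categorical",
        "maternal_age_first_pregnancy": "continuous",
        "treated_water": "categorical",
        "rooms": "continuous",
    },
    "bcaa": {c: "continuous" for c in BCAA_COLUMNS},
    "parasites": {c: "categorical" for c in PARASITE_COLUMNS},
}


@dataclass(frozen=True)
class PipelineConfig:
    """What to run and on which inputs.

    Either ``generator`` (simulation mode) or both ``cohort_path`` and
    ``counts_base`` must be provided. ``topologies`` and ``constructs``
    select which of the four model shapes and four microbiota constructs to
    fit; at least one of each is required.
    """

    generator: GeneratorConfig | None = None
    cohort_path: str | None = None
    counts_base: str | None = None
    blocks: dict[str, dict[str, str]] = field(default_factory=lambda: dict(DEFAULT_BLOCKS))
    threshold: float = 0.2
    topologies: tuple[str, ...] = TOPOLOGIES
    constructs: tuple[str, ...] = ("shannon",)
    outdir: str | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.topologies or not self.constructs:
            raise ValueError("select at least one topology and one construct")
        unknown = set(self.topologies) - set(TOPOLOGIES)
        if unknown:
            raise ValueError(f"unknown topologies: {sorted(unknown)}")
        unknown = set(self.constructs) - set(CONSTRUCTS)
        if unknown:
            raise ValueError(f"unknown constructs: {sorted(unknown)}")
        if self.generator is None and (self.cohort_path is None or self.counts_base is None):
            raise ValueError("provide a generator config or cohort_path + counts_base")


@dataclass
class PipelineResult:
    """All report tables of one pipeline run."""

    cohort_summary: pd.DataFrame
    table1: pd.DataFrame
    diversity_regressions: pd.DataFrame
    taxon_screen: pd.DataFrame
    block_eligibility: pd.DataFrame
    association_matrices: dict[str, pd.DataFrame]
    fits: dict[tuple[str, str], dict]
    effect_table: pd.DataFrame
    run_log: dict


def sem_table(cohort: pd.DataFrame, constructs: pd.DataFrame) -> pd.DataFrame:
    """Merge the cohort with per-sample constructs and add model codings.

    Adds ``aat`` (0 normal / 1 elevated) and ``birth_size_num`` (1/2/3) and
    joins the microbiota construct columns on child id.
    """
    df = cohort.copy()
    df["aat"] = (df["aat_class"] == "elevated").astype(int)
    df["birth_size_num"] = df["birth_size"].map(_BIRTH_SIZE_NUM)
    merged = df.merge(
        constructs, left_on="child_id", right_index=True, how="inner", validate="1:1"
    )
    return merged


def _stage(name: str):
    class _StageContext:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
            return False

    return _StageContext()


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run the full analysis and return (and optionally write) its reports."""
    cfg = config
    with _stage("inputs"):
        if cfg.generator is not None:
            gen = cfg.generator.replace(seed=cfg.seed)
            cohort, truth = generate_cohort(gen)
            taxa = generate_taxa_counts(gen, truth)
        else:
            cohort = read_cohort(cfg.cohort_path)
            taxa = read_counts(cfg.counts_base)

    with _stage("cohort_summary"):
        summary = cohort_summary(cohort)

    with _stage("adjusted_contrasts"):
        rows = []
        for outcome in ("overall_score", *DOMAIN_COLUMNS):
            tab = adjusted_contrast(cohort, outcome, ADJUSTMENT_COVARIATES)
            tab = tab.reset_index()
            tab.insert(0, "outcome", outcome)
            rows.append(tab)
        table1 = pd.concat(rows, ignore_index=True)

    with _stage("microbiota_constructs"):
        constructs = build_constructs(taxa.counts, taxa.taxonomy)

    with _stage("diversity_regressions"):
        run_dummies = pd.get_dummies(taxa.run_label, prefix="run", drop_first=True).astype(float)
        rows = []
        scores = cohort.set_index("child_id")[["overall_score", *DOMAIN_COLUMNS]]
        aligned = scores.join(constructs[["shannon"]], how="inner").join(run_dummies)
        for outcome in scores.columns:
            design = aligned[["shannon", *run_dummies.columns]]
            fit = ols_fit(aligned[outcome], design)
            rows.append(
                {
                    "outcome": outcome,
                    "beta_shannon": fit.params["shannon"],
                    "ci_low": fit.ci_low["shannon"],
                    "ci_high": fit.ci_high["shannon"],
                    "p": fit.pvalues["shannon"],
                    "r2": fit.r2,
                    "bp_p": fit.bp_p,
                    "n": fit.n,
                }
            )
        diversity_reg = pd.DataFrame(rows)

    with _stage("taxon_screen"):
        fam_rel = aggregate_taxa(relative_abundance(taxa.counts), taxa.taxonomy, "family")
        screen = screen_taxa(fam_rel, scores)

    with _stage("block_screen"):
        elig_rows = []
        matrices: dict[str, pd.DataFrame] = {}
        for block_name, types in cfg.blocks.items():
            cols = [c for c in types if c in cohort.columns]
            eligible, mat = screen_block(cohort[cols], {c: types[c] for c in cols}, cfg.threshold)
            matrices[block_name] = mat
            off = np.abs(mat.to_numpy()[~np.eye(len(mat), dtype=bool)])
            elig_rows.append(
                {
                    "block": block_name,
                    "n_indicators": len(cols),
                    "median_association": float(np.nanmedian(off)),
                    "eligible": eligible,
                }
            )
        eligibility = pd.DataFrame(elig_rows).set_index("block")

    with _stage("sem_fits"):
        table = sem_table(cohort, constructs)
        fits: dict[tuple[str, str], dict] = {}
        n_by_model = {}
        for construct in cfg.constructs:
            catalog = build_model_catalog(construct)
            for topology in cfg.topologies:
                entry = catalog[topology]
                fit = estimate(entry.spec, table)
                stats_panel = fit_statistics(fit)
                outcome = "overall_score" if topology == "complex_path" else "Neuro"
                ses_source = "rooms" if topology == "complex_path" else "SES"
                eff = {
                    "ses": effects(fit, ses_source, outcome),
                    "microbiome": effects(fit, construct, outcome),
                }
                fits[(topology, construct)] = {
                    "entry": entry,
                    "fit": fit,
                    "stats": stats_panel,
                    "effects": eff,
                }
                n_by_model[f"{topology}[{construct}]"] = fit.n

    with _stage("effect_table"):
        effect_table = render_effect_table(fits)

    run_log = {
        "seed": cfg.seed,
        "version": stuntsem.__version__,
        "mode": "simulation" if cfg.generator is not None else "files",
        "n_children": int(len(cohort)),
        "n_after_deletion": n_by_model,
    }

    result = PipelineResult(
        cohort_summary=summary,
        table1=table1,
        diversity_regressions=diversity_reg,
        taxon_screen=screen,
        block_eligibility=eligibility,
        association_matrices=matrices,
        fits=fits,
        effect_table=effect_table,
        run_log=run_log,
    )
    if cfg.outdir is not None:
        _write_reports(Path(cfg.outdir), result)
    return result


def render_effect_table(fits: dict[tuple[str, str], dict]) -> pd.DataFrame:
    """Long-format table of direct effects on the outcome, per model.

    One row per (topology, construct, predictor): unstandardized beta,
    standardized beta, 95% CI, p and a significance flag at 0.05.
    """
    rows = []
    for (topology, construct), bundle in fits.items():
        fit = bundle["fit"]
        outcome = "overall_score" if topology == "complex_path" else "Neuro"
        for out, pred in fit.spec.structural:
            if out != outcome:
                continue
            name = f"{out}~{pred}"
            beta = fit.theta[name]
            se = fit.se[name]
            p = fit.p[name]
            rows.append(
                {
                    "topology": topology,
                    "construct": construct,
                    "predictor": pred,
                    "beta": beta,
                    "std_beta": fit.std[name],
                    "ci_low": beta - 1.959963984540054 * se,
                    "ci_high": beta + 1.959963984540054 * se,
                    "p": p,
                    "significant": bool(p <= 0.05),
                }
            )
    cols = [
        "topology",
        "construct",
        "predictor",
        "beta",
        "std_beta",
        "ci_low",
        "ci_high",
        "p",
        "significant",
    ]
    return pd.DataFrame(rows, columns=cols)


def _write_reports(outdir: Path, result: PipelineResult) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    result.cohort_summary.to_csv(outdir / "cohort_summary.csv")
    result.table1.to_csv(outdir / "adjusted_contrasts.csv", index=False)
    result.diversity_regressions.to_csv(outdir / "diversity_regressions.csv", index=False)
    result.taxon_screen.to_csv(outdir / "taxon_screen.csv", index=False)
    result.block_eligibility.to_csv(outdir / "block_eligibility.csv")
    for name, mat in result.association_matrices.items():
        mat.to_csv(outdir / f"association_{name}.csv")
    result.effect_table.to_csv(outdir / "effect_table.csv", index=False)
    fit_stats = {}
    for (topology, construct), bundle in result.fits.items():
        key = f"{topology}[{construct}]"
        fit_stats[key] = bundle["stats"].as_dict()
        bundle["fit"].parameter_table().to_csv(outdir / f"parameters_{topology}_{construct}.csv")
        eff_rows = []
        for label, eff in bundle["effects"].items():
            eff_rows.append(
                {
                    "effect": label,
                    "source": eff.source,
                    "outcome": eff.outcome,
                    "direct": eff.direct,
                    "indirect": eff.indirect,
                    "total": eff.total,
                    "se_indirect": eff.se_indirect,
                    "z_indirect": eff.z_indirect,
                    "p_indirect": eff.p_indirect,
                }
            )
        pd.DataFrame(eff_rows).to_csv(outdir / f"effects_{topology}_{construct}.csv", index=False)
    (outdir / "fit_statistics.json").write_text(json.dumps(fit_stats, indent=2))
    (outdir / "run_log.json").write_text(json.dumps(result.run_log, indent=2))
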