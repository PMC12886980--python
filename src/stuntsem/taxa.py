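"""Synthetic samples x taxa count table with family structure.

Per-sample compositions are Dirichlet draws whose family-block
log-concentrations are shifted by the child's diversity driver: a positive
driver flattens the family-level composition (rare families up, dominant
families down), which raises Shannon diversity. Counts are multinomial at a
Poisson-distributed library size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from stuntsem.cohort import GroundTruth
from stuntsem.config import GeneratorConfig

#: Streptococcaceae first so it is always present regardless of n_families
FAMILY_POOL = (
    "Streptococcaceae",
    "Lachnospiraceae",
    "Ruminococcaceae",
    "Bacteroidaceae",
    "Prevotellaceae",
    "Bifidobacteriaceae",
    "Enterobacteriaceae",
    "Veillonellaceae",
    "Lactobacillaceae",
    "Clostridiaceae",
    "Erysipelotrichaceae",
    "Eubacteriaceae",
    "Oscillospiraceae",
    "Rikenellaceae",
    "Tannerellaceae",
    "Akkermansiaceae",
    "Christensenellaceae",
    "Enterococcaceae",
    "Fusobacteriaceae",
    "Sutterellaceae",
    "Desulfovibrionaceae",
    "Coriobacteriaceae",
    "Eggerthellaceae",
    "Peptostreptococcaceae",
    "Acidaminococcaceae",
    "Moraxellaceae",
    "Pasteurellaceae",
    "Micrococcaceae",
    "Carnobacteriaceae",
    "Leuconostocaceae",
)

RUN_LABELS = ("run1", "run2", "run3", "run4")


@dataclass(frozen=True)
class TaxaCountTable:
    """A samples x taxa count matrix with its taxonomy and batch labels.

    ``counts`` is indexed by sample id with one integer column per taxon;
    ``taxonomy`` is indexed by taxon with ``family`` and ``genus`` columns;
    ``run_label`` maps sample id to sequencing run.
    """

    counts: pd.DataFrame
    taxonomy: pd.DataFrame
    run_label: pd.Series

    def __post_init__(self) -> None:
        if list(self.counts.columns) != list(self.taxonomy.index):
            raise ValueError("counts columns and taxonomy index must match")
        if self.taxonomy["family"].isna().any():
            raise ValueError("every taxon needs a family")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")


def _family_names(n_families: int) -> list[str]:
    names = list(FAMILY_POOL[:n_families])
    for i in range(len(names), n_families):
        names.append(f"Family{i + 1:03d}")
    return names


def generate_taxa_counts(config: GeneratorConfig, truth: GroundTruth) -> TaxaCountTable:
    """Generate a count table for the children in ``truth``.

    Deterministic given ``config.seed`` (a child-independent stream derived
    from it). A ``base_heterogeneity`` of 0 yields a uniform base
    composition; a very large ``dirichlet_concentration`` then drives every
    sample toward the uniform composition (Shannon -> ln n_taxa).
    """
    cfg = config
    if cfg.n_taxa < cfg.n_families:
        raise ValueError("n_taxa must be at least n_families")
    sample_ids = truth.latents["child_id"].to_numpy()
    driver = truth.latents["diversity_driver"].to_numpy()
    n = len(sample_ids)
    rng = np.random.default_rng([cfg.seed, 7919])

    families = _family_names(cfg.n_families)
    if cfg.base_heterogeneity > 0:
        fam_w = np.exp(rng.normal(0.0, cfg.base_heterogeneity, size=cfg.n_families))
    else:
        fam_w = np.ones(cfg.n_families)
    fam_prop = fam_w / fam_w.sum()

    # roughly equal taxa per family (so flattening the family composition
    # flattens the taxon-level composition too), at least one taxon each
    alloc = np.ones(cfg.n_families, dtype=int)
    alloc += rng.multinomial(
        cfg.n_taxa - cfg.n_families, np.full(cfg.n_families, 1.0 / cfg.n_families)
    )

    taxon_family = np.repeat(np.arange(cfg.n_families), alloc)
    if cfg.base_heterogeneity > 0:
        within = np.exp(rng.normal(0.0, 1.0, size=cfg.n_taxa))
    else:
        within = np.ones(cfg.n_taxa)
    if cfg.base_heterogeneity > 0:
        base = np.empty(cfg.n_taxa)
        for f in range(cfg.n_families):
            sel = taxon_family == f
            base[sel] = fam_prop[f] * within[sel] / within[sel].sum()
        base /= base.sum()
    else:
        base = np.full(cfg.n_taxa, 1.0 / cfg.n_taxa)

    # evenness shift: a positive driver suppresses dominant taxa and lifts
    # rare ones (shift proportional to the negated standardized log base
    # abundance), so Shannon diversity increases monotonically in the driver
    log_base = np.log(base)
    if np.std(log_base) > 0:
        shift_taxon = -(log_base - log_base.mean()) / np.std(log_base)
    else:
        shift_taxon = np.zeros(cfg.n_taxa)

    log_q = (
        np.log(base)[None, :]
        + cfg.diversity_coupling * driver[:, None] * shift_taxon[None, :]
    )
    if cfg.strep_effect != 0.0:
        strep_idx = families.index("Streptococcaceae")
        neuro = truth.latents["neuro"].to_numpy()
        log_q[:, taxon_family == strep_idx] += cfg.strep_effect * (-neuro)[:, None]

    # renormalize so every sample keeps the same total concentration: the
    # driver reshapes the expected composition without changing noise level
    q = np.exp(log_q - log_q.max(axis=1, keepdims=True))
    q /= q.sum(axis=1, keepdims=True)
    alpha = cfg.dirichlet_concentration * q
    gam = rng.gamma(shape=alpha)
    # guard against all-zero gamma rows at extreme concentrations
    gam = np.where(gam.sum(axis=1, keepdims=True) > 0, gam, alpha)
    p = gam / gam.sum(axis=1, keepdims=True)

    depth = rng.poisson(cfg.depth_mean, size=n)
    counts = rng.multinomial(depth, p)

    taxa_ids = [f"asv{i:04d}" for i in range(1, cfg.n_taxa + 1)]
    counts_df = pd.DataFrame(counts, index=pd.Index(sample_ids, name="sample_id"), columns=taxa_ids)
    fam_count: dict[str, int] = {}
    genus = []
    for f in taxon_family:
        fam = families[f]
        fam_count[fam] = fam_count.get(fam, 0) + 1
        genus.append(f"{fam[:-4]}_g{fam_count[fam]}")
    taxonomy = pd.DataFrame(
        {"family": [families[f] for f in taxon_family], "genus": genus},
        index=pd.Index(taxa_ids, name="taxon"),
    )
    run = pd.Series(
        rng.choice(np.array(RUN_LABELS), size=n, p=(0.3, 0.3, 0.2, 0.2)),
        index=counts_df.index,
        name="run_label",
    )
    return TaxaCountTable(counts=counts_df, taxonomy=taxonomy, run_label=run)
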