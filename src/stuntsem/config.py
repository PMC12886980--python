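"""Configuration of the synthetic cohort generator.

The generator encodes the causal structure the structural models assume:
latent socioeconomic status (SES) and branched-chain amino acid (BCAA)
factors, an exogenous hemoglobin driver, a microbiota diversity driver, a
continuous HAZ equation, a latent neurodevelopment factor, and indicator
equations mapping each latent onto its observed scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

# Directed edges the structural part of the generator understands.
KNOWN_EDGES = (
    "SES->HAZ",
    "Hb->HAZ",
    "BCAA->HAZ",
    "Microbiota->HAZ",
    "SES->Microbiota",
    "BCAA->Microbiota",
    "SES->Neuro",
    "HAZ->Neuro",
    "Shannon->Neuro",
)

_DEFAULT_PATHS = {
    "SES->HAZ": 0.30,
    "Hb->HAZ": 0.25,
    "BCAA->HAZ": 0.20,
    "Microbiota->HAZ": 0.0,
    "SES->Microbiota": 0.10,
    "BCAA->Microbiota": -0.30,
    "SES->Neuro": 0.35,
    "HAZ->Neuro": 0.30,
    "Shannon->Neuro": 0.15,
}

_DEFAULT_NOISE = {
    "HAZ": 1.0,
    "Neuro": 0.8,
    "Microbiota": 0.95,
    "neuro_ind": 0.7,
    "ses_ind": 0.7,
    "bcaa_ind": 0.6,
}


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the synthetic cohort + taxa-count generator.

    Attributes
    ----------
    n_children:
        Cohort size; the study scale is 349 children aged 24-60 months.
    seed:
        Fully determines all generated output.
    category_probs:
        (normal, moderate, severe) stunting proportions used when
        ``haz_mode='category'``; defaults to the observed 56.4/24.1/19.5%.
    loadings_neuro, loadings_ses, loadings_bcaa:
        Factor loadings of the five indicators of each latent block, in the
        orders (Comm, PS, PES, FM, GM), (socioeconomic score, maternal
        education, maternal age at first pregnancy, treated water, rooms) and
        (alanine, citrulline, valine, leucine, isoleucine). The first loading
        of each block is 1 so latents are on their anchor indicator's scale.
    path_coefficients:
        Mapping from directed edge name (see ``KNOWN_EDGES``) to coefficient,
        on the latent (standardized-driver) scale.
    noise_sd:
        Residual standard deviations per structural equation / indicator block.
    haz_mode:
        'continuous' derives stunting categories from the HAZ equation;
        'category' samples categories directly from ``category_probs`` and
        draws HAZ from the matching truncated normal.
    n_taxa, n_families, depth_mean, dirichlet_concentration:
        Shape of the count table: number of amplicon sequence variants,
        bacterial families, mean library size (Poisson), and total Dirichlet
        concentration governing sample-to-sample compositional noise.
        Defaults mirror a 16S data set with 1626 ASVs and mean depth 22039.
    base_heterogeneity:
        Log-normal sigma of family base abundances (0 gives a uniform base).
    diversity_coupling:
        Strength with which a child's diversity driver flattens (positive
        driver) or sharpens the family-level composition.
    strep_effect:
        Optional taxon-specific effect: shift of the Streptococcaceae family
        log-concentration per unit of the child's (negated) Personal-Social
        latent projection. Off (0.0) by default.
    missing_rate:
        MCAR missingness injected into numeric covariates, default 0.
    """

    n_children: int = 349
    seed: int = 0
    category_probs: tuple[float, float, float] = (0.564, 0.241, 0.195)
    loadings_neuro: tuple[float, ...] = (1.0, 1.25, 0.9, 1.2, 0.85)
    loadings_ses: tuple[float, ...] = (1.0, 0.9, 0.6, 0.7, 0.8)
    loadings_bcaa: tuple[float, ...] = (1.0, 0.6, 1.1, 1.2, 1.1)
    path_coefficients: dict[str, float] = field(default_factory=lambda: dict(_DEFAULT_PATHS))
    noise_sd: dict[str, float] = field(default_factory=lambda: dict(_DEFAULT_NOISE))
    haz_mode: str = "continuous"
    haz_mean: float = -1.75
    n_taxa: int = 1626
    n_families: int = 30
    depth_mean: int = 22039
    dirichlet_concentration: float = 300.0
    base_heterogeneity: float = 1.2
    diversity_coupling: float = 0.3
    strep_effect: float = 0.0
    missing_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.n_children <= 0:
            raise ValueError("n_children must be positive")
        if abs(sum(self.category_probs) - 1.0) > 1e-12:
            raise ValueError("category_probs must sum to 1")
        for name in ("loadings_neuro", "loadings_ses", "loadings_bcaa"):
            if len(getattr(self, name)) != 5:
                raise ValueError(f"{name} must have 5 entries")
        unknown = set(self.path_coefficients) - set(KNOWN_EDGES)
        if unknown:
            raise ValueError(f"unknown edge names in path_coefficients: {sorted(unknown)}")
        if any(sd <= 0 for sd in self.noise_sd.values()):
            raise ValueError("all noise_sd entries must be positive")
        if self.haz_mode not in ("continuous", "category"):
            raise ValueError("haz_mode must be 'continuous' or 'category'")
        if self.n_families > self.n_taxa:
            raise ValueError("n_families must not exceed n_taxa")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")

    def replace(self, **kwargs) -> "GeneratorConfig":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)

    def path(self, edge: str) -> float:
        """Coefficient of a directed edge, defaulting to 0 if unset."""
        if edge not in KNOWN_EDGES:
            raise ValueError(f"unknown edge {edge!r}")
        return self.path_coefficients.get(edge, 0.0)
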