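"""The four pre-specified model topologies, crossed with a microbiota construct.

Topologies:

- ``simplest_sem`` — latent SES and neurodevelopment; only direct effects of
  SES, HAZ and the microbiota construct on neurodevelopment.
- ``simple_sem`` — adds the mediated routes SES -> HAZ and SES -> microbiota.
- ``complex_sem`` — adds a latent BCAA factor, hemoglobin, fecal
  alpha-1-antitrypsin (binary), age and reported birth size; BCAA and
  hemoglobin act on neurodevelopment only indirectly (through HAZ and the
  microbiota), and the microbiota may act on neurodevelopment both directly
  and through HAZ.
- ``complex_path`` — the same shape with observed proxies only (rooms and
  maternal age at first pregnancy for SES, leucine for BCAA, anemia for
  hemoglobin, the overall score for neurodevelopment).
"""

from __future__ import annotations

from dataclasses import dataclass

from stuntsem.sem.model import SemModelSpec

CONSTRUCTS = ("shannon", "streptococcaceae", "pcoa1", "cluster")
TOPOLOGIES = ("simplest_sem", "simple_sem", "complex_sem", "complex_path")

_NEURO_INDICATORS = ("comm", "ps", "pes", "fm", "gm")
_SES_INDICATORS = (
    "ses_score",
    "maternal_education",
    "maternal_age_first_pregnancy",
    "treated_water",
    "rooms",
)
_BCAA_INDICATORS = ("alanine", "citrulline", "valine", "leucine", "isoleucine")


@dataclass(frozen=True)
class ModelCatalogEntry:
    """A topology name, its model spec, and a narrative of its edges."""

    topology: str
    spec: SemModelSpec
    narrative: str


def _edges(outcome: str, predictors: tuple[str, ...]) -> tuple[tuple[str, str], ...]:
    return tuple((outcome, p) for p in predictors)


def build_model_catalog(construct: str) -> dict[str, ModelCatalogEntry]:
    """Instantiate the four topologies with a chosen microbiota construct.

    ``construct`` is the column name substituted as the microbiome node:
    one of shannon, streptococcaceae, pcoa1, cluster.
    """
    if construct not in CONSTRUCTS:
        raise ValueError(f"unknown construct {construct!r}; expected one of {CONSTRUCTS}")
    m = construct

    simplest = SemModelSpec(
        measurement={"Neuro": _NEURO_INDICATORS, "SES": _SES_INDICATORS},
        structural=_edges("Neuro", ("SES", "haz", m)),
        name=f"simplest_sem[{m}]",
    )
    simple = SemModelSpec(
        measurement={"Neuro": _NEURO_INDICATORS, "SES": _SES_INDICATORS},
        structural=_edges("Neuro", ("SES", "haz", m))
        + (("haz", "SES"), (m, "SES")),
        name=f"simple_sem[{m}]",
    )
    complex_sem = SemModelSpec(
        measurement={
            "Neuro": _NEURO_INDICATORS,
            "SES": _SES_INDICATORS,
            "BCAA": _BCAA_INDICATORS,
        },
        structural=_edges("Neuro", ("SES", "haz", m, "aat", "age_months", "birth_size_num"))
        + _edges("haz", ("SES", "hemoglobin", "BCAA", m))
        + _edges(m, ("SES", "BCAA")),
        name=f"complex_sem[{m}]",
    )
    complex_path = SemModelSpec(
        structural=_edges(
            "overall_score",
            (
                "rooms",
                "maternal_age_first_pregnancy",
                "haz",
                m,
                "aat",
                "age_months",
                "birth_size_num",
            ),
        )
        + _edges("haz", ("rooms", "maternal_age_first_pregnancy", "anemia", "leucine", m))
        + _edges(m, ("rooms", "maternal_age_first_pregnancy", "leucine")),
        name=f"complex_path[{m}]",
    )
    narratives = {
        "simplest_sem": "direct effects of SES, HAZ and the microbiota on neurodevelopment",
        "simple_sem": "adds SES -> HAZ and SES -> microbiota mediated routes",
        "complex_sem": (
            "adds BCAA, hemoglobin, AAT, age and birth size; BCAA and hemoglobin "
            "reach neurodevelopment only through HAZ / the microbiota"
        ),
        "complex_path": "observed-proxy path analysis on the overall score, no latents",
    }
    specs = {
        "simplest_sem": simplest,
        "simple_sem": simple,
        "complex_sem": complex_sem,
        "complex_path": complex_path,
    }
    return {
        t: ModelCatalogEntry(topology=t, spec=specs[t], narrative=narratives[t])
        for t in TOPOLOGIES
    }
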