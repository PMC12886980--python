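"""Model specification: measurement and structural equations, plus a text format.

A model is a measurement part (latent =~ indicator list, first loading fixed
to 1 for scaling) and a structural part (directed regressions among latent
and/or observed variables), with optional extra free covariances and fixed
(co)variance values. The plain-text format mirrors the object:

    measurement:
      Neuro =~ comm ps pes fm gm
    structural:
      Neuro ~ SES haz shannon
      haz ~ SES
    variances:
      haz ~~ shannon
      pes ~~ pes = 12.5
"""

from __future__ import annotations

import graphlib
from dataclasses import dataclass, field


@dataclass(frozen=True)
class SemModelSpec:
    """A structural equation model specification.

    ``measurement`` maps each latent variable to its ordered indicator list
    (the first indicator's loading is fixed to 1); ``structural`` lists
    directed edges as (outcome, predictor); ``covariances`` lists extra free
    covariance pairs; ``fixed`` maps (a, b) pairs to fixed (co)variance
    values, overriding the default free parameter.
    """

    measurement: dict[str, tuple[str, ...]] = field(default_factory=dict)
    structural: tuple[tuple[str, str], ...] = ()
    covariances: tuple[tuple[str, str], ...] = ()
    fixed: dict[tuple[str, str], float] = field(default_factory=dict)
    name: str = ""

    def __post_init__(self) -> None:
        for lat, inds in self.measurement.items():
            if len(inds) == 0:
                raise ValueError(f"latent {lat!r} has no indicators")
            if len(set(inds)) != len(inds):
                raise ValueError(f"duplicate indicators for latent {lat!r}")
        if len(set(self.structural)) != len(self.structural):
            raise ValueError("duplicate structural edges")
        for out, pred in self.structural:
            if out == pred:
                raise ValueError(f"self-loop {out!r} ~ {pred!r}")
        # structural part must be acyclic (recursive model)
        ts = graphlib.TopologicalSorter()
        for out, pred in self.structural:
            ts.add(out, pred)
        try:
            ts.prepare()
        except graphlib.CycleError as err:
            raise ValueError(f"structural graph has a cycle: {err.args[1]}") from err

    @property
    def latents(self) -> tuple[str, ...]:
        return tuple(self.measurement)

    @property
    def observed(self) -> tuple[str, ...]:
        """Observed variables in declaration order: indicators, then path-only."""
        seen: dict[str, None] = {}
        for inds in self.measurement.values():
            for v in inds:
                seen.setdefault(v)
        for out, pred in self.structural:
            for v in (out, pred):
                if v not in self.measurement:
                    seen.setdefault(v)
        return tuple(seen)

    @property
    def variables(self) -> tuple[str, ...]:
        return self.observed + self.latents

    def endogenous(self) -> set[str]:
        """Variables with at least one incoming directed edge."""
        endo = {v for inds in self.measurement.values() for v in inds}
        endo |= {out for out, _ in self.structural}
        return endo

    def exogenous(self) -> tuple[str, ...]:
        endo = self.endogenous()
        return tuple(v for v in self.variables if v not in endo)

    def to_text(self) -> str:
        lines = []
        if self.measurement:
            lines.append("measurement:")
            for lat, inds in self.measurement.items():
                lines.append(f"  {lat} =~ {' '.join(inds)}")
        if self.structural:
            lines.append("structural:")
            outcomes: dict[str, list[str]] = {}
            for out, pred in self.structural:
                outcomes.setdefault(out, []).append(pred)
            for out, preds in outcomes.items():
                lines.append(f"  {out} ~ {' '.join(preds)}")
        if self.covariances or self.fixed:
            lines.append("variances:")
            for a, b in self.covariances:
                lines.append(f"  {a} ~~ {b}")
            for (a, b), val in self.fixed.items():
                lines.append(f"  {a} ~~ {b} = {val}")
        return "\n".join(lines) + "\n"


def parse_model(text: str, name: str = "") -> SemModelSpec:
    """Parse the three-section plain-text model format into a spec.

    Round-trips with :meth:`SemModelSpec.to_text`.
    """
    measurement: dict[str, tuple[str, ...]] = {}
    structural: list[tuple[str, str]] = []
    covariances: list[tuple[str, str]] = []
    fixed: dict[tuple[str, str], float] = {}
    section = None
    for raw in text.splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if line.endswith(":") and line[:-1] in ("measurement", "structural", "variances"):
            section = line[:-1]
            continue
        if section == "measurement":
            if "=~" not in line:
                raise ValueError(f"expected '=~' in measurement line: {line!r}")
            lat, rhs = (s.strip() for s in line.split("=~", 1))
            measurement[lat] = tuple(rhs.split())
        elif section == "structural":
            if "~" not in line:
                raise ValueError(f"expected '~' in structural line: {line!r}")
            out, rhs = (s.strip() for s in line.split("~", 1))
            for pred in rhs.split():
                structural.append((out, pred))
        elif section == "variances":
            if "~~" not in line:
                raise ValueError(f"expected '~~' in variances line: {line!r}")
            lhs, rhs = (s.strip() for s in line.split("~~", 1))
            if "=" in rhs:
                other, val = (s.strip() for s in rhs.split("=", 1))
                fixed[(lhs, other)] = float(val)
            else:
                covariances.append((lhs, rhs))
        else:
            raise ValueError(f"line outside any section: {line!r}")
    return SemModelSpec(
        measurement=measurement,
        structural=tuple(structural),
        covariances=tuple(covariances),
        fixed=fixed,
        name=name,
    )
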