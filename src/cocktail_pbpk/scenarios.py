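"""Cirrhosis perturbations and structural hypothesis variants.

Two orthogonal transformations act on a healthy-reference model:

* :func:`apply_cirrhosis` — the disease scaling rules: CYP-mediated
  metabolic activity (and unspecified hepatic clearance routes) reduced
  to a fraction (default 11%) of the healthy value, transporter
  capacities scaled by expression fold changes.  UGT processes are
  deliberately left unchanged: the reference cirrhosis simulation must
  under-predict circulating glucuronides, which is precisely the
  discrepancy the three hypotheses compete to explain.

* :func:`apply_hypothesis` — one of the three candidate mechanisms for
  elevated blood glucuronides, expressed as a single fold-change theta:
  H1 scales glucuronidation (Ugt) activity, H2 scales canalicular
  (biliary, Abcc2) glucuronide export, H3 scales sinusoidal
  (Abcc3/Abcc4) glucuronide export.

Both are pure functions: the input model is never mutated, and they
commute when their targets are disjoint.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from .model import DomainError, ModelDefinition

CYP_PREFIX = "Cyp"
HYPOTHESIS_TARGET_GENES = {
    "H1": ("Ugt",),
    "H2": ("Abcc2",),
    "H3": ("Abcc3", "Abcc4"),
}


class SelectorError(ValueError):
    """A hypothesis selector matched no process in the model."""


class ConfigError(ValueError):
    """Unknown scenario configuration entry."""


@dataclass
class ScalingMap:
    """Gene-wise transporter multipliers with provenance.

    ``provenance[gene]`` is either ``"fixed"`` (a configured value) or
    ``"from_log2fc(x)"`` (derived from an expression fold change).
    """

    entries: dict[str, float] = field(default_factory=dict)
    provenance: dict[str, str] = field(default_factory=dict)

    def set_fixed(self, gene: str, multiplier: float) -> "ScalingMap":
        if multiplier <= 0:
            raise DomainError("multiplier must be > 0")
        self.entries[gene] = multiplier
        self.provenance[gene] = "fixed"
        return self

    def set_from_log2fc(self, gene: str, log2fc: float) -> "ScalingMap":
        self.entries[gene] = 2.0 ** log2fc
        self.provenance[gene] = f"from_log2fc({log2fc})"
        return self

    def validate(self) -> None:
        for g, m in self.entries.items():
            if m <= 0:
                raise DomainError(f"multiplier for {g!r} must be > 0")


@dataclass
class HypothesisSpec:
    """One structural hypothesis and its fold-change parameter.

    ``species`` optionally restricts the selector to processes forming
    (H1) or exporting (H2/H3) a single glucuronide; by default every
    matching process in the model is scaled.
    """

    id: str
    theta: float = 1.0
    bounds: tuple[float, float] = (1e-3, 1e3)
    species: str | None = None

    def validate(self) -> None:
        if self.id not in HYPOTHESIS_TARGET_GENES:
            raise ConfigError(f"hypothesis id must be one of H1/H2/H3, got {self.id!r}")
        lo, hi = self.bounds
        if not (0 < lo <= self.theta <= hi):
            raise DomainError(f"theta {self.theta} outside bounds ({lo}, {hi})")

    def match(self, model: ModelDefinition) -> list[int]:
        """Indices of the processes this hypothesis scales."""
        genes = HYPOTHESIS_TARGET_GENES[self.id]
        hits = []
        for i, p in enumerate(model.processes):
            if p.gene not in genes:
                continue
            if self.species is not None:
                anchor = p.product if self.id == "H1" else p.substrate
                if anchor != self.species:
                    continue
            hits.append(i)
        return hits


@dataclass
class CirrhosisScenario:
    """A complete disease configuration for one simulation arm."""

    cyp_fraction: float = 0.11
    scaling: ScalingMap = field(default_factory=ScalingMap)
    physiology_knobs: dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "cyp_fraction": self.cyp_fraction,
            "scaling": {"entries": dict(self.scaling.entries), "provenance": dict(self.scaling.provenance)},
            "physiology_knobs": dict(self.physiology_knobs),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CirrhosisScenario":
        sc = ScalingMap(
            entries=dict(d.get("scaling", {}).get("entries", {})),
            provenance=dict(d.get("scaling", {}).get("provenance", {})),
        )
        return cls(
            cyp_fraction=d.get("cyp_fraction", 0.11),
            scaling=sc,
            physiology_knobs=dict(d.get("physiology_knobs", {})),
        )


def default_cirrhosis_scenario() -> CirrhosisScenario:
    """CYP activity at 11% plus fixed transporter multipliers.

    The uptake carrier Slco1b2 is halved and the canalicular exporter
    Abcb1a doubled — configured defaults marked ``fixed`` in provenance
    (their fold changes are configuration, not derived values).
    Glucuronide export carriers are deliberately absent: their change is
    what the hypothesis fit estimates.
    """
    sc = ScalingMap()
    sc.set_fixed("Slco1b2", 0.5)
    sc.set_fixed("Abcb1a", 2.0)
    return CirrhosisScenario(cyp_fraction=0.11, scaling=sc)


def apply_cirrhosis(
    model: ModelDefinition,
    scaling: ScalingMap | None = None,
    cyp_fraction: float = 0.11,
) -> ModelDefinition:
    """Return the cirrhotic variant of a healthy-reference model.

    Every CYP-gene enzymatic clearance and every unspecified hepatic
    clearance route is multiplied by ``cyp_fraction``; transporter vmax
    values with an entry in ``scaling`` are multiplied accordingly.
    UGT processes and unlisted genes are unchanged.
    """
    if not (0 < cyp_fraction <= 1):
        raise DomainError("cyp_fraction must be in (0, 1]")
    scaling = scaling if scaling is not None else ScalingMap()
    scaling.validate()
    out = model.copy()
    seen_genes = set()
    for p in out.processes:
        if p.kind == "enzymatic_first_order" and p.gene and p.gene.startswith(CYP_PREFIX):
            p.params["cl"] = p.params["cl"] * cyp_fraction
        elif p.kind == "total_hepatic_clearance":
            p.params["cl"] = p.params["cl"] * cyp_fraction
        elif p.kind == "mm_transport" and p.gene in scaling.entries:
            p.params["vmax"] = p.params["vmax"] * scaling.entries[p.gene]
            seen_genes.add(p.gene)
        elif p.kind == "biliary_clearance" and p.gene in scaling.entries:
            p.params["cl"] = p.params["cl"] * scaling.entries[p.gene]
            seen_genes.add(p.gene)
    for gene in set(scaling.entries) - seen_genes:
        warnings.warn(f"scaling entry for {gene!r} matched no process in model {model.name!r}")
    return out


def apply_scenario(model: ModelDefinition, scenario: CirrhosisScenario) -> ModelDefinition:
    """Apply a full scenario (cirrhosis scaling plus physiology knobs)."""
    out = apply_cirrhosis(model, scenario.scaling, scenario.cyp_fraction)
    if scenario.physiology_knobs:
        out = scale_physiology(out, scenario.physiology_knobs)
    return out


def apply_hypothesis(model: ModelDefinition, spec: HypothesisSpec) -> ModelDefinition:
    """Scale the processes targeted by one hypothesis by its theta."""
    spec.validate()
    hits = spec.match(model)
    if not hits:
        raise SelectorError(
            f"hypothesis {spec.id} matches no process in model {model.name!r} "
            f"(target genes {HYPOTHESIS_TARGET_GENES[spec.id]})"
        )
    out = model.copy()
    for i in hits:
        p = out.processes[i]
        key = "vmax" if "vmax" in p.params else "cl"
        p.params[key] = p.params[key] * spec.theta
    return out


_PHYSIOLOGY_KNOBS = {
    "liver_blood_flow_fraction": ("blood_flows", "liver"),
    "plasma_volume_fraction": ("compartment_volumes", "plasma"),
}


def scale_physiology(model: ModelDefinition, knobs: dict[str, float]) -> ModelDefinition:
    """Multiply named physiology entries; used for sensitivity sweeps."""
    out = model.copy()
    for knob, frac in knobs.items():
        if knob not in _PHYSIOLOGY_KNOBS:
            raise ConfigError(f"unknown physiology knob {knob!r}; valid: {sorted(_PHYSIOLOGY_KNOBS)}")
        if frac <= 0:
            raise DomainError(f"{knob} must be > 0")
        attr, key = _PHYSIOLOGY_KNOBS[knob]
        getattr(out.physiology, attr)[key] *= frac
    return out
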