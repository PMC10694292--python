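"""Compartmental PBPK data model.

The package uses a deliberately reduced whole-body topology with five
physical compartments — ``plasma``, ``liver_blood``, ``hepatocyte``,
``kidney`` and ``rest_of_body`` — plus three cumulative sinks (``urine``,
``bile``, ``unknown_sink``).  This is the smallest structure that can
express every disposition mechanism the analysis reasons about:
sinusoidal uptake and export across the basolateral hepatocyte membrane,
canalicular export into bile, hepatic phase-I/phase-II metabolism and
renal filtration.

Units are fixed package-wide: amounts in nmol, volumes in L,
concentrations in nmol/L, time in min, clearances in L/min,
transport capacities (vmax) in nmol/min and affinities (km) in nmol/L.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field, asdict

SCHEMA_VERSION = "1"

#: fixed, documented ordering of the physical compartments
COMPARTMENTS = ("plasma", "liver_blood", "hepatocyte", "kidney", "rest_of_body")
#: cumulative-amount sinks appended after the physical compartments
SINKS = ("urine", "bile", "unknown_sink")
#: full per-species slot ordering used for state indexing
SLOTS = COMPARTMENTS + SINKS

PROCESS_KINDS = (
    "enzymatic_first_order",
    "total_hepatic_clearance",
    "mm_transport",
    "glomerular_filtration",
    "biliary_clearance",
    "passive_exchange",
)


class DefinitionError(ValueError):
    """A ModelDefinition violates its structural invariants."""


class DomainError(ValueError):
    """A scalar input is outside its admissible domain."""


@dataclass
class Physiology:
    """Organ volumes, blood flows and elimination flows of one animal.

    ``compartment_volumes`` must cover all five physical compartments;
    ``blood_flows`` carries the liver, kidney and rest-of-body flows
    (the liver flow feeds the liver-blood sub-compartment).
    """

    body_weight: float
    compartment_volumes: dict[str, float]
    blood_flows: dict[str, float]
    gfr: float
    bile_flow: float

    def validate(self) -> None:
        if self.body_weight <= 0:
            raise DomainError("body_weight must be > 0")
        missing = set(COMPARTMENTS) - set(self.compartment_volumes)
        if missing:
            raise DefinitionError(f"compartment_volumes missing {sorted(missing)}")
        for name, v in self.compartment_volumes.items():
            if v <= 0:
                raise DefinitionError(f"volume of {name!r} must be > 0, got {v}")
        for organ in ("liver", "kidney", "rest_of_body"):
            if organ not in self.blood_flows:
                raise DefinitionError(f"blood_flows missing {organ!r}")
            if self.blood_flows[organ] < 0:
                raise DefinitionError(f"blood flow of {organ!r} must be >= 0")
        if self.gfr < 0:
            raise DomainError("gfr must be >= 0")
        if self.bile_flow < 0:
            raise DomainError("bile_flow must be >= 0")


@dataclass
class ChemSpecies:
    """A chemical entity (parent drug or metabolite) and its passive behaviour.

    ``partition`` holds tissue:plasma partition coefficients (Kp) for the
    flow-limited compartments (kidney, rest_of_body).  ``passive_exchange_cl``
    is the bidirectional diffusion clearance across the hepatocyte
    basolateral membrane; glucuronides carry 0 here so that carriers are
    their only way out of the hepatocyte.
    """

    name: str
    molecular_weight: float
    fraction_unbound: float
    partition: dict[str, float] = field(default_factory=lambda: {"kidney": 1.0, "rest_of_body": 1.0})
    passive_exchange_cl: float = 0.0

    def validate(self) -> None:
        if not self.name:
            raise DefinitionError("species name must be non-empty")
        if self.molecular_weight <= 0:
            raise DefinitionError(f"{self.name}: molecular_weight must be > 0")
        if not (0.0 < self.fraction_unbound <= 1.0):
            raise DefinitionError(f"{self.name}: fraction_unbound must be in (0, 1]")
        for tissue, kp in self.partition.items():
            if kp <= 0:
                raise DefinitionError(f"{self.name}: Kp[{tissue}] must be > 0")
        if self.passive_exchange_cl < 0:
            raise DefinitionError(f"{self.name}: passive_exchange_cl must be >= 0")


@dataclass
class Process:
    """One ADME process acting on a single substrate.

    ``params`` holds either ``{"cl": L/min}`` (first-order kinetics) or
    ``{"vmax": nmol/min, "km": nmol/L}`` (Michaelis–Menten transport).
    All rates act on the unbound concentration at the source compartment.
    """

    kind: str
    substrate: str
    source: str
    target: str
    params: dict[str, float]
    gene: str | None = None
    product: str | None = None  # metabolite name or "unknown_sink"

    def validate(self) -> None:
        if self.kind not in PROCESS_KINDS:
            raise DefinitionError(f"unknown process kind {self.kind!r}")
        if self.kind == "mm_transport":
            vmax = self.params.get("vmax")
            km = self.params.get("km")
            if vmax is None or km is None:
                raise DefinitionError(f"mm_transport on {self.substrate!r} needs vmax and km")
            if vmax < 0:
                raise DefinitionError("vmax must be >= 0")
            if km <= 0:
                raise DefinitionError("km must be > 0")
            if self.source == self.target:
                raise DefinitionError("mm_transport must move between distinct compartments")
        else:
            cl = self.params.get("cl")
            if cl is None:
                raise DefinitionError(f"{self.kind} on {self.substrate!r} needs a cl parameter")
            if cl < 0:
                raise DefinitionError("cl must be >= 0")
        if self.kind in ("enzymatic_first_order", "total_hepatic_clearance") and self.source != "hepatocyte":
            raise DefinitionError(f"{self.kind} must be located in the hepatocyte")
        if self.kind == "glomerular_filtration" and (self.source != "plasma" or self.target != "urine"):
            raise DefinitionError("glomerular_filtration draws from plasma into the urine sink")
        if self.kind == "biliary_clearance" and self.target != "bile":
            raise DefinitionError("biliary_clearance must target the bile sink")


@dataclass
class DoseEvent:
    """An i.v. bolus of one species into plasma."""

    species: str
    time: float
    amount: float
    route: str = "iv_bolus"

    def validate(self) -> None:
        if self.amount < 0:
            raise DomainError("dose amount must be >= 0")
        if self.time < 0:
            raise DomainError("dose time must be >= 0")
        if self.route != "iv_bolus":
            raise DefinitionError(f"unsupported route {self.route!r}")


@dataclass
class ModelDefinition:
    """One drug family: physiology, chemical species and processes."""

    physiology: Physiology
    species: list[ChemSpecies]
    processes: list[Process]
    name: str = "model"

    def species_names(self) -> list[str]:
        return [s.name for s in self.species]

    def get_species(self, name: str) -> ChemSpecies:
        for s in self.species:
            if s.name == name:
                return s
        raise DefinitionError(f"species {name!r} not declared in model {self.name!r}")

    def find_processes(
        self,
        kind: str | None = None,
        gene: str | None = None,
        substrate: str | None = None,
        product: str | None = None,
        target: str | None = None,
    ) -> list[int]:
        """Indices of processes matching all given criteria (None = any)."""
        hits = []
        for i, p in enumerate(self.processes):
            if kind is not None and p.kind != kind:
                continue
            if gene is not None and p.gene != gene:
                continue
            if substrate is not None and p.substrate != substrate:
                continue
            if product is not None and p.product != product:
                continue
            if target is not None and p.target != target:
                continue
            hits.append(i)
        return hits

    def copy(self) -> "ModelDefinition":
        return copy.deepcopy(self)

    def validate(self) -> None:
        self.physiology.validate()
        names = self.species_names()
        if len(set(names)) != len(names):
            raise DefinitionError("duplicate species names")
        for s in self.species:
            s.validate()
        comp_ok = set(COMPARTMENTS) | set(SINKS)
        edges = []
        for p in self.processes:
            p.validate()
            if p.substrate not in names:
                raise DefinitionError(
                    f"process references undeclared species {p.substrate!r}"
                )
            if p.product is not None and p.product != "unknown_sink" and p.product not in names:
                raise DefinitionError(
                    f"process references undeclared product species {p.product!r}"
                )
            if p.source not in comp_ok or p.target not in comp_ok:
                raise DefinitionError(
                    f"process references unknown compartment {p.source!r} or {p.target!r}"
                )
            if p.product is not None and p.product != "unknown_sink":
                edges.append((p.substrate, p.product))
        _check_acyclic(names, edges)

    # ------------------------------------------------------------------ io
    def to_dict(self) -> dict:
        d = asdict(self)
        d["schema_version"] = SCHEMA_VERSION
        return d

    def to_json(self, path=None, **kw) -> str:
        s = json.dumps(self.to_dict(), indent=2, sort_keys=True, **kw)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s)
        return s

    @classmethod
    def from_dict(cls, d: dict) -> "ModelDefinition":
        d = dict(d)
        d.pop("schema_version", None)
        phys = Physiology(**d["physiology"])
        species = [ChemSpecies(**s) for s in d["species"]]
        processes = [Process(**p) for p in d["processes"]]
        m = cls(physiology=phys, species=species, processes=processes, name=d.get("name", "model"))
        m.validate()
        return m

    @classmethod
    def from_json(cls, src: str) -> "ModelDefinition":
        try:
            with open(src) as fh:
                d = json.load(fh)
        except (OSError, ValueError):
            d = json.loads(src)
        return cls.from_dict(d)


def _check_acyclic(names: list[str], edges: list[tuple[str, str]]) -> None:
    """DFS cycle check on the substrate→product metabolite graph."""
    adj: dict[str, list[str]] = {n: [] for n in names}
    for a, b in edges:
        adj[a].append(b)
    state = {n: 0 for n in names}  # 0 unvisited, 1 on stack, 2 done

    def visit(n: str) -> None:
        state[n] = 1
        for m in adj[n]:
            if state[m] == 1:
                raise DefinitionError(f"cyclic metabolite graph through {m!r}")
            if state[m] == 0:
                visit(m)
        state[n] = 2

    for n in names:
        if state[n] == 0:
            visit(n)


def mgkg_to_nmol(dose_mg_per_kg: float, body_weight_kg: float, mw_g_per_mol: float) -> float:
    """Convert a weight-normalised dose to molar amount.

    nmol = dose [mg/kg] * body weight [kg] * 1e6 / MW [g/mol].
    """
    if dose_mg_per_kg <= 0 or body_weight_kg <= 0 or mw_g_per_mol <= 0:
        raise DomainError("dose, body weight and molecular weight must all be > 0")
    return dose_mg_per_kg * body_weight_kg * 1e6 / mw_g_per_mol
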