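"""The six drug-family models of the probe cocktail.

The cocktail pairs each probe drug with the hepatic process it reports
on: caffeine (Cyp1a2), codeine (Cyp2d22/Cyp3a11 + glucuronidation),
midazolam (Cyp3a11 + glucuronidation), torsemide (Cyp2c29, Slco1b2
uptake), pravastatin (Slco1b2 uptake, Abcc2 biliary export) and
talinolol (Abcb1a canalicular export).  Glucuronides (C6G, M3G,
OH-MDZ-G) are membrane-impermeable and leave the hepatocyte only via
carriers: Abcc3/Abcc4 across the sinusoidal membrane into blood and
Abcc2 across the canalicular membrane into bile.

All drug-specific numeric parameters below are editable placeholders
chosen from standard rodent physiology and typical literature-scale
kinetics; they are not measured constants.  Molecular weights are
standard reference values.  Transport Km is fixed at 1000 nmol/L
(1 umol/L) throughout; only vmax values differ between carriers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .model import (
    ChemSpecies,
    DoseEvent,
    ModelDefinition,
    Physiology,
    Process,
    mgkg_to_nmol,
)

#: default transporter affinity, nmol/L
KM_DEFAULT = 1000.0

#: cocktail doses, mg/kg body weight
DOSES_MG_PER_KG = {
    "caffeine": 5.0,
    "codeine": 2.0,
    "midazolam": 2.0,
    "pravastatin": 20.0,
    "talinolol": 1.0,
    "torsemide": 2.0,
}

#: molecular weights, g/mol (standard reference values)
MOLECULAR_WEIGHTS = {
    "caffeine": 194.19,
    "paraxanthine": 180.16,
    "codeine": 299.36,
    "morphine": 285.34,
    "norcodeine": 285.34,
    "codeine-6-glucuronide": 475.50,
    "morphine-3-glucuronide": 461.46,
    "midazolam": 325.77,
    "1-hydroxymidazolam": 341.77,
    "1-hydroxymidazolam-glucuronide": 517.93,
    "torsemide": 348.42,
    "hydroxy-torsemide": 364.42,
    "pravastatin": 424.53,
    "talinolol": 363.49,
}

FAMILY_NAMES = ("caffeine", "codeine", "midazolam", "torsemide", "pravastatin", "talinolol")


class LookupError_(KeyError):
    """Unknown drug-family name."""


def mouse_physiology(body_weight: float = 0.025) -> Physiology:
    """Reduced mouse physiology (placeholder rodent reference values).

    Volumes and flows scale linearly with body weight around the 25 g
    reference animal.
    """
    f = body_weight / 0.025
    return Physiology(
        body_weight=body_weight,
        compartment_volumes={
            "plasma": 0.0010 * f,
            "liver_blood": 0.0003 * f,
            "hepatocyte": 0.0012 * f,
            "kidney": 0.0004 * f,
            "rest_of_body": 0.0190 * f,
        },
        blood_flows={"liver": 0.0018 * f, "kidney": 0.0013 * f, "rest_of_body": 0.0050 * f},
        gfr=0.00025 * f,
        bile_flow=2.5e-6 * f,
    )


@dataclass
class DrugFamily:
    """Declarative description of one family's metabolite network."""

    name: str
    members: list[str]  # parent first
    network: list[tuple[str, str, str]] = field(default_factory=list)  # (substrate, product, gene)
    transporters: list[tuple[str, str, str]] = field(default_factory=list)  # (species, gene, membrane)


_GLUCURONIDE_EXPORT = {
    # per-glucuronide (Abcc3 vmax, Abcc4 vmax, Abcc2 vmax), nmol/min.
    # Sinusoidal export is a minor share (~10%) of total carrier capacity at
    # baseline; canalicular export dominates, as expected for glucuronides.
    "1-hydroxymidazolam-glucuronide": (0.04, 0.04, 0.72),
    "codeine-6-glucuronide": (0.04, 0.04, 0.72),
    "morphine-3-glucuronide": (0.04, 0.04, 0.72),
}

FAMILIES: dict[str, DrugFamily] = {
    "caffeine": DrugFamily(
        name="caffeine",
        members=["caffeine", "paraxanthine"],
        network=[("caffeine", "paraxanthine", "Cyp1a2")],
    ),
    "codeine": DrugFamily(
        name="codeine",
        members=[
            "codeine",
            "morphine",
            "norcodeine",
            "codeine-6-glucuronide",
            "morphine-3-glucuronide",
        ],
        network=[
            ("codeine", "morphine", "Cyp2d22"),
            ("codeine", "norcodeine", "Cyp3a11"),
            ("codeine", "codeine-6-glucuronide", "Ugt"),
            ("morphine", "morphine-3-glucuronide", "Ugt"),
        ],
        transporters=[
            ("codeine-6-glucuronide", "Abcc3", "sinusoidal_out"),
            ("codeine-6-glucuronide", "Abcc4", "sinusoidal_out"),
            ("codeine-6-glucuronide", "Abcc2", "canalicular"),
            ("morphine-3-glucuronide", "Abcc3", "sinusoidal_out"),
            ("morphine-3-glucuronide", "Abcc4", "sinusoidal_out"),
            ("morphine-3-glucuronide", "Abcc2", "canalicular"),
        ],
    ),
    "midazolam": DrugFamily(
        name="midazolam",
        members=["midazolam", "1-hydroxymidazolam", "1-hydroxymidazolam-glucuronide"],
        network=[
            ("midazolam", "1-hydroxymidazolam", "Cyp3a11"),
            ("1-hydroxymidazolam", "1-hydroxymidazolam-glucuronide", "Ugt"),
        ],
        transporters=[
            ("1-hydroxymidazolam-glucuronide", "Abcc3", "sinusoidal_out"),
            ("1-hydroxymidazolam-glucuronide", "Abcc4", "sinusoidal_out"),
            ("1-hydroxymidazolam-glucuronide", "Abcc2", "canalicular"),
        ],
    ),
    "torsemide": DrugFamily(
        name="torsemide",
        members=["torsemide", "hydroxy-torsemide"],
        network=[("torsemide", "hydroxy-torsemide", "Cyp2c29")],
        transporters=[("torsemide", "Slco1b2", "sinusoidal_in")],
    ),
    "pravastatin": DrugFamily(
        name="pravastatin",
        members=["pravastatin"],
        transporters=[
            ("pravastatin", "Slco1b2", "sinusoidal_in"),
            ("pravastatin", "Abcc2", "canalicular"),
        ],
    ),
    "talinolol": DrugFamily(
        name="talinolol",
        members=["talinolol"],
        transporters=[("talinolol", "Abcb1a", "canalicular")],
    ),
}

#: per-species physicochemical placeholders:
#: (fraction_unbound, Kp kidney, Kp rest_of_body, passive_exchange_cl L/min)
_SPECIES_PARAMS = {
    "caffeine": (0.85, 0.8, 0.8, 0.030),
    "paraxanthine": (0.90, 0.8, 0.8, 0.030),
    "codeine": (0.90, 1.5, 2.5, 0.020),
    "morphine": (0.75, 1.5, 2.5, 0.010),
    "norcodeine": (0.90, 1.5, 2.0, 0.020),
    "codeine-6-glucuronide": (0.85, 0.2, 0.2, 0.0),
    "morphine-3-glucuronide": (0.85, 0.2, 0.2, 0.0),
    "midazolam": (0.04, 2.0, 3.0, 0.050),
    "1-hydroxymidazolam": (0.10, 1.5, 2.0, 0.050),
    "1-hydroxymidazolam-glucuronide": (0.30, 0.2, 0.2, 0.0),
    "torsemide": (0.05, 0.3, 0.3, 0.0),
    "hydroxy-torsemide": (0.10, 0.5, 0.5, 0.020),
    "pravastatin": (0.55, 0.25, 0.25, 0.0),
    "talinolol": (0.60, 1.2, 2.0, 0.010),
}

#: enzymatic clearances (L/min intrinsic, placeholder scale):
#: keyed (substrate, product, gene); product "unknown_sink" = unspecified routes
_ENZYME_CL = {
    ("caffeine", "paraxanthine", "Cyp1a2"): 0.0012,
    ("caffeine", "unknown_sink", None): 0.0003,
    ("paraxanthine", "unknown_sink", None): 0.0008,
    ("codeine", "morphine", "Cyp2d22"): 0.0008,
    ("codeine", "norcodeine", "Cyp3a11"): 0.0004,
    ("codeine", "codeine-6-glucuronide", "Ugt"): 0.0003,
    ("morphine", "morphine-3-glucuronide", "Ugt"): 0.0005,
    ("morphine", "unknown_sink", None): 0.0020,
    ("norcodeine", "unknown_sink", None): 0.0010,
    ("midazolam", "1-hydroxymidazolam", "Cyp3a11"): 0.050,
    ("1-hydroxymidazolam", "1-hydroxymidazolam-glucuronide", "Ugt"): 0.010,
    ("1-hydroxymidazolam", "unknown_sink", None): 1.000,
    ("torsemide", "hydroxy-torsemide", "Cyp2c29"): 0.500,
    ("hydroxy-torsemide", "unknown_sink", None): 0.0005,
    ("pravastatin", "unknown_sink", None): 0.0010,
    ("talinolol", "unknown_sink", None): 0.0002,
}

#: uptake / parent-export transporter capacities (vmax nmol/min), keyed (species, gene)
_TRANSPORT_VMAX = {
    ("torsemide", "Slco1b2"): 2.0,
    ("pravastatin", "Slco1b2"): 10.0,
    ("pravastatin", "Abcc2"): 12.0,
    ("talinolol", "Abcb1a"): 1.5,
}

_MEMBRANE_ROUTE = {
    "sinusoidal_in": ("liver_blood", "hepatocyte"),
    "sinusoidal_out": ("hepatocyte", "liver_blood"),
    "canalicular": ("hepatocyte", "bile"),
}


def get_family_model(name: str, physiology: Physiology | None = None) -> ModelDefinition:
    """Build the ModelDefinition for one drug family.

    Raises a lookup error listing the valid names if ``name`` is not one
    of the six cocktail drugs.
    """
    if name not in FAMILIES:
        raise LookupError_(f"unknown drug family {name!r}; valid names: {sorted(FAMILIES)}")
    fam = FAMILIES[name]
    phys = physiology if physiology is not None else mouse_physiology()

    species = []
    for member in fam.members:
        fu, kp_kid, kp_rob, ps = _SPECIES_PARAMS[member]
        species.append(
            ChemSpecies(
                name=member,
                molecular_weight=MOLECULAR_WEIGHTS[member],
                fraction_unbound=fu,
                partition={"kidney": kp_kid, "rest_of_body": kp_rob},
                passive_exchange_cl=ps,
            )
        )

    processes: list[Process] = []
    # metabolic network (phase I and phase II, plus unspecified routes)
    for (sub, prod, gene), cl in _ENZYME_CL.items():
        if sub not in fam.members:
            continue
        if prod == "unknown_sink":
            processes.append(
                Process(
                    kind="total_hepatic_clearance",
                    substrate=sub,
                    source="hepatocyte",
                    target="unknown_sink",
                    params={"cl": cl},
                    gene=gene,
                    product="unknown_sink",
                )
            )
        else:
            processes.append(
                Process(
                    kind="enzymatic_first_order",
                    substrate=sub,
                    source="hepatocyte",
                    target="hepatocyte",
                    params={"cl": cl},
                    gene=gene,
                    product=prod,
                )
            )
    # carrier-mediated transport
    for sp_name, gene, membrane in fam.transporters:
        src, tgt = _MEMBRANE_ROUTE[membrane]
        if sp_name in _GLUCURONIDE_EXPORT:
            v3, v4, v2 = _GLUCURONIDE_EXPORT[sp_name]
            vmax = {"Abcc3": v3, "Abcc4": v4, "Abcc2": v2}[gene]
        else:
            vmax = _TRANSPORT_VMAX[(sp_name, gene)]
        processes.append(
            Process(
                kind="mm_transport",
                substrate=sp_name,
                source=src,
                target=tgt,
                params={"vmax": vmax, "km": KM_DEFAULT},
                gene=gene,
            )
        )
    # renal elimination: glomerular filtration of unbound drug for every species
    for member in fam.members:
        processes.append(
            Process(
                kind="glomerular_filtration",
                substrate=member,
                source="plasma",
                target="urine",
                params={"cl": phys.gfr},
                gene=None,
            )
        )

    model = ModelDefinition(physiology=phys, species=species, processes=processes, name=name)
    model.validate()
    return model


def default_dose_table(body_weight: float) -> list[DoseEvent]:
    """The six-drug cocktail as simultaneous i.v. boluses at t = 0."""
    return [
        DoseEvent(
            species=drug,
            time=0.0,
            amount=mgkg_to_nmol(DOSES_MG_PER_KG[drug], body_weight, MOLECULAR_WEIGHTS[drug]),
        )
        for drug in FAMILY_NAMES
    ]
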