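"""Synthetic cohorts with the statistical structure the analysis assumes.

Each virtual animal receives the cocktail as an i.v. bolus and is
sampled on the sparse study design: plasma at 15/30/60/120 min,
cumulative urine at 24 h and cumulative bile at 2 h.  Measurements carry
multiplicative lognormal noise; optional inter-animal variability
perturbs the hepatic process parameters (clearances and transport
capacities) per subject.  Every dataset ships with a GroundTruth record
sufficient to regenerate it bit-exactly and to score parameter-recovery
experiments.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .library import DOSES_MG_PER_KG
from .metrics import ObservationSet
from .model import DoseEvent, DomainError, ModelDefinition, mgkg_to_nmol
from .ode import build_ode_system, simulate
from .scenarios import CirrhosisScenario, HypothesisSpec, apply_hypothesis, apply_scenario


class DesignError(ValueError):
    """Sampling design incompatible with the simulation span."""


@dataclass
class SamplingDesign:
    """When and what is measured in each animal."""

    plasma_times: tuple[float, ...] = (15.0, 30.0, 60.0, 120.0)
    urine_time: float = 1440.0
    bile_time: float = 120.0
    include_urine: bool = True
    include_bile: bool = True

    def all_times(self) -> np.ndarray:
        ts = set(self.plasma_times)
        if self.include_urine:
            ts.add(self.urine_time)
        if self.include_bile:
            ts.add(self.bile_time)
        return np.array(sorted(ts))


@dataclass
class NoiseModel:
    """Measurement noise and inter-individual variability.

    ``cv`` is the coefficient of variation of the multiplicative
    lognormal measurement error (sigma = sqrt(log(1 + cv^2)));
    ``iiv_cv`` is the lognormal CV of per-subject multipliers on hepatic
    process parameters.  ``loq`` maps observation kinds to lower limits
    of quantification; values below are flagged, not removed.
    """

    cv: float = 0.20
    iiv_cv: float = 0.30
    loq: dict[str, float] = field(
        default_factory=lambda: {"plasma_conc": 0.5, "urine_cumulative": 0.05, "bile_cumulative": 0.05}
    )

    def validate(self) -> None:
        if self.cv < 0 or self.iiv_cv < 0:
            raise DomainError("cv and iiv_cv must be >= 0")
        if any(v < 0 for v in self.loq.values()):
            raise DomainError("loq values must be >= 0")

    @property
    def sigma(self) -> float:
        return math.sqrt(math.log(1.0 + self.cv**2))

    @property
    def iiv_sigma(self) -> float:
        return math.sqrt(math.log(1.0 + self.iiv_cv**2))


@dataclass
class GroundTruth:
    """Everything needed to regenerate a dataset and score recovery."""

    model: dict
    scenario: dict | None
    hypothesis: dict | None
    noise: dict
    design: dict
    n_subjects: int
    group_label: str
    seed: int

    def to_json(self, path=None) -> str:
        s = json.dumps(asdict(self), indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s)
        return s


def _default_family_doses(model: ModelDefinition) -> list[DoseEvent]:
    parent = model.species[0]
    if model.name not in DOSES_MG_PER_KG:
        raise DomainError(
            f"no default dose for model {model.name!r}; pass doses explicitly"
        )
    amount = mgkg_to_nmol(
        DOSES_MG_PER_KG[model.name], model.physiology.body_weight, parent.molecular_weight
    )
    return [DoseEvent(species=parent.name, time=0.0, amount=amount)]


def _hepatic_param_indices(model: ModelDefinition) -> list[tuple[int, str]]:
    """(process index, param key) pairs that receive IIV multipliers."""
    out = []
    for i, p in enumerate(model.processes):
        if p.kind in ("enzymatic_first_order", "total_hepatic_clearance", "biliary_clearance"):
            out.append((i, "cl"))
        elif p.kind == "mm_transport":
            out.append((i, "vmax"))
    return out


def generate_observations(
    model: ModelDefinition,
    scenario: CirrhosisScenario | None,
    design: SamplingDesign,
    noise: NoiseModel,
    n_subjects: int,
    group_label: str,
    seed,
    doses: list[DoseEvent] | None = None,
    hypothesis: HypothesisSpec | None = None,
) -> tuple[ObservationSet, GroundTruth]:
    """Simulate one group of animals and corrupt the design readouts.

    ``seed`` may be an integer or a ``numpy.random.SeedSequence``/
    ``Generator``; integer seeds make the output bit-reproducible.
    """
    if n_subjects < 1:
        raise DomainError("n_subjects must be >= 1")
    noise.validate()
    truth_model = model if scenario is None else apply_scenario(model, scenario)
    if hypothesis is not None:
        truth_model = apply_hypothesis(truth_model, hypothesis)
    if doses is None:
        doses = _default_family_doses(model)
    rng = np.random.default_rng(seed)

    times = design.all_times()
    if times.min() < 0:
        raise DesignError("design times must be >= 0")
    t_eval = np.unique(np.concatenate([[0.0], times]))
    iiv_slots = _hepatic_param_indices(truth_model)
    # bile is only informative for species with a canalicular export route
    bile_species = {
        truth_model.processes[i].substrate
        for i in truth_model.find_processes(target="bile")
    }

    rows = []
    for subj in range(n_subjects):
        subj_model = truth_model
        if noise.iiv_cv > 0 and iiv_slots:
            subj_model = truth_model.copy()
            mults = np.exp(noise.iiv_sigma * rng.standard_normal(len(iiv_slots)))
            for (i, key), m in zip(iiv_slots, mults):
                subj_model.processes[i].params[key] *= m
        system = build_ode_system(subj_model)
        tc = simulate(system, doses, t_eval)
        sid = f"{group_label}_{subj + 1:02d}"

        def emit(kind: str, species: str, t: float, true_value: float) -> None:
            mult = float(np.exp(noise.sigma * rng.standard_normal())) if noise.cv > 0 else 1.0
            value = true_value * mult
            loq = noise.loq.get(kind, 0.0)
            rows.append(
                {
                    "subject_id": sid,
                    "group": group_label,
                    "species": species,
                    "kind": kind,
                    "time_min": t,
                    "value": value,
                    "below_loq": value < loq,
                }
            )

        for sp in truth_model.species_names():
            conc = tc.concentration("plasma", sp)
            for t in design.plasma_times:
                i = int(np.flatnonzero(np.isclose(t_eval, t))[0])
                emit("plasma_conc", sp, t, float(conc[i]))
            if design.include_urine:
                i = int(np.flatnonzero(np.isclose(t_eval, design.urine_time))[0])
                emit("urine_cumulative", sp, design.urine_time, float(tc.amount("urine", sp)[i]))
            if design.include_bile and sp in bile_species:
                i = int(np.flatnonzero(np.isclose(t_eval, design.bile_time))[0])
                emit("bile_cumulative", sp, design.bile_time, float(tc.amount("bile", sp)[i]))

    obs = ObservationSet(pd.DataFrame(rows))
    truth = GroundTruth(
        model=model.to_dict(),
        scenario=scenario.to_dict() if scenario is not None else None,
        hypothesis=asdict(hypothesis) if hypothesis is not None else None,
        noise=asdict(noise),
        design=asdict(design),
        n_subjects=n_subjects,
        group_label=group_label,
        seed=int(seed) if isinstance(seed, (int, np.integer)) else -1,
    )
    return obs, truth


@dataclass
class CohortBundle:
    """A paired control/cirrhosis study with its generating truth."""

    obs_control: ObservationSet
    obs_cirrhosis: ObservationSet
    truth_control: GroundTruth
    truth_cirrhosis: GroundTruth
    doses: list[DoseEvent]
    design: SamplingDesign
    #: synthetic microsomal glucuronidation-activity ratio (cirrhosis/control):
    #: equals the hypothesis theta when the truth is H1, else ~1
    ugt_activity_ratio_obs: float = 1.0


def generate_paired_cohorts(
    model: ModelDefinition,
    scenario: CirrhosisScenario,
    hypothesis_truth: HypothesisSpec,
    noise: NoiseModel,
    n_per_group: int,
    seed: int,
    design: SamplingDesign | None = None,
    doses: list[DoseEvent] | None = None,
) -> CohortBundle:
    """Generate matched control and cirrhosis groups under one truth.

    The control group is simulated from the reference model; the
    cirrhosis group from the scenario plus the true hypothesis.  A
    synthetic microsomal UGT-activity ratio is included: its true value
    is theta under an H1 truth and 1 otherwise, with the same
    multiplicative noise law as the PK readouts.
    """
    design = design if design is not None else SamplingDesign()
    if doses is None:
        doses = _default_family_doses(model)
    ss = np.random.SeedSequence(seed)
    s_ctrl, s_cirr, s_aux = ss.spawn(3)
    obs_c, truth_c = generate_observations(
        model, None, design, noise, n_per_group, "control", s_ctrl, doses=doses
    )
    obs_d, truth_d = generate_observations(
        model, scenario, design, noise, n_per_group, "cirrhosis", s_cirr,
        doses=doses, hypothesis=hypothesis_truth,
    )
    truth_c.seed = truth_d.seed = int(seed)
    rng = np.random.default_rng(s_aux)
    true_ratio = hypothesis_truth.theta if hypothesis_truth.id == "H1" else 1.0
    ratio_obs = float(true_ratio * np.exp(noise.sigma * rng.standard_normal())) if noise.cv > 0 else float(true_ratio)
    return CohortBundle(
        obs_control=obs_c,
        obs_cirrhosis=obs_d,
        truth_control=truth_c,
        truth_cirrhosis=truth_d,
        doses=doses,
        design=design,
        ugt_activity_ratio_obs=ratio_obs,
    )
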