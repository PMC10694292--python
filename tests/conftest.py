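import warnings

import numpy as np
import pytest

from cocktail_pbpk import (
    ChemSpecies,
    DoseEvent,
    ModelDefinition,
    Physiology,
    Process,
    default_cirrhosis_scenario,
    default_dose_table,
    get_family_model,
)

# scenario warnings about genes absent from single-family models are expected
warnings.filterwarnings("ignore", message="scaling entry for")


@pytest.fixture(scope="session")
def midazolam_model():
    return get_family_model("midazolam")


@pytest.fixture(scope="session")
def midazolam_doses(midazolam_model):
    names = set(midazolam_model.species_names())
    return [d for d in default_dose_table(0.025) if d.species in names]


@pytest.fixture(scope="session")
def cirrhosis_scenario():
    return default_cirrhosis_scenario()


def one_compartment_model(volume=1.0, cl=0.01):
    """Degenerate single-compartment model: bolus into plasma, one
    first-order elimination, no distribution (all flows zero)."""
    phys = Physiology(
        body_weight=0.025,
        compartment_volumes={
            "plasma": volume,
            "liver_blood": 1e-6,
            "hepatocyte": 1e-6,
            "kidney": 1e-6,
            "rest_of_body": 1e-6,
        },
        blood_flows={"liver": 0.0, "kidney": 0.0, "rest_of_body": 0.0},
        gfr=0.0,
        bile_flow=0.0,
    )
    sp = ChemSpecies(name="drug", molecular_weight=300.0, fraction_unbound=1.0,
                     partition={"kidney": 1.0, "rest_of_body": 1.0}, passive_exchange_cl=0.0)
    proc = Process(kind="glomerular_filtration", substrate="drug", source="plasma",
                   target="urine", params={"cl": cl})
    return ModelDefinition(physiology=phys, species=[sp], processes=[proc], name="one_compartment")


@pytest.fixture
def single_compartment():
    return one_compartment_model()


@pytest.fixture
def bolus_100():
    return [DoseEvent(species="drug", time=0.0, amount=100.0)]


@pytest.fixture(scope="session")
def fine_grid():
    return np.linspace(0.0, 240.0, 97)
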