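import numpy as np
import pytest

from crossflux.config import default_config
from crossflux.harmonize import harmonize_table
from crossflux.records import (
    Climate,
    Driver,
    Ecosystem,
    FluxClass,
    FluxRecord,
    GeometrySpec,
    MassBasis,
    MaterialClass,
    MaterialOrigin,
    SpatialBasis,
    TimeBasis,
    UnitSpec,
)
from crossflux.synthetic import generate_dataset, paper_like_config


@pytest.fixture(scope="session")
def config():
    return default_config()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_record(
    record_id="r1",
    ecosystem=Ecosystem.FOREST,
    climate=Climate.TEMPERATE,
    flux_class=FluxClass.GPP,
    value=1.0,
    mass_basis=MassBasis.CARBON,
    spatial_basis=SpatialBasis.PER_M2_RECIPIENT,
    time_basis=TimeBasis.PER_YEAR,
    study_period_days=None,
    **kwargs,
):
    return FluxRecord(
        record_id=record_id,
        study_id="study1",
        ecosystem=ecosystem,
        climate=climate,
        flux_class=flux_class,
        value=value,
        unit=UnitSpec(mass_basis, spatial_basis, time_basis, study_period_days),
        **kwargs,
    )


@pytest.fixture
def harmonized_sample(config):
    """A small but structurally rich harmonized dataset (every flux class)."""
    records, _ = generate_dataset(paper_like_config(seed=7, n_scale=0.05))
    return harmonize_table(records, config)


@pytest.fixture
def spatial_lake_record():
    return make_record(
        record_id="ins1",
        ecosystem=Ecosystem.FOREST,
        climate=Climate.TEMPERATE,
        flux_class=FluxClass.SPATIAL_FLOW,
        value=1.0,
        spatial_basis=SpatialBasis.PER_M2_DONOR,
        material_origin=MaterialOrigin.INVERTEBRATE,
        material_class=MaterialClass.INVERTEBRATE,
        driver=Driver.LIFE_CYCLE,
        donor_ecosystem=Ecosystem.LAKE,
        geometry=GeometrySpec(lake_area=1e4, development_factor=1.0),
    )
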