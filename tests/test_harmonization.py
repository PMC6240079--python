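"""Unit-conversion operations and the composed harmonization path."""

import math

import numpy as np
import pytest

from crossflux.config import default_config
from crossflux.errors import ContractError, DomainError
from crossflux.harmonize import (
    annualize,
    convert_to_carbon,
    depth_from_discharge,
    harmonize_record,
    harmonize_table,
    integrate_over_depth,
    lake_mean_depth,
)
from crossflux.records import (
    Climate,
    Ecosystem,
    FluxClass,
    GeometrySpec,
    MassBasis,
    MaterialClass,
    SpatialBasis,
    TimeBasis,
    UnitSpec,
)
from crossflux.synthetic import generate_dataset, paper_like_config

from conftest import make_record


@pytest.fixture(scope="module")
def cfg():
    return default_config()


class TestCarbonConversion:
    def test_dry_weight_default_factor(self, cfg):
        unit = UnitSpec(mass_basis=MassBasis.DRY_WEIGHT)
        value, factor, _ = convert_to_carbon(100.0, unit, MaterialClass.GENERIC, cfg)
        assert value == 50.0 and factor == 0.5

    def test_carbon_basis_identity(self, cfg):
        unit = UnitSpec(mass_basis=MassBasis.CARBON)
        value, factor, _ = convert_to_carbon(7.3, unit, MaterialClass.VERTEBRATE, cfg)
        assert value == 7.3 and factor == 1.0

    def test_reported_fraction_overrides_table(self, cfg):
        unit = UnitSpec(mass_basis=MassBasis.ASH_FREE_DRY_WEIGHT)
        value, factor, rule = convert_to_carbon(
            100.0, unit, MaterialClass.GENERIC, cfg, reported_fraction=0.42
        )
        assert value == pytest.approx(42.0) and factor == 0.42
        assert "reported" in rule

    def test_invalid_reported_fraction(self, cfg):
        unit = UnitSpec(mass_basis=MassBasis.DRY_WEIGHT)
        with pytest.raises(DomainError):
            convert_to_carbon(1.0, unit, MaterialClass.GENERIC, cfg, reported_fraction=1.5)


class TestAnnualize:
    @pytest.mark.parametrize(
        "climate,expected",
        [
            (Climate.TEMPERATE, 181.0),
            (Climate.TROPICAL, 365.0),
            (Climate.BOREAL, 155.0),
            (Climate.ARCTIC_ALPINE, 116.0),
            (Climate.ARID, 163.0),
        ],
    )
    def test_per_day_scaled_by_growing_season(self, cfg, climate, expected):
        unit = UnitSpec(time_basis=TimeBasis.PER_DAY)
        value, factor, _ = annualize(1.0, unit, climate, cfg)
        assert value == expected and factor == expected

    def test_study_period_longer_than_gsl_unchanged(self, cfg):
        unit = UnitSpec(time_basis=TimeBasis.PER_STUDY_PERIOD, study_period_days=365)
        value, factor, _ = annualize(200.0, unit, Climate.TEMPERATE, cfg)
        assert value == 200.0 and factor == 1.0

    def test_study_period_shorter_than_gsl_scaled_up(self, cfg):
        unit = UnitSpec(time_basis=TimeBasis.PER_STUDY_PERIOD, study_period_days=90.5)
        value, _, _ = annualize(10.0, unit, Climate.TEMPERATE, cfg)
        assert value == pytest.approx(10.0 * 181.0 / 90.5)

    def test_study_period_over_a_year_conserves_totals(self, cfg):
        unit = UnitSpec(time_basis=TimeBasis.PER_STUDY_PERIOD, study_period_days=730)
        value, _, _ = annualize(100.0, unit, Climate.TEMPERATE, cfg)
        assert value == pytest.approx(50.0)

    def test_study_period_without_days_is_contract_error(self, cfg):
        unit = UnitSpec(time_basis=TimeBasis.PER_STUDY_PERIOD)
        with pytest.raises(ContractError):
            annualize(1.0, unit, Climate.TEMPERATE, cfg)

    def test_negative_nep_scales_like_any_flux(self, cfg):
        unit = UnitSpec(time_basis=TimeBasis.PER_DAY)
        value, _, _ = annualize(-0.5, unit, Climate.TEMPERATE, cfg)
        assert value == -90.5


class TestDepths:
    def test_lake_mean_depth_is_volume_over_area(self):
        assert lake_mean_depth(1e6, 1e5) == 10.0
        assert lake_mean_depth(2.5e5, 5e4) == 5.0

    def test_lake_depth_domain_errors(self):
        with pytest.raises(DomainError):
            lake_mean_depth(0.0, 1e5)
        with pytest.raises(DomainError):
            lake_mean_depth(1e5, 0.0)

    def test_depth_from_discharge_power_law(self):
        assert depth_from_discharge(32.0) == pytest.approx(0.8, rel=1e-12)
        assert depth_from_discharge(1.0) == pytest.approx(0.2, rel=1e-12)

    def test_small_catchment_five_cm(self):
        assert depth_from_discharge(catchment_area=0.5) == 0.05
        # catchment rule wins even when discharge is also known
        assert depth_from_discharge(discharge=50.0, catchment_area=0.5) == 0.05

    def test_no_information_is_contract_error(self):
        with pytest.raises(ContractError):
            depth_from_discharge()

    def test_monotone_in_discharge(self):
        q = np.linspace(0.01, 500, 200)
        d = [depth_from_discharge(float(x)) for x in q]
        assert all(b > a for a, b in zip(d, d[1:]))

    def test_integrate_over_depth(self):
        assert integrate_over_depth(2.0, 0.5) == 1.0
        with pytest.raises(ContractError):
            integrate_over_depth(2.0, 0.0)


class TestHarmonizeRecord:
    def test_canonical_record_unchanged_with_empty_audit(self, cfg):
        rec = make_record(value=42.0)
        out = harmonize_record(rec, cfg)
        assert out == rec and out.audit == ()

    def test_composed_dry_weight_volume_day_path(self, cfg):
        # 0.5 g DW m^-3 d^-1 in a boreal lake of mean depth 2 m:
        # 0.5 * 0.5 (carbon) * 2 (depth) * 155 (GSL) = 77.5 gC m^-2 yr^-1
        rec = make_record(
            ecosystem=Ecosystem.LAKE,
            climate=Climate.BOREAL,
            flux_class=FluxClass.SECONDARY_PRODUCTION,
            value=0.5,
            mass_basis=MassBasis.DRY_WEIGHT,
            spatial_basis=SpatialBasis.PER_M3,
            time_basis=TimeBasis.PER_DAY,
            geometry=GeometrySpec(mean_depth=2.0),
        )
        out = harmonize_record(rec, cfg)
        assert out.value == pytest.approx(77.5, rel=1e-12)
        assert out.is_harmonized
        steps = [s.step for s in out.audit]
        assert steps == ["convert_to_carbon", "integrate_over_depth", "annualize"]

    def test_audit_multipliers_reproduce_value(self, cfg):
        records, _ = generate_dataset(paper_like_config(seed=11, n_scale=0.05))
        for raw, out in zip(records, harmonize_table(records, cfg)):
            product = math.prod(s.multiplier for s in out.audit)
            assert out.value == pytest.approx(raw.value * product, rel=1e-9)

    def test_pelagic_default_depth_100m(self, cfg):
        rec = make_record(
            ecosystem=Ecosystem.OCEAN_PELAGIC,
            climate=Climate.TROPICAL,
            flux_class=FluxClass.GPP,
            value=2.0,
            spatial_basis=SpatialBasis.PER_M3,
        )
        out = harmonize_record(rec, cfg)
        assert out.value == pytest.approx(200.0)
        assert any("100 m" in s.rule for s in out.audit)

    def test_donor_area_without_geometry_is_contract_error(self, cfg, spatial_lake_record):
        from dataclasses import replace

        rec = replace(spatial_lake_record, geometry=None)
        with pytest.raises(ContractError, match=rec.record_id):
            harmonize_record(rec, cfg)

    def test_rate_keeps_mass_basis_and_skips_carbon(self, cfg):
        rec = make_record(
            flux_class=FluxClass.DECOMPOSITION_RATE,
            value=0.01,
            mass_basis=MassBasis.DRY_WEIGHT,
            spatial_basis=SpatialBasis.NONE,
            time_basis=TimeBasis.PER_DAY,
            climate=Climate.TROPICAL,
        )
        out = harmonize_record(rec, cfg)
        assert out.value == pytest.approx(3.65)  # x365, never x carbon fraction
        assert out.unit.mass_basis is MassBasis.DRY_WEIGHT
        assert out.is_harmonized


@pytest.fixture(scope="module")
def random_batch():
    cfg = default_config()
    records, _ = generate_dataset(paper_like_config(seed=99, n_scale=0.34))
    assert len(records) >= 1000
    return cfg, records[:1000]


class TestHarmonizationProperties:
    """Idempotence and homogeneity over randomized heterogeneous records."""

    def test_idempotence(self, random_batch):
        cfg, records = random_batch
        once = harmonize_table(records, cfg)
        twice = harmonize_table(once, cfg)
        assert all(a.value == b.value and a.unit == b.unit for a, b in zip(once, twice))

    def test_homogeneity(self, random_batch):
        from dataclasses import replace

        cfg, records = random_batch
        alpha = 3.7
        base = harmonize_table(records, cfg)
        scaled = harmonize_table([replace(r, value=alpha * r.value) for r in records], cfg)
        for a, b in zip(base, scaled):
            assert b.value == pytest.approx(alpha * a.value, rel=1e-12)
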