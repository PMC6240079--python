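"""Generator determinism, exact inversion, and distributional recovery."""

import math

import numpy as np
import pytest

from crossflux.config import default_config
from crossflux.decomposition import decomposition_flux
from crossflux.errors import ConfigError
from crossflux.geometry import distribute_on_band, flow_per_shoreline_lake, lake_perimeter
from crossflux.harmonize import annualize, depth_from_discharge, harmonize_table
from crossflux.records import (
    Climate,
    Driver,
    Ecosystem,
    FluxClass,
    MaterialClass,
    MaterialOrigin,
    SpatialBasis,
    TimeBasis,
    UnitSpec,
)
from crossflux.synthetic import (
    Stratum,
    SyntheticConfig,
    UnitMix,
    generate_dataset,
    make_worked_fixtures,
    paper_like_config,
)


class TestDeterminismAndInversion:
    def test_same_seed_identical_datasets(self):
        cfg = paper_like_config(seed=5, n_scale=0.05)
        r1, t1 = generate_dataset(cfg)
        r2, t2 = generate_dataset(cfg)
        assert r1 == r2
        assert t1.records.equals(t2.records)

    def test_harmonize_inverts_generation_exactly(self, config):
        records, truth = generate_dataset(paper_like_config(seed=42, n_scale=0.25))
        harmonized = harmonize_table(records, config)
        got = np.array([r.value for r in harmonized])
        want = truth.records["canonical_value"].to_numpy()
        rel = np.abs(got - want) / np.maximum(np.abs(want), 1e-300)
        assert rel.max() < 1e-9

    def test_canonical_unit_mix_is_identity(self, config):
        mix = UnitMix(p_carbon=1.0, p_dry=0.0, p_afdw=0.0, p_year=1.0, p_day=0.0,
                      p_period=0.0, p_volume_basis=0.0, p_donor_area=0.0,
                      p_whole_waterbody=0.0, p_shoreline=0.0, p_marine_shoreline=0.0,
                      p_vertical_donor_area=0.0)
        cfg = SyntheticConfig(
            strata=[
                Stratum("s", Ecosystem.FOREST, Climate.TEMPERATE, FluxClass.GPP,
                        n=20, median=100.0, sigma_log=0.5)
            ],
            unit_mix=mix,
            seed=1,
        )
        records, truth = generate_dataset(cfg)
        for rec, want in zip(records, truth.records["canonical_value"]):
            assert rec.value == want
            assert rec.unit == UnitSpec()

    def test_every_harmonization_path_exercised(self):
        records, _ = generate_dataset(paper_like_config(seed=8))
        bases = {r.unit.spatial_basis for r in records}
        assert {
            SpatialBasis.PER_M2_RECIPIENT,
            SpatialBasis.PER_M2_DONOR,
            SpatialBasis.PER_M3,
            SpatialBasis.PER_M_SHORELINE,
            SpatialBasis.PER_LAKE,
            SpatialBasis.PER_STREAM_REACH,
            SpatialBasis.NONE,
        } <= bases
        times = {r.unit.time_basis for r in records}
        assert {
            TimeBasis.PER_YEAR,
            TimeBasis.PER_DAY,
            TimeBasis.PER_STUDY_PERIOD,
            TimeBasis.NONE,
        } <= times
        assert any(r.carbon_fraction is not None for r in records)

    def test_unreachable_basis_is_config_error(self):
        bad = SyntheticConfig(
            strata=[
                Stratum("s", Ecosystem.FOREST, Climate.TEMPERATE, FluxClass.GPP,
                        n=5, median=10.0, force_spatial_basis=SpatialBasis.PER_M_SHORELINE)
            ],
            seed=0,
        )
        with pytest.raises(ConfigError, match="unreachable"):
            generate_dataset(bad)


@pytest.fixture(scope="module")
def full_dataset():
    return generate_dataset(paper_like_config(seed=0))


class TestStudyConditions:
    def test_dataset_counts(self, full_dataset):
        records, _ = full_dataset
        spatial = [r for r in records if r.flux_class is FluxClass.SPATIAL_FLOW]
        assert len(records) == 3034
        assert len(spatial) == 518
        assert len(records) - len(spatial) == 2516

    def test_vocabulary_coverage(self, full_dataset):
        records, _ = full_dataset
        assert {r.ecosystem for r in records} == set(Ecosystem)
        assert {r.climate for r in records} == set(Climate)
        assert {r.flux_class for r in records} >= set(FluxClass) - {
            FluxClass.NPP,
            FluxClass.DECOMPOSITION_FLUX,
        }
        spatial = [r for r in records if r.flux_class is FluxClass.SPATIAL_FLOW]
        assert {r.driver for r in spatial} == set(Driver) - {Driver.NONE}
        assert {r.material_origin for r in spatial} == set(MaterialOrigin) - {
            MaterialOrigin.NONE
        }

    def test_spatial_flows_span_at_least_six_orders(self, full_dataset, config):
        records, _ = full_dataset
        harmonized = harmonize_table(records, config)
        flows = np.array(
            [r.value for r in harmonized if r.flux_class is FluxClass.SPATIAL_FLOW]
        )
        assert math.log10(flows.max() / flows.min()) >= 6.0

    def test_log_median_estimator_unbiased_over_replicates(self, config):
        """Monte-Carlo: mean log-median error within 5% at n = 200 per stratum."""
        targets = {Ecosystem.FOREST: (1379.5, 0.384), Ecosystem.GRASSLAND: (611.5, 0.8)}
        errors = {eco: [] for eco in targets}
        for rep in range(20):
            cfg = SyntheticConfig(
                strata=[
                    Stratum(f"gpp_{eco.value}", eco, Climate.TEMPERATE, FluxClass.GPP,
                            n=200, median=median, sigma_log=sigma)
                    for eco, (median, sigma) in targets.items()
                ],
                seed=500 + rep,
            )
            records, _ = generate_dataset(cfg)
            harmonized = harmonize_table(records, config)
            for eco, (median, _) in targets.items():
                vals = [r.value for r in harmonized if r.ecosystem is eco]
                errors[eco].append(math.log(np.median(vals) / median))
        for eco, errs in errors.items():
            assert abs(np.mean(errs)) < 0.05, eco

    def test_stream_heterotrophy_probability(self):
        """Stream NEP planted at -114.1 with IQR-derived sd gives p+ ~ 0.25-0.35."""
        from crossflux.metabolism import nep_ttest

        cfg = SyntheticConfig(
            strata=[
                Stratum("nep_stream", Ecosystem.STREAM, Climate.TEMPERATE,
                        FluxClass.NEP, n=20000, nep_mean=-114.1, nep_sd=281.4)
            ],
            seed=3,
        )
        records, _ = generate_dataset(cfg)
        harmonized = harmonize_table(records, default_config())
        res = nep_ttest([r.value for r in harmonized])
        assert 0.20 <= res.p_plus <= 0.35
        # around 25-35% probability of autotrophy = ~70% heterotrophy odds


class TestWorkedFixtures:
    def test_fixture_values_recompute(self, config):
        fixtures = make_worked_fixtures().set_index("name")["expected"]
        assert decomposition_flux(100.0, math.log(2), 1.0) == pytest.approx(
            fixtures["halflife_flux"], rel=1e-10
        )
        assert depth_from_discharge(32.0) == pytest.approx(fixtures["q32_depth"], rel=1e-10)
        assert depth_from_discharge(1.0) == pytest.approx(fixtures["q1_depth"], rel=1e-10)
        assert depth_from_discharge(catchment_area=0.5) == fixtures["small_catchment_depth"]
        assert lake_perimeter(math.pi, 1.0) == pytest.approx(
            fixtures["circle_perimeter"], rel=1e-12
        )
        perimeter = lake_perimeter(1e4, 1.0)
        assert perimeter == pytest.approx(fixtures["lake1e4_perimeter"], rel=1e-12)
        shoreline = flow_per_shoreline_lake(1.0, 1e4, perimeter)
        assert shoreline == pytest.approx(fixtures["lake1e4_shoreline"], rel=1e-12)
        assert distribute_on_band(shoreline, 10.0) == pytest.approx(
            fixtures["lake1e4_band10"], rel=1e-12
        )
        day_unit = UnitSpec(time_basis=TimeBasis.PER_DAY)
        assert annualize(1.0, day_unit, Climate.TEMPERATE, config)[0] == fixtures[
            "per_day_temperate"
        ]
        assert annualize(1.0, day_unit, Climate.TROPICAL, config)[0] == fixtures[
            "per_day_tropical"
        ]
        study_unit = UnitSpec(time_basis=TimeBasis.PER_STUDY_PERIOD, study_period_days=365)
        assert annualize(200.0, study_unit, Climate.TEMPERATE, config)[0] == fixtures[
            "study365_temperate"
        ]
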