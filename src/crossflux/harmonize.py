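"""Unit harmonization: raw measurements -> canonical areal carbon units.

Every record is converted to gC per m^2 of the recipient ecosystem per year
(gC m^-2 for detritus stocks, yr^-1 for decomposition rates) by composing, in
order:

1. carbon conversion — study-reported carbon content when available,
   otherwise the most specific (material class, mass basis) factor;
2. volume -> area — integration over the water-column depth (lake depth =
   volume / area; river depth = c * Q^f, 5 cm under 1 km^2 of catchment;
   pelagic photic depth, 100 m fallback);
3. shoreline re-expression — lateral aquatic-to-terrestrial flows routed
   through the donor-area / per-m-shoreline / recipient-band chain
   (see :mod:`crossflux.geometry`);
4. annualization — per-day values scaled by the climate's growing-season
   length; values measured over a study period shorter than the GSL scaled
   up to it, longer periods within a year left as annual.

All steps are multiplicative, so harmonization is linear in the raw value and
idempotent on already-canonical records.  Every applied step is appended to
the record's audit trail as (step, multiplier, rule), making each harmonized
value traceable back to its source: raw value x product(multipliers) equals
the output exactly.

Decomposition rates pass through with the time basis normalized only: a
carbon loss rate is taken to equal the loss rate in the mass basis provided
(the most parsimonious assumption), so no carbon factor is applied.
"""

from __future__ import annotations

import logging
from dataclasses import replace
from typing import Iterable, Optional, Sequence

import pandas as pd

from .config import Config
from .errors import ContractError, DomainError
from .geometry import (
    distribute_on_band,
    flow_per_shoreline_lake,
    flow_per_shoreline_stream,
    lake_perimeter,
)
from .records import (
    AQUATIC,
    TERRESTRIAL,
    AuditStep,
    Climate,
    Ecosystem,
    FluxClass,
    FluxRecord,
    MassBasis,
    MaterialClass,
    SpatialBasis,
    TimeBasis,
    UnitSpec,
)

logger = logging.getLogger("crossflux")

__all__ = [
    "convert_to_carbon",
    "annualize",
    "lake_mean_depth",
    "depth_from_discharge",
    "integrate_over_depth",
    "resolve_depth",
    "harmonize_record",
    "harmonize_table",
    "export_audit",
]


def convert_to_carbon(
    value: float,
    unit: UnitSpec,
    material_class: MaterialClass,
    config: Config,
    reported_fraction: Optional[float] = None,
) -> tuple[float, float, str]:
    """Convert a raw-mass value to gC; returns (value_gC, factor, rule).

    A study-reported carbon fraction takes precedence over the factor table;
    carbon-basis input is returned unchanged with factor 1.
    """
    if unit.mass_basis is MassBasis.CARBON:
        return value, 1.0, "already in carbon units"
    if reported_fraction is not None:
        if not 0 < reported_fraction <= 1:
            raise DomainError(
                f"reported carbon fraction must lie in (0, 1], got {reported_fraction}"
            )
        return (
            value * reported_fraction,
            reported_fraction,
            "study-reported carbon content",
        )
    factor = config.carbon_fraction_for(material_class, unit.mass_basis)
    rule = f"table factor ({material_class.value}, {unit.mass_basis.value})"
    return value * factor, factor, rule


def annualize(
    value: float, unit: UnitSpec, climate: Climate, config: Config
) -> tuple[float, float, str]:
    """Extrapolate a per-day or per-study-period value to the year.

    Per-day values are scaled by the climate's growing-season length (GSL).
    A study period shorter than the GSL is scaled up to the GSL; a period
    between the GSL and a year is taken as the annual value unchanged; a
    period longer than a year is scaled down to 365 days so totals are
    conserved.
    """
    tb = unit.time_basis
    if tb in (TimeBasis.PER_YEAR, TimeBasis.NONE):
        return value, 1.0, "already annual"
    gsl = config.gsl(climate)
    if tb is TimeBasis.PER_DAY:
        return value * gsl, gsl, f"per-day x GSL({climate.value}) = {gsl:g} d"
    # per_study_period
    d = unit.study_period_days
    if d is None or d <= 0:
        raise ContractError("per_study_period requires positive study_period_days")
    if d < gsl:
        factor = gsl / d
        rule = f"study period {d:g} d < GSL({climate.value}) = {gsl:g} d: scaled to GSL"
    elif d <= 365.0:
        factor = 1.0
        rule = f"study period {d:g} d >= GSL({climate.value}): no conversion"
    else:
        factor = 365.0 / d
        rule = f"study period {d:g} d > 365 d: scaled to one year"
    return value * factor, factor, rule


def lake_mean_depth(volume: float, area: float) -> float:
    """Mean lake depth (m) = volume (m^3) / area (m^2)."""
    if volume <= 0:
        raise DomainError(f"lake volume must be positive, got {volume}")
    if area <= 0:
        raise DomainError(f"lake area must be positive, got {area}")
    return volume / area


def depth_from_discharge(
    discharge: Optional[float] = None,
    catchment_area: Optional[float] = None,
    c: float = 0.2,
    f: float = 0.4,
) -> float:
    """River depth (m) from hydraulic geometry: depth = c * Q^f (c=0.2, f=0.4).

    Catchments under 1 km^2 take a 5 cm depth from known river scaling
    properties; at least one of discharge or catchment area is required.
    """
    if catchment_area is not None and catchment_area < 1.0:
        return 0.05
    if discharge is None:
        raise ContractError("either discharge or catchment_area is required")
    if discharge <= 0:
        raise DomainError(f"discharge must be positive, got {discharge}")
    return c * discharge**f


def integrate_over_depth(value: float, depth: float) -> float:
    """Integrate a per-m^3 value over the water column: value * depth (m)."""
    if depth <= 0:
        raise ContractError(f"integration depth must be positive, got {depth}")
    return value * depth


def resolve_depth(record: FluxRecord, config: Config) -> tuple[float, str]:
    """Water-column depth for a per-m^3 record, with the rule that produced it."""
    g = record.geometry
    eco = record.ecosystem
    if g is not None and g.mean_depth is not None:
        return g.mean_depth, "reported mean depth"
    if eco is Ecosystem.LAKE:
        if g is not None and g.lake_volume is not None and g.lake_area is not None:
            return (
                lake_mean_depth(g.lake_volume, g.lake_area),
                "lake depth = volume / area",
            )
        raise ContractError(
            f"record '{record.record_id}': lake per-m3 value needs mean_depth or "
            "lake_volume + lake_area"
        )
    if eco is Ecosystem.STREAM:
        if g is None or (g.discharge is None and g.catchment_area is None):
            raise ContractError(
                f"record '{record.record_id}': stream per-m3 value needs discharge "
                "or catchment_area"
            )
        if (
            g.catchment_area is not None
            and g.catchment_area < config.small_catchment_threshold_km2
        ):
            return (
                config.small_catchment_depth_m,
                f"small catchment (< {config.small_catchment_threshold_km2:g} km^2): "
                f"{100 * config.small_catchment_depth_m:g} cm depth",
            )
        depth = depth_from_discharge(
            g.discharge,
            g.catchment_area,
            c=config.depth_discharge_c,
            f=config.depth_discharge_f,
        )
        return depth, "river depth = c * Q^f"
    if eco in (Ecosystem.OCEAN_PELAGIC, Ecosystem.OCEAN_BENTHIC):
        if g is not None and g.photic_depth is not None:
            return g.photic_depth, "euphotic-zone depth"
        return (
            config.pelagic_default_depth_m,
            "sampling depths only: integrated to 100 m",
        )
    raise ContractError(
        f"record '{record.record_id}': per-m3 basis in non-aquatic ecosystem {eco.value}"
    )


def _lateral_band_steps(
    record: FluxRecord, value: float, config: Config
) -> tuple[float, list[AuditStep]]:
    """Route a lateral aquatic->terrestrial flow through the shoreline band."""
    steps: list[AuditStep] = []
    g = record.geometry
    donor = record.donor_ecosystem
    sb = record.unit.spatial_basis

    if sb in (SpatialBasis.PER_LAKE, SpatialBasis.PER_M2_DONOR) and donor is Ecosystem.LAKE:
        if g is None or g.lake_area is None:
            raise ContractError(
                f"record '{record.record_id}': lake donor-area flow needs lake_area"
            )
        if sb is SpatialBasis.PER_LAKE:
            value = value / g.lake_area
            steps.append(
                AuditStep("per_lake_to_donor_area", 1.0 / g.lake_area, "whole-lake total / lake area")
            )
        if g.lake_perimeter is not None:
            perimeter, prule = g.lake_perimeter, "measured perimeter"
        else:
            d_l = g.development_factor
            if d_l is None:
                d_l, prule = 1.0, "perimeter = 2*sqrt(area*pi), D_L assumed 1 (circular)"
            else:
                prule = f"perimeter = 2*D_L*sqrt(area*pi), D_L = {d_l:g}"
            perimeter = lake_perimeter(g.lake_area, d_l)
        new = flow_per_shoreline_lake(value, g.lake_area, perimeter)
        steps.append(
            AuditStep("lake_to_shoreline", g.lake_area / perimeter, prule)
        )
        value = new
    elif sb in (SpatialBasis.PER_STREAM_REACH, SpatialBasis.PER_M2_DONOR) and donor is Ecosystem.STREAM:
        if g is None or g.stream_width is None:
            raise ContractError(
                f"record '{record.record_id}': stream donor-area flow needs stream_width"
            )
        if sb is SpatialBasis.PER_STREAM_REACH:
            if g.reach_length is None:
                raise ContractError(
                    f"record '{record.record_id}': per_stream_reach needs reach_length"
                )
            denom = g.stream_width * g.reach_length
            value = value / denom
            steps.append(
                AuditStep("per_reach_to_donor_area", 1.0 / denom, "reach total / (width x length)")
            )
        value = flow_per_shoreline_stream(value, g.stream_width)
        steps.append(
            AuditStep("stream_to_shoreline", g.stream_width / 2.0, "x width / 2 (two riversides)")
        )
    elif sb is not SpatialBasis.PER_M_SHORELINE:
        raise ContractError(
            f"record '{record.record_id}': spatial basis {sb.value} with donor "
            f"{donor.value if donor else 'none'} has no shoreline path"
        )
    band = config.band_width_m
    value = distribute_on_band(value, band)
    steps.append(
        AuditStep(
            "distribute_on_band",
            1.0 / band,
            f"uniform distribution over first {band:g} m from shore",
        )
    )
    return value, steps


def _areal_steps(
    record: FluxRecord, value: float, config: Config
) -> tuple[float, list[AuditStep]]:
    sb = record.unit.spatial_basis
    if sb in (SpatialBasis.PER_M2_RECIPIENT, SpatialBasis.NONE):
        return value, []
    if sb is SpatialBasis.PER_M3:
        depth, rule = resolve_depth(record, config)
        return integrate_over_depth(value, depth), [
            AuditStep("integrate_over_depth", depth, rule)
        ]
    # shoreline / donor-area bases apply to spatial flows only
    if record.flux_class is not FluxClass.SPATIAL_FLOW:
        raise ContractError(
            f"record '{record.record_id}': spatial basis {sb.value} is only valid "
            "for spatial flows"
        )
    donor = record.donor_ecosystem
    lateral = donor in AQUATIC and record.ecosystem in TERRESTRIAL
    if lateral or sb in (
        SpatialBasis.PER_M_SHORELINE,
        SpatialBasis.PER_LAKE,
        SpatialBasis.PER_STREAM_REACH,
    ):
        return _lateral_band_steps(record, value, config)
    # vertical or terrestrial-donor flows: donor and recipient areas coincide
    return value, [
        AuditStep(
            "donor_area_equivalence",
            1.0,
            "donor and recipient areas equivalent for this flow",
        )
    ]


def harmonize_record(record: FluxRecord, config: Config) -> FluxRecord:
    """Return a copy of ``record`` in canonical units with an audit trail.

    Already-canonical records are returned unchanged (idempotence).  Errors in
    any step propagate with the record id in their message.
    """
    if record.is_harmonized:
        return record
    steps: list[AuditStep] = []
    value = record.value

    try:
        if record.flux_class is FluxClass.DECOMPOSITION_RATE:
            # time normalization only; no carbon conversion by construction
            value, factor, rule = annualize(value, record.unit, record.climate, config)
            if factor != 1.0:
                steps.append(AuditStep("annualize_rate", factor, rule))
            steps.append(
                AuditStep(
                    "rate_mass_basis",
                    1.0,
                    "loss rate taken as carbon loss rate in the basis provided",
                )
            )
            unit = replace(record.unit, time_basis=TimeBasis.PER_YEAR, study_period_days=None)
            return replace(record, value=value, unit=unit, audit=record.audit + tuple(steps))

        value, factor, rule = convert_to_carbon(
            value, record.unit, record.material_class, config, record.carbon_fraction
        )
        if record.unit.mass_basis is not MassBasis.CARBON:
            steps.append(AuditStep("convert_to_carbon", factor, rule))

        value, areal = _areal_steps(record, value, config)
        steps.extend(areal)

        if record.flux_class is not FluxClass.DETRITUS_STOCK:
            value, factor, rule = annualize(value, record.unit, record.climate, config)
            if factor != 1.0:
                steps.append(AuditStep("annualize", factor, rule))
            time_basis = TimeBasis.PER_YEAR
        else:
            time_basis = TimeBasis.NONE
    except (ContractError, DomainError) as exc:
        if record.record_id not in str(exc):
            raise type(exc)(f"record '{record.record_id}': {exc}") from exc
        raise

    unit = UnitSpec(
        mass_basis=MassBasis.CARBON,
        spatial_basis=SpatialBasis.PER_M2_RECIPIENT,
        time_basis=time_basis,
        study_period_days=None,
    )
    return replace(record, value=value, unit=unit, audit=record.audit + tuple(steps))


def harmonize_table(
    records: Iterable[FluxRecord], config: Config
) -> list[FluxRecord]:
    """Harmonize every record; errors carry the offending record id."""
    return [harmonize_record(r, config) for r in records]


def export_audit(records: Sequence[FluxRecord]) -> pd.DataFrame:
    """Long-format audit table: (record_id, step_index, step_name, multiplier, rule)."""
    rows = []
    for rec in records:
        for i, step in enumerate(rec.audit):
            rows.append(
                {
                    "record_id": rec.record_id,
                    "step_index": i,
                    "step_name": step.step,
                    "multiplier": step.multiplier,
                    "rule": step.rule,
                }
            )
    return pd.DataFrame(
        rows, columns=["record_id", "step_index", "step_name", "multiplier", "rule"]
    )
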