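"""Record schema, controlled vocabularies, and delimited-table I/O.

Every measurement in a compiled flux dataset is one :class:`FluxRecord`: a
single published value of a local carbon flux (GPP, ecosystem respiration,
NEP, secondary production, detritus stock, decomposition rate) or of a
cross-ecosystem spatial flow, together with the metadata needed to convert
it into the canonical unit gC m^-2 yr^-1 of the *recipient* ecosystem
(gC m^-2 for stocks, yr^-1 for decomposition rates).

Vocabularies are closed enums; free-text synonyms ("prairie", "meadow", ...)
must be mapped to the controlled tokens before ingestion.  The full column
dictionary for the delimited on-disk format is in ``docs/column_dictionary.md``.
"""

from __future__ import annotations

import enum
import json
import math
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Iterable, NamedTuple, Optional, Sequence

import pandas as pd

from .errors import ContractError, SchemaError, ValidationError

__all__ = [
    "Ecosystem",
    "Climate",
    "FluxClass",
    "MaterialOrigin",
    "MaterialClass",
    "Driver",
    "MassBasis",
    "SpatialBasis",
    "TimeBasis",
    "UnitSpec",
    "GeometrySpec",
    "AuditStep",
    "FluxRecord",
    "ReadResult",
    "read_flux_table",
    "write_harmonized",
    "records_to_frame",
    "frame_to_records",
    "TERRESTRIAL",
    "FRESHWATER",
    "MARINE",
    "AQUATIC",
    "PASSIVE_DRIVERS",
    "ACTIVE_DRIVERS",
    "COLD_CLIMATES",
    "WARM_CLIMATES",
    "domain_of",
    "interface_of",
    "climate_group",
]


class Ecosystem(str, enum.Enum):
    FOREST = "forest"
    GRASSLAND = "grassland"
    AGRO_ECOSYSTEM = "agro_ecosystem"
    DESERT = "desert"
    STREAM = "stream"
    LAKE = "lake"
    OCEAN_PELAGIC = "ocean_pelagic"
    OCEAN_BENTHIC = "ocean_benthic"


class Climate(str, enum.Enum):
    ARCTIC_ALPINE = "arctic_alpine"
    BOREAL = "boreal"
    TEMPERATE = "temperate"
    TROPICAL = "tropical"
    ARID = "arid"


class FluxClass(str, enum.Enum):
    GPP = "gpp"
    ECOSYSTEM_RESPIRATION = "ecosystem_respiration"
    NEP = "nep"
    NPP = "npp"
    SECONDARY_PRODUCTION = "secondary_production"
    DETRITUS_STOCK = "detritus_stock"
    DECOMPOSITION_RATE = "decomposition_rate"
    DECOMPOSITION_FLUX = "decomposition_flux"
    SPATIAL_FLOW = "spatial_flow"


class MaterialOrigin(str, enum.Enum):
    PRIMARY_PRODUCER = "primary_producer"
    INVERTEBRATE = "invertebrate"
    VERTEBRATE = "vertebrate"
    POC_DOC = "poc_doc"
    NONE = "none"


class MaterialClass(str, enum.Enum):
    """Material category used to pick a carbon-content conversion factor."""

    TERRESTRIAL_PLANT = "terrestrial_plant"
    MACROALGA = "macroalga"
    INVERTEBRATE = "invertebrate"
    VERTEBRATE = "vertebrate"
    MIXED_DETRITUS = "mixed_detritus"
    POC_DOC = "poc_doc"
    GENERIC = "generic"


class Driver(str, enum.Enum):
    FALL_WIND = "fall_wind"
    LEACHING = "leaching"
    CURRENT_TIDES = "current_tides"
    SINKING = "sinking"
    FORAGING = "foraging"
    MIGRATION = "migration"
    LIFE_CYCLE = "life_cycle"
    NONE = "none"


class MassBasis(str, enum.Enum):
    CARBON = "carbon"
    DRY_WEIGHT = "dry_weight"
    ASH_FREE_DRY_WEIGHT = "ash_free_dry_weight"
    WET_WEIGHT = "wet_weight"


class SpatialBasis(str, enum.Enum):
    PER_M2_RECIPIENT = "per_m2_recipient"
    PER_M2_DONOR = "per_m2_donor"
    PER_M3 = "per_m3"
    PER_M_SHORELINE = "per_m_shoreline"
    PER_LAKE = "per_lake"
    PER_STREAM_REACH = "per_stream_reach"
    NONE = "none"  # decomposition rates: the value carries a time dimension only


class TimeBasis(str, enum.Enum):
    PER_YEAR = "per_year"
    PER_DAY = "per_day"
    PER_STUDY_PERIOD = "per_study_period"
    NONE = "none"


TERRESTRIAL = frozenset(
    {Ecosystem.FOREST, Ecosystem.GRASSLAND, Ecosystem.AGRO_ECOSYSTEM, Ecosystem.DESERT}
)
FRESHWATER = frozenset({Ecosystem.STREAM, Ecosystem.LAKE})
MARINE = frozenset({Ecosystem.OCEAN_PELAGIC, Ecosystem.OCEAN_BENTHIC})
AQUATIC = FRESHWATER | MARINE

PASSIVE_DRIVERS = frozenset(
    {Driver.FALL_WIND, Driver.LEACHING, Driver.CURRENT_TIDES, Driver.SINKING}
)
ACTIVE_DRIVERS = frozenset({Driver.FORAGING, Driver.MIGRATION, Driver.LIFE_CYCLE})

# Marine records keep their source climate and are pooled into Cold/Warm only
# at summary time (large water volumes buffer the climate signal).
COLD_CLIMATES = frozenset({Climate.ARCTIC_ALPINE, Climate.BOREAL, Climate.TEMPERATE})
WARM_CLIMATES = frozenset({Climate.ARID, Climate.TROPICAL})


def domain_of(ecosystem: Ecosystem) -> str:
    """Broad domain label used for interface tabulations."""
    if ecosystem in TERRESTRIAL:
        return "terrestrial"
    if ecosystem in FRESHWATER:
        return "freshwater"
    if ecosystem is Ecosystem.OCEAN_PELAGIC:
        return "pelagic"
    return "benthic"


_DOMAIN_ORDER = ("terrestrial", "freshwater", "pelagic", "benthic")


def interface_of(donor: Ecosystem, recipient: Ecosystem) -> str:
    """Unordered donor/recipient interface label, e.g. ``terrestrial-freshwater``."""
    pair = sorted({domain_of(donor), domain_of(recipient)}, key=_DOMAIN_ORDER.index)
    return "-".join(pair) if len(pair) > 1 else f"{pair[0]}-{pair[0]}"


def climate_group(ecosystem: Ecosystem, climate: Climate) -> str:
    """Summary-time climate label: Cold/Warm for marine, the zone itself otherwise."""
    if ecosystem in MARINE:
        return "cold" if climate in COLD_CLIMATES else "warm"
    return climate.value


@dataclass(frozen=True)
class UnitSpec:
    """Mass, spatial, and time basis of a raw value; drives the harmonization path."""

    mass_basis: MassBasis = MassBasis.CARBON
    spatial_basis: SpatialBasis = SpatialBasis.PER_M2_RECIPIENT
    time_basis: TimeBasis = TimeBasis.PER_YEAR
    study_period_days: Optional[float] = None

    def validate(self) -> list[str]:
        problems = []
        if self.time_basis is TimeBasis.PER_STUDY_PERIOD:
            if self.study_period_days is None or self.study_period_days <= 0:
                problems.append(
                    "time_basis=per_study_period requires positive study_period_days"
                )
        return problems


@dataclass(frozen=True)
class GeometrySpec:
    """Waterbody / shoreline metadata needed for depth and band re-expression.

    All lengths in m, areas in m^2 (except catchment_area in km^2), volumes in
    m^3, discharge in m^3 s^-1.
    """

    lake_area: Optional[float] = None
    lake_volume: Optional[float] = None
    lake_perimeter: Optional[float] = None
    development_factor: Optional[float] = None  # D_L >= 1; 1 = circular
    mean_depth: Optional[float] = None
    stream_width: Optional[float] = None
    reach_length: Optional[float] = None
    discharge: Optional[float] = None
    catchment_area: Optional[float] = None
    photic_depth: Optional[float] = None

    def validate(self) -> list[str]:
        problems = []
        if self.development_factor is not None and self.development_factor < 1:
            problems.append("development_factor D_L must be >= 1")
        for name in (
            "lake_area",
            "lake_volume",
            "lake_perimeter",
            "mean_depth",
            "stream_width",
            "reach_length",
            "discharge",
            "catchment_area",
            "photic_depth",
        ):
            v = getattr(self, name)
            if v is not None and v <= 0:
                problems.append(f"{name} must be positive when given")
        return problems

    def is_empty(self) -> bool:
        return all(getattr(self, f.name) is None for f in fields(self))


class AuditStep(NamedTuple):
    """One multiplicative harmonization step: value_out = value_in * multiplier."""

    step: str
    multiplier: float
    rule: str


@dataclass
class FluxRecord:
    """One literature measurement with labels, raw value, unit, and provenance."""

    record_id: str
    study_id: str
    ecosystem: Ecosystem
    climate: Climate
    flux_class: FluxClass
    value: float
    unit: UnitSpec = field(default_factory=UnitSpec)
    material_origin: MaterialOrigin = MaterialOrigin.NONE
    material_class: MaterialClass = MaterialClass.GENERIC
    driver: Driver = Driver.NONE
    donor_ecosystem: Optional[Ecosystem] = None
    geometry: Optional[GeometrySpec] = None
    carbon_fraction: Optional[float] = None  # study-reported carbon content
    audit: tuple[AuditStep, ...] = ()

    @property
    def carbon_content_reported(self) -> bool:
        return self.carbon_fraction is not None

    def validate(self) -> list[str]:
        """Return a list of invariant violations (empty when valid)."""
        p: list[str] = []
        if self.flux_class is FluxClass.SPATIAL_FLOW:
            if self.donor_ecosystem is None:
                p.append("spatial_flow requires donor_ecosystem")
            if self.driver is Driver.NONE:
                p.append("spatial_flow requires a driver")
        else:
            if self.donor_ecosystem is not None:
                p.append("local fluxes must not carry donor_ecosystem")
            if self.driver is not Driver.NONE:
                p.append("local fluxes must not carry a driver")
        if self.flux_class is not FluxClass.NEP and self.value < 0:
            p.append(f"{self.flux_class.value} must be nonnegative")
        if not math.isfinite(self.value):
            p.append("value must be finite")
        if self.flux_class is FluxClass.DETRITUS_STOCK:
            if self.unit.time_basis is not TimeBasis.NONE:
                p.append("detritus_stock carries no time basis")
        elif self.unit.time_basis is TimeBasis.NONE:
            p.append(f"{self.flux_class.value} requires a time basis")
        if self.flux_class is FluxClass.DECOMPOSITION_RATE:
            if self.unit.spatial_basis is not SpatialBasis.NONE:
                p.append("decomposition_rate carries a time basis only (spatial_basis=none)")
        elif self.unit.spatial_basis is SpatialBasis.NONE:
            p.append("spatial_basis=none is reserved for decomposition_rate")
        if self.carbon_fraction is not None and not (0 < self.carbon_fraction <= 1):
            p.append("carbon_fraction must lie in (0, 1]")
        p.extend(self.unit.validate())
        if self.geometry is not None:
            p.extend(self.geometry.validate())
        return p

    @property
    def is_harmonized(self) -> bool:
        """True when the unit is canonical for this flux class."""
        u = self.unit
        if self.flux_class is FluxClass.DECOMPOSITION_RATE:
            return u.time_basis is TimeBasis.PER_YEAR and u.spatial_basis is SpatialBasis.NONE
        if self.flux_class is FluxClass.DETRITUS_STOCK:
            return (
                u.mass_basis is MassBasis.CARBON
                and u.spatial_basis is SpatialBasis.PER_M2_RECIPIENT
                and u.time_basis is TimeBasis.NONE
            )
        return (
            u.mass_basis is MassBasis.CARBON
            and u.spatial_basis is SpatialBasis.PER_M2_RECIPIENT
            and u.time_basis is TimeBasis.PER_YEAR
        )


class ReadResult(NamedTuple):
    records: list[FluxRecord]
    rejects: list[tuple[int, str]]  # (1-based data row number, reason)


# ---------------------------------------------------------------------------
# Delimited-table serialization

MANDATORY_COLUMNS = (
    "record_id",
    "ecosystem",
    "climate",
    "flux_class",
    "value",
    "mass_basis",
    "spatial_basis",
    "time_basis",
)

_GEOMETRY_COLUMNS = (
    "lake_area",
    "lake_volume",
    "lake_perimeter",
    "development_factor",
    "mean_depth",
    "stream_width",
    "reach_length",
    "discharge",
    "catchment_area",
    "photic_depth",
)

ALL_COLUMNS = MANDATORY_COLUMNS + (
    "study_id",
    "material_origin",
    "material_class",
    "driver",
    "donor_ecosystem",
    "study_period_days",
    "carbon_fraction",
) + _GEOMETRY_COLUMNS + ("audit",)


def _parse_enum(enum_cls, token, column, default=None):
    if token is None or (isinstance(token, float) and math.isnan(token)) or token == "":
        if default is not None:
            return default
        raise ValueError(f"missing value in column '{column}'")
    try:
        return enum_cls(str(token).strip().lower())
    except ValueError:
        valid = ", ".join(m.value for m in enum_cls)
        raise ValueError(
            f"unknown token '{token}' in column '{column}' (expected one of: {valid})"
        ) from None


def _opt_float(x):
    if x is None or x == "":
        return None
    x = float(x)
    return None if math.isnan(x) else x


def _row_to_record(row: dict) -> FluxRecord:
    unit = UnitSpec(
        mass_basis=_parse_enum(MassBasis, row.get("mass_basis"), "mass_basis"),
        spatial_basis=_parse_enum(SpatialBasis, row.get("spatial_basis"), "spatial_basis"),
        time_basis=_parse_enum(TimeBasis, row.get("time_basis"), "time_basis"),
        study_period_days=_opt_float(row.get("study_period_days")),
    )
    geom_kwargs = {c: _opt_float(row.get(c)) for c in _GEOMETRY_COLUMNS}
    geometry = None
    if any(v is not None for v in geom_kwargs.values()):
        geometry = GeometrySpec(**geom_kwargs)
    donor_tok = row.get("donor_ecosystem")
    donor = None
    if donor_tok not in (None, "") and not (
        isinstance(donor_tok, float) and math.isnan(donor_tok)
    ):
        if str(donor_tok).strip().lower() != "none":
            donor = _parse_enum(Ecosystem, donor_tok, "donor_ecosystem")
    audit_raw = row.get("audit")
    audit: tuple[AuditStep, ...] = ()
    if isinstance(audit_raw, str) and audit_raw.strip():
        audit = tuple(AuditStep(*entry) for entry in json.loads(audit_raw))
    value = row.get("value")
    if value is None or value == "" or (isinstance(value, float) and math.isnan(value)):
        raise ValueError("missing value in column 'value'")
    return FluxRecord(
        record_id=str(row["record_id"]),
        study_id=str(row.get("study_id") or ""),
        ecosystem=_parse_enum(Ecosystem, row.get("ecosystem"), "ecosystem"),
        climate=_parse_enum(Climate, row.get("climate"), "climate"),
        flux_class=_parse_enum(FluxClass, row.get("flux_class"), "flux_class"),
        value=float(value),
        unit=unit,
        material_origin=_parse_enum(
            MaterialOrigin, row.get("material_origin"), "material_origin", MaterialOrigin.NONE
        ),
        material_class=_parse_enum(
            MaterialClass, row.get("material_class"), "material_class", MaterialClass.GENERIC
        ),
        driver=_parse_enum(Driver, row.get("driver"), "driver", Driver.NONE),
        donor_ecosystem=donor,
        geometry=geometry,
        carbon_fraction=_opt_float(row.get("carbon_fraction")),
        audit=audit,
    )


def read_flux_table(path, strict: bool = True) -> ReadResult:
    """Read and validate a delimited flux table (comma default, tab accepted).

    In strict mode any invalid row raises :class:`ValidationError` with row
    context; in non-strict mode invalid rows are skipped and reported in
    ``rejects`` as (data row number, reason) pairs.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"table {path} is missing mandatory column(s): {', '.join(missing)}")
    records: list[FluxRecord] = []
    rejects: list[tuple[int, str]] = []
    for i, row in enumerate(df.to_dict(orient="records"), start=1):
        try:
            rec = _row_to_record(row)
            problems = rec.validate()
            if problems:
                raise ValueError("; ".join(problems))
        except (ValueError, KeyError) as exc:
            if strict:
                raise ValidationError(f"row {i}: {exc}") from exc
            rejects.append((i, str(exc)))
            continue
        records.append(rec)
    return ReadResult(records, rejects)


def _record_to_row(rec: FluxRecord) -> dict:
    row = {
        "record_id": rec.record_id,
        "study_id": rec.study_id,
        "ecosystem": rec.ecosystem.value,
        "climate": rec.climate.value,
        "flux_class": rec.flux_class.value,
        "value": rec.value,
        "mass_basis": rec.unit.mass_basis.value,
        "spatial_basis": rec.unit.spatial_basis.value,
        "time_basis": rec.unit.time_basis.value,
        "study_period_days": rec.unit.study_period_days,
        "material_origin": rec.material_origin.value,
        "material_class": rec.material_class.value,
        "driver": rec.driver.value,
        "donor_ecosystem": rec.donor_ecosystem.value if rec.donor_ecosystem else "",
        "carbon_fraction": rec.carbon_fraction,
    }
    for c in _GEOMETRY_COLUMNS:
        row[c] = getattr(rec.geometry, c) if rec.geometry is not None else None
    row["audit"] = json.dumps([list(s) for s in rec.audit]) if rec.audit else ""
    return row


def records_to_frame(records: Iterable[FluxRecord]) -> pd.DataFrame:
    """Tabular view of records (one row per record, full column dictionary)."""
    rows = [_record_to_row(r) for r in records]
    return pd.DataFrame(rows, columns=list(ALL_COLUMNS))


def frame_to_records(df: pd.DataFrame) -> list[FluxRecord]:
    return [_row_to_record(row) for row in df.to_dict(orient="records")]


def write_harmonized(records: Sequence[FluxRecord], path) -> None:
    """Write harmonized records so that :func:`read_flux_table` round-trips losslessly.

    Raises :class:`ContractError` naming the first unharmonized record.
    """
    for rec in records:
        if not rec.is_harmonized:
            raise ContractError(
                f"record '{rec.record_id}' is not harmonized (unit {rec.unit})"
            )
    df = records_to_frame(records)
    # %.17g guarantees float round-trip through text
    df.to_csv(path, index=False, float_format="%.17g")
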