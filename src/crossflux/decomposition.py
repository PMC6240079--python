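"""Exponential litter-decay model: rate constants and decomposition fluxes.

Detrital mass decays as D_t = D_t0 * exp(-k (t - t0)) with first-order rate
constant k (yr^-1).  Over a horizon t, a detritus stock D_M (gC m^-2) yields
the decomposition flux

    D_F = D_M * (1 - exp(-k t)),

the carbon transferred from the detritus pool to bacteria and other
detritivores.  When a study reports detritus production D_P and the flux
rather than the rate, k is recovered from

    D_F = (D_P - E) * (1 - exp(-k t)),

with E the detritus export (set to 0 when unknown, which underestimates k —
conservative, since pelagic rates, where this mostly applies, already sit at
the high end of the range).

Stratum-level fluxes: within each ecosystem x climatic-zone combination, the
stock D_M is parameterized as the median of all harmonized detritus stocks
and every literature decomposition rate in the stratum yields one derived
flux via the decay formula with t = 1 yr (the annual canonical unit fixes
the horizon).
"""

from __future__ import annotations

import logging
import math
import statistics
from typing import Iterable, Sequence

from .errors import DomainError, InfiniteRateError
from .records import (
    AuditStep,
    FluxClass,
    FluxRecord,
    MassBasis,
    SpatialBasis,
    TimeBasis,
    UnitSpec,
)

logger = logging.getLogger("crossflux")

__all__ = [
    "decomposition_flux",
    "k_from_massloss",
    "k_from_production",
    "stratum_decomposition_fluxes",
]


def decomposition_flux(d_m: float, k: float, t: float = 1.0) -> float:
    """D_F = D_M * (1 - exp(-k t)); bounded in [0, D_M)."""
    if d_m < 0:
        raise DomainError(f"detritus stock must be nonnegative, got {d_m}")
    if k < 0:
        raise DomainError(f"decay rate must be nonnegative, got {k}")
    if t <= 0:
        raise DomainError(f"time horizon must be positive, got {t}")
    return d_m * -math.expm1(-k * t)


def k_from_massloss(d_t0: float, d_t: float, t: float) -> float:
    """Rate constant from a two-point litter-bag mass loss: k = -ln(D_t/D_t0)/t."""
    if t <= 0:
        raise DomainError(f"duration must be positive, got {t}")
    if d_t0 <= 0:
        raise DomainError(f"initial detrital mass must be positive, got {d_t0}")
    if d_t < 0:
        raise DomainError(f"remaining detrital mass must be nonnegative, got {d_t}")
    if d_t == 0:
        raise InfiniteRateError(
            "complete mass loss: decay rate is unbounded (flag, not a number)"
        )
    if d_t > d_t0:
        raise DomainError(
            f"mass gain (D_t = {d_t} > D_t0 = {d_t0}) is outside the decay model"
        )
    return -math.log(d_t / d_t0) / t


def k_from_production(d_p: float, e: float, d_f: float, t: float = 1.0) -> float:
    """Rate constant from production/flux balance: D_F = (D_P - E)(1 - exp(-kt))."""
    if t <= 0:
        raise DomainError(f"duration must be positive, got {t}")
    if d_f < 0:
        raise DomainError(f"decomposition flux must be nonnegative, got {d_f}")
    if not 0 <= e <= d_p:
        raise DomainError(f"export E = {e} must lie in [0, D_P = {d_p}]")
    available = d_p - e
    if d_f >= available:
        raise DomainError(
            f"decomposition flux D_F = {d_f} must be < available production "
            f"D_P - E = {available}"
        )
    return -math.log1p(-d_f / available) / t


def stratum_decomposition_fluxes(
    records: Iterable[FluxRecord], t: float = 1.0
) -> list[FluxRecord]:
    """Derive one decomposition-flux record per (stratum, rate measurement).

    ``records`` must be harmonized and contain detritus_stock (gC m^-2) and
    decomposition_rate (yr^-1) records; strata are ecosystem x climatic zone.
    Strata with rates but no stocks are skipped with a warning.  Derived
    records carry provenance linking the stock median and the source rate.
    """
    stocks: dict[tuple, list[float]] = {}
    rates: dict[tuple, list[FluxRecord]] = {}
    for rec in records:
        key = (rec.ecosystem, rec.climate)
        if rec.flux_class is FluxClass.DETRITUS_STOCK:
            stocks.setdefault(key, []).append(rec.value)
        elif rec.flux_class is FluxClass.DECOMPOSITION_RATE:
            rates.setdefault(key, []).append(rec)

    derived: list[FluxRecord] = []
    for key, rate_recs in sorted(rates.items(), key=lambda kv: (kv[0][0].value, kv[0][1].value)):
        if key not in stocks:
            logger.warning(
                "stratum (%s, %s) has %d decomposition rates but no detritus "
                "stocks: skipped",
                key[0].value,
                key[1].value,
                len(rate_recs),
            )
            continue
        stock_values = stocks[key]
        d_m = statistics.median(stock_values)  # midpoint of middle two for even n
        for rate_rec in rate_recs:
            flux = decomposition_flux(d_m, rate_rec.value, t)
            derived.append(
                FluxRecord(
                    record_id=f"df_{rate_rec.record_id}",
                    study_id=rate_rec.study_id,
                    ecosystem=rate_rec.ecosystem,
                    climate=rate_rec.climate,
                    flux_class=FluxClass.DECOMPOSITION_FLUX,
                    value=flux,
                    unit=UnitSpec(
                        MassBasis.CARBON,
                        SpatialBasis.PER_M2_RECIPIENT,
                        TimeBasis.PER_YEAR,
                    ),
                    audit=(
                        AuditStep(
                            "eq_decay_flux",
                            flux / rate_rec.value if rate_rec.value else 0.0,
                            f"D_F = D_M(1-exp(-kt)); D_M = median of "
                            f"{len(stock_values)} stocks = {d_m:g} gC m^-2, "
                            f"k = {rate_rec.value:g} yr^-1 from record "
                            f"'{rate_rec.record_id}', t = {t:g} yr",
                        ),
                    ),
                )
            )
    return derived
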