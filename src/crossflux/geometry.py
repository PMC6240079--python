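"""Shoreline geometry: re-expressing lateral aquatic-to-terrestrial flows.

Flows measured per m^2 of the *donor* waterbody (e.g. emerging insects per
m^2 of lake) cannot be compared directly with fluxes per m^2 of the
*recipient* terrestrial ecosystem: the areal magnitude on land depends on the
donor's total productive surface and on the boundary length through which the
flow crosses.  The re-expression runs donor-area -> per-m-shoreline ->
per-m^2 of a uniform recipient band along the shore (10 m by default):

* lakes: flow/m shoreline = flow/m^2 lake x area / perimeter, the perimeter
  approximated by 2 * D_L * sqrt(area * pi) when not measured, with D_L the
  shoreline development factor (1 = circular);
* streams: flow/m shoreline = flow/m^2 stream x width / 2 (two riversides);
* band: flow/m^2 recipient = flow/m shoreline / band width.

The composition conserves carbon exactly: per-band flow x perimeter x band
width equals per-donor-m^2 flow x donor area.
"""

from __future__ import annotations

import math

from .errors import ContractError, DomainError

__all__ = [
    "lake_perimeter",
    "flow_per_shoreline_lake",
    "flow_per_shoreline_stream",
    "distribute_on_band",
]


def lake_perimeter(area: float, development_factor: float = 1.0) -> float:
    """Perimeter (m) of a lake of given area (m^2): 2 * D_L * sqrt(area * pi).

    D_L = 1 gives exactly the circumference of the circle of that area; a
    measured perimeter, when available, should be used instead of this
    approximation.
    """
    if area <= 0:
        raise DomainError(f"lake area must be positive, got {area}")
    if development_factor < 1:
        raise DomainError(
            f"development factor D_L must be >= 1, got {development_factor}"
        )
    return 2.0 * development_factor * math.sqrt(area * math.pi)


def flow_per_shoreline_lake(flow: float, area: float, perimeter: float) -> float:
    """gC per m shoreline per yr from a flow per m^2 of lake: flow * area / perimeter."""
    if area <= 0:
        raise DomainError(f"lake area must be positive, got {area}")
    if perimeter <= 0:
        raise DomainError(f"lake perimeter must be positive, got {perimeter}")
    return flow * area / perimeter


def flow_per_shoreline_stream(flow: float, width: float) -> float:
    """gC per m shoreline per yr from a flow per m^2 of stream: flow * width / 2."""
    if width is None:
        raise ContractError("stream width is required to re-express a donor-area flow")
    if width <= 0:
        raise ContractError(f"stream width must be positive, got {width}")
    return flow * width / 2.0


def distribute_on_band(flow: float, band_width: float) -> float:
    """gC per m^2 of recipient band from a per-m-shoreline flow: flow / band width."""
    if band_width <= 0:
        raise DomainError(f"band width must be positive, got {band_width}")
    return flow / band_width
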