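"""Lipoprotein metabolism indicators: ratios of modeled process fluxes.

Each indicator is a dimensionless ratio of process fluxes (or a rate
constant over a flux) aggregated in one of three diameter ranges
(VLDL through LDL, VLDL only, IDL through LDL).  Because the kinetic fit
is identifiable only up to a joint rescaling of production and rate
constants, every indicator is invariant under that rescaling; indicators
are therefore comparable between subjects even though absolute fluxes are
not.

The two named indicators selected as risk markers:

* ``VLDL_E`` (extrahepatic lipolysis): LPL lipolysis flux in the VLDL
  range divided by the particle influx into that range (production plus
  lipolysis of larger particles).  Lower values mean incoming VLDL is
  lipolysed more slowly in peripheral tissue.
* ``VLDL_H`` (hepatic turnover): the average of (i) the mean HL rate
  constant over VLDL divided by the VLDL production flux and (ii) the
  liver attachment flux over VLDL divided by the VLDL production flux.
  Lower values mean less hepatic VLDL processing per produced particle.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Dict, Tuple

from .errors import UndefinedIndicatorError
from .kinetics import (
    DEFAULT_SHAPES,
    KineticParameters,
    LipaseShapes,
    ParticleProfile,
    ProcessFluxes,
    PROCESS_NAMES,
    RANGE_NAMES,
    process_fluxes,
    steady_state_concentrations,
)

__all__ = [
    "IndicatorSet",
    "vldl_extrahepatic_lipolysis_indicator",
    "vldl_hepatic_turnover_indicator",
    "indicator_matrix",
    "indicator_column_names",
]


def vldl_extrahepatic_lipolysis_indicator(fluxes: ProcessFluxes) -> float:
    """VLDL_E = F_LPL(VLDL) / influx(VLDL).

    ``fluxes`` must be aggregated over the VLDL-only range.  Raises
    :class:`UndefinedIndicatorError` when the influx is zero.
    """
    influx = fluxes.influx
    if influx <= 0:
        raise UndefinedIndicatorError("zero particle influx into the VLDL range")
    return fluxes.lpl_lipolysis / influx


def vldl_hepatic_turnover_indicator(fluxes: ProcessFluxes) -> float:
    """VLDL_H = 1/2 * (mean_HL_rate(VLDL)/F_prod(VLDL) + F_att(VLDL)/F_prod(VLDL)).

    Raises :class:`UndefinedIndicatorError` when the VLDL production flux
    is zero.
    """
    if fluxes.production <= 0:
        raise UndefinedIndicatorError("zero VLDL production flux")
    return 0.5 * (
        fluxes.mean_hl_rate_constant / fluxes.production
        + fluxes.attachment / fluxes.production
    )


#: Canonical orientation of the 15 unordered process pairs.
PROCESS_PAIRS: Tuple[Tuple[str, str], ...] = tuple(
    itertools.combinations(PROCESS_NAMES, 2)
)


def _pair_column(range_name: str, num: str, den: str) -> str:
    return f"{range_name}__{num}_over_{den}"


def indicator_column_names() -> Tuple[str, ...]:
    """Column names of the full indicator matrix: vldl_e, vldl_h, then the
    45 pair ratios named range__processA_over_processB."""
    cols = ["vldl_e", "vldl_h"]
    for range_name in RANGE_NAMES:
        for a, b in PROCESS_PAIRS:
            cols.append(_pair_column(range_name, a, b))
    return tuple(cols)


@dataclass(frozen=True)
class IndicatorSet:
    """All pairwise process-flux ratios per range plus the two named
    VLDL indicators.  Undefined ratios (zero denominator) are stored as
    NaN, never imputed."""

    ratios: Dict[Tuple[str, str, str], float]
    vldl_e: float
    vldl_h: float

    def ratio(self, range_name: str, num: str, den: str) -> float:
        """Ratio of two process fluxes in a range; either orientation of a
        stored pair is available (reciprocal of the canonical one)."""
        key = (range_name, num, den)
        if key in self.ratios:
            return self.ratios[key]
        flipped = self.ratios.get((range_name, den, num))
        if flipped is None:
            raise KeyError(f"unknown ratio {key}")
        if math.isnan(flipped):
            return float("nan")
        if flipped == 0.0:
            return float("nan")  # reciprocal of zero: undefined
        return 1.0 / flipped

    def as_row(self) -> Dict[str, float]:
        row = {"vldl_e": self.vldl_e, "vldl_h": self.vldl_h}
        for range_name in RANGE_NAMES:
            for a, b in PROCESS_PAIRS:
                row[_pair_column(range_name, a, b)] = self.ratios[(range_name, a, b)]
        return row


def indicator_matrix(
    params: KineticParameters,
    profile: ParticleProfile | None = None,
    grid=None,
    shapes: LipaseShapes = DEFAULT_SHAPES,
) -> IndicatorSet:
    """Compute the full indicator set from fitted kinetic parameters.

    ``profile`` defaults to the steady-state profile implied by ``params``
    on ``grid`` (the appropriate choice for fitted parameters).  Ratios
    with zero denominator are NaN; the subject is retained with per-ratio
    missingness.  The two named indicators are NaN when their own
    denominator vanishes.
    """
    if profile is None:
        if grid is None:
            raise ValueError("pass either a steady-state profile or a grid")
        profile = steady_state_concentrations(params, grid, shapes)
    ratios: Dict[Tuple[str, str, str], float] = {}
    fluxes_by_range = {
        r: process_fluxes(params, profile, r, shapes) for r in RANGE_NAMES
    }
    for range_name, fx in fluxes_by_range.items():
        flux = fx.by_process()
        for a, b in PROCESS_PAIRS:
            den = flux[b]
            ratios[(range_name, a, b)] = flux[a] / den if den > 0 else float("nan")
    vldl = fluxes_by_range["VLDL_only"]
    try:
        vldl_e = vldl_extrahepatic_lipolysis_indicator(vldl)
    except UndefinedIndicatorError:
        vldl_e = float("nan")
    try:
        vldl_h = vldl_hepatic_turnover_indicator(vldl)
    except UndefinedIndicatorError:
        vldl_h = float("nan")
    return IndicatorSet(ratios=ratios, vldl_e=vldl_e, vldl_h=vldl_h)
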