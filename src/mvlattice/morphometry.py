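"""Population statistics and error-propagated derived quantities.

Two kinds of numbers come out of the pipeline: per-field population
statistics (microvillus density, mean height / LDV / radius bounds)
and a short chain of derived arithmetic that turns the radius-bound
model into a mean microvillar diameter and the smallest
intermicrovillar spacing:

* the bounds (r_min, r_max) are doubled into diameter bounds;
* their midpoint, rounded by the significant-figure convention, is the
  mean diameter;
* subtracting the diameter from a lattice constant gives the smallest
  surface-to-surface distance between neighboring microvilli.

All derived values follow one rounding convention, implemented in
:func:`round_to_error_sigfig`: the SD is rounded to one significant
figure and the central value is rounded half-up to the same decimal
place.  Half-up (not banker's) rounding matters: 105 with SD 70 prints
as 110 ± 70.
"""

from __future__ import annotations

import dataclasses
import math
from typing import List, Optional, Sequence

import numpy as np
from scipy import stats

from .detect import MicrovillusDetection

__all__ = [
    "QuantityWithError",
    "PopulationStats",
    "population_stats",
    "round_to_error_sigfig",
    "diameter_from_bounds",
    "smallest_distance",
    "density_ttest",
]


@dataclasses.dataclass(frozen=True)
class QuantityWithError:
    """value ± 1 SD in stated units."""

    value: float
    sd: float = 0.0
    units: str = "nm"
    flag: str = ""

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("sd must be >= 0")

    def __str__(self) -> str:
        return f"{self.value:g} ± {self.sd:g} {self.units}"


def _round_half_up(x: float, decimals: int) -> float:
    """Decimal round-half-up (105 → 110 at the tens digit)."""
    factor = 10.0 ** decimals
    return math.floor(x * factor + 0.5) / factor


def round_to_error_sigfig(q: QuantityWithError) -> QuantityWithError:
    """Round to significant digits dictated by the uncertainty.

    The SD is rounded to one significant figure; the central value is
    rounded half-up to the decimal place of that rounded SD.  A zero SD
    leaves the value untouched.
    """
    if q.sd == 0:
        return q
    exponent = math.floor(math.log10(abs(q.sd)))
    sd_rounded = _round_half_up(q.sd, -exponent)
    # rounding can promote the SD to the next decade (e.g. 0.96 -> 1)
    exponent = math.floor(math.log10(abs(sd_rounded)))
    value = _round_half_up(q.value, -exponent)
    return QuantityWithError(value=value, sd=sd_rounded, units=q.units,
                             flag=q.flag)


def diameter_from_bounds(r_min: QuantityWithError,
                         r_max: QuantityWithError) -> QuantityWithError:
    """Mean microvillar diameter from the two radius bounds.

    Doubles each radius bound into a diameter bound, rounds each bound
    by the significant-figure convention, and returns their midpoint,
    itself rounded per convention.  For the bounds 18 ± 2 and 63 ± 5 nm
    this chain gives diameter bounds 36 ± 4 and 130 ± 10 nm and a mean
    diameter of 80 nm.

    The reported SD is a convention, not a derivable quantity: the
    larger of half the bound range and the quadrature sum of the bound
    SDs, rounded to one significant figure.
    """
    if not r_min.value < r_max.value:
        raise ValueError(f"crossed radius bounds: r_min={r_min.value} "
                         f">= r_max={r_max.value}")
    d_lo = round_to_error_sigfig(
        QuantityWithError(2 * r_min.value, 2 * r_min.sd, r_min.units))
    d_hi = round_to_error_sigfig(
        QuantityWithError(2 * r_max.value, 2 * r_max.sd, r_max.units))
    mid = 0.5 * (d_lo.value + d_hi.value)
    half_range = 0.5 * (d_hi.value - d_lo.value)
    quad = math.hypot(d_lo.sd, d_hi.sd) / 2.0
    sd = max(half_range, quad)
    return round_to_error_sigfig(
        QuantityWithError(mid, sd, units=r_min.units))


def smallest_distance(lattice_constant: QuantityWithError,
                      diameter: QuantityWithError) -> QuantityWithError:
    """Smallest intermicrovillar (surface-to-surface) distance.

    Lattice constant minus diameter, SDs combined in quadrature, both
    rounded by the significant-figure convention.  A negative central
    value (overlapping microvilli) is allowed but flagged.
    """
    value = lattice_constant.value - diameter.value
    sd = math.hypot(lattice_constant.sd, diameter.sd)
    flag = "negative" if value < 0 else ""
    return round_to_error_sigfig(
        QuantityWithError(value, sd, units=lattice_constant.units, flag=flag))


# ---------------------------------------------------------------------------
# population statistics
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class PopulationStats:
    """Per-ROI summary of a detection population.

    ``n`` counts all detections in the ROI (density = n / area);
    ``n_measured`` counts the unflagged, fully measured interior
    objects that enter the shape statistics.  With fewer than two
    measured objects the SDs are missing rather than zero.
    """

    n: int
    n_measured: int
    density_per_um2: float
    height: Optional[QuantityWithError]
    ldv: Optional[QuantityWithError]
    r_min: Optional[QuantityWithError]
    r_max: Optional[QuantityWithError]


def _mean_sd(values: Sequence[float], units: str) -> Optional[QuantityWithError]:
    vals = [v for v in values if v is not None and np.isfinite(v)]
    if not vals:
        return None
    mean = float(np.mean(vals))
    sd = float(np.std(vals, ddof=1)) if len(vals) >= 2 else float("nan")
    return QuantityWithError(mean, sd if np.isfinite(sd) else 0.0, units,
                             flag="" if len(vals) >= 2 else "n<2")


def population_stats(detections: Sequence[MicrovillusDetection],
                     roi_area_um2: float) -> PopulationStats:
    """Summarise one ROI's detections.

    Density counts every detected tip in the ROI; morphometric means
    and SDs use only unflagged (interior, fully measured) detections,
    whose radius discs do not cross the ROI border.
    """
    if not roi_area_um2 > 0:
        raise ValueError("ROI area must be > 0")
    n = len(detections)
    clean = [d for d in detections if not d.flag]
    density = n / roi_area_um2
    return PopulationStats(
        n=n,
        n_measured=len(clean),
        density_per_um2=density,
        height=_mean_sd([d.height_nm for d in clean], "nm"),
        ldv=_mean_sd([d.ldv_nm3 for d in clean], "nm3"),
        r_min=_mean_sd([d.r_min_nm for d in clean], "nm"),
        r_max=_mean_sd([d.r_max_nm for d in clean], "nm"),
    )


def density_ttest(densities_a: Sequence[float],
                  densities_b: Sequence[float]):
    """Two-sample Student's t-test between per-image density samples.

    Used to compare microvillar densities between lattice classes
    (e.g. rhombic vs hexagonal fields).  Returns the scipy result
    object with ``statistic`` and ``pvalue``.
    """
    return stats.ttest_ind(list(densities_a), list(densities_b))
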