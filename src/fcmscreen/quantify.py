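"""Semi-quantification, calibration, and system-suitability statistics.

Screening concentrations are *semi-quantitative*: the detector response of
the spiked internal standards (area counts per ng/mL) stands in for every
unknown's response, ignoring compound-specific ionization differences by
construction.  Confirmed compounds are quantified properly against a
standard calibration curve (area ratio vs concentration, ordinary least
squares).  Extract concentrations convert to migration per kg of food via
the extract volume, the extracted film area, and the conventional
6 dm2/kg food-contact surface ratio.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .msdata import ElementalFormula, monoisotopic_mass, ppm_error

__all__ = [
    "InternalStandard",
    "ExtractGeometry",
    "QuantResult",
    "average_response_factor",
    "estimate_concentration",
    "concentration_to_migration",
    "quantify_area",
    "calibrate_and_quantify",
    "system_suitability",
]

NG_PER_ML_TO_MG_PER_ML = 1e-6


@dataclass
class InternalStandard:
    """A spiked internal standard and its per-replicate measurements.

    ``areas`` aligns with ``rts`` and ``observed_mzs`` by replicate.  The
    monitored ion's theoretical m/z defaults to the radical-cation mass of
    the formula when not given explicitly (isotope-labelled standards parse
    with D / [13C] tokens).
    """

    name: str
    spiked_conc: float = 200.0  # ng/mL
    cas: Optional[str] = None
    formula: Optional[ElementalFormula] = None
    areas: list[float] = field(default_factory=list)
    rts: list[float] = field(default_factory=list)
    observed_mzs: list[float] = field(default_factory=list)
    theoretical_mz: Optional[float] = None

    def __post_init__(self) -> None:
        if self.spiked_conc <= 0:
            raise ValueError(f"{self.name}: spiked concentration must be positive")
        if self.theoretical_mz is None and self.formula is not None:
            self.theoretical_mz = monoisotopic_mass(self.formula, as_radical_cation=True)


@dataclass(frozen=True)
class ExtractGeometry:
    """Film/extract geometry for the migration conversion.

    Defaults: a 5 cm x 5 cm film portion (0.25 dm2) extracted into a final
    volume of 1 mL, with the conventional 6 dm2 of packaging surface per kg
    of food.
    """

    film_area: float = 0.25  # dm2
    extract_volume: float = 1.0  # mL
    food_contact_ratio: float = 6.0  # dm2 per kg food

    def __post_init__(self) -> None:
        if min(self.film_area, self.extract_volume, self.food_contact_ratio) <= 0:
            raise ValueError("all geometry parameters must be positive")


@dataclass
class QuantResult:
    compound: str
    est_conc: float  # ng/mL in the extract
    migration: float  # mg per kg food
    method: str  # response_factor | calibration
    uncertainty: Optional[float] = None
    extrapolated: bool = False

    def __post_init__(self) -> None:
        if self.migration < 0:
            raise ValueError("migration cannot be negative")
        if self.method not in ("response_factor", "calibration"):
            raise ValueError(f"unknown quantification method {self.method!r}")


def average_response_factor(standards: Sequence[InternalStandard]) -> float:
    """Mean area-per-concentration ratio over all standards and replicates."""
    ratios = [
        area / std.spiked_conc for std in standards for area in std.areas
    ]
    if not ratios:
        raise ValueError("no internal-standard areas to average")
    return float(np.mean(ratios))


def estimate_concentration(area: float, rf: float) -> float:
    """Concentration (ng/mL) = peak area / average response factor."""
    if rf <= 0:
        raise ValueError(f"response factor must be positive, got {rf}")
    if area < 0:
        raise ValueError("area cannot be negative")
    return area / rf


def concentration_to_migration(conc_mg_per_ml: float, geom: ExtractGeometry = ExtractGeometry()) -> float:
    """Migration (mg/kg food) from extract concentration (mg/mL).

    mg/kg = conc * extract_volume / film_area * food_contact_ratio —
    the mass in the extract, per dm2 of film, times the dm2 contacting one
    kg of food.
    """
    if conc_mg_per_ml < 0:
        raise ValueError("concentration cannot be negative")
    return conc_mg_per_ml * geom.extract_volume / geom.film_area * geom.food_contact_ratio


def quantify_area(
    compound: str,
    area: float,
    rf: float,
    geom: ExtractGeometry = ExtractGeometry(),
) -> QuantResult:
    """Response-factor semi-quantification of one feature area."""
    conc_ng = estimate_concentration(area, rf)
    migration = concentration_to_migration(conc_ng * NG_PER_ML_TO_MG_PER_ML, geom)
    return QuantResult(
        compound=compound, est_conc=conc_ng, migration=migration, method="response_factor"
    )


def calibrate_and_quantify(
    curve_points: Sequence[tuple[float, float]],
    sample_area_ratio: float,
) -> tuple[float, bool]:
    """Inverse prediction from an area-ratio calibration line.

    ``curve_points`` are (concentration ng/mL, area ratio analyte/IS).
    Fits ordinary least squares and returns (concentration, extrapolated);
    a sample response outside the fitted curve's range is flagged.
    """
    if len(curve_points) < 3:
        raise ValueError("calibration needs at least 3 points")
    conc = np.array([p[0] for p in curve_points], dtype=float)
    ratio = np.array([p[1] for p in curve_points], dtype=float)
    if np.ptp(conc) == 0:
        raise ValueError("calibration points all at the same concentration")
    fit = stats.linregress(conc, ratio)
    if fit.slope == 0:
        raise ValueError("degenerate calibration: zero slope")
    est = (sample_area_ratio - fit.intercept) / fit.slope
    extrapolated = not (ratio.min() <= sample_area_ratio <= ratio.max())
    return float(est), bool(extrapolated)


def system_suitability(
    standards: Sequence[InternalStandard],
    max_abs_ppm: float = 2.0,
) -> pd.DataFrame:
    """Replicate precision and mass accuracy per internal standard.

    For each standard: RSD% of peak area and retention time (sample
    standard deviation over mean), and the mean signed mass error (ppm) of
    the monitored ion against its theoretical m/z.  ``passed`` requires
    |mean ppm| <= ``max_abs_ppm`` (the identification mass tolerance).
    """
    rows = []
    for std in standards:
        if len(std.areas) < 2:
            raise ValueError(f"{std.name}: need >= 2 replicates for RSD")

        def rsd(values: Sequence[float]) -> float:
            arr = np.asarray(values, dtype=float)
            return float(np.std(arr, ddof=1) / np.mean(arr) * 100.0)

        row: dict = {
            "standard": std.name,
            "rsd_area_pct": rsd(std.areas),
            "rsd_rt_pct": rsd(std.rts) if len(std.rts) >= 2 else np.nan,
        }
        if std.observed_mzs and std.theoretical_mz is not None:
            ppms = [ppm_error(mz, std.theoretical_mz) for mz in std.observed_mzs]
            row["delta_mass_ppm"] = float(np.mean(ppms))
            row["passed"] = abs(row["delta_mass_ppm"]) <= max_abs_ppm
        else:
            row["delta_mass_ppm"] = np.nan
            row["passed"] = True
        rows.append(row)
    return pd.DataFrame(rows)
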