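"""Body-water enrichment from isotope-analyzer readings via a standard curve.

Plasma is distilled, diluted 1:300 in doubly-distilled water and read on a
liquid water isotope analyzer alongside standards of known D2O content.
An ordinary least-squares line ``reading = slope * known_fraction +
intercept`` is fitted to the standards and inverted for the samples.  If the
standards went through the same dilution as the samples (the default
assumption, ``curve_includes_dilution=True``), no rescaling is needed;
otherwise the back-calculated fraction is multiplied by the dilution factor.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .errors import CalibrationError, MeasurementError

__all__ = ["StandardCurve", "BodyWaterEnrichment", "fit_standard_curve", "enrichment_from_reading"]

#: back-calculated enrichments in (-NEGATIVE_TOL, 0) are clamped to 0 and
#: flagged as instrument noise; anything more negative is treated as a bug.
NEGATIVE_TOL = 1e-4

#: the study's plasma dilution before the analyzer
DEFAULT_DILUTION = 300.0


@dataclass(frozen=True)
class StandardCurve:
    """Fitted calibration line for the water isotope analyzer."""

    slope: float
    intercept: float
    r_squared: float
    points: tuple[tuple[float, float], ...]
    curve_id: str = "curve"

    def __post_init__(self) -> None:
        if not np.isfinite(self.slope) or self.slope == 0:
            raise CalibrationError(f"slope must be finite and nonzero, got {self.slope}")
        if not -1e-12 <= self.r_squared <= 1 + 1e-12:
            raise CalibrationError(f"r_squared out of [0, 1]: {self.r_squared}")

    def predict(self, fraction: float) -> float:
        """Expected analyzer reading for a known D2O fraction."""
        return self.slope * fraction + self.intercept


@dataclass(frozen=True)
class BodyWaterEnrichment:
    """One sample's body-water D2O content as a fraction of total water."""

    sample_id: str
    enrichment: float
    dilution_factor: float = DEFAULT_DILUTION
    curve_id: str | None = None
    clamped: bool = field(default=False)

    def __post_init__(self) -> None:
        if not 0.0 <= self.enrichment <= 1.0:
            raise MeasurementError(
                f"enrichment must be in [0, 1], got {self.enrichment} for {self.sample_id!r}"
            )
        if self.dilution_factor <= 0:
            raise MeasurementError(f"dilution_factor must be positive, got {self.dilution_factor}")


def fit_standard_curve(
    points: Iterable[Sequence[float]], curve_id: str = "curve"
) -> StandardCurve:
    """OLS fit of ``reading = slope * known_fraction + intercept``.

    ``points`` are (known_d2o_fraction, instrument_reading) pairs; at least
    two distinct known fractions are required.
    """
    pts = tuple((float(x), float(y)) for x, y in points)
    if len(pts) < 2:
        raise CalibrationError(f"need >= 2 standards, got {len(pts)}")
    x = np.array([p[0] for p in pts])
    y = np.array([p[1] for p in pts])
    if np.unique(x).size < 2:
        raise CalibrationError("need >= 2 distinct known fractions to fit a line")
    fit = stats.linregress(x, y)
    # two points or an exact line give rvalue 1 up to rounding
    r2 = min(float(fit.rvalue) ** 2, 1.0)
    return StandardCurve(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=r2,
        points=pts,
        curve_id=curve_id,
    )


def enrichment_from_reading(
    curve: StandardCurve,
    reading: float,
    sample_id: str = "",
    dilution_factor: float = DEFAULT_DILUTION,
    curve_includes_dilution: bool = True,
) -> BodyWaterEnrichment:
    """Invert the standard curve for one sample reading.

    With ``curve_includes_dilution=True`` (standards diluted like the
    samples) the back-calculated fraction is already on the body-water
    scale; otherwise it is multiplied by ``dilution_factor``.  Tiny negative
    values (instrument noise around a blank) are clamped to zero and
    flagged; values below ``-NEGATIVE_TOL`` or above 1 raise.
    """
    fraction = (float(reading) - curve.intercept) / curve.slope
    if not curve_includes_dilution:
        fraction *= dilution_factor
    clamped = False
    if fraction < 0:
        if fraction < -NEGATIVE_TOL:
            raise MeasurementError(
                f"back-calculated enrichment {fraction:.3g} for {sample_id!r} "
                f"is below the noise tolerance -{NEGATIVE_TOL}"
            )
        fraction = 0.0
        clamped = True
    if fraction > 1.0:
        raise MeasurementError(
            f"back-calculated enrichment {fraction:.3g} for {sample_id!r} exceeds 1"
        )
    return BodyWaterEnrichment(
        sample_id=sample_id,
        enrichment=fraction,
        dilution_factor=dilution_factor,
        curve_id=curve.curve_id,
        clamped=clamped,
    )
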