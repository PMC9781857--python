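"""Fractional gluconeogenesis from SIM intensity pairs and body-water enrichment.

The two defining relations, applied per sample:

    fragment enrichment = [(M+1)/(M) - background] / n_sites        (ratio form)
    fGNG                = fragment enrichment / body-water enrichment

with n_sites = 6 for the glucose penta-acetate m/z 169 fragment.  Background
subtraction defaults to 0 (the raw-ratio form); an unlabeled-baseline M+1/M
ratio may be supplied per batch.

The result also carries the dietary-adequacy classification used clinically:
fGNG in [0, 0.15] indicates a fed state (with [0, 0.10] suggesting
overfeeding), above 0.40 an unfed state, and the unnamed middle band is
reported as indeterminate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .calibration import BodyWaterEnrichment
from .errors import DomainError, MeasurementError
from .isotope import GLUCOSE_PENTAACETATE_169, FragmentModel

__all__ = [
    "IsotopologueMeasurement",
    "FGNGResult",
    "fragment_enrichment",
    "compute_fgng",
    "classify_feeding_state",
    "estimate_sample",
    "FED_MAX",
    "OVERFED_MAX",
    "UNFED_MIN",
    "SUPERUNITY_TOL",
]

#: feeding-state band edges (fractions of glucose production), inclusive as
#: fed [0, 0.15], indeterminate (0.15, 0.40], unfed (0.40, 1]
FED_MAX = 0.15
UNFED_MIN = 0.40
OVERFED_MAX = 0.10

#: noise can push the ratio slightly past the physical bound; values in
#: (1, 1 + SUPERUNITY_TOL] are clamped to 1 and flagged, beyond is an error
SUPERUNITY_TOL = 0.05


@dataclass(frozen=True)
class IsotopologueMeasurement:
    """One sample's SIM intensities at the monitored M and M+1 masses."""

    sample_id: str
    intensity_m: float
    intensity_m1: float

    def __post_init__(self) -> None:
        if self.intensity_m <= 0:
            raise MeasurementError(
                f"intensity at M must be positive, got {self.intensity_m} "
                f"for {self.sample_id!r}"
            )
        if self.intensity_m1 < 0:
            raise MeasurementError(
                f"intensity at M+1 must be >= 0, got {self.intensity_m1} "
                f"for {self.sample_id!r}"
            )


@dataclass(frozen=True)
class FGNGResult:
    """Per-sample estimate with its intermediates and QC annotations."""

    sample_id: str
    fragment_enrichment: float
    body_water_enrichment: float
    fgng: float
    feeding_state: str
    overfed_flag: bool
    qc_flags: tuple[str, ...] = field(default_factory=tuple)


def fragment_enrichment(
    meas: IsotopologueMeasurement,
    fragment: FragmentModel = GLUCOSE_PENTAACETATE_169,
    background_ratio: float = 0.0,
) -> float:
    """Per-site deuterium enrichment of the fragment from its M+1/M ratio.

    Floors at zero when background subtraction overshoots; use
    :func:`estimate_sample` to retain the QC flag for that case.
    """
    value, _ = _enrichment_and_flags(meas, fragment, background_ratio)
    return value


def _enrichment_and_flags(
    meas: IsotopologueMeasurement,
    fragment: FragmentModel,
    background_ratio: float,
) -> tuple[float, tuple[str, ...]]:
    if background_ratio < 0:
        raise DomainError(f"background_ratio must be >= 0, got {background_ratio}")
    ratio = meas.intensity_m1 / meas.intensity_m
    enrichment = (ratio - background_ratio) / fragment.n_sites
    if background_ratio > 0 and ratio <= background_ratio:
        # the baseline consumed the whole signal: no usable enrichment
        return 0.0, ("negative-after-background",)
    return max(enrichment, 0.0), ()


def compute_fgng(
    fragment_enrichment: float,
    body_water: BodyWaterEnrichment,
    sample_id: str | None = None,
    qc_flags: tuple[str, ...] = (),
) -> FGNGResult:
    """Divide fragment enrichment by precursor (body-water) enrichment.

    Values in (1, 1 + SUPERUNITY_TOL] are clamped to the physical bound and
    flagged ``superunity``; beyond the tolerance the measurements are
    inconsistent and an error is raised.
    """
    if fragment_enrichment < 0:
        raise DomainError(f"fragment_enrichment must be >= 0, got {fragment_enrichment}")
    if body_water.enrichment <= 0:
        raise MeasurementError(
            f"body-water enrichment must be positive to divide, got "
            f"{body_water.enrichment} for {body_water.sample_id!r}"
        )
    sid = sample_id if sample_id is not None else body_water.sample_id
    fgng = fragment_enrichment / body_water.enrichment
    flags = tuple(qc_flags)
    if fgng > 1.0 + SUPERUNITY_TOL:
        raise MeasurementError(
            f"fGNG {fgng:.4f} for {sid!r} exceeds 1 by more than {SUPERUNITY_TOL:.0%}; "
            "fragment and body-water enrichments are inconsistent"
        )
    if fgng > 1.0:
        fgng = 1.0
        flags += ("superunity",)
    state, overfed = classify_feeding_state(fgng)
    return FGNGResult(
        sample_id=sid,
        fragment_enrichment=fragment_enrichment,
        body_water_enrichment=body_water.enrichment,
        fgng=fgng,
        feeding_state=state,
        overfed_flag=overfed,
        qc_flags=flags,
    )


def classify_feeding_state(fgng: float) -> tuple[str, bool]:
    """Dietary-adequacy band of an fGNG value.

    Returns ``(state, overfed_flag)`` with state one of ``"fed"``
    (fgng <= 0.15), ``"unfed"`` (fgng > 0.40) or ``"indeterminate"``;
    the overfed flag marks the low sub-band fgng <= 0.10.
    """
    if not 0.0 <= fgng <= 1.0:
        raise DomainError(f"fgng must be in [0, 1], got {fgng}")
    if fgng <= FED_MAX:
        state = "fed"
    elif fgng > UNFED_MIN:
        state = "unfed"
    else:
        state = "indeterminate"
    return state, fgng <= OVERFED_MAX


def estimate_sample(
    meas: IsotopologueMeasurement,
    body_water: BodyWaterEnrichment,
    fragment: FragmentModel = GLUCOSE_PENTAACETATE_169,
    background_ratio: float = 0.0,
) -> FGNGResult:
    """Full per-sample estimate: ratio form, division, classification, QC."""
    enrichment, flags = _enrichment_and_flags(meas, fragment, background_ratio)
    return compute_fgng(enrichment, body_water, sample_id=meas.sample_id, qc_flags=flags)
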