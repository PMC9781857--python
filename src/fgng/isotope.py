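"""Forward model of deuterium labeling in a monitored GC-MS fragment.

Glucose made by gluconeogenesis in an animal drinking heavy water picks up
deuterium from body water at exchangeable carbon-bound hydrogen positions.
The monitored penta-acetate fragment (m/z 169) carries six such positions
(C1, C3, C4, C5, C6 hydrogens); the hydrogen on C2 is absent from this
fragment, which is what makes its labeling specific to gluconeogenesis
rather than to total glucose turnover.

This module predicts the isotopologue distribution (relative abundances of
the M, M+1, M+2, ... species) of the fragment for a given body-water
enrichment ``p_water`` and true gluconeogenic fraction ``fgng_true``,
optionally convolved with the natural-abundance background of the ion's
elemental composition.  The estimator in :mod:`fgng.estimator` inverts the
first-order version of this model.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources

import numpy as np
from scipy.stats import binom

from .errors import ConfigurationError, DomainError

__all__ = [
    "FragmentModel",
    "IsotopologueDistribution",
    "GLUCOSE_PENTAACETATE_169",
    "label_distribution",
    "natural_abundance_m1",
    "background_distribution",
    "convolve",
    "convolve_background",
]

#: distributions must sum to one within this tolerance
_SUM_TOL = 1e-12


@lru_cache(maxsize=1)
def _abundance_table() -> dict[str, dict[str, float]]:
    text = resources.files("fgng.data").joinpath("isotope_abundances.json").read_text()
    return json.loads(text)["elements"]


@dataclass(frozen=True)
class FragmentModel:
    """Labeling geometry of the monitored fragment ion.

    Parameters
    ----------
    n_sites:
        Number of deuterium-exchangeable hydrogens the fragment carries
        (6 for the glucose penta-acetate m/z 169 ion).
    base_mz:
        m/z of the unlabeled monoisotopic ion.
    elemental_composition:
        Element -> atom count map used for the natural-abundance M+1
        background.  Empty (the default) disables the background, matching
        the raw-ratio usage of the defining equations; the composition of
        the m/z 169 ion is not established, so no default is baked in.
    """

    n_sites: int = 6
    base_mz: int = 169
    elemental_composition: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_sites < 1:
            raise ConfigurationError(f"n_sites must be >= 1, got {self.n_sites}")
        if self.base_mz <= 0:
            raise ConfigurationError(f"base_mz must be positive, got {self.base_mz}")
        for element, count in self.elemental_composition.items():
            if count < 0:
                raise ConfigurationError(f"negative atom count for {element!r}")


#: the study's monitored fragment, background disabled
GLUCOSE_PENTAACETATE_169 = FragmentModel(n_sites=6, base_mz=169)


@dataclass(frozen=True, eq=False)
class IsotopologueDistribution:
    """Probabilities of mass shifts 0..K for one fragment ion."""

    probabilities: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.probabilities, dtype=float)
        if p.ndim != 1 or p.size < 1:
            raise DomainError("probabilities must be a non-empty 1-D sequence")
        if np.any(p < -1e-15) or np.any(p > 1 + 1e-12):
            raise DomainError("probabilities must lie in [0, 1]")
        if abs(p.sum() - 1.0) > _SUM_TOL:
            raise DomainError(f"probabilities must sum to 1, got {p.sum()!r}")
        p = np.clip(p, 0.0, 1.0)
        p.setflags(write=False)
        object.__setattr__(self, "probabilities", p)

    def __len__(self) -> int:
        return int(self.probabilities.size)

    @property
    def ratio_m1_m0(self) -> float:
        """The M+1/M abundance ratio the estimator consumes."""
        if self.probabilities[0] <= 0:
            raise DomainError("M abundance is zero; M+1/M undefined")
        if len(self) < 2:
            return 0.0
        return float(self.probabilities[1] / self.probabilities[0])


def _check_fraction(name: str, value: float) -> float:
    value = float(value)
    if not 0.0 <= value <= 1.0:
        raise DomainError(f"{name} must be in [0, 1], got {value}")
    return value


def label_distribution(
    p_water: float,
    fgng_true: float,
    fragment: FragmentModel = GLUCOSE_PENTAACETATE_169,
    mode: str = "binomial",
) -> IsotopologueDistribution:
    """Isotopologue distribution of tracer labeling, before any background.

    Circulating glucose is modeled as a two-component mixture: a fraction
    ``fgng_true`` made de novo, each of the fragment's ``n_sites`` hydrogens
    independently deuterated with probability ``p_water``, and the remainder
    (glycogenolytic or pre-label glucose) unlabeled at those sites.

    ``mode="binomial"`` returns the exact mixture
    ``fgng_true * Binomial(n_sites, p_water) + (1 - fgng_true) * delta_0``
    of length ``n_sites + 1``.  ``mode="linear"`` truncates to the
    first-order two-point distribution whose M+1/M ratio is exactly
    ``fgng_true * n_sites * p_water`` — the implicit assumption of the
    ratio-over-n estimator.
    """
    p_water = _check_fraction("p_water", p_water)
    fgng_true = _check_fraction("fgng_true", fgng_true)
    n = fragment.n_sites
    if mode == "binomial":
        probs = fgng_true * binom.pmf(np.arange(n + 1), n, p_water)
        probs[0] += 1.0 - fgng_true
    elif mode == "linear":
        r = fgng_true * n * p_water
        probs = np.array([1.0, r]) / (1.0 + r)
    else:
        raise DomainError(f"mode must be 'linear' or 'binomial', got {mode!r}")
    return IsotopologueDistribution(probs / probs.sum())


def natural_abundance_m1(fragment: FragmentModel) -> float:
    """Exact M+1/M probability ratio from the composition's heavy isotopes.

    Exactly one atom heavy gives P(M+1)/P(M) = sum over elements of
    n_atoms * a1/a0; this is exact, not a first-order truncation, because
    only single +1 substitutions produce a +1 shift.
    """
    table = _abundance_table()
    ratio = 0.0
    for element, count in fragment.elemental_composition.items():
        if element not in table:
            raise ConfigurationError(
                f"element {element!r} not in the pinned isotope table "
                f"(known: {sorted(table)})"
            )
        iso = table[element]
        ratio += count * iso["m1"] / iso["m0"]
    return ratio


def background_distribution(fragment: FragmentModel) -> IsotopologueDistribution:
    """Full natural-abundance mass-shift distribution of the composition.

    Product of per-element binomials in the +1 isotope (abundances
    renormalized over the two tracked isotopes).  Empty composition gives a
    point mass at shift 0.
    """
    table = _abundance_table()
    dist = np.array([1.0])
    for element, count in fragment.elemental_composition.items():
        if element not in table:
            raise ConfigurationError(f"element {element!r} not in the pinned isotope table")
        if count == 0:
            continue
        iso = table[element]
        q = iso["m1"] / (iso["m0"] + iso["m1"])
        atom = np.array([1.0 - q, q])
        for _ in range(count):
            dist = np.convolve(dist, atom)
    return IsotopologueDistribution(dist / dist.sum())


def convolve(
    a: IsotopologueDistribution, b: IsotopologueDistribution
) -> IsotopologueDistribution:
    """Mass-shift convolution of two independent isotopologue distributions."""
    out = np.convolve(a.probabilities, b.probabilities)
    return IsotopologueDistribution(out / out.sum())


def convolve_background(
    labeled: IsotopologueDistribution, fragment: FragmentModel
) -> IsotopologueDistribution:
    """Overlay the fragment's natural-abundance background on a labeling pattern."""
    background = background_distribution(fragment)
    if len(background) == 1:
        return labeled
    return convolve(labeled, background)
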