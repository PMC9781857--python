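"""Synthetic heavy-water cohorts with the statistical structure of the rat study.

The generator emits everything the pipeline consumes — a design table, SIM
intensity pairs per injection, body-water analyzer readings, and a standard
curve — together with the underlying truth, so every downstream stage can be
verified without any external data.

Default condition: four cells (ad libitum or 50 % caloric restriction,
crossed with sham or closed-head TBI) of sizes 3/6/6/5; per-cell true fGNG
means and between-animal SDs follow the reference cohort the simulator
emulates (pre-intervention ~35-37 %, post-intervention AL ~60-63 %,
CR ~79-80 %); steady-state body water near the 6 % drinking-water level
(default 5.5 %, slightly diluted by metabolic and food water); lognormal
multiplicative SIM noise of 2 % CV over 3 injections.

Pre-intervention dispersion defaults derive from standard errors (x sqrt(n))
while post-intervention values are between-animal SDs as printed; only that
reading is consistent with the reference cohort's own reported p-values
(see docs/methods.md).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import norm, truncnorm

from . import isotope
from .errors import ConfigurationError
from .isotope import FragmentModel

__all__ = [
    "SimulationConfig",
    "CohortBundle",
    "simulate_cohort",
    "simulate_trajectories",
    "CELLS",
    "DEFAULT_N_PER_CELL",
    "DEFAULT_TRUE_FGNG",
    "cell_factors",
]

CELLS = ("AL-Con", "AL+TBI", "CR-Con", "CR+TBI")

DEFAULT_N_PER_CELL = {"AL-Con": 3, "AL+TBI": 6, "CR-Con": 6, "CR+TBI": 5}

#: (mean, between-animal sd) of true fGNG per cell and timepoint, as fractions
DEFAULT_TRUE_FGNG = {
    ("AL-Con", "pre"): (0.356, 0.0330),
    ("AL+TBI", "pre"): (0.352, 0.0330),
    ("CR-Con", "pre"): (0.3662, 0.0567),
    ("CR+TBI", "pre"): (0.3662, 0.0567),
    ("AL-Con", "post"): (0.6264, 0.0633),
    ("AL+TBI", "post"): (0.5985, 0.0501),
    ("CR-Con", "post"): (0.7983, 0.0443),
    ("CR+TBI", "post"): (0.7910, 0.0452),
}

#: body-weight cell means in grams at (pre, 24 h, 13 d)
_WEIGHT_MEANS = {
    "AL-Con": (249.3, 248.7, 294.3),
    "AL+TBI": (252.2, 241.2, 285.3),
    "CR-Con": (292.16, 291.5, 278.3),
    "CR+TBI": (244.8, 233.0, 216.6),
}

#: daily food-intake cell means in grams at (pre, 24 h, 13 d); None = from
#: the half-ration rule applied per animal
_FOOD_MEANS = {
    "AL-Con": (22.5, 18.0, 21.1),
    "AL+TBI": (22.7, 12.3, 21.0),
    "CR-Con": (25.0, None, None),
    "CR+TBI": (21.9, None, None),
}


def cell_factors(cell: str) -> tuple[str, str]:
    """Split a cell label like ``"CR+TBI"`` into (feeding, injury)."""
    if cell not in CELLS:
        raise ConfigurationError(f"unknown cell {cell!r}; expected one of {CELLS}")
    return cell[:2], "TBI" if cell.endswith("TBI") else "Con"


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the synthetic cohort; the seed is mandatory."""

    seed: int
    n_per_cell: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_N_PER_CELL))
    true_fgng: dict[tuple[str, str], tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_TRUE_FGNG)
    )
    body_water_mean: float = 0.055
    body_water_sd: float = 0.003
    intensity_noise_cv: float = 0.02
    n_injections: int = 3
    incorporation_mode: str = "linear"
    background_composition: dict[str, int] = field(default_factory=dict)
    base_intensity: float = 1.0e6
    curve_slope: float = 1.0
    curve_intercept: float = 0.0
    standard_fractions: tuple[float, ...] = (
        0.0, 0.01, 0.02, 0.03, 0.04, 0.05, 0.06, 0.07, 0.08,
    )
    reading_noise_sd: float = 2.0e-4
    dilution_factor: float = 300.0
    curve_includes_dilution: bool = True
    timepoints: tuple[str, ...] = ("pre", "post")

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ConfigurationError("seed is mandatory")
        for cell, n in self.n_per_cell.items():
            cell_factors(cell)
            if n < 1:
                raise ConfigurationError(f"n_per_cell[{cell!r}] must be >= 1, got {n}")
        for (cell, tp), (mean, sd) in self.true_fgng.items():
            if not 0.0 <= mean <= 1.0:
                raise ConfigurationError(f"true fGNG mean for {(cell, tp)} out of [0,1]")
            if sd < 0:
                raise ConfigurationError(f"negative sd for {(cell, tp)}")
        if not 0.0 <= self.body_water_mean <= 1.0 or self.body_water_sd < 0:
            raise ConfigurationError("invalid body-water parameters")
        if self.intensity_noise_cv < 0 or self.reading_noise_sd < 0:
            raise ConfigurationError("noise parameters must be >= 0")
        if self.n_injections < 1:
            raise ConfigurationError("n_injections must be >= 1")
        if self.incorporation_mode not in ("linear", "binomial"):
            raise ConfigurationError(
                f"incorporation_mode must be 'linear' or 'binomial', "
                f"got {self.incorporation_mode!r}"
            )
        if self.dilution_factor <= 0 or self.base_intensity <= 0:
            raise ConfigurationError("dilution_factor and base_intensity must be positive")
        for (cell, tp), (mean, sd) in self.true_fgng.items():
            if sd > 0:
                inside = norm.cdf(1, mean, sd) - norm.cdf(0, mean, sd)
                if inside < 0.5:
                    warnings.warn(
                        f"truncation removes {1 - inside:.0%} of the fGNG "
                        f"distribution for {(cell, tp)}",
                        stacklevel=2,
                    )

    def fragment(self) -> FragmentModel:
        return FragmentModel(elemental_composition=dict(self.background_composition))


@dataclass
class CohortBundle:
    """All simulated tables plus the truth behind every observable."""

    design: pd.DataFrame
    truth: pd.DataFrame
    intensities: pd.DataFrame
    bodywater: pd.DataFrame
    standard_curve: pd.DataFrame

    _FILES = {
        "design": "design.csv",
        "truth": "truth.csv",
        "intensities": "sim_intensities.csv",
        "bodywater": "bodywater_readings.csv",
        "standard_curve": "standard_curve.csv",
    }

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {}
        for attr, name in self._FILES.items():
            path = out / name
            getattr(self, attr).to_csv(path, index=False)
            paths[attr] = path
        return paths


def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, size: int
) -> np.ndarray:
    """Normal(mean, sd) truncated to [0, 1]; degenerate at sd = 0."""
    if sd == 0:
        return np.full(size, mean)
    a, b = (0.0 - mean) / sd, (1.0 - mean) / sd
    return truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def _lognormal_factors(
    rng: np.random.Generator, cv: float, size: int
) -> np.ndarray:
    """Mean-one multiplicative lognormal noise with coefficient of variation cv."""
    if cv == 0:
        return np.ones(size)
    sigma = math.sqrt(math.log1p(cv**2))
    return rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=size)


def simulate_cohort(config: SimulationConfig) -> CohortBundle:
    """Draw one complete cohort; byte-identical output under a fixed seed.

    Per animal and timepoint: true fGNG from the cell's truncated normal,
    body water from its own truncated normal, isotopologue distribution via
    the forward model in the configured mode (convolved with natural-
    abundance background when a composition is configured), intensities
    scaled to ``base_intensity`` with independent lognormal noise per
    injection and channel, and an analyzer reading through the simulated
    standard curve.
    """
    rng = np.random.default_rng(config.seed)
    fragment = config.fragment()

    std_rows = []
    for known in config.standard_fractions:
        reading = (
            config.curve_slope * known
            + config.curve_intercept
            + rng.normal(0.0, config.reading_noise_sd)
        )
        std_rows.append({"known_fraction": known, "reading": reading})

    design_rows, truth_rows, intensity_rows, bw_rows = [], [], [], []
    animal_index = 0
    for cell in CELLS:
        if cell not in config.n_per_cell:
            continue
        feeding, injury = cell_factors(cell)
        for _ in range(config.n_per_cell[cell]):
            animal_index += 1
            animal_id = f"R{animal_index:02d}"
            for tp in config.timepoints:
                if (cell, tp) not in config.true_fgng:
                    raise ConfigurationError(f"no true fGNG configured for {(cell, tp)}")
                mean, sd = config.true_fgng[(cell, tp)]
                fgng_true = float(_truncated_normal(rng, mean, sd, 1)[0])
                bw_true = float(
                    _truncated_normal(rng, config.body_water_mean, config.body_water_sd, 1)[0]
                )
                sample_id = f"{animal_id}_{tp}"
                design_rows.append(
                    {
                        "sample_id": sample_id,
                        "animal_id": animal_id,
                        "feeding": feeding,
                        "injury": injury,
                        "timepoint": tp,
                        "cell": cell,
                    }
                )
                truth_rows.append(
                    {
                        "sample_id": sample_id,
                        "true_fgng": fgng_true,
                        "true_body_water": bw_true,
                    }
                )

                dist = isotope.label_distribution(
                    bw_true, fgng_true, fragment, mode=config.incorporation_mode
                )
                if fragment.elemental_composition:
                    dist = isotope.convolve_background(dist, fragment)
                p0 = float(dist.probabilities[0])
                p1 = float(dist.probabilities[1]) if len(dist) > 1 else 0.0
                noise = _lognormal_factors(
                    rng, config.intensity_noise_cv, 2 * config.n_injections
                )
                for inj in range(config.n_injections):
                    intensity_rows.append(
                        {
                            "sample_id": sample_id,
                            "injection": inj + 1,
                            "intensity_169": config.base_intensity * p0 * noise[2 * inj],
                            "intensity_170": config.base_intensity * p1 * noise[2 * inj + 1],
                        }
                    )

                diluted = bw_true if config.curve_includes_dilution else bw_true / config.dilution_factor
                reading = (
                    config.curve_slope * diluted
                    + config.curve_intercept
                    + rng.normal(0.0, config.reading_noise_sd)
                )
                bw_rows.append({"sample_id": sample_id, "reading": reading})

    return CohortBundle(
        design=pd.DataFrame(design_rows),
        truth=pd.DataFrame(truth_rows),
        intensities=pd.DataFrame(intensity_rows),
        bodywater=pd.DataFrame(bw_rows),
        standard_curve=pd.DataFrame(std_rows),
    )


def _ceil_to_half(x: float) -> float:
    """Round up to the nearest half gram (the ration-setting convention)."""
    return math.ceil(2.0 * x) / 2.0


def simulate_trajectories(
    config: SimulationConfig,
    weight_noise_sd: float = 5.0,
    food_noise_sd: float = 1.0,
) -> pd.DataFrame:
    """Optional per-animal body-weight and food-intake series.

    Cell means follow the reference cohort's weight and intake tables at
    pre-intervention, 24 h, and 13 days post-intervention, with independent
    Gaussian noise per measurement.  Calorically restricted animals receive
    a fixed ration from 24 h onward: half their pre-intervention daily
    intake rounded up to the nearest half gram.  At zero noise the columns
    reproduce the reference cell means (and the ration rule for CR intake).
    """
    if weight_noise_sd < 0 or food_noise_sd < 0:
        raise ConfigurationError("noise sds must be >= 0")
    # separate stream from simulate_cohort so the two can be combined freely
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    rows = []
    animal_index = 0
    for cell in CELLS:
        if cell not in config.n_per_cell:
            continue
        feeding, injury = cell_factors(cell)
        w_pre, w_24h, w_13d = _WEIGHT_MEANS[cell]
        f_pre, f_24h, f_13d = _FOOD_MEANS[cell]
        for _ in range(config.n_per_cell[cell]):
            animal_index += 1
            weights = [
                m + rng.normal(0.0, weight_noise_sd) for m in (w_pre, w_24h, w_13d)
            ]
            food_pre = f_pre + rng.normal(0.0, food_noise_sd)
            if feeding == "CR":
                ration = _ceil_to_half(food_pre) / 2.0
                food_24h, food_13d = ration, ration
            else:
                food_24h = f_24h + rng.normal(0.0, food_noise_sd)
                food_13d = f_13d + rng.normal(0.0, food_noise_sd)
            rows.append(
                {
                    "animal_id": f"R{animal_index:02d}",
                    "cell": cell,
                    "feeding": feeding,
                    "injury": injury,
                    "weight_pre_g": weights[0],
                    "weight_24h_g": weights[1],
                    "weight_13d_g": weights[2],
                    "weight_change_g": weights[2] - weights[0],
                    "food_pre_g": food_pre,
                    "food_24h_g": food_24h,
                    "food_13d_g": food_13d,
                }
            )
    return pd.DataFrame(rows)


def config_for_cells(
    seed: int,
    cells: dict[str, int],
    timepoints: tuple[str, ...] = ("pre", "post"),
    **overrides,
) -> SimulationConfig:
    """Convenience constructor for sub-designs (e.g. a single cell or timepoint)."""
    base = SimulationConfig(seed=seed, timepoints=timepoints, **overrides)
    return replace(base, n_per_cell=dict(cells))
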