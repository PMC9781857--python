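"""End-to-end orchestration: tables in, per-animal estimates and statistics out.

Input contract (plain CSV, UTF-8, "." decimal):

* design:         sample_id, animal_id, feeding, injury, timepoint
* intensities:    sample_id, injection, intensity_169, intensity_170
* body water:     sample_id, reading
* standard curve: known_fraction, reading

Each injection is ratioed on its own and the per-injection fragment
enrichments are averaged per sample before dividing by body-water
enrichment.  Statistics (two-way ANOVA, t-tests, Tukey) run on the
post-intervention records, with the pre-intervention feeding t-test
reported alongside.  Outputs are CSV tables plus a JSON manifest carrying a
hash of the semantically meaningful configuration; running twice on the
same inputs yields byte-identical files.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .calibration import (
    DEFAULT_DILUTION,
    StandardCurve,
    enrichment_from_reading,
    fit_standard_curve,
)
from .errors import PipelineError
from .estimator import IsotopologueMeasurement, compute_fgng, estimate_sample
from .isotope import FragmentModel
from .stats import independent_t_test, tukey_hsd, two_way_anova

logger = logging.getLogger("fgng.pipeline")

__all__ = [
    "PipelineOptions",
    "PipelineConfig",
    "ValidationReport",
    "validate_inputs",
    "estimate_frames",
    "group_summary",
    "run_group_stats",
    "run_pipeline",
    "config_hash",
]

_DESIGN_COLS = ["sample_id", "animal_id", "feeding", "injury", "timepoint"]
_INTENSITY_COLS = ["sample_id", "intensity_169", "intensity_170"]
_BODYWATER_COLS = ["sample_id", "reading"]
_CURVE_COLS = ["known_fraction", "reading"]


@dataclass(frozen=True)
class PipelineOptions:
    """Semantically meaningful analysis options (hashed into the manifest)."""

    n_sites: int = 6
    base_mz: int = 169
    background_composition: dict[str, int] = field(default_factory=dict)
    background_ratio: float = 0.0
    dilution_factor: float = DEFAULT_DILUTION
    curve_includes_dilution: bool = True
    ss_type: int = 3
    t_test: str = "student"

    def fragment(self) -> FragmentModel:
        return FragmentModel(
            n_sites=self.n_sites,
            base_mz=self.base_mz,
            elemental_composition=dict(self.background_composition),
        )


@dataclass(frozen=True)
class PipelineConfig:
    design_path: Path
    intensities_path: Path
    bodywater_path: Path
    standard_curve_path: Path
    out_dir: Path
    options: PipelineOptions = field(default_factory=PipelineOptions)
    log_level: str = "INFO"

    @classmethod
    def from_dir(cls, in_dir: str | Path, out_dir: str | Path, **kwargs) -> "PipelineConfig":
        """Conventional file names inside one directory (as written by simulate)."""
        d = Path(in_dir)
        return cls(
            design_path=d / "design.csv",
            intensities_path=d / "sim_intensities.csv",
            bodywater_path=d / "bodywater_readings.csv",
            standard_curve_path=d / "standard_curve.csv",
            out_dir=Path(out_dir),
            **kwargs,
        )


def config_hash(options: PipelineOptions) -> str:
    """Stable digest of the options that change results."""
    payload = dataclasses.asdict(options)
    canonical = json.dumps(payload, sort_keys=True, separators=(",", ":"))
    return hashlib.sha256(canonical.encode()).hexdigest()


@dataclass
class ValidationReport:
    errors: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors


def _read_csv(path: Path, required: list[str], errors: list[str]) -> pd.DataFrame | None:
    try:
        df = pd.read_csv(path)
    except OSError as exc:
        errors.append(f"cannot read {path}: {exc}")
        return None
    except Exception as exc:  # malformed CSV
        errors.append(f"cannot parse {path}: {exc}")
        return None
    missing = [c for c in required if c not in df.columns]
    if missing:
        errors.append(f"{path}: missing columns {missing}")
        return None
    return df


def validate_inputs(config: PipelineConfig) -> ValidationReport:
    """Schema, join, duplicate, and range checks over the four input tables."""
    errors: list[str] = []
    design = _read_csv(config.design_path, _DESIGN_COLS, errors)
    intens = _read_csv(config.intensities_path, _INTENSITY_COLS, errors)
    bw = _read_csv(config.bodywater_path, _BODYWATER_COLS, errors)
    curve = _read_csv(config.standard_curve_path, _CURVE_COLS, errors)
    if errors:
        return ValidationReport(errors)

    dupes = design[design["sample_id"].duplicated()]["sample_id"].tolist()
    if dupes:
        errors.append(f"design: duplicate sample_id {dupes}")
    bw_dupes = bw[bw["sample_id"].duplicated()]["sample_id"].tolist()
    if bw_dupes:
        errors.append(f"body water: duplicate sample_id {bw_dupes}")

    known = set(design["sample_id"])
    for name, df in (("intensities", intens), ("body water", bw)):
        orphans = sorted(set(df["sample_id"]) - known)
        if orphans:
            errors.append(f"{name}: sample_id not in design: {orphans}")
    missing_bw = sorted(known - set(bw["sample_id"]))
    if missing_bw:
        errors.append(f"body water: no reading for {missing_bw}")
    missing_int = sorted(known - set(intens["sample_id"]))
    if missing_int:
        errors.append(f"intensities: no rows for {missing_int}")

    bad = intens[intens["intensity_169"] <= 0]
    for _, row in bad.iterrows():
        errors.append(
            f"intensities: intensity_169 must be > 0, got {row['intensity_169']} "
            f"for sample {row['sample_id']!r}"
        )
    bad = intens[intens["intensity_170"] < 0]
    for _, row in bad.iterrows():
        errors.append(
            f"intensities: intensity_170 must be >= 0 for sample {row['sample_id']!r}"
        )

    if curve["known_fraction"].nunique() < 2:
        errors.append("standard curve: need >= 2 distinct known fractions")
    out_of_range = curve[(curve["known_fraction"] < 0) | (curve["known_fraction"] > 1)]
    if not out_of_range.empty:
        errors.append("standard curve: known_fraction outside [0, 1]")
    return ValidationReport(errors)


def estimate_frames(
    design: pd.DataFrame,
    intensities: pd.DataFrame,
    bodywater: pd.DataFrame,
    standard_curve: pd.DataFrame,
    options: PipelineOptions = PipelineOptions(),
) -> tuple[pd.DataFrame, StandardCurve]:
    """Run calibration and the per-sample estimator over in-memory tables.

    Returns one row per sample with the estimate, its intermediates, the
    feeding-state class, and QC flags, joined to the design factors.
    """
    curve = fit_standard_curve(
        standard_curve[["known_fraction", "reading"]].itertuples(index=False)
    )
    fragment = options.fragment()

    bw_by_sample = {}
    for row in bodywater.itertuples(index=False):
        bw_by_sample[row.sample_id] = enrichment_from_reading(
            curve,
            row.reading,
            sample_id=row.sample_id,
            dilution_factor=options.dilution_factor,
            curve_includes_dilution=options.curve_includes_dilution,
        )

    results = []
    for sample_id, group in intensities.groupby("sample_id", sort=False):
        if sample_id not in bw_by_sample:
            raise PipelineError(f"no body-water reading for sample {sample_id!r}")
        per_injection = []
        flags: tuple[str, ...] = ()
        for row in group.itertuples(index=False):
            meas = IsotopologueMeasurement(
                sample_id=str(sample_id),
                intensity_m=row.intensity_169,
                intensity_m1=row.intensity_170,
            )
            res = estimate_sample(
                meas, bw_by_sample[sample_id], fragment, options.background_ratio
            )
            per_injection.append(res.fragment_enrichment)
            flags += res.qc_flags
            logger.debug(
                "sample %s injection ratio=%.6g enrichment=%.6g",
                sample_id,
                row.intensity_170 / row.intensity_169,
                res.fragment_enrichment,
            )
        mean_enrichment = float(np.mean(per_injection))
        final = compute_fgng(
            mean_enrichment,
            bw_by_sample[sample_id],
            sample_id=str(sample_id),
            qc_flags=tuple(dict.fromkeys(flags)),
        )
        logger.debug("sample %s fGNG=%.6g", sample_id, final.fgng)
        results.append(
            {
                "sample_id": final.sample_id,
                "fragment_enrichment": final.fragment_enrichment,
                "body_water_enrichment": final.body_water_enrichment,
                "fgng": final.fgng,
                "feeding_state": final.feeding_state,
                "overfed_flag": final.overfed_flag,
                "qc_flags": "|".join(final.qc_flags),
            }
        )
    frame = pd.DataFrame(results)
    merged = design.merge(frame, on="sample_id", how="inner", validate="one_to_one")
    return merged, curve


def group_summary(results: pd.DataFrame) -> pd.DataFrame:
    """Mean, SD and n of fGNG per feeding x injury cell and timepoint."""
    g = results.groupby(["timepoint", "feeding", "injury"], observed=True)["fgng"]
    out = g.agg(n="count", mean_fgng="mean", sd_fgng="std").reset_index()
    return out.sort_values(["timepoint", "feeding", "injury"]).reset_index(drop=True)


def run_group_stats(results: pd.DataFrame, options: PipelineOptions = PipelineOptions()) -> dict:
    """The statistical battery on whatever timepoints the results contain."""
    out: dict[str, object] = {}
    ttest_rows = []
    for tp in ("pre", "post"):
        sub = results[results["timepoint"] == tp]
        if sub.empty:
            continue
        al = sub.loc[sub["feeding"] == "AL", "fgng"]
        cr = sub.loc[sub["feeding"] == "CR", "fgng"]
        if len(al) >= 2 and len(cr) >= 2:
            t = independent_t_test(al, cr, variant=options.t_test)
            ttest_rows.append(
                {"timepoint": tp, "comparison": "AL-vs-CR", "t": t.t, "df": t.df, "p": t.p}
            )
        con = sub.loc[sub["injury"] == "Con", "fgng"]
        tbi = sub.loc[sub["injury"] == "TBI", "fgng"]
        if tp == "post" and len(con) >= 2 and len(tbi) >= 2:
            t = independent_t_test(con, tbi, variant=options.t_test)
            ttest_rows.append(
                {"timepoint": tp, "comparison": "Con-vs-TBI", "t": t.t, "df": t.df, "p": t.p}
            )
    if ttest_rows:
        out["ttests"] = pd.DataFrame(ttest_rows)

    post = results[results["timepoint"] == "post"]
    if not post.empty and post.groupby(["feeding", "injury"]).ngroups == 4:
        anova = two_way_anova(post, response="fgng", ss_type=options.ss_type)
        out["anova"] = anova.to_frame().reset_index(names="effect")
        out["tukey"] = tukey_hsd(post, response="fgng")
    return out


def run_pipeline(config: PipelineConfig) -> dict[str, Path]:
    """Validate, estimate, summarize, test; write all outputs under out_dir.

    Raises :class:`PipelineError` (after removing partial outputs) when the
    inputs fail validation or any stage errors; returns a name -> path map
    of everything written.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    report = validate_inputs(config)
    if not report.ok:
        raise PipelineError("input validation failed:\n" + "\n".join(report.errors))

    design = pd.read_csv(config.design_path)
    intens = pd.read_csv(config.intensities_path)
    bw = pd.read_csv(config.bodywater_path)
    std = pd.read_csv(config.standard_curve_path)

    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    def _write(name: str, df: pd.DataFrame) -> None:
        path = out_dir / f"{name}.csv"
        df.to_csv(path, index=False)
        written[name] = path

    try:
        results, curve = estimate_frames(design, intens, bw, std, config.options)
        _write("results", results)
        _write("group_summary", group_summary(results))
        stats_tables = run_group_stats(results, config.options)
        for name, table in stats_tables.items():
            _write(name, table)

        summary = group_summary(results)
        report_payload = {
            "group_means_percent": [
                {
                    "timepoint": row.timepoint,
                    "cell": f"{row.feeding}-{row.injury}",
                    "n": int(row.n),
                    "mean": round(100 * row.mean_fgng, 2),
                    "sd": round(100 * row.sd_fgng, 2) if pd.notna(row.sd_fgng) else None,
                }
                for row in summary.itertuples(index=False)
            ],
        }
        if "anova" in stats_tables:
            anova_df = stats_tables["anova"].set_index("effect")
            report_payload["anova_p"] = {
                effect: (None if pd.isna(anova_df.loc[effect, "p"]) else float(anova_df.loc[effect, "p"]))
                for effect in anova_df.index
                if effect != "residual"
            }
        if "ttests" in stats_tables:
            report_payload["t_tests"] = stats_tables["ttests"].to_dict(orient="records")
        report_path = out_dir / "report.json"
        report_path.write_text(json.dumps(report_payload, indent=2, sort_keys=True))
        written["report"] = report_path

        manifest = {
            "software": "fgng",
            "version": __version__,
            "config_hash": config_hash(config.options),
            "options": dataclasses.asdict(config.options),
            "inputs": {
                "design": str(config.design_path),
                "intensities": str(config.intensities_path),
                "bodywater": str(config.bodywater_path),
                "standard_curve": str(config.standard_curve_path),
            },
            "standard_curve_fit": {
                "slope": curve.slope,
                "intercept": curve.intercept,
                "r_squared": curve.r_squared,
            },
            "n_samples": int(len(results)),
            "outputs": sorted(p.name for p in written.values()),
        }
        manifest_path = out_dir / "manifest.json"
        manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
        written["manifest"] = manifest_path
    except Exception:
        for path in written.values():
            path.unlink(missing_ok=True)
        raise
    return written
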