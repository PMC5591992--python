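"""End-to-end orchestration of the chamber sensitivity study.

One :func:`run_study` call builds the six-segment library, generates the
randomized leaf-error trials (3 levels x 10 trials per segment by default),
scores every aperture with the chamber surrogate, runs the four sensitivity
estimators per segment, and synthesizes the cross-segment power-law trends.
All randomness flows from one run seed through named substreams, so the whole
study — and any single trial in isolation — is reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field, field_validator
from scipy import stats

from . import iqm_chamber, mlc_segments
from .iqm_chamber import ChamberModel, NoiseModel
from .mlc_segments import Segment, build_library, generate_trials, segment_area, write_segments
from .sensitivity_methods import SensitivityResult, TrialSet, analyze_trial_set
from .trend_synthesis import PowerFit, summarize_segments

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


class ChamberConfig(BaseModel):
    span_cm: float = 40.0
    w0: float = 1.0
    gradient_per_cm: float = 0.02
    plateau_fraction: float = 0.2

    def build(self) -> ChamberModel:
        return ChamberModel(**self.model_dump())


class RunConfig(BaseModel):
    """Validated configuration of one study run."""

    seed: int = 0
    levels_mm: list[float] = Field(default_factory=lambda: [1.0, 2.0, 3.0])
    trials_per_level: int = 10
    noise_relative_sigma: float = 0.01
    normalization: Literal["relative", "raw"] = "relative"
    var_bins: int = 5
    epsilon: float = 1e-6
    fit_method: Literal["nls", "loglog"] = "nls"
    chamber: ChamberConfig = Field(default_factory=ChamberConfig)
    output_dir: str = "iqm_sense_run"

    @field_validator("levels_mm")
    @classmethod
    def _positive_levels(cls, v: list[float]) -> list[float]:
        if not v or any(l <= 0 for l in v):
            raise ValueError("levels_mm must be non-empty and strictly positive")
        return v

    @field_validator("trials_per_level", "var_bins")
    @classmethod
    def _positive(cls, v: int) -> int:
        if v < 1:
            raise ValueError("must be >= 1")
        return v

    @field_validator("noise_relative_sigma", "epsilon")
    @classmethod
    def _non_negative(cls, v: float) -> float:
        if v < 0:
            raise ValueError("must be >= 0")
        return v

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.model_validate(data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.model_dump(), sort_keys=False))


@dataclass
class StudyReport:
    """In-memory result of one run; files live under ``output_dir``."""

    config: RunConfig
    trials: pd.DataFrame
    results: dict[str, dict[str, SensitivityResult]]
    summary: pd.DataFrame
    fits: dict[str, PowerFit]
    output_dir: Path


def _noise_model(config: RunConfig) -> NoiseModel | None:
    if config.noise_relative_sigma == 0:
        return None
    seed = int(np.random.SeedSequence([config.seed, 0x5194]).generate_state(1)[0] % 2**31)
    return NoiseModel(relative_sigma=config.noise_relative_sigma, seed=seed)


def score_trials(
    config: RunConfig,
    segments: Sequence[Segment] | None = None,
) -> pd.DataFrame:
    """Generate and score every trial; returns the tidy trials table.

    Columns: segment, level_mm, trial, area_cm2, signal.  The unaltered
    reference of each segment appears as the level_mm == 0, trial 0 row; in
    relative mode its signal is exactly 1.  With noise enabled, every scored
    aperture (reference included) receives one multiplicative Gaussian draw.
    """
    segments = list(segments) if segments is not None else build_library()
    chamber = config.chamber.build()
    noise = _noise_model(config)
    rows = []
    for seg in segments:
        ref_raw = iqm_chamber.signal(chamber, seg, noise=noise)
        if ref_raw <= 0:
            raise StageError(f"scoring: reference signal non-positive for {seg.label!r}")
        denom = ref_raw if config.normalization == "relative" else 1.0
        rows.append(
            {
                "segment": seg.label,
                "level_mm": 0.0,
                "trial": 0,
                "area_cm2": segment_area(seg),
                "signal": ref_raw / denom,
            }
        )
        for trial in generate_trials(seg, config.levels_mm, config.trials_per_level, config.seed):
            s = iqm_chamber.signal(chamber, trial.segment, noise=noise)
            rows.append(
                {
                    "segment": seg.label,
                    "level_mm": trial.level_mm,
                    "trial": trial.trial_index,
                    "area_cm2": segment_area(trial.segment),
                    "signal": s / denom,
                }
            )
    return pd.DataFrame(rows)


def analyze_trials(config: RunConfig, trials: pd.DataFrame) -> dict[str, dict[str, SensitivityResult]]:
    """Run all four estimators on every segment in the trials table."""
    results: dict[str, dict[str, SensitivityResult]] = {}
    for label in trials["segment"].unique():
        trial_set = TrialSet.from_dataframe(trials, label)
        results[label] = analyze_trial_set(
            trial_set, n_bins=config.var_bins, epsilon=config.epsilon
        )
    return results


def run_study(config: RunConfig, segments: Sequence[Segment] | None = None) -> StudyReport:
    """Execute the full study and write all artifacts under the output directory.

    Artifacts: config echo (config.yaml), segment definitions (segments.seg),
    trials table (trials.csv), per-segment estimator tables
    (sensitivity_<segment>.csv), cross-segment summary (summary.csv), fitted
    trend report (report.txt), and a log (run.log).  Noise-free runs are
    bitwise-reproducible for a fixed (config, seed).
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines = [f"seed {config.seed}", f"normalization {config.normalization}"]
    config.to_yaml(out / "config.yaml")

    segments = list(segments) if segments is not None else build_library()
    try:
        write_segments(out / "segments.seg", segments)
    except Exception as exc:  # pragma: no cover - defensive
        raise StageError(f"segment-library stage failed: {exc}") from exc

    try:
        trials = score_trials(config, segments)
    except StageError:
        raise
    except Exception as exc:
        raise StageError(f"scoring stage failed: {exc}") from exc
    trials.to_csv(out / "trials.csv", index=False)
    n_altered = int((trials["level_mm"] != 0).sum())
    log_lines.append(
        f"scored {n_altered} altered + {len(segments)} unaltered apertures"
    )
    log_lines += [
        f"substream key: (seed={config.seed}, segment_label, level_um, trial_index)"
    ]

    try:
        results = analyze_trials(config, trials)
    except Exception as exc:
        raise StageError(f"analysis stage failed: {exc}") from exc
    for label, methods in results.items():
        frames = [res.to_frame() for res in methods.values()]
        pd.concat(frames, ignore_index=True).to_csv(
            out / f"sensitivity_{label}.csv", index=False
        )

    try:
        areas = {seg.label: segment_area(seg) for seg in segments}
        summary, fits = summarize_segments(results, areas, fit_method=config.fit_method)
    except Exception as exc:
        raise StageError(f"trend-synthesis stage failed: {exc}") from exc
    summary.to_csv(out / "summary.csv", index=False)

    report_lines = ["Cross-segment sensitivity trends", "=" * 34]
    for column, fit in fits.items():
        report_lines.append(f"{column}: {fit.describe()}  (rss={fit.rss:.3g}, {fit.method})")
    (out / "report.txt").write_text("\n".join(report_lines) + "\n")
    (out / "run.log").write_text("\n".join(log_lines) + "\n")

    return StudyReport(
        config=config,
        trials=trials,
        results=results,
        summary=summary,
        fits=fits,
        output_dir=out,
    )


def run_profile_experiment(
    config: RunConfig,
    fields_cm: Sequence[float] = (3.0, 5.0, 7.0),
    offsets_cm: Sequence[float] | None = None,
) -> pd.DataFrame:
    """Move square fields along the chamber gradient and fit their trend slopes.

    Returns a tidy table (field_cm, offset_cm, signal) with the per-field
    linear-trend slope attached via attrs["slopes"].  Noise-free: profiles are
    diagnostics of the chamber surrogate itself.  Slopes increase strictly
    with field size because a larger aperture integrates more of the ramp.
    """
    chamber = config.chamber.build()
    if offsets_cm is None:
        offsets_cm = np.arange(-10.0, 15.0, 2.0)
    offsets_cm = np.asarray(list(offsets_cm), dtype=float)
    rows = []
    slopes: dict[float, float] = {}
    for size in fields_cm:
        seg = mlc_segments.square_segment(float(size), f"profile_{size:g}x{size:g}")
        profile = iqm_chamber.gradient_profile(chamber, seg, offsets_cm)
        for off, sig in profile:
            rows.append({"field_cm": float(size), "offset_cm": off, "signal": sig})
        if len(offsets_cm) < 2:
            logger.warning("profile for %g cm field has a degenerate (single-point) grid", size)
            slopes[float(size)] = float("nan")
        else:
            fit = stats.linregress(offsets_cm, [s for _, s in profile])
            slopes[float(size)] = float(fit.slope)
    df = pd.DataFrame(rows)
    df.attrs["slopes"] = slopes
    return df
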