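"""End-to-end orchestration: simulate -> screen -> clean -> fit -> compare ->
frame correlations -> optional noise audit.

Every stage's inputs and outputs are persisted under the output directory and
all randomness flows from the single cohort seed, so a run is fully
reproducible (byte-identical reports) from its config file.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import CohortConfig, simulate_cohort, write_trial_table
from .frames import frame_correlation
from .models import VARIANTS, compare_models, fit_mixed_model
from .motion import build_test_profile, solve_test_profile, TEST_PEAK_ACCEL, TEST_TOTAL_TIME, TEST_TOTAL_DISTANCE
from .noise import noise_vs_threshold, synthesize_imu, preprocess_imu
from .preprocess import (
    error_pattern,
    remove_outlier_trials,
    screen_participants,
)
from .frames import to_body_frame

logger = logging.getLogger("distaniso")

__all__ = ["PipelineConfig", "run_pipeline", "FIT_CONDITIONS"]

#: the three fitting conditions reported side by side: upright (frames
#: coincide), and the pitched orientation coded earth- and body-centered
FIT_CONDITIONS = (
    ("upright", "earth"),
    ("pitch30", "earth"),
    ("pitch30", "body"),
)


@dataclass
class PipelineConfig:
    """Settings for one full pipeline run."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    variants: tuple[str, ...] = VARIANTS
    output_dir: str = "pipeline_out"
    alpha_level: float = 0.05
    include_noise_audit: bool = False
    noise_sd_per_axis: float = 0.02
    fit_n_starts: int = 5
    log_level: str = "INFO"

    def __post_init__(self):
        if isinstance(self.cohort, dict):
            self.cohort = CohortConfig(**self.cohort)
        if not self.variants:
            raise ValueError("at least one model variant must be requested")
        unknown = set(self.variants) - set(VARIANTS)
        if unknown:
            raise ValueError(f"unknown variants: {sorted(unknown)}")


def _dump_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, sort_keys=True, indent=2) + "\n")


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and return the machine-readable report bundle.

    Persists: the raw and cleaned trial tables (CSV), the exclusion report,
    one fit JSON per condition and variant, a model-comparison table per
    condition (CSV + JSON), the frame correlations, and (optionally) the
    synthetic noise audit. A stage failure propagates with the stage name;
    outputs written up to that point remain on disk.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=config.log_level)
    report: dict = {"seed": config.cohort.seed}

    stage = "simulate"
    try:
        table = simulate_cohort(config.cohort)
        write_trial_table(table, out / "trials.csv")
        config.cohort.to_yaml(out / "cohort_config.yaml")

        stage = "screen"
        kept, exclusions = screen_participants(table, config.alpha_level)
        logger.info("screen: excluded %d participants", len(exclusions.excluded))

        stage = "clean"
        cleaned, removed_fraction = remove_outlier_trials(kept)
        exclusions.removed_trial_fraction = removed_fraction
        write_trial_table(cleaned, out / "cleaned.csv")
        _dump_json(exclusions.to_dict(), out / "exclusions.json")
        report["exclusions"] = exclusions.to_dict()

        stage = "fit"
        fits_dir = out / "fits"
        fits_dir.mkdir(exist_ok=True)
        comparisons = {}
        for orientation, frame in FIT_CONDITIONS:
            sub = cleaned[cleaned["orientation"] == orientation].copy()
            if frame == "body" and orientation == "pitch30":
                sub["direction_deg"] = to_body_frame(
                    sub["direction_deg"].to_numpy(float), config.cohort.pitch_deg
                )
            fits = []
            for variant in config.variants:
                fit = fit_mixed_model(
                    sub, variant, n_starts=config.fit_n_starts, seed=config.cohort.seed
                )
                if not fit.converged:
                    logger.warning("fit %s/%s/%s did not converge", orientation, frame, variant)
                _dump_json(fit.to_dict(), fits_dir / f"{orientation}_{frame}_{variant}.json")
                fits.append(fit)
            if len(fits) > 1:
                comparison = compare_models(fits)
            else:  # a single requested variant has nothing to rank against
                comparison = pd.DataFrame(
                    [{"variant": fits[0].variant, "k": fits[0].k,
                      "loglik": fits[0].loglik, "aicc": fits[0].aicc,
                      "daicc": 0.0, "best": True, "indistinguishable": True}]
                )
            key = f"{orientation}_{frame}"
            comparison.to_csv(out / f"comparison_{key}.csv", index=False)
            comparisons[key] = comparison.to_dict(orient="records")
        _dump_json(comparisons, out / "comparison.json")
        report["comparisons"] = comparisons

        stage = "frames"
        pattern_upright = error_pattern(cleaned, "upright", "earth")
        corr = {}
        for frame in ("earth", "body"):
            pattern_pitched = error_pattern(cleaned, "pitch30", frame,
                                            pitch_deg=config.cohort.pitch_deg)
            corr[frame] = frame_correlation(pattern_upright, pattern_pitched, frame).to_dict()
        frames_out = {
            "correlations": corr,
            "pattern_upright": pattern_upright.to_dict(),
        }
        _dump_json(frames_out, out / "frames.json")
        report["frame_correlations"] = corr

        if config.include_noise_audit:
            stage = "noise"
            report["noise_audit"] = _synthetic_noise_audit(config, out)
    except Exception as exc:  # noqa: BLE001 - halt with the stage name
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    _dump_json(report, out / "report.json")
    return report


def _synthetic_noise_audit(config: PipelineConfig, out: Path) -> dict:
    """Noise audit on synthesized recordings covering the upright design."""
    from .cohort import DIRECTIONS_DEG, TARGET_DISTANCES
    from .motion import target_profile

    rng = np.random.default_rng(config.cohort.seed + 1)
    test_profile = build_test_profile(
        solve_test_profile(TEST_PEAK_ACCEL, TEST_TOTAL_TIME, TEST_TOTAL_DISTANCE)
    )
    recordings = []
    for direction in DIRECTIONS_DEG:
        for distance in TARGET_DISTANCES:
            prof = target_profile(distance)
            recordings.append(
                preprocess_imu(synthesize_imu(
                    prof, direction, config.noise_sd_per_axis, seed=rng,
                    target_distance=distance, phase="target",
                ))
            )
        recordings.append(
            preprocess_imu(synthesize_imu(
                test_profile, direction, config.noise_sd_per_axis, seed=rng, phase="test",
            ))
        )
    audit = noise_vs_threshold(recordings)
    audit.table.to_csv(out / "noise_audit.csv", index=False)
    _dump_json(audit.to_dict(), out / "noise_audit.json")
    return audit.to_dict()
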