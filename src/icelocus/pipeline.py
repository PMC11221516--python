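"""End-to-end analysis pipeline: locate -> sectors -> null -> spectra.

A run is described by a :class:`RunConfig` (JSON or YAML on disk). Inputs
are either image stacks, which are localized first, or a ready-made onset
CSV. The report carries the sector summary, the Monte Carlo null and AWI
decision, the freezing spectrum, optional per-stack front velocities, and
provenance (seed and config hash), so that a rerun with the same config is
byte-identical apart from nothing — timestamps are deliberately omitted.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import geometry as geom
from . import io as iio
from . import locate as loc
from . import mcnull, spectra, velocity as vel

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "load_config"]

log = logging.getLogger("icelocus")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and input."""


@dataclass
class RunConfig:
    """Configuration of one analysis run."""

    onsets_csv: str | None = None
    stacks: list[str] = field(default_factory=list)
    n_sectors: int = 5
    mc_n_reps: int = 10_000
    seed: int = 0
    area_min_px: int = 25
    slide_spacing_um: float = 220.0
    blank_low_C: float = -30.0
    blank_high_C: float = -23.2
    track_velocity: bool = False
    out_dir: str | None = None

    def validate(self) -> None:
        if self.onsets_csv is None and not self.stacks:
            raise PipelineError(
                "configuration error: neither onsets_csv nor stacks given"
            )
        for p in ([self.onsets_csv] if self.onsets_csv else []) + list(self.stacks):
            if not any(ch in str(p) for ch in "*?[") and not Path(p).exists():
                raise PipelineError(f"configuration error: input path {p} not found")

    def hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def load_config(path: str | Path) -> RunConfig:
    """Read a RunConfig from JSON (YAML accepted)."""
    text = Path(path).read_text()
    data = yaml.safe_load(text)  # YAML is a superset of JSON
    return RunConfig(**data)


def _locate_stage(config: RunConfig) -> pd.DataFrame:
    rows = []
    for stack_path in config.stacks:
        try:
            stack = iio.read_stack(stack_path)
            geometry = loc.fit_droplet_circle(stack, config.slide_spacing_um)
            onset = loc.detect_onset(stack, geometry, config.area_min_px)
        except Exception as exc:  # surface the failing input
            raise PipelineError(f"stage locate failed on {stack_path}: {exc}") from exc
        row = {
            "droplet_id": Path(stack_path).stem,
            "cycle": 1,
            "r_norm": onset.r_norm,
            "theta_rad": onset.theta_rad,
            "temp_C": np.nan,
            "frame_index": onset.frame_index,
            "clamped": onset.clamped,
        }
        if config.track_velocity:
            try:
                track = vel.track_front(stack, onset, geometry)
                v, se = vel.fit_velocity(track)
                row["velocity_cm_s"] = v
                row["velocity_stderr"] = se
            except Exception as exc:
                raise PipelineError(
                    f"stage velocity failed on {stack_path}: {exc}"
                ) from exc
        rows.append(row)
        log.info("located onset in %s: r=%.3f frame=%d", stack_path, row["r_norm"], row["frame_index"])
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis and return (and optionally write) a report.

    Stages: localization (for image-stack inputs), equal-volume sector
    statistics, Monte Carlo bulk null + AWI decision, freezing-temperature
    spectrum with blank screening, and optional front-velocity fits.
    """
    config.validate()
    report: dict = {"config_hash": config.hash(), "seed": config.seed, "stages": []}
    failure = None
    try:
        if config.stacks:
            records = _locate_stage(config)
            report["stages"].append("locate")
        else:
            records = iio.read_onsets_csv(config.onsets_csv)
        if config.onsets_csv and config.stacks:
            extra = iio.read_onsets_csv(config.onsets_csv)
            records = pd.concat([records, extra], ignore_index=True)

        scheme = geom.SectorScheme(config.n_sectors)
        have_temps = "temp_C" in records and records["temp_C"].notna().any()
        if have_temps:
            screened, n_excluded = spectra.blank_screen(
                records.dropna(subset=["temp_C"]),
                (config.blank_low_C, config.blank_high_C),
            )
            report["blank_excluded"] = n_excluded
            report["stages"].append("blank_screen")
        else:
            screened = records

        try:
            summary = geom.summarize_sectors(screened, scheme)
        except Exception as exc:
            raise PipelineError(f"stage geometry failed: {exc}") from exc
        report["sector_summary"] = summary.to_dict()
        curve = geom.frozen_fraction_vs_volume(screened)
        report["frozen_fraction_curve"] = curve.to_numpy().tolist()
        report["stages"].append("geometry")

        try:
            null = mcnull.simulate_null(
                n_events=summary.n_events, n_reps=config.mc_n_reps, seed=config.seed
            )
        except Exception as exc:
            raise PipelineError(f"stage mcnull failed: {exc}") from exc
        report["null"] = null.to_dict()
        report["decision"] = mcnull.decide_awi(summary.outermost_frequency, null)
        report["stages"].append("mcnull")

        if have_temps:
            spec = spectra.compute_spectrum(screened["temp_C"].to_numpy())
            report["spectrum"] = spec.to_dict()
            report["stages"].append("spectra")

        if "velocity_cm_s" in records:
            report["velocities_cm_s"] = records["velocity_cm_s"].dropna().tolist()
            report["stages"].append("velocity")
    except PipelineError as exc:
        failure = str(exc)
        report["failure"] = failure
        log.error("%s", failure)

    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(json.dumps(report, indent=2))
        if failure:
            (out / "FAILED.json").write_text(json.dumps({"failure": failure}))
    if failure:
        raise PipelineError(failure)
    return report
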