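"""End-to-end orchestration: image pairs + cohort table -> metric tables.

The pipeline applies, per eye and per threshold radius:
compensate -> binarize -> component metrics, then assembles the cohort
outputs (per-eye metrics CSV, per-radius sensitivity summary,
group-comparison table, regression screen report, log-log fit).  A run
manifest records package version, configuration hash and seed so a run
can be reproduced byte-identically.

Per-eye failures (missing or unreadable scans) are logged and skipped so
one corrupt scan does not void a cohort run; an empty manifest is fatal.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import __version__
from .binarization import PhansalkarParams, binarize
from .compensation import CompensationParams, compensate
from .cohort_stats import build_table2, loglog_size_number_fit, regression_screen
from .fd_quantification import FDMetrics, compute_metrics, sensitivity_analysis
from .image_io import DEFAULT_PITCH_UM, EnFaceImage, read_cohort, read_enface

logger = logging.getLogger("ccfd.pipeline")

__all__ = ["RunConfig", "quantify_eye", "run_pipeline"]

DEFAULT_RADII = (4, 8, 10, 15)


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one pipeline run.

    ``manifest_path`` names a CSV with columns ``eye_id, flow_path,
    structure_path``; image paths are resolved relative to the manifest's
    directory.  ``radii`` lists the Phansalkar window radii to quantify
    (the first radius is the primary analysis, the rest feed the
    sensitivity table).
    """

    manifest_path: str
    output_dir: str
    cohort_path: str | None = None
    radii: tuple[int, ...] = DEFAULT_RADII
    pixel_pitch_um: float = DEFAULT_PITCH_UM
    blur_sigma_px: float = 2.0
    phansalkar_k: float = 0.25
    phansalkar_r_norm: float = 0.5
    phansalkar_p: float = 2.0
    phansalkar_q: float = 10.0
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if len(self.radii) == 0 or any(r < 1 for r in self.radii):
            raise ValueError(f"radii must be nonempty and positive, got {self.radii}")

    def phansalkar_params(self, radius_px: int) -> PhansalkarParams:
        return PhansalkarParams(
            radius_px=radius_px,
            k=self.phansalkar_k,
            r_norm=self.phansalkar_r_norm,
            p=self.phansalkar_p,
            q=self.phansalkar_q,
        )

    def compensation_params(self) -> CompensationParams:
        return CompensationParams(blur_sigma_px=self.blur_sigma_px)

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()


def quantify_eye(
    flow: EnFaceImage,
    structure: EnFaceImage,
    radii: Sequence[int] = (15,),
    comp_params: CompensationParams = CompensationParams(),
    base_phansalkar: PhansalkarParams = PhansalkarParams(),
) -> tuple[EnFaceImage, list[FDMetrics]]:
    """Compensate one eye and quantify its FDs at each radius."""
    compensated = compensate(flow, structure, comp_params)
    metrics = []
    for radius in radii:
        params = dataclasses.replace(base_phansalkar, radius_px=int(radius))
        metrics.append(compute_metrics(binarize(compensated, params)))
    return compensated, metrics


def _read_manifest(path: Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str)
    required = ["eye_id", "flow_path", "structure_path"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: manifest missing column(s) {missing}")
    if len(df) == 0:
        raise ValueError(f"{path}: manifest lists no eyes")
    return df


def run_pipeline(config: RunConfig) -> dict[str, object]:
    """Run the full quantification + statistics pipeline.

    Returns a dict of the artifacts written (paths and in-memory tables).
    """
    logging.basicConfig(level=config.log_level)
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest_path = Path(config.manifest_path)
    manifest = _read_manifest(manifest_path)
    base = manifest_path.parent

    per_eye_rows: list[dict[str, object]] = []
    compensated_images: list[EnFaceImage] = []
    failures: list[dict[str, str]] = []
    for _, row in manifest.iterrows():
        eye_id = str(row["eye_id"])
        try:
            flow = read_enface(
                base / row["flow_path"],
                pixel_pitch_um=config.pixel_pitch_um,
                modality="flow",
                eye_id=eye_id,
            )
            structure = read_enface(
                base / row["structure_path"],
                pixel_pitch_um=config.pixel_pitch_um,
                modality="structure",
                eye_id=eye_id,
            )
            compensated, metrics = quantify_eye(
                flow,
                structure,
                radii=config.radii,
                comp_params=config.compensation_params(),
                base_phansalkar=config.phansalkar_params(config.radii[0]),
            )
        except (OSError, ValueError) as exc:
            logger.error("eye %s failed: %s", eye_id, exc)
            failures.append({"eye_id": eye_id, "error": str(exc)})
            continue
        compensated_images.append(compensated)
        per_eye_rows.extend(m.as_row() for m in metrics)
    if not per_eye_rows:
        raise RuntimeError("no eye could be processed; aborting run")

    metrics_df = pd.DataFrame(per_eye_rows)
    metrics_csv = out_dir / "per_eye_metrics.csv"
    metrics_df.to_csv(metrics_csv, index=False)

    summary_df = sensitivity_analysis(
        compensated_images, config.radii, config.phansalkar_params(config.radii[0])
    )
    summary_csv = out_dir / "radius_sensitivity.csv"
    summary_df.to_csv(summary_csv, index=False)

    artifacts: dict[str, object] = {
        "per_eye_metrics": metrics_df,
        "per_eye_metrics_csv": str(metrics_csv),
        "radius_sensitivity": summary_df,
        "radius_sensitivity_csv": str(summary_csv),
        "failures": failures,
    }

    if config.cohort_path is not None:
        cohort = read_cohort(config.cohort_path)
        artifacts.update(_run_stats(cohort, out_dir))

    run_manifest = {
        "ccfd_version": __version__,
        "config": dataclasses.asdict(config),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "n_eyes_processed": len(compensated_images),
        "n_eyes_failed": len(failures),
    }
    manifest_json = out_dir / "run_manifest.json"
    manifest_json.write_text(json.dumps(run_manifest, indent=2, sort_keys=True))
    artifacts["run_manifest_json"] = str(manifest_json)
    return artifacts


def _run_stats(cohort, out_dir: Path) -> dict[str, object]:
    """Cohort statistics artifacts (group comparison, screens, log-log)."""
    artifacts: dict[str, object] = {}
    counts = cohort.group_counts()
    if counts["non_neovascular"] > 0 and counts["neovascular"] > 0:
        table2 = build_table2(cohort)
        path = out_dir / "group_comparison.csv"
        table2.table.to_csv(path, index=False)
        artifacts["group_comparison"] = table2
        artifacts["group_comparison_csv"] = str(path)

    df = cohort.to_frame()
    if "fd_percent" in df.columns:
        screens = []
        for outcome in ("fd_percent", "mean_fd_size_um2", "n_fd"):
            try:
                screens.append(regression_screen(df, outcome).to_frame())
            except ValueError as exc:
                logger.warning("regression screen for %s skipped: %s", outcome, exc)
        if screens:
            reg_df = pd.concat(screens, ignore_index=True)
            path = out_dir / "regression_screen.csv"
            reg_df.to_csv(path, index=False)
            artifacts["regression_screen"] = reg_df
            artifacts["regression_screen_csv"] = str(path)
        positive = df[(df["n_fd"] > 0) & (df["mean_fd_size_um2"] > 0)]
        if len(positive) >= 3:
            fit = loglog_size_number_fit(
                positive["n_fd"].to_numpy(), positive["mean_fd_size_um2"].to_numpy()
            )
            path = out_dir / "loglog_fit.json"
            path.write_text(
                json.dumps(
                    {
                        "slope": fit.slope,
                        "intercept_log10": fit.intercept,
                        "r_squared": fit.r_squared,
                        "slope_se": fit.slope_se,
                        "slope_ci": list(fit.slope_ci),
                        "n": fit.n,
                    },
                    indent=2,
                )
            )
            artifacts["loglog_fit"] = fit
            artifacts["loglog_fit_json"] = str(path)
    return artifacts
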