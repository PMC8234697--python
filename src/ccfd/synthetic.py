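"""Synthetic en face scenes and cohort tables with known ground truth.

No per-eye scan data are publicly deposited for this kind of study, so
every pipeline stage is exercised against synthetic material generated
here:

* :func:`generate_scene` builds a co-registered flow/structure slab pair
  with a known flow-deficit mask and a known drusen attenuation field.
  The deficit geometry comes from quantile-thresholding a smoothed noise
  field, which yields the irregular, scale-controllable morphology of
  real choriocapillaris deficit maps and exact control of the planted
  area fraction.  Drusen shadows are soft-edged discs that multiply both
  channels by the same attenuation factor — the multiplicative artifact
  the compensation step is designed to remove.

* :func:`generate_cohort` samples per-eye covariates and plants linear
  covariate effects on the FD metrics, plus a log-log law coupling FD
  count to FD size, so that the statistical layer can be validated by
  parameter recovery.

All randomness flows through one ``numpy`` Generator keyed by ``seed``;
identical parameters and seed give bit-identical output.  Drusen
parameters are drawn last, so scenes with and without drusen share the
same deficit mask and noise realization for paired comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
from scipy import ndimage

from .image_io import DEFAULT_PITCH_UM, CohortTable, EnFaceImage, EyeRecord

__all__ = [
    "SceneParams",
    "SceneTruth",
    "CohortSimParams",
    "generate_scene",
    "generate_cohort",
]


@dataclass(frozen=True)
class SceneParams:
    """Parameters of one synthetic scene.

    Defaults are calibrated to the operating point of published
    choriocapillaris studies: a deficit fraction near 0.45, a dark flow
    slab (mean intensity ~0.2-0.3, where the Phansalkar exponential term
    makes shadowing consequential), and a drusen load covering roughly a
    quarter of the 3 x 3 mm field with 105-280 um radius soft shadows at
    attenuation 0.6.
    """

    size_px: int = 512
    pitch_um: float = DEFAULT_PITCH_UM
    target_fd_fraction: float = 0.45
    fd_texture_scale_px: float = 6.0
    flow_level: float = 0.30
    deficit_level: float = 0.12
    structure_level: float = 0.62
    noise_sd: float = 0.05
    n_drusen: int = 24
    drusen_radius_px: tuple[float, float] = (18.0, 48.0)
    attenuation: float = 0.6
    drusen_edge_sigma_px: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.size_px < 8:
            raise ValueError(f"size_px must be >= 8, got {self.size_px}")
        if not 0.0 <= self.target_fd_fraction <= 1.0:
            raise ValueError(f"target_fd_fraction must be in [0, 1], got {self.target_fd_fraction}")
        for name in ("flow_level", "deficit_level", "structure_level"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.noise_sd < 0:
            raise ValueError(f"noise_sd must be >= 0, got {self.noise_sd}")
        if not 0.0 < self.attenuation <= 1.0:
            raise ValueError(f"attenuation must be in (0, 1], got {self.attenuation}")
        if self.n_drusen < 0:
            raise ValueError(f"n_drusen must be >= 0, got {self.n_drusen}")
        lo, hi = self.drusen_radius_px
        if lo <= 0 or hi < lo:
            raise ValueError(f"invalid drusen_radius_px range {self.drusen_radius_px}")


@dataclass
class SceneTruth:
    """Ground truth of a synthetic scene: deficit mask and attenuation."""

    fd_mask: np.ndarray
    attenuation_field: np.ndarray
    realized_fd_fraction: float
    params: SceneParams


def _deficit_mask(rng: np.random.Generator, params: SceneParams) -> np.ndarray:
    s = params.size_px
    noise = rng.standard_normal((s, s))
    target = params.target_fd_fraction
    if target in (0.0, 1.0) and params.fd_texture_scale_px == 0:
        raise ValueError(
            "target_fd_fraction of exactly 0 or 1 is infeasible with zero texture scale"
        )
    if target == 0.0:
        return np.zeros((s, s), dtype=bool)
    if target == 1.0:
        return np.ones((s, s), dtype=bool)
    if params.fd_texture_scale_px > 0:
        field_arr = ndimage.gaussian_filter(noise, params.fd_texture_scale_px, mode="reflect")
    else:
        field_arr = noise
    return field_arr <= np.quantile(field_arr, target)


def _attenuation_field(rng: np.random.Generator, params: SceneParams) -> np.ndarray:
    s = params.size_px
    if params.n_drusen == 0 or params.attenuation == 1.0:
        return np.ones((s, s))
    centers = rng.uniform(0, s, size=(params.n_drusen, 2))
    lo, hi = params.drusen_radius_px
    radii = rng.uniform(lo, hi, size=params.n_drusen)
    yy, xx = np.mgrid[0:s, 0:s]
    inside = np.zeros((s, s), dtype=bool)
    for (cy, cx), r in zip(centers, radii):
        inside |= (yy - cy) ** 2 + (xx - cx) ** 2 <= r * r
    field_arr = np.where(inside, params.attenuation, 1.0)
    if params.drusen_edge_sigma_px > 0:
        field_arr = ndimage.gaussian_filter(
            field_arr, params.drusen_edge_sigma_px, mode="reflect"
        )
    return np.clip(field_arr, params.attenuation, 1.0)


def generate_scene(
    params: SceneParams = SceneParams(),
) -> tuple[EnFaceImage, EnFaceImage, SceneTruth]:
    """Generate a co-registered (flow, structure) pair with ground truth.

    The flow slab takes ``flow_level`` on flow pixels and
    ``deficit_level`` on deficit pixels plus Gaussian noise; the
    structure slab is a uniform bright field plus independent noise.
    Both are multiplied by the same attenuation field.  Deterministic in
    ``params.seed``.
    """
    rng = np.random.default_rng(params.seed)
    fd_mask = _deficit_mask(rng, params)
    s = params.size_px
    flow_base = np.where(fd_mask, params.deficit_level, params.flow_level)
    flow_noise = rng.normal(0.0, params.noise_sd, (s, s)) if params.noise_sd else 0.0
    struct_noise = rng.normal(0.0, params.noise_sd, (s, s)) if params.noise_sd else 0.0
    attenuation = _attenuation_field(rng, params)
    flow_px = np.clip(flow_base + flow_noise, 0.0, 1.0) * attenuation
    struct_px = np.clip(params.structure_level + struct_noise, 0.0, 1.0) * attenuation
    eye_id = f"synthetic-{params.seed}"
    flow = EnFaceImage(flow_px, params.pitch_um, "flow", eye_id)
    structure = EnFaceImage(struct_px, params.pitch_um, "structure", eye_id)
    truth = SceneTruth(
        fd_mask=fd_mask,
        attenuation_field=attenuation,
        realized_fd_fraction=float(fd_mask.mean()),
        params=params,
    )
    return flow, structure, truth


@dataclass(frozen=True)
class CohortSimParams:
    """Parameters of the cohort simulator.

    Covariate distributions default to the profile of an elderly AMD
    fellow-eye cohort (age ~ N(79, 7.7), CT ~ N(209, 83) um, etc.; flag
    prevalences near 2/3 for drusen, ~0.2 for atrophy).  Effects are
    linear on the stated outcome scale; the FD% model is
    ``fd_percent = intercept + sum(effect_j * x_j) + N(0, residual_sd)``
    and the size-count coupling is
    ``log10(n_fd) = loglog_intercept + loglog_slope * log10(size) + eps``.
    """

    n_eyes: int = 89
    seed: int = 0
    age_mean: float = 79.0
    age_sd: float = 7.7
    bcva_mean: float = 0.18
    bcva_sd: float = 0.2
    cmt_mean: float = 232.0
    cmt_sd: float = 44.0
    ct_mean: float = 209.0
    ct_sd: float = 83.0
    flag_prevalence: Mapping[str, float] = field(
        default_factory=lambda: {
            "small_drusen": 0.66,
            "large_drusen": 0.73,
            "drusenoid_ped": 0.42,
            "rpd": 0.56,
            "atrophy": 0.21,
        }
    )
    fd_intercept: float = -3.0
    fd_effects: Mapping[str, float] = field(default_factory=lambda: {"age_years": 0.62})
    fd_residual_sd: float = 10.0
    size_log10_intercept: float = 3.55
    size_effects: Mapping[str, float] = field(default_factory=dict)
    size_log10_residual_sd: float = 0.2
    loglog_slope: float = -0.0604
    loglog_intercept: float = 3.3556
    count_log10_residual_sd: float = 0.05

    def __post_init__(self) -> None:
        if self.n_eyes < 3:
            raise ValueError(f"n_eyes must be >= 3, got {self.n_eyes}")
        for name, p in self.flag_prevalence.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"prevalence of {name!r} must be in [0, 1], got {p}")


def generate_cohort(params: CohortSimParams = CohortSimParams()) -> CohortTable:
    """Simulate a non-neovascular cohort with planted covariate effects.

    FD% follows its own linear model while FD size and count follow the
    planted log-log law; the two are deliberately not tied through the
    per-image area identity (a cohort-level emulator, not an image
    model).  Raises if the planted FD% model leaves [0, 100] in more
    than 1% of draws.
    """
    from .fd_quantification import FDMetrics

    rng = np.random.default_rng(params.seed)
    n = params.n_eyes
    cov = {
        "age_years": np.clip(rng.normal(params.age_mean, params.age_sd, n), 50.0, 105.0),
        "bcva_logmar": np.clip(rng.normal(params.bcva_mean, params.bcva_sd, n), 0.0, 2.0),
        "cmt_um": np.clip(rng.normal(params.cmt_mean, params.cmt_sd, n), 120.0, None),
        "ct_um": np.clip(rng.normal(params.ct_mean, params.ct_sd, n), 60.0, None),
    }
    flags = {
        name: rng.random(n) < p for name, p in params.flag_prevalence.items()
    }
    values = dict(cov)
    values.update({k: v.astype(float) for k, v in flags.items()})

    def linear(intercept: float, effects: Mapping[str, float]) -> np.ndarray:
        out = np.full(n, intercept)
        for name, beta in effects.items():
            out = out + beta * values[name]
        return out

    fd_percent = linear(params.fd_intercept, params.fd_effects) + rng.normal(
        0.0, params.fd_residual_sd, n
    )
    out_of_range = np.mean((fd_percent < 0) | (fd_percent > 100))
    if out_of_range > 0.01:
        raise ValueError(
            f"planted FD% model leaves [0, 100] in {100 * out_of_range:.1f}% of draws"
        )
    fd_percent = np.clip(fd_percent, 0.0, 100.0)
    log_size = linear(params.size_log10_intercept, params.size_effects) + rng.normal(
        0.0, params.size_log10_residual_sd, n
    )
    log_count = (
        params.loglog_intercept
        + params.loglog_slope * log_size
        + rng.normal(0.0, params.count_log10_residual_sd, n)
    )
    size_um2 = 10.0**log_size
    n_fd = np.maximum(1, np.rint(10.0**log_count).astype(int))
    records = []
    for i in range(n):
        metrics = FDMetrics(
            fd_percent=float(fd_percent[i]),
            n_fd=int(n_fd[i]),
            mean_fd_size_um2=float(size_um2[i]),
            total_fd_area_mm2=float(n_fd[i] * size_um2[i] * 1e-6),
            component_sizes_px=None,
            eye_id=f"sim-{params.seed}-{i:03d}",
        )
        records.append(
            EyeRecord(
                eye_id=metrics.eye_id,
                group="non_neovascular",
                age_years=float(cov["age_years"][i]),
                bcva_logmar=float(cov["bcva_logmar"][i]),
                cmt_um=float(cov["cmt_um"][i]),
                ct_um=float(cov["ct_um"][i]),
                small_drusen=bool(flags["small_drusen"][i]),
                large_drusen=bool(flags["large_drusen"][i]),
                drusenoid_ped=bool(flags["drusenoid_ped"][i]),
                rpd=bool(flags["rpd"][i]),
                atrophy=bool(flags["atrophy"][i]),
                metrics=metrics,
            )
        )
    return CohortTable(records)
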