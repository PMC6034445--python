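"""End-to-end venation extraction pipeline.

Ties the stages together — ambient subtraction, foreground segmentation,
normal recovery, curvature, Gabor fusion, binarisation, polarity — under a
single serialisable configuration, with per-stage error reporting and a
deterministic JSON report.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import yaml
from scipy import ndimage

from . import io as lvio
from .curvature import CurvatureMaps, shape_weight_map
from .photometric import (
    GradientField,
    PSStack,
    integrate_depth,
    segment_foreground,
    solve_normals,
    subtract_ambient,
)
from .venation import (
    GaborBankConfig,
    VenationResult,
    binarize_venation,
    determine_polarity,
    gabor_response,
    venation_response,
)

__all__ = ["PipelineConfig", "PipelineError", "PipelineResult", "run_pipeline"]


class PipelineError(RuntimeError):
    """A stage failure, carrying the name of the stage that raised it."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        self.cause = cause
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")


@dataclass(frozen=True)
class PipelineConfig:
    """All tunables of one pipeline run.

    ``min_region_frac`` is the small-region cleanup size as a fraction of
    the foreground area (default 1e-4, i.e. 0.01%).  ``mask_erosion_px``
    shrinks the analysis mask away from the leaf outline so the curvedness
    step at the blade boundary cannot leak into the statistics.
    ``polarity`` is ``auto`` (dual-score rule) or forced to ``positive`` /
    ``negative``.  The config round-trips through YAML unchanged.
    """

    stack_dir: str | None = None
    out_dir: str | None = None
    lights_path: str | None = None
    smoothing_sigma_px: float = 2.0
    gabor_orientations: int = 10
    gabor_wavelength: float = 10.0
    gabor_bandwidth: float = 1.0
    butterworth_order: float = 4.0
    butterworth_cutoff: float = 0.4
    pseudo_factor: float = 1.2
    min_region_frac: float = 1e-4
    mask_erosion_px: int = 2
    polarity: str = "auto"
    seed: int = 0

    def __post_init__(self):
        if self.smoothing_sigma_px <= 0:
            raise ValueError("smoothing_sigma_px must be positive")
        if self.polarity not in ("auto", "positive", "negative"):
            raise ValueError("polarity must be auto, positive or negative")
        if not 0 <= self.min_region_frac < 1:
            raise ValueError("min_region_frac must lie in [0, 1)")
        if self.mask_erosion_px < 0:
            raise ValueError("mask_erosion_px must be non-negative")

    def gabor_config(self) -> GaborBankConfig:
        return GaborBankConfig(
            n_orientations=self.gabor_orientations,
            wavelength=self.gabor_wavelength,
            bandwidth=self.gabor_bandwidth,
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


@dataclass
class PipelineResult:
    """All intermediates and the final report of one run."""

    corrected: PSStack
    foreground: np.ndarray
    analysis_mask: np.ndarray
    gradients: GradientField
    curvature: CurvatureMaps
    venation: VenationResult
    report: dict


def _stage(name):
    """Decorator-free stage wrapper: call fn, re-raise with the stage name."""
    class _Ctx:
        def __init__(self, stage_name):
            self.name = stage_name

        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, PipelineError):
                raise PipelineError(self.name, exc) from exc
            return False

    return _Ctx(name)


def run_pipeline(
    config: PipelineConfig,
    stack: PSStack | None = None,
) -> PipelineResult:
    """Run the full extraction on a stack (loaded from disk if not given).

    When ``config.out_dir`` is set, intermediates are flushed to disk as
    each stage completes, so a later failure still leaves the earlier
    products on disk.  Identical config and inputs produce byte-identical
    reports.
    """
    out = Path(config.out_dir) if config.out_dir else None
    if out:
        out.mkdir(parents=True, exist_ok=True)

    with _stage("load"):
        if stack is None:
            if config.stack_dir is None:
                raise ValueError("no stack given and no stack_dir configured")
            stack = lvio.read_stack(config.stack_dir, config.lights_path)

    with _stage("ambient_subtraction"):
        corrected = subtract_ambient(stack)

    with _stage("foreground_segmentation"):
        mean_frame = corrected.frames.mean(axis=0)
        foreground = segment_foreground(mean_frame)
        analysis_mask = foreground
        if config.mask_erosion_px > 0:
            analysis_mask = ndimage.binary_erosion(
                foreground, iterations=config.mask_erosion_px)
    if out:
        lvio.write_mask(foreground, out / "foreground.png")

    with _stage("normal_recovery"):
        gradients = solve_normals(corrected)
    if out:
        lvio.write_float_map(gradients.p, out / "p.tif")
        lvio.write_float_map(gradients.q, out / "q.tif")
        lvio.write_float_map(gradients.albedo, out / "albedo.tif")
        lvio.write_mask(gradients.valid, out / "valid.png")
        lvio.write_float_map(integrate_depth(gradients).z, out / "depth.tif")

    with _stage("curvature"):
        curv = CurvatureMaps.from_gradients(
            gradients, sigma_px=config.smoothing_sigma_px)
    if out:
        lvio.write_float_map(curv.k1, out / "k1.tif")
        lvio.write_float_map(curv.k2, out / "k2.tif")
        lvio.write_float_map(np.nan_to_num(curv.s), out / "shape_index.tif")
        lvio.write_float_map(curv.c, out / "curvedness.tif")

    with _stage("gabor"):
        g_map = gabor_response(curv.c, config.gabor_config(),
                               mask=analysis_mask)
    if out:
        lvio.write_float_map(g_map, out / "gabor.tif")

    with _stage("polarity"):
        pol = determine_polarity(
            curv.s, g_map, factor=config.pseudo_factor, mask=analysis_mask,
            sigma=config.butterworth_order, omega=config.butterworth_cutoff,
            planar=curv.planar,
        )
        if config.polarity == "auto":
            if pol.verdict == "undetermined":
                raise ValueError(
                    "polarity undetermined (tied or zero scores); "
                    "force a polarity to proceed"
                )
            chosen = pol.verdict
        else:
            chosen = config.polarity

    with _stage("fusion"):
        sw = shape_weight_map(
            curv.s, "ridge" if chosen == "positive" else "rut",
            sigma=config.butterworth_order, omega=config.butterworth_cutoff,
            planar=curv.planar,
        )
        v_map = venation_response(sw, g_map)
    if out:
        lvio.write_float_map(sw.weights, out / "shape_weight.tif")
        lvio.write_float_map(v_map, out / "venation_response.tif")

    with _stage("binarisation"):
        min_px = max(1, int(round(
            config.min_region_frac * np.count_nonzero(foreground))))
        vein_mask = binarize_venation(v_map, min_region_px=min_px,
                                      mask=analysis_mask)
        from .venation import pseudo_venation
        pseudo = pseudo_venation(g_map, factor=config.pseudo_factor,
                                 mask=analysis_mask)

    venation = VenationResult(
        gabor=g_map, response=v_map, vein_mask=vein_mask,
        pseudo_mask=pseudo, polarity=pol,
    )

    from . import __version__
    report = {
        "version": __version__,
        "polarity": chosen,
        "polarity_mode": config.polarity,
        "ridge_score": pol.ridge_score,
        "rut_score": pol.rut_score,
        "vein_pixels": int(np.count_nonzero(vein_mask)),
        "foreground_pixels": int(np.count_nonzero(foreground)),
        "min_region_px": min_px,
        "parameters": asdict(config),
    }
    if out:
        lvio.write_mask(vein_mask, out / "vein_mask.png")
        lvio.write_mask(pseudo, out / "pseudo_venation.png")
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)

    return PipelineResult(
        corrected=corrected, foreground=foreground,
        analysis_mask=analysis_mask, gradients=gradients, curvature=curv,
        venation=venation, report=report,
    )
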