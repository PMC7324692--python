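"""Orchestration of the four monthly MVCT QA tests, baseline management,
tolerance configuration and report assembly.

The canonical machine-readable result is the JSON report; the one-page PDF
is a rendering of it (see :mod:`phantomqa.report`).  Baselines persist the
numbers a later run is compared against.  Noise and uniformity baselines are
displayed for reference only and never graded against baseline: uniformity
is graded against its absolute tolerance, noise is purely informational.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np

from . import layout
from .dicom_io import Volume, read_series
from .errors import BaselineFormatError, QAError
from .image_quality import (
    NoiseResult,
    PlugMeasurement,
    UniformityResult,
    contrast_test,
    measure_contrast,
    noise_test,
    select_contrast_slice,
    select_uniform_slice,
    uniformity_test,
)
from .phantom_geometry import (
    GeometricResult,
    MarkerSet,
    detect_markers,
    estimate_rotation,
    geometric_test,
    longitudinal_distance,
    transaxial_distances,
)
from .resolution import (
    ResolutionResult,
    locate_resolution_plug,
    record_visual_grade,
    window_plug_image,
)

__version__ = "0.1.0"
FORMAT_VERSION = "1"
SUPPORTED_FORMAT_VERSIONS = ("1",)

log = logging.getLogger("phantomqa")


@dataclass
class ToleranceConfig:
    """Every tunable parameter of the QA analysis, with TG-148-style defaults.

    ``mode`` selects the geometric tolerance (1 mm for SRS/SBRT, 2 mm
    otherwise); ``dose_calc`` selects the uniformity tolerance (25 HU when
    the images feed dose calculation, 30 HU for imaging-only use) unless
    ``uniformity_tolerance_hu`` overrides it explicitly.
    """

    mode: str = "srs"  # "srs" | "non_srs"
    dose_calc: bool = True
    uniformity_tolerance_hu: Optional[float] = None
    contrast_tolerances_hu: tuple[float, float] = (30.0, 50.0)
    water_like_limit_hu: float = 100.0
    per_plug_tolerance_hu: dict = field(default_factory=dict)  # label -> HU
    noise_reference_band_hu: tuple[float, float] = (50.0, 70.0)
    resolution_criterion_mm: float = 1.6
    roi_diameter_mm: float = 10.0
    periphery_radius_mm: float = 105.0
    big_roi_diameter_mm: float = 60.0
    resolution_roi_diameter_mm: float = 14.0
    marker_threshold_hu: float = 800.0
    marker_area_px: tuple[int, int] = (2, 200)
    body_threshold_hu: float = -300.0
    uniform_offset_mm: float = 10.0
    contrast_offset_mm: float = 50.0
    uniform_direction: Optional[int] = None
    contrast_direction: Optional[int] = None
    resolution_hole_index: Optional[int] = None
    resolution_offset_mm: Optional[float] = None
    selected_plugs: Optional[list[int]] = None  # hole indices; None -> all
    marker_layout_mm: list = field(
        default_factory=lambda: layout.DEFAULT_MARKER_POSITIONS_MM.tolist()
    )
    plug_layout_mm: list = field(
        default_factory=lambda: [list(h) for h in layout.default_plug_layout()]
    )
    format_version: str = FORMAT_VERSION

    def __post_init__(self) -> None:
        if self.mode not in ("srs", "non_srs"):
            raise ValueError(f"mode must be 'srs' or 'non_srs', got {self.mode!r}")
        for tol in (*self.contrast_tolerances_hu, self.resolution_criterion_mm):
            if tol <= 0:
                raise ValueError("tolerances must be positive")
        if self.uniformity_tolerance_hu is not None and self.uniformity_tolerance_hu <= 0:
            raise ValueError("tolerances must be positive")

    @property
    def geometric_tolerance_mm(self) -> float:
        return 1.0 if self.mode == "srs" else 2.0

    @property
    def effective_uniformity_tolerance_hu(self) -> float:
        if self.uniformity_tolerance_hu is not None:
            return self.uniformity_tolerance_hu
        return 25.0 if self.dose_calc else 30.0

    def to_dict(self) -> dict:
        d = asdict(self)
        d["contrast_tolerances_hu"] = list(self.contrast_tolerances_hu)
        d["noise_reference_band_hu"] = list(self.noise_reference_band_hu)
        d["marker_area_px"] = list(self.marker_area_px)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ToleranceConfig":
        d = dict(d)
        for key in ("contrast_tolerances_hu", "noise_reference_band_hu",
                    "marker_area_px"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def load(cls, path) -> "ToleranceConfig":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))


@dataclass
class BaselineRecord:
    """Persisted results of a prior QA run, used for all consistency tests."""

    machine_id: str
    acquisition_date: str
    distances_mm: dict  # {"d_ab", "d_bc", "d_ca", "d_bd"}
    uniformity_hu: float
    noise_small_hu: float
    noise_big_hu: float
    contrast: list  # [{"label": str, "hu": float}, ...]
    config: dict = field(default_factory=dict)
    format_version: str = FORMAT_VERSION

    def __post_init__(self) -> None:
        if len(self.contrast) < 1:
            raise BaselineFormatError("baseline needs at least one contrast entry")

    def distance_tuple(self) -> tuple[float, float, float, float]:
        d = self.distances_mm
        return (d["d_ab"], d["d_bc"], d["d_ca"], d["d_bd"])

    def contrast_hus(self) -> list[float]:
        return [float(e["hu"]) for e in self.contrast]

    def contrast_labels(self) -> list[str]:
        return [str(e.get("label", f"plug {i}")) for i, e in enumerate(self.contrast)]


def save_baseline(record: BaselineRecord, path) -> None:
    """Serialize a baseline to JSON (floats round-trip exactly)."""
    Path(path).write_text(json.dumps(asdict(record), indent=2, sort_keys=True))


def load_baseline(path) -> BaselineRecord:
    path = Path(path)
    try:
        data = json.loads(path.read_text())
    except (OSError, json.JSONDecodeError) as exc:
        raise BaselineFormatError(f"cannot parse baseline file {path}: {exc}") from exc
    version = str(data.get("format_version", "?"))
    if version not in SUPPORTED_FORMAT_VERSIONS:
        raise BaselineFormatError(
            f"unsupported baseline version {version!r} in {path} "
            f"(supported: {SUPPORTED_FORMAT_VERSIONS})"
        )
    try:
        return BaselineRecord(**data)
    except TypeError as exc:
        raise BaselineFormatError(f"malformed baseline file {path}: {exc}") from exc


@dataclass
class QAReport:
    """Graded results of the four tests plus metadata.

    ``overall_status`` is recomputed from the per-test results: "pass" iff
    every graded test passed and the resolution was visually graded pass;
    "fail" if any graded test (or the visual grade) failed; "incomplete"
    otherwise.
    """

    machine_id: str = ""
    timestamp: str = ""
    program_version: str = __version__
    format_version: str = FORMAT_VERSION
    config: dict = field(default_factory=dict)
    rotation_deg: float = 0.0
    geometric: Optional[GeometricResult] = None
    uniformity: Optional[UniformityResult] = None
    noise: Optional[NoiseResult] = None
    contrast: list = field(default_factory=list)  # list[PlugMeasurement]
    resolution: Optional[ResolutionResult] = None
    baseline: Optional[dict] = None  # summary of the baseline used
    stage_errors: dict = field(default_factory=dict)
    figure_paths: dict = field(default_factory=dict)
    panels: dict = field(default_factory=dict, repr=False)  # arrays, not serialized

    @property
    def overall_status(self) -> str:
        verdicts: list[Optional[bool]] = []
        if self.geometric is not None:
            verdicts.append(self.geometric.passed)
        if self.uniformity is not None:
            verdicts.append(self.uniformity.passed)
        graded_plugs = [m.passed for m in self.contrast if m.passed is not None]
        if self.contrast:
            verdicts.append(all(graded_plugs) if graded_plugs else None)
        if self.resolution is not None and self.resolution.visual_grade != "ungraded":
            verdicts.append(self.resolution.visual_grade == "pass")
        else:
            verdicts.append(None)
        if any(v is False for v in verdicts):
            return "fail"
        if self.stage_errors or any(v is None for v in verdicts) or not verdicts:
            return "incomplete"
        return "pass"

    def to_dict(self) -> dict:
        def conv(obj):
            if isinstance(obj, (GeometricResult, UniformityResult, NoiseResult,
                                ResolutionResult, PlugMeasurement)):
                return conv(asdict(obj))
            if isinstance(obj, dict):
                return {str(k): conv(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [conv(v) for v in obj]
            if isinstance(obj, np.ndarray):
                return obj.tolist()
            if isinstance(obj, (np.floating, np.integer)):
                return obj.item()
            return obj

        d = {
            k: conv(v)
            for k, v in self.__dict__.items()
            if k != "panels"
        }
        d["overall_status"] = self.overall_status
        return d

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)

    def as_baseline(self, machine_id: Optional[str] = None,
                    acquisition_date: str = "") -> BaselineRecord:
        """Export this report's measurements as a new baseline record."""
        if self.geometric is None or self.uniformity is None or self.noise is None:
            raise QAError("report is missing results required for a baseline")
        g = self.geometric
        return BaselineRecord(
            machine_id=machine_id if machine_id is not None else self.machine_id,
            acquisition_date=acquisition_date or self.timestamp,
            distances_mm={
                "d_ab": g.d_ab_mm, "d_bc": g.d_bc_mm,
                "d_ca": g.d_ca_mm, "d_bd": g.d_bd_mm,
            },
            uniformity_hu=self.uniformity.max_abs_diff_hu,
            noise_small_hu=self.noise.sigma_small_hu,
            noise_big_hu=self.noise.sigma_big_hu,
            contrast=[
                {"label": m.label or f"hole {m.hole_index}", "hu": m.mean_hu}
                for m in self.contrast
            ],
            config=self.config,
        )


def _rotated_plug_centers(
    config: ToleranceConfig, rotation_deg: float
) -> dict[int, tuple[float, float]]:
    holes = np.array([[h[0], h[1]] for h in config.plug_layout_mm], dtype=float)
    rotated = layout.rotate_xy(holes, rotation_deg)
    selected = (
        config.selected_plugs
        if config.selected_plugs is not None
        else list(range(len(config.plug_layout_mm)))
    )
    return {int(i): (float(rotated[i, 0]), float(rotated[i, 1])) for i in selected}


def run_qa(
    dicom_folder,
    baseline: Union[BaselineRecord, str, Path, None] = None,
    config: Optional[ToleranceConfig] = None,
    grade_resolution: Optional[str] = None,
    machine_id: str = "",
    timestamp: str = "",
) -> QAReport:
    """Run the full QA pipeline on one DICOM series folder.

    Stages run in order (read -> markers -> geometry -> uniformity/noise ->
    contrast -> resolution).  Marker detection failure aborts (every stage
    needs the markers); any later stage error is recorded per stage and the
    remaining stages still run.  Without a baseline the consistency tests
    are left ungraded and marked as establishing a new baseline.
    """
    config = config or ToleranceConfig()
    if isinstance(baseline, (str, Path)):
        baseline = load_baseline(baseline)

    report = QAReport(
        machine_id=machine_id,
        timestamp=timestamp,
        config=config.to_dict(),
        baseline=None
        if baseline is None
        else {
            "machine_id": baseline.machine_id,
            "acquisition_date": baseline.acquisition_date,
            "distances_mm": baseline.distances_mm,
            "uniformity_hu": baseline.uniformity_hu,
            "noise_small_hu": baseline.noise_small_hu,
            "noise_big_hu": baseline.noise_big_hu,
            "contrast": baseline.contrast,
        },
    )

    t0 = time.perf_counter()
    volume = read_series(dicom_folder)
    log.info("read %d slices in %.2f s", volume.n_slices, time.perf_counter() - t0)

    t0 = time.perf_counter()
    markers = detect_markers(
        volume, config.marker_threshold_hu, config.marker_area_px
    )  # fatal by design: every later stage is anchored on the markers
    rotation = estimate_rotation(
        markers.centroids_mm, np.asarray(config.marker_layout_mm, dtype=float)
    )
    report.rotation_deg = rotation
    log.info(
        "markers at middle slice %d, rotation %g deg (%.2f s)",
        markers.middle_slice_index, rotation, time.perf_counter() - t0,
    )

    # -- geometric distortions -------------------------------------------
    t0 = time.perf_counter()
    try:
        d_ab, d_bc, d_ca = transaxial_distances(markers)
        d_bd = longitudinal_distance(volume, markers, config.body_threshold_hu)
        report.geometric = geometric_test(
            (d_ab, d_bc, d_ca, d_bd),
            baseline.distance_tuple() if baseline is not None else None,
            config.mode,
        )
    except QAError as exc:
        report.stage_errors["geometric"] = str(exc)
    log.info("geometric stage %.2f s", time.perf_counter() - t0)

    # -- uniformity and noise ---------------------------------------------
    t0 = time.perf_counter()
    try:
        report.uniformity = uniformity_test(
            volume, markers,
            roi_diameter_mm=config.roi_diameter_mm,
            periphery_radius_mm=config.periphery_radius_mm,
            tolerance_hu=config.effective_uniformity_tolerance_hu,
            offset_mm=config.uniform_offset_mm,
            direction=config.uniform_direction,
            body_threshold_hu=config.body_threshold_hu,
        )
    except QAError as exc:
        report.stage_errors["uniformity"] = str(exc)
    try:
        report.noise = noise_test(
            volume, markers,
            roi_diameter_mm=config.roi_diameter_mm,
            big_roi_diameter_mm=config.big_roi_diameter_mm,
            offset_mm=config.uniform_offset_mm,
            direction=config.uniform_direction,
            body_threshold_hu=config.body_threshold_hu,
        )
    except QAError as exc:
        report.stage_errors["noise"] = str(exc)
    log.info("uniformity/noise stage %.2f s", time.perf_counter() - t0)

    # -- contrast -----------------------------------------------------------
    t0 = time.perf_counter()
    plug_centers = _rotated_plug_centers(config, rotation)
    try:
        labels = {
            i: f"hole {i}" for i in plug_centers
        }
        measurements = measure_contrast(
            volume, markers, plug_centers,
            roi_diameter_mm=config.roi_diameter_mm,
            offset_mm=config.contrast_offset_mm,
            direction=config.contrast_direction,
            labels=labels,
        )
        if baseline is not None:
            measurements = contrast_test(
                measurements,
                baseline.contrast_hus(),
                baseline.contrast_labels(),
                tolerances_hu=config.contrast_tolerances_hu,
                water_like_limit_hu=config.water_like_limit_hu,
                per_plug_tolerance_hu=config.per_plug_tolerance_hu,
            )
        report.contrast = measurements
    except QAError as exc:
        report.stage_errors["contrast"] = str(exc)
    log.info("contrast stage %.2f s", time.perf_counter() - t0)

    # -- spatial resolution -------------------------------------------------
    t0 = time.perf_counter()
    try:
        all_centers = _rotated_plug_centers(
            ToleranceConfig.from_dict({**config.to_dict(), "selected_plugs": None}),
            rotation,
        )
        off, hole, sigma = locate_resolution_plug(
            volume, markers, all_centers,
            search_roi_diameter_mm=config.resolution_roi_diameter_mm,
            override_hole_index=config.resolution_hole_index,
            override_offset_mm=config.resolution_offset_mm,
        )
        slice_index = markers.middle_slice_index + int(
            round(off / volume.slice_thickness_mm)
        )
        sub, bounds = window_plug_image(volume, slice_index, all_centers[hole])
        report.resolution = ResolutionResult(
            found_slice_offset_mm=off,
            hole_index=hole,
            plug_sigma_hu=sigma,
            window_bounds_hu=bounds,
            criterion_mm=config.resolution_criterion_mm,
            manual_override=config.resolution_hole_index is not None,
        )
        report.panels["resolution"] = sub
        if grade_resolution is not None:
            report.resolution = record_visual_grade(report.resolution, grade_resolution)
    except QAError as exc:
        report.stage_errors["resolution"] = str(exc)
    log.info("resolution stage %.2f s", time.perf_counter() - t0)

    # -- figure panel source data -------------------------------------------
    report.panels["markers"] = volume.hu[markers.middle_slice_index]
    report.panels["marker_centroids_mm"] = markers.centroids_mm
    report.panels["pixel_spacing_mm"] = volume.meta.pixel_spacing_mm
    if report.uniformity is not None:
        report.panels["uniformity_slice"] = volume.hu[report.uniformity.slice_index]
    return report
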