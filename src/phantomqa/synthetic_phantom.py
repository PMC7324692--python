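"""Simulate MVCT series of the cylindrical cheese phantom with known ground
truth.

The simulator renders a water-equivalent cylinder (default 30 cm diameter x
18 cm long, body 0 HU) in air (-1024 HU) on a CT grid (default 512 x 512 at
0.76 mm pixels, 1 mm slices — the "fine" scan mode), with:

* three or four high-HU fiducial marker rods spanning a few slices at the
  phantom mid-plane,
* 20 peripheral plug holes on two concentric rings, fillable with density
  plugs of specified HU or left empty (air),
* a high-texture spatial-resolution plug insertable at +-35 mm or +-90 mm
  from the mid-plane,
* additive Gaussian image noise (quantized to integer HU, clamped at the
  scanner floor of -1024),
* in-plane phantom rotations of 0/90/180/270 degrees and injectable per-axis
  geometric scaling errors.

Voxels take a structure's HU when their centre lies inside the structure
(no antialiasing), so every geometric quantity has an exact analytic ground
truth, returned alongside the volume as :class:`GroundTruth`.

As on a real scanner, voxel values are integer HU: structure values are
rounded to the nearest integer at render time (``GroundTruth.plug_hu_map``
reports the rendered values) and noise is drawn from a zero-mean discrete
Gaussian — a 16-bit inverse-CDF quantization of N(0, sigma^2), whose
sample standard deviation matches ``noise_sigma_hu`` to better than 0.1%.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np
from scipy import ndimage
from scipy.special import ndtri

from . import layout
from .dicom_io import HU_MAX, HU_MIN, SeriesMeta, Volume
from .errors import LayoutConflictError

PlugContent = Union[float, str]  # HU value, "empty" (air) or "resolution"

#: Resolution-plug hole-pattern diameters (mm) drilled into its surface.
RESOLUTION_HOLE_DIAMETERS_MM = (0.8, 1.0, 1.2, 1.4, 1.6, 1.8, 2.0)
VALID_RESOLUTION_OFFSETS_MM = (35.0, -35.0, 90.0, -90.0)


def default_plug_contents() -> dict[int, PlugContent]:
    """Default insert layout: the seven reference density plugs in outer-ring
    holes 0-6, hole 7 ejected to measure air, resolution plug in hole 10."""
    contents: dict[int, PlugContent] = {
        i: hu for i, hu in enumerate(layout.PLUG_BASELINE_HU.values())
    }
    contents[7] = "empty"
    contents[10] = "resolution"
    return contents


def default_plug_labels() -> dict[int, str]:
    labels = {i: name for i, name in enumerate(layout.PLUG_BASELINE_HU)}
    labels[7] = "Air"
    return labels


@dataclass
class PhantomSpec:
    """Full parameterization of one simulated phantom acquisition."""

    diameter_mm: float = layout.PHANTOM_DIAMETER_MM
    length_mm: float = layout.PHANTOM_LENGTH_MM
    body_hu: float = 0.0
    background_hu: float = -1024.0
    marker_hu: float = 1100.0
    marker_diameter_mm: float = 4.0
    marker_length_mm: float = 3.0
    marker_positions: Optional[np.ndarray] = None  # (3|4, 2) mm; None -> default
    plug_layout: Optional[list[tuple[float, float, float]]] = None
    plug_contents: Optional[dict[int, PlugContent]] = None
    plug_labels: Optional[dict[int, str]] = None
    plug_hole_diameter_mm: float = layout.PLUG_HOLE_DIAMETER_MM
    plug_side: int = +1  # end of the phantom the plugs are inserted from
    resolution_plug_offset_mm: float = 35.0
    resolution_hole_index: Optional[int] = None
    resolution_jitter_hu: float = 300.0
    resolution_plug_length_mm: float = 14.0
    marker_axial_offset_mm: float = 0.0  # marker plane relative to mid-plane
    noise_sigma_hu: float = 20.0
    rotation_deg: float = 0.0
    scale_error: tuple[float, float, float] = (1.0, 1.0, 1.0)  # (x, y, z)
    axial_offset_mm: float = 0.0
    pixel_spacing_mm: tuple[float, float] = (0.76, 0.76)
    matrix_size: int = 512
    slice_thickness_mm: float = 1.0
    scan_margin_mm: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.marker_positions is None:
            self.marker_positions = layout.DEFAULT_MARKER_POSITIONS_MM.copy()
        else:
            self.marker_positions = np.asarray(self.marker_positions, dtype=float)
        if self.plug_layout is None:
            self.plug_layout = layout.default_plug_layout()
        if self.plug_contents is None:
            self.plug_contents = default_plug_contents()
        if self.plug_labels is None:
            self.plug_labels = default_plug_labels()
        self.validate()

    def validate(self) -> None:
        if self.marker_positions.shape[0] not in (3, 4):
            raise ValueError("the phantom has 3 or 4 fiducial markers")
        if self.noise_sigma_hu < 0:
            raise ValueError("noise_sigma_hu must be nonnegative")
        if self.rotation_deg % 360 not in (0, 90, 180, 270):
            raise ValueError("rotation_deg must be a multiple of 90")
        if self.resolution_plug_offset_mm not in VALID_RESOLUTION_OFFSETS_MM:
            raise ValueError(
                f"resolution plug offset must be one of {VALID_RESOLUTION_OFFSETS_MM}"
            )
        if self.plug_side not in (+1, -1):
            raise ValueError("plug_side must be +1 or -1")
        for sf in self.scale_error:
            if not (0.9 < sf < 1.1):
                raise ValueError("scale factors must lie in (0.9, 1.1)")
        body_r = self.diameter_mm / 2.0
        hole_r = self.plug_hole_diameter_mm / 2.0
        for hx, hz, _ in self.plug_layout:
            if math.hypot(hx, hz) + hole_r > body_r:
                raise ValueError(f"plug hole at ({hx:.1f}, {hz:.1f}) pokes out of the body")
        for mx, mz in np.atleast_2d(self.marker_positions):
            if math.hypot(mx, mz) >= body_r:
                raise ValueError(f"marker at ({mx:.1f}, {mz:.1f}) outside the body")

    # -- derived layout ----------------------------------------------------
    def resolution_hole(self) -> Optional[int]:
        """Hole index holding the resolution plug, or None.

        Raises :class:`LayoutConflictError` if a manual hole index points at
        a hole already holding a density plug.
        """
        from_contents = [
            h for h, v in self.plug_contents.items() if v == "resolution"
        ]
        if len(from_contents) > 1:
            raise LayoutConflictError(
                f"resolution plug assigned to several holes: {sorted(from_contents)}"
            )
        if self.resolution_hole_index is not None:
            v = self.plug_contents.get(self.resolution_hole_index)
            if isinstance(v, (int, float)):
                raise LayoutConflictError(
                    f"hole {self.resolution_hole_index} already holds a density "
                    f"plug ({v} HU); cannot also hold the resolution plug"
                )
            return self.resolution_hole_index
        return from_contents[0] if from_contents else None

    def to_dict(self) -> dict:
        d = {
            k: v
            for k, v in self.__dict__.items()
            if k not in ("marker_positions", "plug_layout", "plug_contents", "plug_labels")
        }
        d["scale_error"] = list(self.scale_error)
        d["pixel_spacing_mm"] = list(self.pixel_spacing_mm)
        d["marker_positions"] = np.asarray(self.marker_positions).tolist()
        d["plug_layout"] = [list(h) for h in self.plug_layout]
        d["plug_contents"] = {str(k): v for k, v in self.plug_contents.items()}
        d["plug_labels"] = {str(k): v for k, v in self.plug_labels.items()}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PhantomSpec":
        d = dict(d)
        for key in ("scale_error", "pixel_spacing_mm"):
            if key in d:
                d[key] = tuple(d[key])
        if d.get("plug_layout") is not None:
            d["plug_layout"] = [tuple(h) for h in d["plug_layout"]]
        if d.get("plug_contents") is not None:
            d["plug_contents"] = {int(k): v for k, v in d["plug_contents"].items()}
        if d.get("plug_labels") is not None:
            d["plug_labels"] = {int(k): v for k, v in d["plug_labels"].items()}
        return cls(**d)


@dataclass
class GroundTruth:
    """Analytic truth for everything the QA pipeline measures, derived
    deterministically from the spec before noise is added."""

    marker_positions_mm: np.ndarray  # rendered (rotated+scaled) positions
    pairwise_distances_mm: tuple[float, float, float]  # ascending
    middle_slice_index: int
    marker_slice_center: float  # sub-slice marker plane position (index units)
    marker_to_surface_mm: float  # mid-plane to nearest rendered end face
    plug_hu_map: dict[int, float]  # hole -> rendered HU (empty holes -> air)
    plug_centers_mm: dict[int, tuple[float, float]]  # rendered hole centres
    resolution_plug_location: Optional[tuple[float, int]]  # (offset_mm, hole)
    plug_side: int
    rotation_deg: float
    body_center_y_mm: float
    n_slices: int


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def _discrete_gaussian(rng: np.random.Generator, shape: tuple, sigma: float) -> np.ndarray:
    """Zero-mean integer-HU Gaussian noise via a 65536-level inverse-CDF
    lookup table driven by raw 64-bit generator output (fast and exactly
    reproducible for a given seed)."""
    quantiles = (np.arange(65536) + 0.5) / 65536.0
    lut = np.rint(ndtri(quantiles) * sigma).astype(np.int16)
    n = int(np.prod(shape))
    raw = rng.bit_generator.random_raw((n + 3) // 4)
    return lut[raw.view(np.uint16)[:n]].reshape(shape)


def _slices_in_band(y_centers: np.ndarray, lo: float, hi: float) -> np.ndarray:
    return np.flatnonzero((y_centers >= lo) & (y_centers <= hi))


def _ellipse_mask(
    x: np.ndarray, z: np.ndarray, cx: float, cz: float, rx: float, rz: float
):
    """Pixel-centre-inside test for an axis-aligned ellipse; returns
    (row_indices slice, col_indices slice, bool mask on that bounding box)."""
    cols = np.flatnonzero(np.abs(x - cx) <= rx)
    rows = np.flatnonzero(np.abs(z - cz) <= rz)
    if cols.size == 0 or rows.size == 0:
        return slice(0, 0), slice(0, 0), np.zeros((0, 0), dtype=bool)
    rsl = slice(rows[0], rows[-1] + 1)
    csl = slice(cols[0], cols[-1] + 1)
    xs = (x[csl] - cx) / rx
    zs = (z[rsl] - cz) / rz
    mask = xs[None, :] ** 2 + zs[:, None] ** 2 <= 1.0
    return rsl, csl, mask


def generate_phantom(spec: PhantomSpec) -> tuple[Volume, GroundTruth]:
    """Render the phantom described by ``spec`` and its ground truth.

    Identical specs (including seed) produce identical volumes.
    """
    sx, sy, sz = spec.scale_error
    t = spec.slice_thickness_mm
    ps_r, ps_c = spec.pixel_spacing_mm
    n_px = spec.matrix_size

    scan_length = spec.length_mm * sy + 2 * spec.scan_margin_mm
    n_slices = int(round(scan_length / t))
    y_centers = (np.arange(n_slices) + 0.5) * t
    y_mid = scan_length / 2.0 + spec.axial_offset_mm

    x = (np.arange(n_px) - (n_px - 1) / 2.0) * ps_c
    z = (np.arange(n_px) - (n_px - 1) / 2.0) * ps_r

    body_r = spec.diameter_mm / 2.0
    body2d = (x[None, :] / sx) ** 2 + (z[:, None] / sz) ** 2 <= body_r**2

    body_i = np.int16(round(spec.body_hu))
    bg_i = np.int16(round(spec.background_hu))
    marker_i = np.int16(round(spec.marker_hu))
    hu = np.empty((n_slices, n_px, n_px), dtype=np.int16)
    base = np.where(body2d, body_i, bg_i)
    half_len = spec.length_mm * sy / 2.0
    in_length = np.abs(y_centers - y_mid) <= half_len
    hu[in_length] = base
    hu[~in_length] = bg_i

    # -- fiducial markers (rotated with the phantom, scaled by the scanner) --
    markers = layout.rotate_xy(np.atleast_2d(spec.marker_positions), spec.rotation_deg)
    markers = markers * np.array([sx, sz])
    mr_x = spec.marker_diameter_mm / 2.0 * sx
    mr_z = spec.marker_diameter_mm / 2.0 * sz
    y_marker = y_mid + spec.marker_axial_offset_mm * sy
    marker_slices = _slices_in_band(
        y_centers, y_marker - spec.marker_length_mm / 2.0 * sy,
        y_marker + spec.marker_length_mm / 2.0 * sy,
    )
    for mx, mz in markers:
        rsl, csl, mask = _ellipse_mask(x, z, mx, mz, mr_x, mr_z)
        for si in marker_slices:
            hu[si, rsl, csl][mask] = marker_i

    # -- plug holes ----------------------------------------------------------
    holes = np.array(
        [[hx, hz] for hx, hz, _ in spec.plug_layout], dtype=float
    ).reshape(-1, 2)
    holes = layout.rotate_xy(holes, spec.rotation_deg) * np.array([sx, sz])
    hole_r_x = spec.plug_hole_diameter_mm / 2.0 * sx
    hole_r_z = spec.plug_hole_diameter_mm / 2.0 * sz
    res_hole = spec.resolution_hole()

    # Holes are drilled from the plug-side face down to ~30 mm short of the
    # mid-plane; density plugs fill the whole hole, ejected holes read air.
    face = y_mid + spec.plug_side * half_len
    hole_lo, hole_hi = sorted((y_mid + spec.plug_side * 30.0 * sy, face))
    plug_slices = _slices_in_band(y_centers, hole_lo, hole_hi)

    plug_hu_map: dict[int, float] = {}
    plug_centers: dict[int, tuple[float, float]] = {}
    rng = np.random.default_rng(spec.seed)
    for hole_idx, content in sorted(spec.plug_contents.items()):
        hx, hz = holes[hole_idx]
        plug_centers[hole_idx] = (float(hx), float(hz))
        if content == "resolution":
            continue
        value = spec.background_hu if content == "empty" else float(content)
        value_i = np.int16(round(value))
        plug_hu_map[hole_idx] = float(value_i)
        rsl, csl, mask = _ellipse_mask(x, z, hx, hz, hole_r_x, hole_r_z)
        for si in plug_slices:
            hu[si, rsl, csl][mask] = value_i

    # -- resolution plug -----------------------------------------------------
    res_location = None
    if res_hole is not None:
        hx, hz = holes[res_hole]
        plug_centers[res_hole] = (float(hx), float(hz))
        off = spec.resolution_plug_offset_mm
        center_y = y_mid + off * sy
        half = spec.resolution_plug_length_mm / 2.0 * sy
        res_slices = _slices_in_band(y_centers, center_y - half, center_y + half)
        rsl, csl, mask = _ellipse_mask(x, z, hx, hz, hole_r_x, hole_r_z)
        j = spec.resolution_jitter_hu
        for si in res_slices:
            jitter = np.rint(
                spec.body_hu + rng.uniform(-j, j, size=int(mask.sum()))
            ).astype(np.int16)
            hu[si, rsl, csl][mask] = jitter
        # Drilled hole-pattern groups (one group per diameter), visual only.
        for gi, dia in enumerate(RESOLUTION_HOLE_DIAMETERS_MM):
            ang = math.radians(gi * 360.0 / len(RESOLUTION_HOLE_DIAMETERS_MM))
            ux, uz = math.cos(ang), math.sin(ang)
            for k, rad in enumerate((3.5, 6.5, 9.5)):
                ox, oz = hx + rad * ux * sx, hz + rad * uz * sz
                hrsl, hcsl, hmask = _ellipse_mask(
                    x, z, ox, oz, dia / 2.0 * sx, dia / 2.0 * sz
                )
                for si in res_slices:
                    hu[si, hrsl, hcsl][hmask] = bg_i
        res_location = (off, res_hole)

    # -- noise (already integer HU), clamped to the representable range ------
    if spec.noise_sigma_hu > 0:
        hu += _discrete_gaussian(rng, hu.shape, spec.noise_sigma_hu)
        np.clip(hu, int(HU_MIN), int(HU_MAX), out=hu)

    # -- ground truth ----------------------------------------------------------
    if markers.shape[0] == 4:
        from .phantom_geometry import select_best_three

        kept = markers[list(select_best_three(markers))]
    else:
        kept = markers
    dists = sorted(
        float(np.linalg.norm(kept[i] - kept[j]))
        for i in range(3)
        for j in range(i + 1, 3)
    )
    marker_slice_center = float(np.mean(marker_slices))
    middle_slice_index = _round_half_up(marker_slice_center)
    truth = GroundTruth(
        marker_positions_mm=markers,
        pairwise_distances_mm=tuple(dists),
        middle_slice_index=middle_slice_index,
        marker_slice_center=marker_slice_center,
        marker_to_surface_mm=half_len + spec.marker_axial_offset_mm * sy,
        plug_hu_map=plug_hu_map,
        plug_centers_mm=plug_centers,
        resolution_plug_location=res_location,
        plug_side=spec.plug_side,
        rotation_deg=spec.rotation_deg,
        body_center_y_mm=y_mid,
        n_slices=n_slices,
    )
    meta = SeriesMeta(
        pixel_spacing_mm=(ps_r, ps_c),
        slice_thickness_mm=t,
        n_slices=n_slices,
        rescale_slope=1.0,
        rescale_intercept=0.0,
        series_uid="",
    )
    return Volume(hu, meta), truth


def inject_distortion(
    volume: Volume, scale_error: tuple[float, float, float]
) -> Volume:
    """Return a copy of ``volume`` with a per-axis multiplicative geometric
    scaling error applied about the volume centre.

    ``scale_error`` is (x, y, z); marker separations scale by the per-axis
    factor to within voxel quantization.  A factor of 1.0 on all axes
    returns an identical copy.  Factors must lie in (0.9, 1.1).
    """
    sx, sy, sz = scale_error
    for sf in (sx, sy, sz):
        if not (0.9 < sf < 1.1):
            raise ValueError("scale factors must lie in (0.9, 1.1)")
    if (sx, sy, sz) == (1.0, 1.0, 1.0):
        return volume.copy()
    # Array axes are (slice=y, row=z, col=x).  affine_transform maps output
    # index o to input index m*o + offset; scaling features by s needs m=1/s
    # about the centre c: offset = c * (1 - 1/s).
    n_sl, n_r, n_c = volume.hu.shape
    centers = np.array([(n_sl - 1) / 2.0, (n_r - 1) / 2.0, (n_c - 1) / 2.0])
    inv = np.array([1.0 / sy, 1.0 / sz, 1.0 / sx])
    offset = centers * (1.0 - inv)
    out = ndimage.affine_transform(
        volume.hu.astype(np.float32),
        inv,
        offset=offset,
        order=1,
        mode="constant",
        cval=np.float32(HU_MIN),
        output=np.float32,
    )
    return Volume(out, volume.meta)
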