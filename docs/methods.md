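# Methods

This note documents the models, conventions and numerical choices behind
`phantomqa`, in the order the pipeline runs them.

## Volume model and coordinates

A series is one 3D array of Hounsfield units indexed `(slice, row, col)`:

* slice axis = longitudinal **y**, slice *i* centred at `(i + 0.5) · t` mm
  from the scan start (`t` = slice thickness);
* row axis = vertical **z**, col axis = lateral **x**; in-plane mm
  coordinates are measured from the image centre at pixel centres.

Slices are ordered by ascending `InstanceNumber` (the rule clinical DICOM
export follows), falling back to slice position with a warning when the tag
is missing; gapped or non-1-based sequences are sorted and accepted with a
warning. Stored pixels are calibrated as `HU = slope · stored + intercept`;
missing rescale tags default to slope 1 / intercept 0 with a warning. Valid
HU span [−1024, 4000] (air floor up to the densest fiducial). Writing
inverts the same affine into signed 16-bit stored values, so a write → read
round trip is bit-exact; out-of-range values raise unless clamping is
requested (never a silent wraparound).

## Synthetic phantom

The simulator is the package's data source for tests and examples. It
renders, on a default 512 × 512 grid of 0.76 mm pixels with 1 mm slices
("fine" scan mode):

* a 30 cm ⌀ × 18 cm cylinder, body 0 HU, in −1024 HU air, with 5 mm air
  margin on each scan end (so end surfaces are always inside the scan);
* three 4 mm ⌀ × 3 mm fiducial rods of 1100 HU at the mid-plane, placed so
  their pairwise distances are (101.0, 147.7, 226.4) mm — the reference
  machine's baseline triangle; an optional fourth marker reproduces the
  four-marker phantom variant. The exact marker angles are package-defined
  constants (only the distances are published for the commercial phantom);
* 20 plug holes (25 mm ⌀) on two rings, 12 at r = 115 mm and 8 at
  r = 65 mm, drilled from one face to 30 mm short of the mid-plane. Density
  plugs fill their hole with a constant HU (defaults: the seven reference
  materials LN-300 … cortical bone); ejected holes read air;
* a resolution plug: 14 mm-long cylinder of per-voxel uniform ±300 HU
  jitter (ROI σ ≈ 173 HU, ≈9× the default image noise) plus drilled hole
  groups of 0.8–2.0 mm, centred at ±35 or ±90 mm from the mid-plane. At the
  ±90 mm (face) positions the texture band is still centred on the nominal
  offset and may extend a few millimetres past the face — this mirrors the
  analyzer's candidate-slice convention and keeps the localization test
  geometry exact;
* whole-phantom rotations of 0/90/180/270° (applied to marker and hole
  coordinates with exact integer rotation matrices) and per-axis
  multiplicative scale errors in (0.9, 1.1), applied either analytically at
  render time or post-hoc by trilinear resampling (`inject_distortion`).

Rendering uses a pixel-centre-inside rule with no antialiasing, so every
geometric quantity has a closed-form ground truth. Voxels are integer HU,
as on a real scanner: structure values are rounded at render time (the
ground truth reports the rendered values) and noise is drawn from a
65536-level inverse-CDF discretization of N(0, σ²) driven by the raw
64-bit generator stream — exactly seeded and with sample σ within 0.1% of
the request; this sampler is several times faster than a float normal draw
on a single CPU, which matters for the multi-hundred-volume test sweeps.
Values are clamped at the −1024 HU scanner floor, so ROI means over *air*
are biased high by ≈ σ·φ(0) ≈ 8 HU at σ = 20 — real scanners clip the same
way.

Default noise is σ = 20 HU, matching the σ_CT the reference machines
actually measured (16–19 HU) rather than the 50–70 HU "typical" band, which
the report carries as an informational reference only.

What the simulator does **not** emulate: ring/streak/beam-hardening
artifacts, scatter, detector response, partial-volume blur at structure
boundaries, couch structures. Passing tests therefore demonstrate correct
measurement and grading logic under realistic geometry and noise, not
robustness to every clinical artifact (the manual overrides exist for that).

## Marker detection and geometry

Binarize at 800 HU (the fiducials exceed 1000 HU; 800 leaves margin against
partial volume), label connected components in 3D (26-connectivity, which
yields the same per-slice components as 2D 8-connectivity stacked), and
keep components whose largest per-slice cross-section is 2–200 px.
Centroids are unweighted means of member pixel centres. Fewer than three
candidates is an error; exactly four keeps the triple with maximal pairwise
distance sum (ties: larger summed area, then scan order); more than four is
reported as ambiguous with the candidate list. Two centroids within 1 mm
are a degenerate pair.

Edges are labelled by ascending length (A–B ≤ B–C ≤ C–A), making labels
invariant under rotation and detection order; vertex B joins the two
shortest edges. The marker plane is the unweighted mean slice coordinate of
all marker voxels (a float; its half-up rounding anchors slice selection).

The longitudinal distance runs from the marker plane to the outer face of
the end-surface slice (+0.5 voxel): the surface is the outermost slice
whose body-mask (HU > −300) area reaches 50% of the maximum cross-section.
By convention the low-index end is used, the other end if the first is
truncated, and a phantom truncated on both ends (which includes a scan the
phantom fills exactly) has no measurable surface. With these conventions a
centred marker plane in the 18 cm phantom measures exactly 90.0 mm at 1 mm
slices; at 2 mm slices the surface quantization contributes up to t/2.
Because the phantom and its surface move together, only a shift of the
*marker plane within the phantom* changes this distance — the simulator
exposes `marker_axial_offset_mm` for exactly that.

Grading: deviations = measured − baseline per label; pass iff
max |deviation| ≤ 1 mm (SRS/SBRT) or 2 mm, **inclusive** — the reference
machine's QA sits exactly on the 1.0 mm boundary (B–D 89.0 → 90.0 mm)
within an overall passing session, which fixes the inclusive rule.

## ROI statistics and slice selection

One membership rule everywhere: a pixel belongs to a circular ROI when its
centre lies within the radius (inclusive). Mean is the plain average;
σ_CT is the sample standard deviation (n − 1), computed in float64; ROIs
under 5 pixels are rejected. Both statistics are verified against an
independent per-pixel loop to 1e-9.

The plug-bearing side of the phantom is detected as the side with the
higher mean per-slice in-body σ over a 50 mm slab from the middle slice
(the middle slice's body mask is reused on every probed slice, so
air-filled holes inflate the σ of the side that holds them; the σ of the
two ±10 mm candidate slices alone would not discriminate, as the holes
start ≈30 mm out). The uniformity/noise slice is 10 mm on the *opposite*
side; the contrast slice is 50 mm on the plug side; both directions can be
forced in the config.

Uniformity: centre ROI at the body-mask centroid plus four cardinal ROIs at
105 mm radius (the vendor publishes no placement radius; 105 mm keeps a
10 mm ROI ≥ 35 mm inside the rim). Tolerance 25 HU when images feed dose
calculation, 30 HU for imaging-only use (the imaging-only default adopts
the water-like contrast reference), both overridable. Periphery ROIs that
leave the body mask are an error naming the ROI.

Contrast: measured plug means are matched to baseline HUs by a
minimum-total-|ΔHU| one-to-one assignment (scipy's Hungarian solver,
verified exhaustively up to n = 7) — by design position-independent, since
plugs are commonly re-shuffled between sessions. Per-pair tolerance: 30 HU
when |baseline| ≤ 100 HU (water-like), 50 HU otherwise; the 100 HU split
and every per-plug value are user-overridable. On the reference machine's
detector-replacement session these defaults flag Water (40.72 HU),
Inner bone (36.44 HU) and CB2-50% (58.15 HU); the original analysis flagged
only Water and CB2-50%, implying locally adjusted per-plug tolerances —
the defaults are not tuned to reproduce that pair.

## Resolution plug

σ is computed in a 14 mm search ROI (between the 10 mm stat ROI and the
hole pitch) at all 20 hole positions on every in-range candidate slice
(±35, ±90 mm); the global maximum wins. If the runner-up σ comes within
10% of the best the location is declared ambiguous — a recoverable error
(manual hole/offset override bypasses the search), preferred over a silent
guess. Auto-window = 1st/99th percentile of the cropped sub-image; a
constant crop windows to value ± 1 HU. No MTF or automated visibility
scoring is attempted: the 1.6 mm criterion is graded by the inspector, and
the verdict is recorded verbatim ("ungraded" leaves the session
incomplete).

## Orchestration, baselines, reports

Stages run read → markers → geometry → uniformity/noise → contrast →
resolution. Marker failure aborts (everything is anchored on the middle
slice); any later stage records its error and the rest still run. Overall
status: *pass* iff every graded test passed and the resolution was graded
pass; *fail* on any failed grade; *incomplete* otherwise (including
bootstrap runs without a baseline, which mark the consistency tests as
"baseline established").

All artifacts (config, baseline, report) carry a `format_version`. JSON is
the canonical result; floats round-trip exactly through repr-based JSON
serialization, verified by save/load equality. Report timestamps are
caller-supplied verbatim (never read from the wall clock), so identical
runs produce byte-identical sidecars. The PDF is a single-page rendering
with generated figure panels (marker overlay, ROI overlay, windowed
resolution sub-image).

## Problem sizes used by the test suite

The default phantom is 512 × 512 × 190 voxels. The multi-volume sweeps
(geometry recovery over 20 seeds × 4 rotations × {1, 2} mm slices;
resolution localization over 20 seeds × 4 insert positions × 4 rotations)
and `scripts/acceptance.py` use a 448-pixel matrix — same 0.76 mm pixels,
340 mm field of view, phantom and all structures fully contained — which is
the package's chosen balance between realism and sweep size. The
acceptance script further samples 5 seeds for its geometry/contrast
summaries and 2 × 4 × 4 cases for localization.

## Known limitations

* Hole and marker *angular* positions are package constants; analyzing a
  real scan of the commercial phantom requires entering its true layout in
  the config (`marker_layout_mm`, `plug_layout_mm`).
* Rotation detection assumes quarter-turn phantom placement (the clinical
  case); arbitrary angles are out of scope.
* Uncompressed, single-frame CT DICOM only (plus whatever transfer
  syntaxes pydicom decodes natively); no DICOM-RT, no networking.
* The resolution test automates localization and display, not the visual
  judgement itself.
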