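# phantomqa

Automated image-quality QA for mega-voltage CT (MVCT) scans of the
cylindrical water-equivalent "cheese" phantom used on helical tomotherapy
units (TomoTherapy / Radixact).

Medical physicists image this phantom monthly: a 30 cm diameter × 18 cm
cylinder with fiducial markers embedded in its mid-plane and 20 peripheral
holes for density and resolution plugs. TG-148-style QA then asks four
questions of the images, and answering them by hand (ruler tools, ad-hoc
ROIs) is slow and analyst-dependent. `phantomqa` reads the exported DICOM
series and answers them automatically, reproducibly, and against a persisted
baseline:

1. **Geometric distortion** — binarize the mid-plane, find the three marker
   centroids (connected components, unweighted pixel centroids), measure the
   three transaxial distances d(A–B) ≤ d(B–C) ≤ d(C–A) plus the longitudinal
   marker-to-surface distance d(B–D), and grade the deviations from baseline
   against 1 mm (SRS/SBRT) or 2 mm (inclusive).
2. **Uniformity** — on the slice 10 mm from the middle (away from the plug
   region), compare a 10 mm centre ROI against four cardinal periphery ROIs:
   max |HU̅_periph − HU̅_centre| ≤ 25 HU (dose-calculation use) or 30 HU.
3. **Noise** — σ_CT of the small (10 mm) and big (60 mm) centre ROIs,
   reported for reference against the typical 50–70 HU band (never graded
   against baseline: noise is a property of the image itself).
4. **Contrast** — mean HU of each density plug on the slice 50 mm toward the
   plug side, matched to the *nearest baseline HU* (plug position is
   deliberately ignored, so plugs may be re-shuffled between sessions) by a
   minimum-total-|ΔHU| assignment, each pair graded against 30 HU
   (water-like) / 50 HU (dense) tolerances.
5. **Spatial resolution** — the high-texture resolution plug is localized as
   the global σ maximum over the 20 hole positions on the ±35 / ±90 mm
   candidate slices, cropped and auto-windowed (1st–99th percentile); the
   actual visibility verdict for the 1.6 mm hole group stays with the human
   inspector and is recorded verbatim.

The result is a one-page PDF report plus a canonical JSON sidecar, and any
run can be saved as the baseline for the next one.

A full synthetic-phantom simulator (`phantomqa.synthetic_phantom`) renders
DICOM series of the phantom with analytic ground truth — marker geometry,
plug HUs, rotations of 0/90/180/270°, injectable scale errors, seeded
noise — and backs the entire test suite; no scanner data is required.

## Worked example

```sh
$ phantomqa simulate --out series --seed 7      # 190-slice synthetic scan
wrote 190 slices to series
$ phantomqa baseline series --out baseline.json --machine-id HDA-1
baseline saved to baseline.json
$ phantomqa run series --baseline baseline.json --grade-resolution pass --out qa
overall status: pass
report: qa/qa_report.pdf
sidecar: qa/qa_report.json
```

The sidecar from this exact session reads (abridged):

* geometric distances **101.08 / 147.65 / 226.42 / 90.00 mm** — the simulated
  marker triangle is (101.0, 147.7, 226.4) mm and the marker plane sits 90 mm
  from the phantom face, so every distance is recovered to well under half a
  pixel (0.76 mm pixels, 1 mm slices); deviations from the just-saved
  baseline are exactly 0.0 at the 1 mm SRS/SBRT tolerance;
* uniformity max |Δ| **2.86 HU** (tolerance 25 HU) — pure noise residue on a
  phantom generated perfectly uniform;
* noise σ_CT **18.74 / 19.78 HU** (small / big ROI) for generated σ = 20 HU;
* contrast: e.g. the LN-300 lung plug measures **−683.97 HU** against its
  rendered −686 HU, within the noise-limited band; all baseline deviations 0;
* resolution plug found at **+35 mm, hole 10** with texture σ 380.9 HU —
  exactly where the simulator inserted it;
* `overall_status: "pass"` (the resolution grade was supplied as `pass`).

Run `phantomqa run --help` for manual overrides (resolution hole/offset,
mode, per-plug tolerances via a config file).

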