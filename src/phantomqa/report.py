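"""One-page PDF rendering of a QA report, plus its JSON sidecar.

The JSON sidecar is the canonical machine-readable result; the PDF is a
human-facing rendering with measured values, baseline values, deviations,
pass/fail per item, the configuration snapshot and generated figure panels
(marker overlay, ROI overlay, resolution plug sub-image).
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.patches as mpatches
import matplotlib.pyplot as plt
from matplotlib.backends.backend_pdf import PdfPages

from .qa_engine import QAReport

_STATUS_COLOR = {"pass": "tab:green", "fail": "tab:red", "incomplete": "tab:orange"}


def _verdict(passed) -> str:
    return {True: "PASS", False: "FAIL", None: "--"}[passed]


def _geometry_lines(report: QAReport) -> list[str]:
    g = report.geometric
    if g is None:
        return [f"geometric: ERROR — {report.stage_errors.get('geometric', '?')}"]
    lines = [f"Geometric distortions ({g.mode}, tol {g.tolerance_mm:.0f} mm)"
             f"  [{_verdict(g.passed) if g.status == 'graded' else g.status}]"]
    names = ("A-B", "B-C", "C-A", "B-D")
    for i, name in enumerate(names):
        meas = g.distances_mm[i]
        if g.baseline_mm is not None:
            lines.append(
                f"  {name}: {meas:8.2f} mm   baseline {g.baseline_mm[i]:8.2f}"
                f"   dev {g.deviations_mm[i]:+6.2f} mm"
            )
        else:
            lines.append(f"  {name}: {meas:8.2f} mm   (new baseline)")
    return lines


def _uniformity_noise_lines(report: QAReport) -> list[str]:
    lines = []
    u = report.uniformity
    if u is None:
        lines.append(f"uniformity: ERROR — {report.stage_errors.get('uniformity', '?')}")
    else:
        lines.append(
            f"Uniformity (slice {u.slice_index}): max |center-periphery| "
            f"= {u.max_abs_diff_hu:.2f} HU (tol {u.tolerance_hu:.0f})  "
            f"[{_verdict(u.passed)}]"
        )
    n = report.noise
    if n is None:
        lines.append(f"noise: ERROR — {report.stage_errors.get('noise', '?')}")
    else:
        lines.append(
            f"Noise (informational): sigma_small = {n.sigma_small_hu:.2f} HU, "
            f"sigma_big = {n.sigma_big_hu:.2f} HU "
            f"(typical band {n.reference_band_hu[0]:.0f}-{n.reference_band_hu[1]:.0f})"
        )
    if report.baseline is not None and n is not None:
        lines.append(
            f"  baseline for reference: uniformity {report.baseline['uniformity_hu']:.2f}, "
            f"noise {report.baseline['noise_small_hu']:.2f}/"
            f"{report.baseline['noise_big_hu']:.2f} HU"
        )
    return lines


def _contrast_lines(report: QAReport) -> list[str]:
    if "contrast" in report.stage_errors:
        return [f"contrast: ERROR — {report.stage_errors['contrast']}"]
    if not report.contrast:
        return ["Contrast: no plugs measured"]
    lines = ["Contrast (HU):"]
    for m in report.contrast:
        if m.matched_baseline_hu is None:
            lines.append(f"  {m.label or m.hole_index}: {m.mean_hu:8.2f}  (unmatched)")
        else:
            lines.append(
                f"  {m.matched_baseline_label or m.label}: {m.mean_hu:8.2f}  "
                f"baseline {m.matched_baseline_hu:8.2f}  dev {m.deviation_hu:+7.2f} "
                f"(tol {m.tolerance_hu:.0f})  [{_verdict(m.passed)}]"
            )
    return lines


def _resolution_lines(report: QAReport) -> list[str]:
    r = report.resolution
    if r is None:
        return [f"resolution: ERROR — {report.stage_errors.get('resolution', '?')}"]
    grade = r.visual_grade.upper() if r.visual_grade != "ungraded" else "ungraded"
    return [
        f"Spatial resolution (criterion {r.criterion_mm} mm, manually graded): "
        f"[{grade}]",
        f"  plug at offset {r.found_slice_offset_mm:+.0f} mm, hole "
        f"{r.hole_index}, sigma {r.plug_sigma_hu:.1f} HU, window "
        f"[{r.window_bounds_hu[0]:.0f}, {r.window_bounds_hu[1]:.0f}] HU"
        + ("  (manual override)" if r.manual_override else ""),
    ]


def render_report(report: QAReport, out_path) -> tuple[Path, Path]:
    """Write a one-page PDF and its JSON sidecar.

    Returns ``(pdf_path, json_path)``.  Figure panel PNGs are written next
    to the PDF and recorded in ``report.figure_paths``.
    """
    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    pdf_path = out_path if out_path.suffix == ".pdf" else out_path.with_suffix(".pdf")
    json_path = pdf_path.with_suffix(".json")

    # Export panels as PNG before building the page so paths land in the JSON.
    panel_axes = []
    panels = report.panels or {}
    if "markers" in panels:
        panel_axes.append(("Marker overlay", "markers"))
    if "uniformity_slice" in panels:
        panel_axes.append(("Uniformity ROIs", "uniformity_slice"))
    if "resolution" in panels:
        panel_axes.append(("Resolution plug", "resolution"))
    for title, key in panel_axes:
        png = pdf_path.with_name(f"{pdf_path.stem}_{key}.png")
        fig, ax = plt.subplots(figsize=(4, 4))
        _draw_panel(ax, report, key)
        ax.set_title(title, fontsize=9)
        fig.savefig(png, dpi=120, bbox_inches="tight")
        plt.close(fig)
        report.figure_paths[key] = png.name  # relative to the PDF directory

    json_path.write_text(report.to_json())

    fig = plt.figure(figsize=(8.5, 11))
    status = report.overall_status
    fig.text(0.06, 0.965, "MVCT QA report — cheese phantom", fontsize=15,
             fontweight="bold")
    fig.text(0.94, 0.965, status.upper(), fontsize=15, fontweight="bold",
             color=_STATUS_COLOR[status], ha="right")
    header = (
        f"machine: {report.machine_id or '-'}    analyzed: "
        f"{report.timestamp or '-'}    rotation: {report.rotation_deg:g} deg    "
        f"program {report.program_version} / format {report.format_version}"
    )
    fig.text(0.06, 0.945, header, fontsize=8, color="0.3")

    lines: list[str] = []
    lines += _geometry_lines(report)
    lines.append("")
    lines += _uniformity_noise_lines(report)
    lines.append("")
    lines += _contrast_lines(report)
    lines.append("")
    lines += _resolution_lines(report)
    for stage, msg in report.stage_errors.items():
        lines.append(f"stage error [{stage}]: {msg}")
    fig.text(0.06, 0.92, "\n".join(lines), fontsize=7.5, family="monospace",
             va="top")

    cfg = report.config or {}
    cfg_text = ", ".join(
        f"{k}={cfg[k]}"
        for k in ("mode", "dose_calc", "roi_diameter_mm", "periphery_radius_mm",
                  "big_roi_diameter_mm", "marker_threshold_hu")
        if k in cfg
    )
    fig.text(0.06, 0.40, "config: " + cfg_text, fontsize=7, color="0.35",
             family="monospace")

    for i, (title, key) in enumerate(panel_axes[:3]):
        ax = fig.add_axes([0.06 + i * 0.31, 0.05, 0.28, 0.28])
        _draw_panel(ax, report, key)
        ax.set_title(title, fontsize=8)

    with PdfPages(pdf_path) as pdf:
        pdf.savefig(fig)
    plt.close(fig)
    return pdf_path, json_path


def _draw_panel(ax, report: QAReport, key: str) -> None:
    panels = report.panels
    if key == "resolution":
        lo, hi = (report.resolution.window_bounds_hu
                  if report.resolution is not None else (None, None))
        ax.imshow(panels[key], cmap="gray", vmin=lo, vmax=hi)
    elif key == "markers":
        img = panels[key]
        ax.imshow(img, cmap="gray", vmin=-1024, vmax=1200)
        cents = panels.get("marker_centroids_mm")
        if cents is not None:
            n_r, n_c = img.shape
            # mm -> pixel for overlay crosses
            for label, (x, z) in zip("ABC", cents):
                col = x / _spacing(report, 1) + (n_c - 1) / 2.0
                row = z / _spacing(report, 0) + (n_r - 1) / 2.0
                ax.plot(col, row, "r+", markersize=10)
                ax.annotate(label, (col, row), color="red", fontsize=8,
                            xytext=(4, 4), textcoords="offset points")
    elif key == "uniformity_slice":
        img = panels[key]
        ax.imshow(img, cmap="gray", vmin=-1024, vmax=200)
        u = report.uniformity
        if u is not None:
            n_r, n_c = img.shape
            cfg = report.config or {}
            roi_d = cfg.get("roi_diameter_mm", 10.0)
            centers = [u.center] + list(u.periphery.values())
            # centre ROI is at the body centroid; periphery at cardinal points
            pr = cfg.get("periphery_radius_mm", 105.0)
            offsets = [(0, 0), (0, -pr), (pr, 0), (0, pr), (-pr, 0)]
            for (ox, oz) in offsets:
                col = ox / _spacing(report, 1) + (n_c - 1) / 2.0
                row = oz / _spacing(report, 0) + (n_r - 1) / 2.0
                ax.add_patch(mpatches.Circle(
                    (col, row), roi_d / 2.0 / _spacing(report, 1),
                    fill=False, color="yellow", linewidth=0.8))
    ax.set_xticks([])
    ax.set_yticks([])


def _spacing(report: QAReport, axis: int) -> float:
    spacing = (report.panels or {}).get("pixel_spacing_mm", (0.76, 0.76))
    return float(spacing[axis])
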