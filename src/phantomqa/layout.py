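"""Canonical cheese-phantom geometry constants shared by the simulator and
the QA engine.

The commercial phantom is a 30 cm diameter x 18 cm long water-equivalent
cylinder with three (or four) fiducial markers embedded in its mid-plane and
20 plug holes for density / resolution inserts.  Only the diameter, length,
marker count and hole count are vendor-published; the exact marker angles and
hole coordinates used here are package-defined constants, chosen so that the
marker pairwise distances reproduce the reference machine values and the
holes sit on two concentric rings well inside the body.  All coordinates are
millimetres in the transaxial (x = lateral, z = vertical) plane, relative to
the cylinder axis.
"""

from __future__ import annotations

import math

import numpy as np

#: Reference pairwise marker distances (mm), ascending: A-B, B-C, C-A.
DEFAULT_MARKER_DISTANCES_MM: tuple[float, float, float] = (101.0, 147.7, 226.4)

#: Phantom body dimensions (mm).
PHANTOM_DIAMETER_MM = 300.0
PHANTOM_LENGTH_MM = 180.0

#: Plug-hole rings: 12 holes at r=115 mm, 8 holes at r=65 mm (20 total).
OUTER_RING_RADIUS_MM = 115.0
INNER_RING_RADIUS_MM = 65.0
N_OUTER_HOLES = 12
N_INNER_HOLES = 8
PLUG_HOLE_DIAMETER_MM = 25.0

#: Reference density-plug CT numbers (HU) by material, as measured on a
#: clinical machine at baseline.  Used as simulator defaults.
PLUG_BASELINE_HU: dict[str, float] = {
    "LN-300": -685.70,
    "LN-450": -515.72,
    "Water": -1.12,
    "Inner bone": 97.95,
    "CB2-30%": 269.95,
    "CB2-50%": 467.28,
    "Cortical bone": 668.27,
}


def marker_positions_from_distances(
    d_ab: float, d_bc: float, d_ca: float
) -> np.ndarray:
    """Place three points A, B, C in the plane with the given pairwise
    distances (|AB| = d_ab, |BC| = d_bc, |CA| = d_ca), centred on their
    centroid.

    Returns a (3, 2) array of (x, z) mm rows in order A, B, C.  Raises
    ``ValueError`` if the distances violate the triangle inequality.
    """
    if not (d_ab + d_bc > d_ca and d_bc + d_ca > d_ab and d_ca + d_ab > d_bc):
        raise ValueError(f"distances {(d_ab, d_bc, d_ca)} violate the triangle inequality")
    # A at origin, B on the +x axis, C above.
    cx = (d_ca**2 - d_bc**2 + d_ab**2) / (2.0 * d_ab)
    cz = math.sqrt(d_ca**2 - cx**2)
    pts = np.array([[0.0, 0.0], [d_ab, 0.0], [cx, cz]], dtype=float)
    pts -= pts.mean(axis=0)
    return pts


#: Default three-marker layout (rows A, B, C), mm relative to the axis.
DEFAULT_MARKER_POSITIONS_MM: np.ndarray = marker_positions_from_distances(
    *DEFAULT_MARKER_DISTANCES_MM
)

#: Optional fourth marker for the four-marker phantom variant: placed opposite
#: the triangle centroid, at mid radius.  Package-defined constant.
FOURTH_MARKER_POSITION_MM: tuple[float, float] = (-60.0, 95.0)


def default_plug_layout() -> list[tuple[float, float, float]]:
    """The 20 plug-hole centres as (x_mm, z_mm, angle_deg) tuples.

    Holes 0-11 lie on the outer ring (every 30 deg starting at 0 deg), holes
    12-19 on the inner ring (every 45 deg, offset 22.5 deg).
    """
    holes: list[tuple[float, float, float]] = []
    for i in range(N_OUTER_HOLES):
        ang = i * 360.0 / N_OUTER_HOLES
        holes.append(
            (
                OUTER_RING_RADIUS_MM * math.cos(math.radians(ang)),
                OUTER_RING_RADIUS_MM * math.sin(math.radians(ang)),
                ang,
            )
        )
    for i in range(N_INNER_HOLES):
        ang = i * 360.0 / N_INNER_HOLES + 22.5
        holes.append(
            (
                INNER_RING_RADIUS_MM * math.cos(math.radians(ang)),
                INNER_RING_RADIUS_MM * math.sin(math.radians(ang)),
                ang,
            )
        )
    return holes


def rotate_xy(points: np.ndarray, degrees: float) -> np.ndarray:
    """Rotate (N, 2) points counter-clockwise about the origin.

    Multiples of 90 degrees use an exact integer rotation matrix so that
    quarter-turn symmetry holds to machine precision.
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    deg = degrees % 360.0
    if deg in (0.0, 90.0, 180.0, 270.0):
        k = int(deg // 90)
        c, s = [(1, 0), (0, 1), (-1, 0), (0, -1)][k]
    else:
        c, s = math.cos(math.radians(deg)), math.sin(math.radians(deg))
    rot = np.array([[c, -s], [s, c]], dtype=float)
    return pts @ rot.T
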