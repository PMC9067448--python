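"""Fixed geometric constants of the 68-point facial landmark scheme.

Each landmark is given a canonical direction on the head surface as an
(azimuth, elevation) pair in degrees: azimuth is measured from the forward
(anterior, +A) axis, positive toward the subject's right (+R); elevation
from the axial plane toward superior (+S).  A point on an ellipsoidal head
with semi-axes (a, b, c) is then ``center + (a dx, b dy, c dz)`` for the
unit direction d of those angles.

These constants are shared by the synthetic phantom generator (which places
landmarks on phantom heads) and serve as the canonical reference geometry.
The index ranges and the left/right mirror pairing follow the common
68-point convention: 0-16 jawline, 17-26 eyebrows, 27-35 nose, 36-47 eyes,
48-67 mouth; index 0 is on the subject's right.
"""

from __future__ import annotations

import numpy as np


def _jaw() -> list[tuple[float, float]]:
    out = []
    for i in range(17):
        t = (i - 8) / 8.0
        out.append((-t * 85.0, -20.0 - 45.0 * (1.0 - abs(t))))
    return out


#: (azimuth_deg, elevation_deg) for each of the 68 landmarks.
LANDMARK_ANGLES_DEG: tuple[tuple[float, float], ...] = tuple(
    _jaw()
    + [(55, 25), (45, 25), (35, 25), (25, 25), (15, 25)]        # right brow 17-21
    + [(-15, 25), (-25, 25), (-35, 25), (-45, 25), (-55, 25)]   # left brow 22-26
    + [(0, 20), (0, 15), (0, 10), (0, 5)]                       # nasal bridge 27-30
    + [(10, 0), (5, -1), (0, -2), (-5, -1), (-10, 0)]           # nostril row 31-35
    + [(38, 15), (33, 18), (28, 18), (23, 15), (28, 12), (33, 12)]    # right eye
    + [(-23, 15), (-28, 18), (-33, 18), (-38, 15), (-33, 12), (-28, 12)]  # left eye
    + [(18, -25), (12, -21), (6, -19), (0, -18), (-6, -19), (-12, -21),
       (-18, -25), (-12, -29), (-6, -31), (0, -32), (6, -31), (12, -29)]  # outer lip
    + [(14, -25), (7, -23), (0, -22), (-7, -23), (-14, -25), (-7, -27),
       (0, -28), (7, -27)]                                      # inner lip 60-67
)

assert len(LANDMARK_ANGLES_DEG) == 68


def _mirror_map() -> dict[int, int]:
    pairs = (
        [(i, 16 - i) for i in range(8)]
        + [(17, 26), (18, 25), (19, 24), (20, 23), (21, 22)]
        + [(31, 35), (32, 34)]
        + [(36, 45), (37, 44), (38, 43), (39, 42), (40, 47), (41, 46)]
        + [(48, 54), (49, 53), (50, 52), (55, 59), (56, 58)]
        + [(60, 64), (61, 63), (65, 67)]
    )
    m = {i: i for i in range(68)}
    for a, b in pairs:
        m[a], m[b] = b, a
    return m


#: Index map swapping each landmark with its left/right mirror partner
#: (midline landmarks map to themselves).
MIRROR_MAP: dict[int, int] = _mirror_map()


def landmark_directions() -> np.ndarray:
    """Unit direction vectors (68, 3) in RAS for the canonical angles."""
    ang = np.deg2rad(np.asarray(LANDMARK_ANGLES_DEG))
    az, el = ang[:, 0], ang[:, 1]
    return np.column_stack(
        [np.cos(el) * np.sin(az), np.cos(el) * np.cos(az), np.sin(el)]
    )


def ellipsoid_surface_points(
    directions: np.ndarray,
    center: np.ndarray,
    semi_axes: np.ndarray,
) -> np.ndarray:
    """Map unit directions to points on an axis-aligned ellipsoid surface."""
    return np.asarray(center) + np.asarray(directions) * np.asarray(semi_axes)
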