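"""Angular arithmetic on compass directions.

All directions are degrees clockwise from (magnetic) North, normalized
into [0, 360). Arithmetic is modular throughout.
"""

from __future__ import annotations

import math

import numpy as np

__all__ = ["normalize_angle", "angular_difference", "correct_alignment"]


def normalize_angle(a: float) -> float:
    """Normalize a signed angle in degrees into [0, 360).

    Parameters
    ----------
    a : float
        Angle in degrees, any finite value.

    Returns
    -------
    float
        ``a mod 360`` in ``[0, 360)``.
    """
    if not math.isfinite(a):
        raise ValueError(f"angle must be finite, got {a!r}")
    out = float(np.mod(a, 360.0))
    return 0.0 if out >= 360.0 else out  # np.mod(-1e-16, 360) rounds to 360


def angular_difference(a: float, b: float) -> float:
    """Smallest angular distance between two directions, in [0, 180].

    Symmetric: ``angular_difference(a, b) == angular_difference(b, a)``.
    """
    d = abs(normalize_angle(a) - normalize_angle(b)) % 360.0
    return min(d, 360.0 - d)


def correct_alignment(assessed: float, alignment: float) -> float:
    """Rotate an observer's assessed direction by the funnel alignment.

    Observers read scratch-mark directions assuming the funnel overlap
    point faces North; when the funnel was actually aligned with its
    overlap at ``alignment`` degrees, the true direction is the assessed
    one rotated by that offset. North alignment (0°) leaves the call
    unchanged; South alignment (180°) flips it.
    """
    return normalize_angle(normalize_angle(assessed) + normalize_angle(alignment))
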