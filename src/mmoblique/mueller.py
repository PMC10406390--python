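"""Mueller calculus building blocks for the polarimeter forward model.

All matrices act on Stokes vectors (I, Q, U, V). Angles are in degrees,
measured counterclockwise from the horizontal (+x) axis.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "rotator",
    "linear_polarizer",
    "linear_retarder",
    "unpolarized_stokes",
]


def rotator(angle_deg: float) -> np.ndarray:
    """Mueller rotation matrix R(angle) for a frame rotation by ``angle_deg``."""
    a = 2.0 * np.deg2rad(angle_deg)
    c, s = np.cos(a), np.sin(a)
    return np.array(
        [
            [1.0, 0.0, 0.0, 0.0],
            [0.0, c, s, 0.0],
            [0.0, -s, c, 0.0],
            [0.0, 0.0, 0.0, 1.0],
        ]
    )


def linear_polarizer(angle_deg: float = 0.0) -> np.ndarray:
    """Ideal linear polarizer with transmission axis at ``angle_deg``."""
    p = 0.5 * np.array(
        [
            [1.0, 1.0, 0.0, 0.0],
            [1.0, 1.0, 0.0, 0.0],
            [0.0, 0.0, 0.0, 0.0],
            [0.0, 0.0, 0.0, 0.0],
        ]
    )
    return rotator(-angle_deg) @ p @ rotator(angle_deg)


def linear_retarder(retardance_deg: float, fast_axis_deg: float) -> np.ndarray:
    """Linear retarder of given retardance with fast axis at ``fast_axis_deg``.

    ``retardance_deg = 90`` is a quarter-wave plate; ``0`` is the identity.
    """
    d = np.deg2rad(retardance_deg)
    cd, sd = np.cos(d), np.sin(d)
    m = np.array(
        [
            [1.0, 0.0, 0.0, 0.0],
            [0.0, 1.0, 0.0, 0.0],
            [0.0, 0.0, cd, sd],
            [0.0, 0.0, -sd, cd],
        ]
    )
    return rotator(-fast_axis_deg) @ m @ rotator(fast_axis_deg)


def unpolarized_stokes(intensity: float = 1.0) -> np.ndarray:
    """Stokes vector of a fully unpolarized beam."""
    return np.array([intensity, 0.0, 0.0, 0.0])
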