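"""In-memory container for 16-channel Mueller-matrix images."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterator, Tuple

import numpy as np

ElementIndex = Tuple[int, int]

#: all 16 element indices in row-major order: (1,1), (1,2), ..., (4,4)
ALL_ELEMENTS: tuple[ElementIndex, ...] = tuple(
    (i, j) for i in range(1, 5) for j in range(1, 5)
)


def element_name(index: ElementIndex) -> str:
    """Canonical lowercase name of an element, e.g. ``(1, 2) -> 'm12'``."""
    i, j = index
    return f"m{i}{j}"


def check_element_index(index: ElementIndex) -> ElementIndex:
    i, j = index
    if not (1 <= i <= 4 and 1 <= j <= 4):
        raise ValueError(
            f"unknown Mueller element index {index!r}; expected (i, j) with i, j in 1..4"
        )
    return (int(i), int(j))


@dataclass
class MMImage:
    """A spatial map of all 16 Mueller-matrix elements.

    Parameters
    ----------
    elements
        Array of shape ``(4, 4, H, W)``; ``elements[i-1, j-1]`` is the map of
        element ``(i, j)``. Masked pixels are NaN.
    normalized
        True when every channel has been divided pixelwise by M11 (so channel
        (1, 1) is identically 1 where defined).
    incidence_theta
        Oblique incidence angle between the illumination and detection arms,
        in degrees, if known.
    provenance
        Free-form origin tag (e.g. ``"phantom"``, ``"reconstructed"``).
    """

    elements: np.ndarray
    normalized: bool = False
    incidence_theta: float | None = None
    provenance: str = ""
    metadata: Dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.elements = np.asarray(self.elements, dtype=float)
        if self.elements.shape[:2] != (4, 4) or self.elements.ndim != 4:
            raise ValueError(
                f"elements must have shape (4, 4, H, W); got {self.elements.shape}"
            )

    @property
    def shape(self) -> Tuple[int, int]:
        """Spatial shape (H, W)."""
        return self.elements.shape[2:]

    def channel(self, index: ElementIndex) -> np.ndarray:
        """Spatial map of one element; view, not a copy."""
        i, j = check_element_index(index)
        return self.elements[i - 1, j - 1]

    def matrix_at(self, row: int, col: int) -> np.ndarray:
        """The 4x4 Mueller matrix at one pixel."""
        return self.elements[:, :, row, col]

    def iter_channels(self) -> Iterator[Tuple[ElementIndex, np.ndarray]]:
        for index in ALL_ELEMENTS:
            yield index, self.channel(index)

    def copy(self) -> "MMImage":
        return MMImage(
            elements=self.elements.copy(),
            normalized=self.normalized,
            incidence_theta=self.incidence_theta,
            provenance=self.provenance,
            metadata=dict(self.metadata),
        )

    @classmethod
    def from_matrix(cls, matrix: np.ndarray, shape: Tuple[int, int], **kwargs) -> "MMImage":
        """Constant image in which every pixel carries the same 4x4 matrix."""
        matrix = np.asarray(matrix, dtype=float)
        if matrix.shape != (4, 4):
            raise ValueError(f"matrix must be 4x4; got {matrix.shape}")
        elements = np.broadcast_to(
            matrix[:, :, None, None], (4, 4) + tuple(shape)
        ).copy()
        return cls(elements=elements, **kwargs)
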