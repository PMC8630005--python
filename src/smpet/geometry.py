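"""2-D affine maps between camera channels.

Coordinates are (x, y) in pixel units, 0-based, with pixel centres at
integer positions.  An :class:`AffineMap` sends points ``p`` to
``matrix @ p + offset``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np


@dataclass
class AffineMap:
    matrix: np.ndarray = field(default_factory=lambda: np.eye(2))
    offset: np.ndarray = field(default_factory=lambda: np.zeros(2))

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float).reshape(2, 2)
        self.offset = np.asarray(self.offset, dtype=float).reshape(2)
        if abs(np.linalg.det(self.matrix)) < 1e-12:
            raise ValueError("affine linear part is singular")

    @classmethod
    def identity(cls) -> "AffineMap":
        return cls()

    @classmethod
    def from_shift(cls, dx: float, dy: float) -> "AffineMap":
        return cls(np.eye(2), np.array([dx, dy], dtype=float))

    @classmethod
    def from_rotation(cls, angle_deg: float, center: tuple[float, float] = (0.0, 0.0),
                      shift: tuple[float, float] = (0.0, 0.0)) -> "AffineMap":
        """Rotation about ``center`` followed by a translation ``shift``."""
        a = math.radians(angle_deg)
        rot = np.array([[math.cos(a), -math.sin(a)], [math.sin(a), math.cos(a)]])
        c = np.asarray(center, dtype=float)
        off = c - rot @ c + np.asarray(shift, dtype=float)
        return cls(rot, off)

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return pts @ self.matrix.T + self.offset

    def inverse(self) -> "AffineMap":
        inv = np.linalg.inv(self.matrix)
        return AffineMap(inv, -inv @ self.offset)

    def compose(self, other: "AffineMap") -> "AffineMap":
        """Map equal to applying ``other`` first, then ``self``."""
        return AffineMap(self.matrix @ other.matrix,
                         self.matrix @ other.offset + self.offset)
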