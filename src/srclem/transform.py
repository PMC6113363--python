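"""Planar affine transforms between imaging coordinate frames.

A single SEM acquisition has to be mapped onto the light-microscopy (LM)
pixel grid (or vice versa).  Because critical-point drying and sputtering
distort the sample slightly anisotropically, a similarity transform
(scale + rotation + translation) is not sufficient and the full 6-parameter
affine model -- which adds shear and anisotropic scale -- is required.

Conventions
-----------
* Points are ``(x, y)`` pairs; arrays of points have shape ``(n, 2)``.
* A transform maps source coordinates to target coordinates via
  ``y = A @ x + t`` with ``A`` the 2x2 matrix and ``t`` the translation.
* Pixel indices are 0-based with pixel centers on integer coordinates;
  ``x`` runs along columns, ``y`` along rows.
"""
from __future__ import annotations

import dataclasses
import math
from typing import Iterable

import numpy as np

__all__ = ["AffineTransform2D"]


@dataclasses.dataclass(frozen=True)
class AffineTransform2D:
    """2D affine map ``y = A x + t``.

    Parameters
    ----------
    matrix:
        Row-major 2x2 matrix ``((a11, a12), (a21, a22))`` (dimensionless
        when source and target share units, otherwise carrying the unit
        conversion, e.g. nm -> SEM pixel).
    translation:
        ``(tx, ty)`` offset in target units.
    """

    matrix: tuple[tuple[float, float], tuple[float, float]] = ((1.0, 0.0), (0.0, 1.0))
    translation: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        A = np.asarray(self.matrix, dtype=float)
        t = np.asarray(self.translation, dtype=float)
        if A.shape != (2, 2) or t.shape != (2,):
            raise ValueError("matrix must be 2x2 and translation length 2")
        if not (np.all(np.isfinite(A)) and np.all(np.isfinite(t))):
            raise ValueError("affine parameters must be finite")
        object.__setattr__(self, "matrix", ((float(A[0, 0]), float(A[0, 1])),
                                            (float(A[1, 0]), float(A[1, 1]))))
        object.__setattr__(self, "translation", (float(t[0]), float(t[1])))

    # -- constructors ---------------------------------------------------
    @classmethod
    def identity(cls) -> "AffineTransform2D":
        return cls()

    @classmethod
    def from_components(
        cls,
        scale: float | tuple[float, float] = 1.0,
        rotation_deg: float = 0.0,
        shear: float = 0.0,
        translation: tuple[float, float] = (0.0, 0.0),
    ) -> "AffineTransform2D":
        """Compose ``A = R(rotation) @ diag(sx, sy) @ [[1, shear], [0, 1]]``.

        ``shear`` is the dimensionless horizontal shear factor (1% shear =
        0.01); ``scale`` may be a scalar or an anisotropic ``(sx, sy)`` pair.
        """
        if np.isscalar(scale):
            sx = sy = float(scale)
        else:
            sx, sy = (float(s) for s in scale)
        th = math.radians(rotation_deg)
        R = np.array([[math.cos(th), -math.sin(th)], [math.sin(th), math.cos(th)]])
        S = np.diag([sx, sy])
        H = np.array([[1.0, float(shear)], [0.0, 1.0]])
        return cls(tuple(map(tuple, R @ S @ H)), tuple(translation))

    # -- accessors ------------------------------------------------------
    @property
    def A(self) -> np.ndarray:
        return np.asarray(self.matrix, dtype=float)

    @property
    def t(self) -> np.ndarray:
        return np.asarray(self.translation, dtype=float)

    @property
    def determinant(self) -> float:
        A = self.A
        return float(A[0, 0] * A[1, 1] - A[0, 1] * A[1, 0])

    def is_invertible(self, tol: float = 1e-12) -> bool:
        return abs(self.determinant) > tol

    # -- algebra --------------------------------------------------------
    def apply(self, points: Iterable) -> np.ndarray:
        """Map ``(n, 2)`` (or a single ``(2,)``) source points to target."""
        p = np.asarray(points, dtype=float)
        single = p.ndim == 1
        p = np.atleast_2d(p)
        if p.shape[-1] != 2:
            raise ValueError("points must have shape (n, 2)")
        out = p @ self.A.T + self.t
        return out[0] if single else out

    def __call__(self, points: Iterable) -> np.ndarray:
        return self.apply(points)

    def compose(self, other: "AffineTransform2D") -> "AffineTransform2D":
        """Return ``self after other``: ``(self o other)(x) = self(other(x))``."""
        A = self.A @ other.A
        t = self.A @ other.t + self.t
        return AffineTransform2D(tuple(map(tuple, A)), tuple(t))

    def inverse(self) -> "AffineTransform2D":
        if not self.is_invertible():
            raise ValueError("affine transform is singular and cannot be inverted")
        Ainv = np.linalg.inv(self.A)
        return AffineTransform2D(tuple(map(tuple, Ainv)), tuple(-Ainv @ self.t))

    # -- serialization --------------------------------------------------
    def to_dict(self) -> dict:
        return {"matrix": [list(r) for r in self.matrix],
                "translation": list(self.translation)}

    @classmethod
    def from_dict(cls, d: dict) -> "AffineTransform2D":
        return cls(tuple(map(tuple, d["matrix"])), tuple(d["translation"]))

    def isclose(self, other: "AffineTransform2D", rtol: float = 1e-9,
                atol: float = 1e-9) -> bool:
        return bool(
            np.allclose(self.A, other.A, rtol=rtol, atol=atol)
            and np.allclose(self.t, other.t, rtol=rtol, atol=atol)
        )
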