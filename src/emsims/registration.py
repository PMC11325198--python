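"""Landmark-based registration between the EM frame and the SIMS frame.

Correlative workflows image the same ultrathin section twice: first a TEM
mosaic (where structures are annotated), then a nanoSIMS scan (where ion
counts are quantified). The two frames differ by translation, rotation,
scale and a mild anisotropic scan stretch, so a full 6-parameter affine map
is fitted by linear least squares from user-supplied landmark point pairs.
A 4-parameter similarity fit is available for sanity checks.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "AffineMap",
    "DegenerateLandmarksError",
    "fit_affine",
    "apply_affine",
    "read_landmarks",
    "write_landmarks",
]


class DegenerateLandmarksError(ValueError):
    """Fewer than three landmark pairs, or a collinear configuration."""


@dataclass(frozen=True)
class AffineMap:
    """A planar affine transform ``x -> linear @ x + offset`` (pixel units).

    Attributes
    ----------
    linear : (2, 2) ndarray
        Non-singular linear part.
    offset : (2,) ndarray
        Translation, in pixels.
    rms_residual : float
        Root-mean-square landmark residual of the fit that produced the map
        (0 for exactly constructed maps).
    """

    linear: np.ndarray
    offset: np.ndarray
    rms_residual: float = 0.0

    def __post_init__(self) -> None:
        lin = np.asarray(self.linear, dtype=float).reshape(2, 2)
        off = np.asarray(self.offset, dtype=float).reshape(2)
        if abs(np.linalg.det(lin)) < 1e-12:
            raise ValueError("affine linear part is singular")
        if self.rms_residual < 0:
            raise ValueError("rms_residual must be non-negative")
        object.__setattr__(self, "linear", lin)
        object.__setattr__(self, "offset", off)

    # -- algebra ---------------------------------------------------------
    @classmethod
    def identity(cls) -> "AffineMap":
        return cls(np.eye(2), np.zeros(2))

    @property
    def is_identity(self) -> bool:
        return bool(
            np.allclose(self.linear, np.eye(2), atol=1e-12)
            and np.allclose(self.offset, 0.0, atol=1e-12)
        )

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        single = pts.ndim == 1
        pts = np.atleast_2d(pts)
        out = pts @ self.linear.T + self.offset
        return out[0] if single else out

    def compose(self, inner: "AffineMap") -> "AffineMap":
        """Return the map ``self o inner`` (apply ``inner`` first)."""
        return AffineMap(
            self.linear @ inner.linear,
            self.linear @ inner.offset + self.offset,
        )

    def inverse(self) -> "AffineMap":
        inv = np.linalg.inv(self.linear)
        return AffineMap(inv, -inv @ self.offset)

    # -- serialization ---------------------------------------------------
    def to_record(self) -> str:
        """Serialize to a single text line: a11 a12 a21 a22 tx ty rms."""
        vals = [*self.linear.ravel(), *self.offset, self.rms_residual]
        return " ".join(format(v, ".17g") for v in vals)

    @classmethod
    def from_record(cls, record: str) -> "AffineMap":
        vals = [float(tok) for tok in record.split()]
        if len(vals) not in (6, 7):
            raise ValueError("affine record must hold 6 or 7 numbers")
        rms = vals[6] if len(vals) == 7 else 0.0
        return cls(np.array(vals[:4]).reshape(2, 2), np.array(vals[4:6]), rms)


def _split_pairs(
    pairs, sims_points
) -> tuple[np.ndarray, np.ndarray]:
    if sims_points is None:
        arr = [(np.asarray(em, float), np.asarray(sm, float)) for em, sm in pairs]
        em = np.array([a for a, _ in arr], dtype=float)
        sims = np.array([b for _, b in arr], dtype=float)
    else:
        em = np.asarray(pairs, dtype=float)
        sims = np.asarray(sims_points, dtype=float)
    if em.shape != sims.shape or em.ndim != 2 or em.shape[1] != 2:
        raise ValueError("landmarks must be matched (n, 2) point sets")
    return em, sims


def fit_affine(
    pairs: Iterable[tuple[Sequence[float], Sequence[float]]] | np.ndarray,
    sims_points: np.ndarray | None = None,
    *,
    model: str = "affine",
) -> AffineMap:
    """Fit the EM -> SIMS map minimizing squared SIMS-frame residuals.

    Parameters
    ----------
    pairs
        Either an iterable of ``(em_point, sims_point)`` tuples, or an
        ``(n, 2)`` array of EM points (then ``sims_points`` must be given).
    model
        ``"affine"`` (6 parameters, default) or ``"similarity"``
        (rotation + isotropic scale + translation, via the orthogonal
        Procrustes solution).

    With exactly three non-collinear pairs the affine fit interpolates.
    """
    em, sims = _split_pairs(pairs, sims_points)
    n = em.shape[0]
    if n < 3:
        raise DegenerateLandmarksError(f"need >= 3 landmark pairs, got {n}")
    centered = em - em.mean(axis=0)
    svals = np.linalg.svd(centered, compute_uv=False)
    if svals[1] <= 1e-9 * max(svals[0], 1.0):
        raise DegenerateLandmarksError("EM landmarks are (near-)collinear")

    if model == "affine":
        design = np.column_stack([em, np.ones(n)])
        coef, *_ = np.linalg.lstsq(design, sims, rcond=None)
        linear = coef[:2].T
        offset = coef[2]
    elif model == "similarity":
        mu_e, mu_s = em.mean(axis=0), sims.mean(axis=0)
        e, s = em - mu_e, sims - mu_s
        u, sv, vt = np.linalg.svd(s.T @ e)
        d = np.sign(np.linalg.det(u @ vt))
        rot = u @ np.diag([1.0, d]) @ vt
        scale = (sv @ [1.0, d]) / (e**2).sum()
        linear = scale * rot
        offset = mu_s - linear @ mu_e
    else:
        raise ValueError(f"unknown model {model!r}")

    resid = em @ linear.T + offset - sims
    rms = float(np.sqrt((resid**2).sum(axis=1).mean()))
    return AffineMap(linear, offset, rms)


def apply_affine(affine: AffineMap, geometry):
    """Transport a point, an ``(n, 2)`` point set, or a shapely Polygon.

    Polygons keep their topology (vertices are mapped one-to-one); the
    returned object has the same kind as the input.
    """
    try:
        from shapely.geometry import Polygon
    except ImportError:  # pragma: no cover
        Polygon = None
    if Polygon is not None and isinstance(geometry, Polygon):
        shell = affine.apply(np.asarray(geometry.exterior.coords))
        holes = [affine.apply(np.asarray(r.coords)) for r in geometry.interiors]
        return Polygon(shell, holes)
    return affine.apply(geometry)


def write_landmarks(path, em_points: np.ndarray, sims_points: np.ndarray) -> None:
    """Write the landmark CSV (columns em_x, em_y, sims_x, sims_y)."""
    em = np.asarray(em_points, float)
    sims = np.asarray(sims_points, float)
    table = np.column_stack([em, sims])
    header = "em_x,em_y,sims_x,sims_y"
    np.savetxt(path, table, delimiter=",", header=header, comments="")


def read_landmarks(path) -> tuple[np.ndarray, np.ndarray]:
    data = np.loadtxt(Path(path), delimiter=",", skiprows=1, ndmin=2)
    if data.shape[1] != 4:
        raise ValueError("landmark CSV must have 4 columns")
    return data[:, :2], data[:, 2:]
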