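"""ROI annotations: polygons with structure-class labels, in EM-frame pixels.

The GeoJSON dialect mirrors hand annotation on the EM mosaic: each Feature is
a Polygon whose properties carry the structure class, optional vesicle
points, a nascent-zone flag (PSDs), a pre/post pair identifier, a parent link
for sub-compartments, and the myelin inner contour.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from shapely.geometry import Polygon

STRUCTURE_CLASSES = (
    "myelin",
    "axon",
    "neurite",
    "mitochondrion",
    "presynapse",
    "postsynapse",
    "active_zone",
    "PSD",
)

#: label-image codes; 0 is background
CLASS_CODES = {name: i + 1 for i, name in enumerate(STRUCTURE_CLASSES)}

__all__ = [
    "STRUCTURE_CLASSES",
    "CLASS_CODES",
    "RoiAnnotation",
    "InvalidPolygonError",
    "read_annotations",
    "write_annotations",
]


class InvalidPolygonError(ValueError):
    """Self-intersecting or degenerate (<3 vertices) outline."""


@dataclass
class RoiAnnotation:
    """One annotated structure.

    ``polygon`` vertices are EM-frame pixel coordinates (x=column, y=row).
    ``inner_contour`` is present exactly for myelin (the sheath's inner
    boundary); ``vesicles`` only for presynapses; ``nascent_zone`` only for
    PSDs; ``parent_id`` links active zones / PSDs / contained mitochondria
    to their parent structure.
    """

    object_id: int
    structure: str
    polygon: np.ndarray
    vesicles: np.ndarray | None = None
    nascent_zone: bool | None = None
    pair_id: int | None = None
    inner_contour: np.ndarray | None = None
    parent_id: int | None = None

    def __post_init__(self) -> None:
        if self.structure not in STRUCTURE_CLASSES:
            raise ValueError(f"unknown structure class {self.structure!r}")
        self.polygon = _check_polygon(np.asarray(self.polygon, dtype=float))
        if self.vesicles is not None:
            self.vesicles = np.asarray(self.vesicles, dtype=float).reshape(-1, 2)
        if (self.inner_contour is not None) != (self.structure == "myelin"):
            raise ValueError("inner_contour must be present iff class is myelin")
        if self.inner_contour is not None:
            self.inner_contour = _check_polygon(
                np.asarray(self.inner_contour, dtype=float)
            )

    def to_feature(self) -> dict:
        props = {
            "object_id": int(self.object_id),
            "class": self.structure,
            "pair_id": None if self.pair_id is None else int(self.pair_id),
            "nascent_zone": self.nascent_zone,
            "parent_id": None if self.parent_id is None else int(self.parent_id),
        }
        if self.vesicles is not None:
            props["vesicles"] = self.vesicles.tolist()
        if self.inner_contour is not None:
            props["inner_contour"] = self.inner_contour.tolist()
        ring = self.polygon.tolist()
        ring.append(ring[0])  # GeoJSON rings close explicitly
        return {
            "type": "Feature",
            "geometry": {"type": "Polygon", "coordinates": [ring]},
            "properties": props,
        }

    @classmethod
    def from_feature(cls, feature: dict) -> "RoiAnnotation":
        geom = feature["geometry"]
        if geom["type"] != "Polygon":
            raise ValueError("annotation features must be Polygons")
        ring = np.asarray(geom["coordinates"][0], dtype=float)
        if len(ring) > 1 and np.allclose(ring[0], ring[-1]):
            ring = ring[:-1]
        p = feature.get("properties", {})
        vesicles = p.get("vesicles")
        inner = p.get("inner_contour")
        return cls(
            object_id=int(p["object_id"]),
            structure=p["class"],
            polygon=ring,
            vesicles=None if vesicles is None else np.asarray(vesicles, float),
            nascent_zone=p.get("nascent_zone"),
            pair_id=p.get("pair_id"),
            inner_contour=None if inner is None else np.asarray(inner, float),
            parent_id=p.get("parent_id"),
        )


def _check_polygon(verts: np.ndarray) -> np.ndarray:
    if verts.ndim != 2 or verts.shape[1] != 2 or verts.shape[0] < 3:
        raise InvalidPolygonError("polygon needs at least 3 (x, y) vertices")
    poly = Polygon(verts)
    if not poly.is_valid or poly.area == 0:
        raise InvalidPolygonError("polygon is self-intersecting or degenerate")
    return verts


def write_annotations(path: str | Path, annotations: list[RoiAnnotation]) -> None:
    collection = {
        "type": "FeatureCollection",
        "features": [a.to_feature() for a in annotations],
    }
    Path(path).write_text(json.dumps(collection))


def read_annotations(path: str | Path) -> list[RoiAnnotation]:
    collection = json.loads(Path(path).read_text())
    return [RoiAnnotation.from_feature(f) for f in collection["features"]]
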