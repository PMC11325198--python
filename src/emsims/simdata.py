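"""Synthetic brain-ultrastructure scenes with simulated nanoSIMS acquisition.

No public dataset of paired EM annotations and ion-count images exists, so
the pipeline is exercised on generated scenes with known ground truth. A
scene is a square field (default 15 um at 512 px, i.e. ~29 nm pixels, inside
the instrument's usual 20-43 nm window) populated with the eight analyzed
structure classes: myelin sheaths (annuli around axon cores), axons,
neurites, mitochondria, and pre/postsynapse pairs carrying active-zone and
PSD sub-compartments plus vesicle point clouds.

Enrichment model
----------------
Each object of class c carries a true ^15N/^14N ratio

    r = mu_c * exp(beta * z + sigma * g - (beta^2 + sigma^2)/2)

where mu_c is the class mean, z is the object's standardized log-size,
g ~ N(0, 1) is object-level dispersion with sigma = sqrt(ln(1 + cv^2)), and
beta couples size to enrichment (negative by default: larger objects are
metabolically older). E[r] = mu_c exactly; beta = 0, cv = 0 gives identical
ratios within a class. Active zones and PSDs inherit their parent's ratio
scaled by mu_child/mu_parent with reduced extra dispersion. Paired pre/post
ratios are drawn with Pearson correlation ``pair_correlation_rho`` (both the
size and dispersion deviations are drawn from a Gaussian copula whose latent
correlation is solved from the lognormal moment identity). Nascent-zone
flags are Bernoulli with a logistic link in the PSD's standardized
log-ratio.

Acquisition model
-----------------
Ion counting is shot-noise limited: with per-pixel total CN- yield lambda_c
for class c and true ratio r, the channels are independent Poisson draws

    C14 ~ Poisson(lambda_c / (1 + r)),   C15 ~ Poisson(lambda_c * r / (1 + r))

so the expected channel sum is lambda_c and the expected count ratio is
exactly r. The SIMS grid is the EM grid pushed through the scene's
``em_to_sims`` affine (identity by default).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from shapely.geometry import Polygon

from ._rng import substream
from .annotations import CLASS_CODES, STRUCTURE_CLASSES, RoiAnnotation, read_annotations, write_annotations
from .geometry import polygon_mask
from .isotope_ratio import NATURAL_15N_RATIO, IonImagePair
from .registration import AffineMap, read_landmarks, write_landmarks

__all__ = [
    "SceneSpec",
    "AcquisitionParams",
    "ObjectTruth",
    "SceneTruth",
    "Fixture",
    "PlacementError",
    "build_scene",
    "simulate_acquisition",
    "expected_rate_images",
    "export_fixture",
    "import_fixture",
    "sample_cohort",
]

# ----------------------------------------------------------------------
# defaults: class composition of one field
# ----------------------------------------------------------------------

DEFAULT_STRUCTURE_COUNTS = {
    "myelin": 2,
    "axon": 4,
    "neurite": 6,
    "mitochondrion": 6,
    "presynapse": 8,
    "postsynapse": 8,
    "active_zone": 8,
    "PSD": 8,
}

#: mean true ^15N/^14N per class after 21 d of full ^15N labeling: synaptic
#: sub-compartments are the most turnover-active, myelin the least, and all
#: sit well above the natural 0.0037 baseline.
DEFAULT_CLASS_ENRICHMENT = {
    "myelin": 0.006,
    "axon": 0.009,
    "neurite": 0.010,
    "mitochondrion": 0.011,
    "presynapse": 0.014,
    "postsynapse": 0.015,
    "active_zone": 0.018,
    "PSD": 0.018,
}

#: typical section-profile equivalent radii (nm)
BASE_RADIUS_NM = {
    "myelin": 550.0,  # outer sheath radius
    "axon": 250.0,
    "neurite": 400.0,
    "mitochondrion": 300.0,
    "presynapse": 350.0,
    "postsynapse": 330.0,
}

MYELIN_WIDTH_NM = 150.0  # mean sheath thickness
SIZE_LOG_SD = 0.25  # log-sd of object radius; z below is this deviate
VESICLE_DENSITY_PER_UM2 = 75.0
AZ_DEPTH_NM = 80.0  # active-zone band depth along the synaptic face
PSD_DEPTH_NM = 100.0
ASPECT = {"neurite": 3.2, "mitochondrion": 1.6}
#: sub-compartment area as a fraction of the parent profile (sampling path)
CHILD_AREA_FRACTION = {"active_zone": 0.18, "PSD": 0.22}

#: fraction of the scanned area covered by annotated structures in the
#: object-level sampling path; the rest is unannotated tissue/resin at the
#: background ratio (hand annotation covers a small part of each field)
ANNOTATED_AREA_FRACTION = 0.05


class PlacementError(RuntimeError):
    """A structure could not be placed within the retry budget."""


@dataclass
class SceneSpec:
    """Generative parameters of one synthetic field."""

    field_size_um: float = 15.0
    pixels_per_side: int = 512
    structure_counts: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_STRUCTURE_COUNTS)
    )
    class_enrichment: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_ENRICHMENT)
    )
    enrichment_cv: float = 0.3
    size_coupling_beta: float = -0.3
    pair_correlation_rho: float = 0.7
    nascent_logit_slope: float = 2.0
    background_ratio: float = NATURAL_15N_RATIO
    seed: int = 0
    em_to_sims: AffineMap | None = None

    def __post_init__(self) -> None:
        if self.field_size_um <= 0 or self.pixels_per_side <= 0:
            raise ValueError("field size and pixel count must be positive")
        if self.pixels_per_side not in (256, 512, 1024):
            warnings.warn(
                f"{self.pixels_per_side} px per side is outside the usual "
                "{256, 512, 1024} acquisition formats",
                stacklevel=2,
            )
        for cls, n in self.structure_counts.items():
            if cls not in STRUCTURE_CLASSES:
                raise ValueError(f"unknown structure class {cls!r}")
            if n < 0:
                raise ValueError(f"negative count for {cls}")
        for cls, r in self.class_enrichment.items():
            if r <= 0:
                raise ValueError(f"class ratio for {cls} must be positive")
        if self.background_ratio <= 0:
            raise ValueError("background_ratio must be positive")
        if self.enrichment_cv < 0:
            raise ValueError("enrichment_cv must be non-negative")
        if not -1.0 <= self.pair_correlation_rho <= 1.0:
            raise ValueError("pair_correlation_rho must lie in [-1, 1]")
        n_az = self.structure_counts.get("active_zone", 0)
        n_psd = self.structure_counts.get("PSD", 0)
        if n_az > self.structure_counts.get("presynapse", 0):
            raise ValueError("more active zones requested than presynapses")
        if n_psd > self.structure_counts.get("postsynapse", 0):
            raise ValueError("more PSDs requested than postsynapses")

    @property
    def pixel_size_nm(self) -> float:
        return 1000.0 * self.field_size_um / self.pixels_per_side


@dataclass
class AcquisitionParams:
    """Per-class expected total CN- counts per pixel, plus scan metadata."""

    yield_per_pixel: dict[str, float] = field(
        default_factory=lambda: {c: 800.0 for c in (*STRUCTURE_CLASSES, "background")}
    )
    dwell_time_ms: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        for cls, lam in self.yield_per_pixel.items():
            if lam < 0:
                raise ValueError(f"negative yield for {cls}")
        if not 4.0 <= self.dwell_time_ms <= 11.0:
            warnings.warn(
                f"dwell time {self.dwell_time_ms} ms outside the usual 4-11 ms",
                stacklevel=2,
            )

    def lam(self, cls: str) -> float:
        return float(self.yield_per_pixel[cls])


@dataclass
class ObjectTruth:
    """One generated object with its realized ground truth."""

    object_id: int
    structure: str
    polygon: np.ndarray  # EM-frame pixel vertices
    true_ratio: float
    area_px: int  # rasterized footprint of the polygon (ring for myelin)
    size_z: float
    radius_px: float
    vesicles: np.ndarray | None = None
    vesicle_count: int = 0
    nascent_zone: bool | None = None
    pair_id: int | None = None
    parent_id: int | None = None
    inner_contour: np.ndarray | None = None
    width_px: float | None = None


@dataclass
class SceneTruth:
    """Realized scene: label/ratio images plus the object list."""

    spec: SceneSpec
    label_image: np.ndarray  # uint8 class codes, 0 = background
    object_id_image: np.ndarray  # int32 object ids, 0 = background
    ratio_image: np.ndarray  # per-pixel true ratio
    objects: list[ObjectTruth]
    em_to_sims: AffineMap
    landmarks_em: np.ndarray
    landmarks_sims: np.ndarray


@dataclass
class Fixture:
    """A re-imported on-disk fixture."""

    pair: IonImagePair
    annotations: list[RoiAnnotation]
    landmarks_em: np.ndarray
    landmarks_sims: np.ndarray
    truth: pd.DataFrame
    label_image: np.ndarray
    meta: dict


# ----------------------------------------------------------------------
# object parameter draws (shared by the imaging and sampling paths)
# ----------------------------------------------------------------------


def _sigma_ln(cv: float) -> float:
    return float(np.sqrt(np.log1p(cv**2)))


def _latent_rho(rho: float, s2: float) -> float:
    """Gaussian-copula correlation giving lognormal Pearson correlation rho.

    For equal log-variances s2, Pearson(levels) = (exp(rho_g*s2)-1) /
    (exp(s2)-1); invert for rho_g and clip to the feasible range.
    """
    if s2 <= 0 or rho == 0:
        return 0.0
    arg = 1.0 + rho * np.expm1(s2)
    if arg <= 0:
        return -1.0
    return float(np.clip(np.log(arg) / s2, -1.0, 1.0))


def _bivariate(rng: np.random.Generator, rho: float) -> tuple[float, float]:
    a = rng.standard_normal()
    b = rho * a + np.sqrt(max(1.0 - rho**2, 0.0)) * rng.standard_normal()
    return float(a), float(b)


def _draw_objects(spec: SceneSpec, rng: np.random.Generator) -> list[dict]:
    """Draw per-object classes, sizes, true ratios, pairing and flags.

    Returns dicts in a fixed id order (myelin, axons, neurites,
    mitochondria, synapse pairs, unpaired synapses, active zones, PSDs);
    geometry placement happens separately so that the parameter stream does
    not depend on placement retries.
    """
    counts = {c: int(spec.structure_counts.get(c, 0)) for c in STRUCTURE_CLASSES}
    mu = {**DEFAULT_CLASS_ENRICHMENT, **spec.class_enrichment}
    sigma = _sigma_ln(spec.enrichment_cv)
    beta = spec.size_coupling_beta
    s2 = beta**2 + sigma**2
    rho_g = _latent_rho(spec.pair_correlation_rho, s2)
    px = spec.pixel_size_nm

    def base_radius_px(cls: str) -> float:
        return BASE_RADIUS_NM[cls] / px

    def ratio_of(cls: str, z: float, g: float) -> float:
        return mu[cls] * float(np.exp(beta * z + sigma * g - s2 / 2.0))

    objects: list[dict] = []
    next_id = 1

    def new(cls: str, **kw) -> dict:
        nonlocal next_id
        obj = {
            "object_id": next_id,
            "structure": cls,
            "pair_id": None,
            "parent_id": None,
            "core_of": None,
            "width_px": None,
            "vesicle_count": 0,
            "nascent": None,
            **kw,
        }
        objects.append(obj)
        next_id += 1
        return obj

    # myelin sheaths (annuli); width shares the size deviate so thicker
    # sheaths couple to enrichment through beta, matching outer size
    myelin_objs = []
    for _ in range(counts["myelin"]):
        z, g = rng.standard_normal(), rng.standard_normal()
        r_out = base_radius_px("myelin") * np.exp(SIZE_LOG_SD * z)
        width = (MYELIN_WIDTH_NM / px) * np.exp(SIZE_LOG_SD * z)
        width = min(width, 0.6 * r_out)
        myelin_objs.append(
            new(
                "myelin",
                size_z=z,
                radius_px=float(r_out),
                width_px=float(width),
                true_ratio=ratio_of("myelin", z, g),
            )
        )

    # axons: the first ones are myelin cores (radius = the sheath's inner
    # radius, with z back-computed so the size-enrichment coupling is kept)
    n_core = min(counts["myelin"], counts["axon"])
    for k in range(counts["axon"]):
        z, g = rng.standard_normal(), rng.standard_normal()
        if k < n_core:
            host = myelin_objs[k]
            radius = host["radius_px"] - host["width_px"]
            z = float(np.log(radius / base_radius_px("axon")) / SIZE_LOG_SD)
            core_of = host["object_id"]
        else:
            radius = base_radius_px("axon") * np.exp(SIZE_LOG_SD * z)
            core_of = None
        new(
            "axon",
            size_z=float(z),
            radius_px=float(radius),
            true_ratio=ratio_of("axon", z, g),
            core_of=core_of,
        )

    for cls in ("neurite", "mitochondrion"):
        for _ in range(counts[cls]):
            z, g = rng.standard_normal(), rng.standard_normal()
            new(
                cls,
                size_z=float(z),
                radius_px=float(base_radius_px(cls) * np.exp(SIZE_LOG_SD * z)),
                true_ratio=ratio_of(cls, z, g),
            )

    # synapses: paired first, then unpaired leftovers
    n_pairs = min(counts["presynapse"], counts["postsynapse"])
    pre_objs, post_objs = [], []
    pair_id = 0
    for _ in range(n_pairs):
        pair_id += 1
        z_pre, z_post = _bivariate(rng, rho_g)
        g_pre, g_post = _bivariate(rng, rho_g)
        pre_objs.append(
            new(
                "presynapse",
                size_z=z_pre,
                radius_px=float(base_radius_px("presynapse") * np.exp(SIZE_LOG_SD * z_pre)),
                true_ratio=ratio_of("presynapse", z_pre, g_pre),
                pair_id=pair_id,
            )
        )
        post_objs.append(
            new(
                "postsynapse",
                size_z=z_post,
                radius_px=float(base_radius_px("postsynapse") * np.exp(SIZE_LOG_SD * z_post)),
                true_ratio=ratio_of("postsynapse", z_post, g_post),
                pair_id=pair_id,
            )
        )
    for cls, store in (("presynapse", pre_objs), ("postsynapse", post_objs)):
        for _ in range(counts[cls] - n_pairs):
            pair_id += 1
            z, g = rng.standard_normal(), rng.standard_normal()
            store.append(
                new(
                    cls,
                    size_z=float(z),
                    radius_px=float(base_radius_px(cls) * np.exp(SIZE_LOG_SD * z)),
                    true_ratio=ratio_of(cls, z, g),
                    pair_id=pair_id,
                )
            )

    # sub-compartments inherit the parent ratio scaled by the class-mean
    # quotient, with halved extra dispersion
    sig_c = sigma / 2.0
    for child_cls, parents, parent_cls in (
        ("active_zone", pre_objs, "presynapse"),
        ("PSD", post_objs, "postsynapse"),
    ):
        boost = mu[child_cls] / mu[parent_cls]
        for parent in parents[: counts[child_cls]]:
            g_c = rng.standard_normal()
            ratio = parent["true_ratio"] * boost * float(
                np.exp(sig_c * g_c - sig_c**2 / 2.0)
            )
            new(
                child_cls,
                size_z=parent["size_z"],
                radius_px=parent["radius_px"],
                true_ratio=ratio,
                pair_id=parent["pair_id"],
                parent_id=parent["object_id"],
            )

    # vesicle counts scale with the bouton profile area
    px_area_um2 = (px / 1000.0) ** 2
    for obj in pre_objs:
        area_um2 = np.pi * obj["radius_px"] ** 2 * px_area_um2
        obj["vesicle_count"] = int(rng.poisson(VESICLE_DENSITY_PER_UM2 * area_um2))

    # nascent-zone flags: logistic in the PSD's standardized log-ratio
    psds = [o for o in objects if o["structure"] == "PSD"]
    if psds:
        logs = np.log([o["true_ratio"] for o in psds])
        sd = logs.std()
        zscores = (logs - logs.mean()) / sd if sd > 0 else np.zeros(len(logs))
        prob = 1.0 / (1.0 + np.exp(-spec.nascent_logit_slope * zscores))
        draws = rng.uniform(size=len(psds))
        for o, p, u in zip(psds, prob, draws):
            o["nascent"] = bool(u < p)

    return objects


# ----------------------------------------------------------------------
# shapes and placement
# ----------------------------------------------------------------------


def _disc(center, radius: float, n: int = 256) -> np.ndarray:
    ang = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
    return np.column_stack(
        [center[0] + radius * np.cos(ang), center[1] + radius * np.sin(ang)]
    )


def _ellipse(center, a: float, b: float, angle: float, n: int = 64) -> np.ndarray:
    ang = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
    x = a * np.cos(ang)
    y = b * np.sin(ang)
    ca, sa = np.cos(angle), np.sin(angle)
    return np.column_stack(
        [center[0] + ca * x - sa * y, center[1] + sa * x + ca * y]
    )


def _blob(center, radius: float, rng: np.random.Generator, n: int = 28) -> np.ndarray:
    """Star-shaped (hence simple), roughly convex outline."""
    ang = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
    ph = rng.uniform(0.0, 2.0 * np.pi, size=2)
    amp = rng.uniform(0.04, 0.14, size=2)
    rad = radius * (1.0 + amp[0] * np.cos(2 * ang + ph[0]) + amp[1] * np.cos(3 * ang + ph[1]))
    return np.column_stack([center[0] + rad * np.cos(ang), center[1] + rad * np.sin(ang)])


def _face_band(parent: np.ndarray, direction: np.ndarray, depth: float) -> np.ndarray:
    """Band of the parent outline within ``depth`` of its extreme point
    along ``direction`` (the synaptic face)."""
    poly = Polygon(parent)
    u = direction / np.linalg.norm(direction)
    v = np.array([-u[1], u[0]])
    proj = parent @ u
    perp = parent @ v
    pmax = proj.max()
    tmid = 0.5 * (perp.min() + perp.max())
    half_w = 4.0 * max(Polygon(parent).length / (2 * np.pi), depth)
    corners = [
        (pmax - depth) * u + (tmid + half_w) * v,
        (pmax - depth) * u + (tmid - half_w) * v,
        (pmax + 2.0) * u + (tmid - half_w) * v,
        (pmax + 2.0) * u + (tmid + half_w) * v,
    ]
    band = poly.intersection(Polygon(np.array(corners)))
    if band.is_empty:
        raise PlacementError("synaptic face band is empty")
    if band.geom_type == "MultiPolygon":
        band = max(band.geoms, key=lambda g: g.area)
    verts = np.asarray(band.exterior.coords)[:-1]
    if len(verts) < 3:
        raise PlacementError("degenerate synaptic face band")
    return verts


def _sample_points_in(polygon: np.ndarray, n: int, rng: np.random.Generator) -> np.ndarray:
    if n == 0:
        return np.zeros((0, 2))
    poly = Polygon(polygon)
    minx, miny, maxx, maxy = poly.bounds
    out = []
    budget = 200 * max(n, 1)
    while len(out) < n and budget > 0:
        m = max(4 * (n - len(out)), 16)
        budget -= m
        cand = np.column_stack(
            [rng.uniform(minx, maxx, m), rng.uniform(miny, maxy, m)]
        )
        import shapely

        keep = shapely.intersects_xy(poly, cand[:, 0], cand[:, 1])
        out.extend(cand[keep].tolist())
    return np.asarray(out[:n])


def build_scene(spec: SceneSpec) -> SceneTruth:
    """Generate a scene: draw object parameters, place geometry, rasterize.

    Deterministic for a fixed ``spec.seed``. Raises :class:`PlacementError`
    naming the class when a structure cannot be placed without overlap
    within the retry budget.
    """
    params = _draw_objects(spec, substream(spec.seed, "objects"))
    rng = substream(spec.seed, "geometry")
    n = spec.pixels_per_side

    placed: dict[int, dict] = {}  # object_id -> geometry record
    occupied: list[Polygon] = []

    def fits(poly: Polygon, margin: float = 1.0) -> bool:
        minx, miny, maxx, maxy = poly.bounds
        if minx < 1 or miny < 1 or maxx > n - 2 or maxy > n - 2:
            return False
        return all(not poly.buffer(margin).intersects(q) for q in occupied)

    def place(obj: dict, maker, retries: int = 800) -> dict:
        for _ in range(retries):
            center = rng.uniform(obj["radius_px"] + 2, n - obj["radius_px"] - 3, 2)
            geo = maker(center)
            if geo is None:
                continue
            shape = geo["shape"]
            if fits(shape):
                occupied.append(shape)
                geo["center"] = center
                placed[obj["object_id"]] = geo
                return geo
        raise PlacementError(
            f"could not place a {obj['structure']} within the retry budget"
        )

    # --- geometry: largest structures first so crowded fields still pack;
    # children after their parents. Paint order (below) stays id-ordered.
    priority = {
        "presynapse": 0,
        "postsynapse": 1,
        "myelin": 2,
        "axon": 3,
        "neurite": 4,
        "mitochondrion": 5,
        "active_zone": 6,
        "PSD": 6,
    }
    for obj in sorted(params, key=lambda o: priority[o["structure"]]):
        cls = obj["structure"]
        if cls == "myelin":
            def mk(center, obj=obj):
                outer = _disc(center, obj["radius_px"], 128)
                inner = _disc(center, obj["radius_px"] - obj["width_px"], 128)
                return {"polygon": outer, "inner": inner, "shape": Polygon(outer)}

            place(obj, mk)
        elif cls == "axon":
            if obj["core_of"] is not None:
                host = placed[obj["core_of"]]
                poly = host["inner"]
                placed[obj["object_id"]] = {"polygon": poly, "shape": Polygon(poly)}
            else:
                place(obj, lambda c, obj=obj: {
                    "polygon": _disc(c, obj["radius_px"], 96),
                    "shape": Polygon(_disc(c, obj["radius_px"], 96)),
                })
        elif cls in ("neurite", "mitochondrion"):
            aspect = ASPECT[cls]
            a = obj["radius_px"] * np.sqrt(aspect)
            b = obj["radius_px"] / np.sqrt(aspect)

            def mk(center, a=a, b=b):
                angle = rng.uniform(0, np.pi)
                poly = _ellipse(center, a, b, angle)
                return {"polygon": poly, "shape": Polygon(poly)}

            place({**obj, "radius_px": a}, mk)  # a = bounding radius
        elif cls == "presynapse" and obj["pair_id"] is not None and _partner(params, obj) is not None:
            partner = _partner(params, obj)

            def mk(center, pre=obj, post=partner):
                theta = rng.uniform(0, 2 * np.pi)
                u = np.array([np.cos(theta), np.sin(theta)])
                sep = 1.18 * (pre["radius_px"] + post["radius_px"])
                c_pre = center - u * sep / 2.0
                c_post = center + u * sep / 2.0
                p_pre = _blob(c_pre, pre["radius_px"], rng)
                p_post = _blob(c_post, post["radius_px"], rng)
                s_pre, s_post = Polygon(p_pre), Polygon(p_post)
                for _ in range(10):
                    if not s_pre.buffer(0.8).intersects(s_post):
                        break
                    c_post = c_post + u
                    p_post = p_post + u
                    s_post = Polygon(p_post)
                else:
                    return None
                both = s_pre.union(s_post)
                return {
                    "polygon": p_pre,
                    "shape": both,
                    "post_polygon": p_post,
                    "u": u,
                }

            bound = obj["radius_px"] + partner["radius_px"] + 4
            geo = place({**obj, "radius_px": bound}, mk)
            placed[obj["object_id"]] = {"polygon": geo["polygon"], "shape": Polygon(geo["polygon"]), "u": geo["u"]}
            placed[partner["object_id"]] = {
                "polygon": geo["post_polygon"],
                "shape": Polygon(geo["post_polygon"]),
                "u": -geo["u"],
            }
        elif cls == "presynapse" or cls == "postsynapse":
            if obj["object_id"] in placed:
                continue  # placed together with its partner

            def mk(center, obj=obj):
                poly = _blob(center, obj["radius_px"], rng)
                return {"polygon": poly, "shape": Polygon(poly)}

            place(obj, mk)
        elif cls in ("active_zone", "PSD"):
            parent_geo = placed[obj["parent_id"]]
            depth_nm = AZ_DEPTH_NM if cls == "active_zone" else PSD_DEPTH_NM
            depth = max(depth_nm / spec.pixel_size_nm, 2.0)
            direction = parent_geo.get("u")
            if direction is None:  # unpaired parent: arbitrary face
                direction = np.array([1.0, 0.0])
            band = _face_band(parent_geo["polygon"], direction, depth)
            placed[obj["object_id"]] = {"polygon": band, "shape": Polygon(band)}

    # vesicles inside boutons
    for obj in params:
        if obj["structure"] == "presynapse":
            geo = placed[obj["object_id"]]
            geo["vesicles"] = _sample_points_in(
                geo["polygon"], obj["vesicle_count"], rng
            )

    # --- rasterize ---------------------------------------------------------
    label = np.zeros((n, n), dtype=np.uint8)
    oid_img = np.zeros((n, n), dtype=np.int32)
    ratio_img = np.full((n, n), spec.background_ratio, dtype=np.float64)
    objects: list[ObjectTruth] = []

    for obj in params:  # id order == paint order (children come last)
        geo = placed[obj["object_id"]]
        mask = polygon_mask(geo["polygon"], (n, n))
        inner = geo.get("inner")
        if inner is not None:
            mask &= ~polygon_mask(inner, (n, n))
        label[mask] = CLASS_CODES[obj["structure"]]
        oid_img[mask] = obj["object_id"]
        ratio_img[mask] = obj["true_ratio"]
        objects.append(
            ObjectTruth(
                object_id=obj["object_id"],
                structure=obj["structure"],
                polygon=np.asarray(geo["polygon"], dtype=float),
                true_ratio=float(obj["true_ratio"]),
                area_px=int(mask.sum()),
                size_z=float(obj["size_z"]),
                radius_px=float(obj["radius_px"]),
                vesicles=geo.get("vesicles"),
                vesicle_count=int(obj["vesicle_count"]),
                nascent_zone=obj["nascent"],
                pair_id=obj["pair_id"],
                parent_id=obj["parent_id"],
                inner_contour=None if inner is None else np.asarray(inner, float),
                width_px=obj["width_px"],
            )
        )

    em_to_sims = spec.em_to_sims or AffineMap.identity()
    fr = np.array([0.1, 0.5, 0.9])
    em_pts = np.array([(x * (n - 1), y * (n - 1)) for x in fr for y in fr])
    return SceneTruth(
        spec=spec,
        label_image=label,
        object_id_image=oid_img,
        ratio_image=ratio_img,
        objects=objects,
        em_to_sims=em_to_sims,
        landmarks_em=em_pts,
        landmarks_sims=em_to_sims.apply(em_pts),
    )


def _partner(params: list[dict], pre: dict) -> dict | None:
    for o in params:
        if (
            o["structure"] == "postsynapse"
            and o["pair_id"] == pre["pair_id"]
            and o is not pre
        ):
            return o
    return None


# ----------------------------------------------------------------------
# acquisition
# ----------------------------------------------------------------------


def _sims_frame_images(truth: SceneTruth) -> tuple[np.ndarray, np.ndarray]:
    """Label and ratio images on the SIMS grid (EM grid pushed through
    the scene's affine; identity reuses the EM rasters)."""
    if truth.em_to_sims.is_identity:
        return truth.label_image, truth.ratio_image
    n = truth.spec.pixels_per_side
    label = np.zeros((n, n), dtype=np.uint8)
    ratio = np.full((n, n), truth.spec.background_ratio, dtype=np.float64)
    for obj in truth.objects:  # id order == paint order
        poly = truth.em_to_sims.apply(obj.polygon)
        mask = polygon_mask(poly, (n, n))
        if obj.inner_contour is not None:
            mask &= ~polygon_mask(truth.em_to_sims.apply(obj.inner_contour), (n, n))
        label[mask] = CLASS_CODES[obj.structure]
        ratio[mask] = obj.true_ratio
    return label, ratio


def expected_rate_images(
    truth: SceneTruth, acq: AcquisitionParams
) -> tuple[np.ndarray, np.ndarray]:
    """Expected per-pixel channel rates (mu14, mu15) on the SIMS grid.

    These are the Poisson means of :func:`simulate_acquisition`; useful as
    the ground-truth expectation when checking ratio recovery.
    """
    label, ratio = _sims_frame_images(truth)
    lam_table = np.zeros(len(STRUCTURE_CLASSES) + 1)
    lam_table[0] = acq.lam("background")
    for cls, code in CLASS_CODES.items():
        lam_table[code] = acq.lam(cls)
    lam = lam_table[label]
    return lam / (1.0 + ratio), lam * ratio / (1.0 + ratio)


def simulate_acquisition(truth: SceneTruth, acq: AcquisitionParams) -> IonImagePair:
    """Simulate the two-channel Poisson ion-count acquisition.

    Per pixel with class yield lambda and true ratio r the channels are
    independent Poisson(lambda/(1+r)) and Poisson(lambda*r/(1+r)) draws;
    deterministic for a fixed ``acq.seed``.
    """
    label, ratio = _sims_frame_images(truth)
    lam_table = np.zeros(len(STRUCTURE_CLASSES) + 1)
    lam_table[0] = acq.lam("background")
    for cls, code in CLASS_CODES.items():
        lam_table[code] = acq.lam(cls)
    lam = lam_table[label]
    rng = substream(acq.seed, "acquisition")
    c14 = rng.poisson(lam / (1.0 + ratio))
    c15 = rng.poisson(lam * ratio / (1.0 + ratio))
    spec = truth.spec
    return IonImagePair(
        c14=c14,
        c15=c15,
        pixel_size_nm=spec.pixel_size_nm,
        metadata={
            "field_size_um": spec.field_size_um,
            "pixels_per_side": spec.pixels_per_side,
            "dwell_time_ms": acq.dwell_time_ms,
            "scene_seed": spec.seed,
            "acquisition_seed": acq.seed,
        },
    )


# ----------------------------------------------------------------------
# fixture I/O
# ----------------------------------------------------------------------

_TRUTH_COLUMNS = [
    "object_id",
    "structure",
    "true_ratio",
    "area_px",
    "vesicle_count",
    "nascent_zone",
    "pair_id",
    "parent_id",
    "size_z",
    "radius_px",
    "width_px",
]


def truth_table(truth: SceneTruth) -> pd.DataFrame:
    rows = [{c: getattr(o, c) for c in _TRUTH_COLUMNS} for o in truth.objects]
    return pd.DataFrame(rows, columns=_TRUTH_COLUMNS)


def scene_annotations(truth: SceneTruth) -> list[RoiAnnotation]:
    """The scene's objects as EM-frame ROI annotations."""
    anns = []
    for o in truth.objects:
        anns.append(
            RoiAnnotation(
                object_id=o.object_id,
                structure=o.structure,
                polygon=o.polygon,
                vesicles=o.vesicles if o.structure == "presynapse" else None,
                nascent_zone=o.nascent_zone,
                pair_id=o.pair_id,
                inner_contour=o.inner_contour,
                parent_id=o.parent_id,
            )
        )
    return anns


def export_fixture(truth: SceneTruth, pair: IonImagePair, destination) -> Path:
    """Write the fixture file set; returns the destination directory.

    Layout: counts_14N.tif / counts_15N.tif (int32), labels.tif (uint16),
    annotations.geojson, landmarks.csv, truth.csv, scene.json.
    """
    import tifffile

    dest = Path(destination)
    dest.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(dest / "counts_14N.tif", pair.c14.astype(np.int32))
    tifffile.imwrite(dest / "counts_15N.tif", pair.c15.astype(np.int32))
    tifffile.imwrite(dest / "labels.tif", truth.label_image.astype(np.uint16))
    write_annotations(dest / "annotations.geojson", scene_annotations(truth))
    write_landmarks(dest / "landmarks.csv", truth.landmarks_em, truth.landmarks_sims)
    truth_table(truth).to_csv(dest / "truth.csv", index=False)
    meta = {
        "pixel_size_nm": pair.pixel_size_nm,
        "metadata": pair.metadata,
        "em_to_sims": truth.em_to_sims.to_record(),
        "background_ratio": truth.spec.background_ratio,
    }
    (dest / "scene.json").write_text(json.dumps(meta, indent=1))
    return dest


def import_fixture(source) -> Fixture:
    import tifffile

    src = Path(source)
    for name in ("counts_14N.tif", "counts_15N.tif"):
        if not (src / name).exists():
            raise FileNotFoundError(f"missing channel file: {src / name}")
    meta = json.loads((src / "scene.json").read_text())
    pair = IonImagePair(
        c14=tifffile.imread(src / "counts_14N.tif"),
        c15=tifffile.imread(src / "counts_15N.tif"),
        pixel_size_nm=meta["pixel_size_nm"],
        metadata=meta.get("metadata", {}),
    )
    em, sims = read_landmarks(src / "landmarks.csv")
    return Fixture(
        pair=pair,
        annotations=read_annotations(src / "annotations.geojson"),
        landmarks_em=em,
        landmarks_sims=sims,
        truth=pd.read_csv(src / "truth.csv"),
        label_image=tifffile.imread(src / "labels.tif"),
        meta=meta,
    )


# ----------------------------------------------------------------------
# object-level sampling path (no imaging)
# ----------------------------------------------------------------------


def sample_cohort(
    spec: SceneSpec,
    acq: AcquisitionParams | None = None,
    *,
    region: str = "CA1",
    age_group: str = "young",
    image_id: str = "img0",
    rng: np.random.Generator | None = None,
    n_fields: int | None = None,
) -> pd.DataFrame:
    """Draw a cohort of measured objects without rasterizing a scene.

    Summed Poisson counts over an ROI of a uniform-ratio object are
    distribution-identical to a single Poisson draw of the summed rates, so
    per-object measured ratios can be sampled directly: Lambda = lambda_c *
    area_px, S14 ~ Poisson(Lambda/(1+r)), S15 ~ Poisson(Lambda*r/(1+r)).
    This makes cohort-scale statistical calibration (hundreds of repeats)
    cheap while exercising the same enrichment model as :func:`build_scene`.

    The cohort is treated as pooled over as many scanned fields as needed
    for the annotated objects to cover :data:`ANNOTATED_AREA_FRACTION` of
    the total area (``n_fields`` overrides); the remaining area contributes
    background counts to the whole-area sums.

    Returns a turnover table (one row per object) including the cohort's
    whole-area sums for whole-organ normalization.
    """
    acq = acq or AcquisitionParams()
    rng = rng or substream(spec.seed, "objects")
    params = _draw_objects(spec, rng)
    px_area_um2 = (spec.pixel_size_nm / 1000.0) ** 2

    by_id = {o["object_id"]: o for o in params}
    rows = []
    total_area = 0.0
    for o in params:
        cls = o["structure"]
        if cls == "myelin":
            r_in = o["radius_px"] - o["width_px"]
            area_px = np.pi * (o["radius_px"] ** 2 - r_in**2)
        elif cls in CHILD_AREA_FRACTION:
            parent = by_id[o["parent_id"]]
            area_px = CHILD_AREA_FRACTION[cls] * np.pi * parent["radius_px"] ** 2
        else:
            area_px = np.pi * o["radius_px"] ** 2
        if cls not in CHILD_AREA_FRACTION:
            total_area += area_px
        lam_tot = acq.lam(cls) * area_px
        r = o["true_ratio"]
        s14 = int(rng.poisson(lam_tot / (1.0 + r)))
        s15 = int(rng.poisson(lam_tot * r / (1.0 + r)))
        aspect = ASPECT.get(cls, 1.0)
        rows.append(
            {
                "object_id": o["object_id"],
                "structure": cls,
                "region": region,
                "age_group": age_group,
                "image_id": image_id,
                "ratio": s15 / max(s14, 1),
                "true_ratio": r,
                "sum15": s15,
                "sum14": s14,
                "n_pixels": int(round(area_px)),
                "area_um2": area_px * px_area_um2,
                "length_um": 2.0
                * o["radius_px"]
                * np.sqrt(aspect)
                * spec.pixel_size_nm
                / 1000.0,
                "vesicle_count": o["vesicle_count"] if cls == "presynapse" else None,
                "thickness_nm": (
                    o["width_px"] * spec.pixel_size_nm if cls == "myelin" else None
                ),
                "nascent_zone": o["nascent"],
                "in_presynapse": False if cls == "mitochondrion" else None,
                "pair_id": o["pair_id"],
                "parent_id": o["parent_id"],
            }
        )

    # whole-area sums: objects plus surrounding background tissue
    field_px = spec.pixels_per_side**2
    if n_fields is None:
        n_fields = max(1, int(np.ceil(total_area / (ANNOTATED_AREA_FRACTION * field_px))))
    bg_px = max(n_fields * field_px - total_area, 0.0)
    lam_bg = acq.lam("background") * bg_px
    rb = spec.background_ratio
    s14_img = int(rng.poisson(lam_bg / (1.0 + rb)))
    s15_img = int(rng.poisson(lam_bg * rb / (1.0 + rb)))
    for row in rows:
        if row["structure"] not in CHILD_AREA_FRACTION:
            s14_img += row["sum14"]
            s15_img += row["sum15"]
    whole = s15_img / max(s14_img, 1)
    df = pd.DataFrame(rows)
    df["whole_area_ratio"] = whole
    df["image_sum15"] = s15_img
    df["image_sum14"] = s14_img
    return df
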