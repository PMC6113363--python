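"""Ground-truth synthetic podosome scenes for correlative LM/SEM analysis.

Dendritic-cell podosomes on ventral plasma membranes consist of a dense
actin core (~700 nm across) surrounded by an adhesive ring.  Vinculin sits
in a ring of ~360 nm radius close to the membrane, zyxin in a tighter
(~200 nm) zone placed axially higher, toward the top of the core.  Cores
radiate actin filaments, the membrane carries a mat of ventral filaments,
and closely associated core pairs share one continuous vinculin ring and
are joined by a thick interpodosomal bundle of parallel actin filaments.

This module builds seeded, fully annotated scenes of that geometry and
renders them both as multi-channel fluorescence z-stacks (Gaussian PSF,
optional signal-dependent noise) and as a high-resolution SEM-like 2D
image related to the LM frame by a known ground-truth affine transform.
Every downstream stage of the pipeline (registration, overlay, profiling,
association) is therefore testable against exact ground truth without any
external data.

Units: all world coordinates and lengths are nanometres; the world frame
coincides with the LM frame.  The SEM frame is reached through
``GroundTruthScene.affine_true`` (world nm -> SEM pixel).
"""
from __future__ import annotations

import dataclasses
import json
import math
from typing import Sequence

import numpy as np
from scipy import ndimage

from .transform import AffineTransform2D

__all__ = [
    "PodosomeSpec",
    "ClusterSpec",
    "OpticsSpec",
    "SEMSpec",
    "FilamentSegment",
    "RingAnnotation",
    "GroundTruthScene",
    "generate_scene",
    "render_lm_stack",
    "render_sem",
    "CHANNELS",
]

#: channel order of rendered LM stacks
CHANNELS = ("actin", "vinculin", "zyxin", "beads")

FWHM_TO_SIGMA = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))  # 1/2.355

# rendered peak intensities (arbitrary fluorescence units, before noise)
_CORE_PEAK = 150.0
_RING_PEAK = 120.0
_CAP_PEAK = 120.0
_FILAMENT_PEAK = 50.0
_BEAD_PEAK = 250.0

# SEM peak factors, as multiples of SEMSpec.edge_contrast
_SEM_CORE_FACTOR = 1.5
_SEM_BEAD_FACTOR = 3.0


class SceneError(ValueError):
    """Invalid scene specification (geometry that cannot be generated)."""


# ---------------------------------------------------------------------------
# specifications
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class PodosomeSpec:
    """Geometry of one podosome, all lengths in nm.

    The axial ordering constraint ``zyxin_cap_z > vinculin_ring_z`` encodes
    the biological layering: vinculin lies close to the membrane while zyxin
    decorates the core from the middle to the top.
    """

    center_xy: tuple[float, float] = (0.0, 0.0)
    core_diameter: float = 700.0
    core_height: float = 600.0
    vinculin_ring_radius: float = 360.0
    vinculin_ring_z: float = 50.0
    zyxin_cap_radius: float = 200.0
    zyxin_cap_z: float = 400.0
    n_radiating_filaments: int = 8
    filament_length_range: tuple[float, float] = (500.0, 1500.0)

    def __post_init__(self) -> None:
        lengths = (self.core_diameter, self.core_height, self.vinculin_ring_radius,
                   self.zyxin_cap_radius, *self.filament_length_range)
        if not all(np.isfinite(v) and v >= 0 for v in lengths):
            raise SceneError("all podosome lengths must be finite and non-negative")
        if self.core_diameter <= 0:
            raise SceneError("core_diameter must be positive")
        if not self.vinculin_ring_radius > self.zyxin_cap_radius:
            raise SceneError("vinculin_ring_radius must exceed zyxin_cap_radius")
        if not self.zyxin_cap_z > self.vinculin_ring_z:
            raise SceneError("zyxin_cap_z must lie above vinculin_ring_z")


@dataclasses.dataclass
class ClusterSpec:
    """Layout of a podosome cluster on the ventral plasma membrane.

    ``associated_pairs`` lists index pairs of podosomes that share one
    merged vinculin ring and are joined by an interpodosomal actin bundle.
    ``cytoD_mode`` emulates cytochalasin-D treatment: ventral and radiating
    filaments are suppressed while cores and interpodosomal bundles are
    retained (the experimentally observed contrast).
    """

    n_podosomes: int = 6
    field_size_xy: tuple[float, float] = (12000.0, 12000.0)
    associated_pairs: tuple[tuple[int, int], ...] = ()
    ventral_filament_density: float = 3.0  # filaments per um^2
    cytoD_mode: bool = False
    pair_separation: float = 1000.0  # center-to-center distance of pairs, nm
    min_spacing: float = 1500.0  # minimum center spacing of non-pair cores, nm
    max_pair_separation: float = 1500.0

    def __post_init__(self) -> None:
        for i, j in self.associated_pairs:
            if i == j:
                raise SceneError("associated pair members must be distinct")
            if not (0 <= i < self.n_podosomes and 0 <= j < self.n_podosomes):
                raise SceneError("associated pair index out of range")
        if self.pair_separation > self.max_pair_separation:
            raise SceneError(
                f"pair_separation {self.pair_separation} nm exceeds the maximum "
                f"separation {self.max_pair_separation} nm for close association")
        if self.ventral_filament_density < 0:
            raise SceneError("ventral_filament_density must be non-negative")


@dataclasses.dataclass
class OpticsSpec:
    """Airyscan-scale light-microscope sampling and PSF model.

    Defaults correspond to typical Airyscan acquisition: ~140 nm lateral
    FWHM sampled at 40 nm/px, ~350 nm axial FWHM at a 150 nm z-step.  Noise
    is background plus signal-dependent Gaussian noise; ``noise_scale = 0``
    turns noise off (renders are then exact).
    """

    lm_pixel_xy: float = 40.0
    lm_z_step: float = 150.0
    lateral_fwhm: float = 140.0
    axial_fwhm: float = 350.0
    n_z_slices: int = 10
    background: float = 10.0
    noise_scale: float = 0.0
    bead_diameter: float = 200.0
    bead_count: int = 6

    def __post_init__(self) -> None:
        if self.lm_pixel_xy <= 0 or self.lm_z_step <= 0:
            raise SceneError("pixel sizes must be positive")
        if self.lateral_fwhm < self.lm_pixel_xy:
            raise SceneError("lateral_fwhm must be at least one LM pixel")
        if self.bead_count < 0:
            raise SceneError("bead_count must be non-negative")


@dataclasses.dataclass
class SEMSpec:
    """SEM-like rendering parameters.

    The SEM appearance model is a geometric sketch: filaments and core
    outlines become bright ridges of ``filament_width`` FWHM, beads bright
    discs, on a noisy background.  Only the geometry is meaningful.
    """

    sem_pixel: float = 2.0
    filament_width: float = 50.0
    edge_contrast: float = 100.0
    background: float = 20.0
    noise_scale: float = 4.0
    bit_depth: int = 16

    def __post_init__(self) -> None:
        if self.sem_pixel <= 0:
            raise SceneError("sem_pixel must be positive")
        if self.filament_width <= 0:
            raise SceneError("filament_width must be positive")
        if self.bit_depth not in (8, 16):
            raise SceneError("bit_depth must be 8 or 16")


# ---------------------------------------------------------------------------
# scene containers
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class FilamentSegment:
    """3D polyline (nm, world frame) tagged by filament class."""

    points: np.ndarray  # (k, 3) x, y, z in nm
    kind: str  # {"radiating", "ventral", "interpodosomal"}

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise SceneError("filament points must have shape (k, 3)")
        if self.kind not in ("radiating", "ventral", "interpodosomal"):
            raise SceneError(f"unknown filament kind {self.kind!r}")


@dataclasses.dataclass
class RingAnnotation:
    """A vinculin ring drawn as a capsule (stadium) contour.

    The contour is the set of points at distance ``radius`` from the segment
    ``p0 -> p1``; for an isolated podosome ``p0 == p1`` and the ring is a
    circle.  For an associated pair the segment joins the two core centers,
    yielding one continuous merged ring around both cores.
    """

    core_indices: tuple[int, ...]
    p0: tuple[float, float]
    p1: tuple[float, float]
    radius: float
    z: float


@dataclasses.dataclass
class GroundTruthScene:
    """Complete description of a synthetic scene, in world (LM-frame) nm."""

    podosomes: list[PodosomeSpec]
    beads: np.ndarray  # (n, 2) world nm
    affine_true: AffineTransform2D  # world nm -> SEM pixel
    filament_segments: list[FilamentSegment]
    rings: list[RingAnnotation]
    field_size_xy: tuple[float, float]
    seed: int

    def __post_init__(self) -> None:
        self.beads = np.asarray(self.beads, dtype=float).reshape(-1, 2)

    # lossless JSON round-trip (floats serialize via repr)
    def to_dict(self) -> dict:
        return {
            "podosomes": [dataclasses.asdict(p) for p in self.podosomes],
            "beads": self.beads.tolist(),
            "affine_true": self.affine_true.to_dict(),
            "filament_segments": [
                {"points": f.points.tolist(), "kind": f.kind}
                for f in self.filament_segments
            ],
            "rings": [dataclasses.asdict(r) for r in self.rings],
            "field_size_xy": list(self.field_size_xy),
            "seed": self.seed,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruthScene":
        def _tup(x):
            return tuple(x) if isinstance(x, list) else x

        podosomes = []
        for p in d["podosomes"]:
            p = dict(p)
            p["center_xy"] = _tup(p["center_xy"])
            p["filament_length_range"] = _tup(p["filament_length_range"])
            podosomes.append(PodosomeSpec(**p))
        rings = []
        for r in d["rings"]:
            rings.append(RingAnnotation(
                core_indices=tuple(r["core_indices"]),
                p0=tuple(r["p0"]), p1=tuple(r["p1"]),
                radius=r["radius"], z=r["z"]))
        return cls(
            podosomes=podosomes,
            beads=np.asarray(d["beads"], dtype=float).reshape(-1, 2),
            affine_true=AffineTransform2D.from_dict(d["affine_true"]),
            filament_segments=[
                FilamentSegment(np.asarray(f["points"], dtype=float), f["kind"])
                for f in d["filament_segments"]
            ],
            rings=rings,
            field_size_xy=tuple(d["field_size_xy"]),
            seed=int(d["seed"]),
        )

    @classmethod
    def from_json(cls, s: str) -> "GroundTruthScene":
        return cls.from_dict(json.loads(s))

    def max_structure_z(self) -> float:
        z = 0.0
        for p in self.podosomes:
            z = max(z, p.core_height, p.zyxin_cap_z)
        for f in self.filament_segments:
            if len(f.points):
                z = max(z, float(np.max(f.points[:, 2])))
        return z


# ---------------------------------------------------------------------------
# scene generation
# ---------------------------------------------------------------------------

_MARGIN = 3000.0  # nm kept clear around podosome centers


def _place_centers(cluster: ClusterSpec, rng: np.random.Generator) -> np.ndarray:
    """Random podosome centers honouring pair separations and min spacing."""
    fx, fy = cluster.field_size_xy
    lo = np.array([_MARGIN, _MARGIN])
    hi = np.array([fx - _MARGIN, fy - _MARGIN])
    paired = {i for ij in cluster.associated_pairs for i in ij}
    centers = np.full((cluster.n_podosomes, 2), np.nan)

    def ok(pt, placed, min_d):
        if np.any(pt < lo) or np.any(pt > hi):
            return False
        for q in placed:
            if np.linalg.norm(pt - q) < min_d:
                return False
        return True

    placed: list[np.ndarray] = []
    # pairs first: anchor + partner at pair_separation along a random direction
    for i, j in cluster.associated_pairs:
        for _ in range(10_000):
            a = rng.uniform(lo, hi)
            th = rng.uniform(0, 2 * math.pi)
            b = a + cluster.pair_separation * np.array([math.cos(th), math.sin(th)])
            others = [c for k, c in enumerate(centers) if not np.isnan(c[0])]
            if ok(a, others, cluster.min_spacing) and ok(b, others, cluster.min_spacing):
                centers[i], centers[j] = a, b
                break
        else:
            raise SceneError("could not place associated pair; field too crowded")
    for i in range(cluster.n_podosomes):
        if i in paired:
            continue
        for _ in range(10_000):
            a = rng.uniform(lo, hi)
            others = [c for c in centers if not np.isnan(c[0])]
            if ok(a, others, cluster.min_spacing):
                centers[i] = a
                break
        else:
            raise SceneError("could not place podosome; field too crowded")
    return centers


def _default_affine(sem: SEMSpec, rng: np.random.Generator) -> AffineTransform2D:
    """Ground-truth world(nm)->SEM(px) affine.

    Relative to the LM pixel grid the scale is ~lm_px/sem_px (~20x for the
    defaults); small anisotropy, up to +-5 deg rotation and up to 1% shear
    emulate the physical distortion that makes a similarity-only fit fail.
    """
    base = 1.0 / sem.sem_pixel
    sx = base * (1.0 + rng.uniform(-0.005, 0.005))
    sy = base * (1.0 + rng.uniform(-0.005, 0.005))
    rot = rng.uniform(-5.0, 5.0)
    shear = rng.uniform(0.005, 0.01)
    return AffineTransform2D.from_components((sx, sy), rot, shear, (0.0, 0.0))


def _with_positive_translation(
    affine: AffineTransform2D, field: tuple[float, float],
    rng: np.random.Generator) -> AffineTransform2D:
    """Shift the affine so the mapped field lands at small positive pixels."""
    fx, fy = field
    corners = np.array([[0, 0], [fx, 0], [0, fy], [fx, fy]], dtype=float)
    mapped = affine.apply(corners)
    jitter = rng.uniform(10.0, 40.0, size=2)
    t = -mapped.min(axis=0) + jitter
    return AffineTransform2D(affine.matrix, tuple(affine.t + t))


def generate_scene(
    cluster: ClusterSpec,
    optics: OpticsSpec,
    sem: SEMSpec,
    seed: int,
    affine_true: AffineTransform2D | None = None,
) -> GroundTruthScene:
    """Generate a deterministic, fully annotated podosome scene.

    Podosome centers keep a 3 um margin to the field border (room for the
    3 um profiling line and the filament halo).  Every associated pair gets
    one merged capsule vinculin ring and one interpodosomal bundle of 2-4
    parallel ridges; beads avoid core centers by at least one bead diameter.
    In ``cytoD_mode`` radiating and ventral filaments are omitted while
    cores and bundles are retained.
    """
    if cluster.n_podosomes == 0 and cluster.associated_pairs:
        raise SceneError("associated_pairs given but n_podosomes is zero")
    fx, fy = cluster.field_size_xy
    if cluster.n_podosomes > 0 and (fx < 2 * _MARGIN or fy < 2 * _MARGIN):
        raise SceneError(
            f"field {cluster.field_size_xy} nm too small: podosomes need a "
            f"{_MARGIN:.0f} nm margin on every side")

    rng = np.random.default_rng(seed)
    centers = _place_centers(cluster, rng) if cluster.n_podosomes else np.zeros((0, 2))
    podosomes = [PodosomeSpec(center_xy=(float(c[0]), float(c[1]))) for c in centers]

    paired = {i for ij in cluster.associated_pairs for i in ij}
    rings: list[RingAnnotation] = []
    for i, j in cluster.associated_pairs:
        pi, pj = podosomes[i], podosomes[j]
        rings.append(RingAnnotation(
            core_indices=(i, j), p0=pi.center_xy, p1=pj.center_xy,
            radius=pi.vinculin_ring_radius, z=pi.vinculin_ring_z))
    for i, p in enumerate(podosomes):
        if i not in paired:
            rings.append(RingAnnotation(
                core_indices=(i,), p0=p.center_xy, p1=p.center_xy,
                radius=p.vinculin_ring_radius, z=p.vinculin_ring_z))

    segments: list[FilamentSegment] = []
    # radiating filaments: from the core top edge down to the membrane
    if not cluster.cytoD_mode:
        for p in podosomes:
            r0 = p.core_diameter / 2.0
            for _ in range(p.n_radiating_filaments):
                th = rng.uniform(0, 2 * math.pi)
                length = rng.uniform(*p.filament_length_range)
                u = np.array([math.cos(th), math.sin(th)])
                start = np.array(p.center_xy) + r0 * u
                end = np.array(p.center_xy) + (r0 + length) * u
                segments.append(FilamentSegment(
                    np.array([[start[0], start[1], p.core_height * 0.8],
                              [end[0], end[1], 20.0]]), "radiating"))
        # ventral mat: short membrane-proximal filaments over the whole field
        area_um2 = (fx / 1000.0) * (fy / 1000.0)
        n_ventral = rng.poisson(cluster.ventral_filament_density * area_um2)
        for _ in range(int(n_ventral)):
            c = rng.uniform([0.0, 0.0], [fx, fy])
            th = rng.uniform(0, 2 * math.pi)
            half = rng.uniform(250.0, 750.0)
            u = np.array([math.cos(th), math.sin(th)])
            a, b = c - half * u, c + half * u
            segments.append(FilamentSegment(
                np.array([[a[0], a[1], 20.0], [b[0], b[1], 20.0]]), "ventral"))
    # interpodosomal bundles: 2-4 parallel ridges, CytoD-insensitive
    for i, j in cluster.associated_pairs:
        a = np.array(podosomes[i].center_xy)
        b = np.array(podosomes[j].center_xy)
        u = (b - a) / np.linalg.norm(b - a)
        n_perp = np.array([-u[1], u[0]])
        n_ridges = int(rng.integers(2, 5))
        # tightly bundled filaments: ~25 nm spacing keeps the bundle a
        # single thick ridge rather than resolvable parallel lines
        offsets = (np.arange(n_ridges) - (n_ridges - 1) / 2.0) * 25.0
        for off in offsets:
            pa = a + off * n_perp
            pb = b + off * n_perp
            segments.append(FilamentSegment(
                np.array([[pa[0], pa[1], 100.0], [pb[0], pb[1], 100.0]]),
                "interpodosomal"))

    # beads: anywhere in the field (with a margin so the PSF is not edge-
    # truncated), but >= 1 bead diameter from core centers
    beads = []
    bead_margin = optics.bead_diameter + 300.0
    for _ in range(optics.bead_count):
        for _ in range(10_000):
            b = rng.uniform([bead_margin, bead_margin],
                            [fx - bead_margin, fy - bead_margin])
            if all(np.linalg.norm(b - c) >= optics.bead_diameter for c in centers):
                beads.append(b)
                break
        else:
            raise SceneError("could not place bead clear of core centers")
    beads = np.asarray(beads, dtype=float).reshape(-1, 2)

    if affine_true is None:
        affine_true = _with_positive_translation(
            _default_affine(sem, rng), cluster.field_size_xy, rng)
    if not affine_true.is_invertible():
        raise SceneError("ground-truth affine must be invertible")

    return GroundTruthScene(
        podosomes=podosomes, beads=beads, affine_true=affine_true,
        filament_segments=segments, rings=rings,
        field_size_xy=(float(fx), float(fy)), seed=int(seed))


# ---------------------------------------------------------------------------
# rendering helpers
# ---------------------------------------------------------------------------

def _deposit3d(grid: np.ndarray, zyx: np.ndarray, w: np.ndarray) -> None:
    """Trilinear deposit of weighted samples; samples outside are dropped."""
    nz, ny, nx = grid.shape
    z, y, x = zyx[:, 0], zyx[:, 1], zyx[:, 2]
    keep = (z > -1) & (z < nz) & (y > -1) & (y < ny) & (x > -1) & (x < nx)
    z, y, x, w = z[keep], y[keep], x[keep], w[keep]
    z0, y0, x0 = np.floor(z).astype(int), np.floor(y).astype(int), np.floor(x).astype(int)
    fz, fy, fx = z - z0, y - y0, x - x0
    for dz, wz in ((0, 1 - fz), (1, fz)):
        for dy, wy in ((0, 1 - fy), (1, fy)):
            for dx, wx in ((0, 1 - fx), (1, fx)):
                zz, yy, xx = z0 + dz, y0 + dy, x0 + dx
                m = (zz >= 0) & (zz < nz) & (yy >= 0) & (yy < ny) & (xx >= 0) & (xx < nx)
                np.add.at(grid, (zz[m], yy[m], xx[m]), (w * wz * wy * wx)[m])


def _deposit2d(grid: np.ndarray, yx: np.ndarray, w: np.ndarray) -> None:
    ny, nx = grid.shape
    y, x = yx[:, 0], yx[:, 1]
    keep = (y > -1) & (y < ny) & (x > -1) & (x < nx)
    y, x, w = y[keep], x[keep], w[keep]
    y0, x0 = np.floor(y).astype(int), np.floor(x).astype(int)
    fy, fx = y - y0, x - x0
    for dy, wy in ((0, 1 - fy), (1, fy)):
        for dx, wx in ((0, 1 - fx), (1, fx)):
            yy, xx = y0 + dy, x0 + dx
            m = (yy >= 0) & (yy < ny) & (xx >= 0) & (xx < nx)
            np.add.at(grid, (yy[m], xx[m]), (w * wy * wx)[m])


def _sample_polyline(points: np.ndarray, step: float) -> tuple[np.ndarray, np.ndarray]:
    """Evenly spaced samples along a polyline; returns (samples, ds per sample)."""
    out = []
    ds_list = []
    for a, b in zip(points[:-1], points[1:]):
        length = float(np.linalg.norm(b - a))
        if length == 0:
            continue
        n = max(2, int(math.ceil(length / step)) + 1)
        t = np.linspace(0.0, 1.0, n)
        seg = a[None, :] + t[:, None] * (b - a)[None, :]
        out.append(seg)
        ds_list.append(np.full(n, length / n))
    if not out:
        return np.zeros((0, points.shape[1])), np.zeros(0)
    return np.concatenate(out), np.concatenate(ds_list)


def _capsule_contour(p0, p1, radius: float, step: float) -> np.ndarray:
    """Points on the capsule (stadium) contour at distance ``radius`` from
    the segment p0-p1, evenly spaced at ~``step``."""
    p0 = np.asarray(p0, dtype=float)
    p1 = np.asarray(p1, dtype=float)
    d = p1 - p0
    L = float(np.linalg.norm(d))
    pts = []
    if L == 0:
        n = max(8, int(math.ceil(2 * math.pi * radius / step)))
        th = np.linspace(0, 2 * math.pi, n, endpoint=False)
        return p0[None, :] + radius * np.stack([np.cos(th), np.sin(th)], axis=1)
    u = d / L
    nvec = np.array([-u[1], u[0]])
    phi0 = math.atan2(u[1], u[0])
    # two straight sides
    n_side = max(2, int(math.ceil(L / step)))
    t = np.linspace(0.0, 1.0, n_side, endpoint=False)
    side = p0[None, :] + t[:, None] * d[None, :]
    pts.append(side + radius * nvec)
    pts.append(side - radius * nvec)
    # two end caps (half circles)
    n_cap = max(4, int(math.ceil(math.pi * radius / step)))
    th = np.linspace(0.5 * math.pi, 1.5 * math.pi, n_cap, endpoint=False)
    cap0 = p0[None, :] + radius * np.stack(
        [np.cos(th + phi0), np.sin(th + phi0)], axis=1)
    th2 = np.linspace(-0.5 * math.pi, 0.5 * math.pi, n_cap, endpoint=False)
    cap1 = p1[None, :] + radius * np.stack(
        [np.cos(th2 + phi0), np.sin(th2 + phi0)], axis=1)
    pts.extend([cap0, cap1])
    return np.concatenate(pts)


# ---------------------------------------------------------------------------
# LM rendering
# ---------------------------------------------------------------------------

def lm_grid_shape(scene: GroundTruthScene, optics: OpticsSpec) -> tuple[int, int, int]:
    fx, fy = scene.field_size_xy
    nx = int(round(fx / optics.lm_pixel_xy)) + 1
    ny = int(round(fy / optics.lm_pixel_xy)) + 1
    return optics.n_z_slices, ny, nx


def render_lm_stack(
    scene: GroundTruthScene,
    optics: OpticsSpec,
    structure_amplitude: float = 1.0,
) -> np.ndarray:
    """Render the 4-channel LM z-stack (actin, vinculin, zyxin, beads).

    Point-like and line-like structures are deposited as weighted samples
    and convolved with the Gaussian PSF of the stated FWHMs; cores are added
    analytically as Gaussian blobs whose width combines the ~700 nm core
    with the PSF.  Beads are point sources rendered into every channel.
    ``structure_amplitude = 0`` yields pure background (plus noise if on).

    Returns a float array of shape ``(4, nz, ny, nx)``, intensities >= 0.
    """
    nz, ny, nx = lm_grid_shape(scene, optics)
    ps, zs = optics.lm_pixel_xy, optics.lm_z_step
    z_max = (nz - 1) * zs
    if scene.max_structure_z() > z_max:
        raise SceneError(
            f"z-range {z_max:.0f} nm does not cover the tallest structure "
            f"({scene.max_structure_z():.0f} nm); increase n_z_slices")

    sig_xy = optics.lateral_fwhm * FWHM_TO_SIGMA / ps  # px
    sig_z = optics.axial_fwhm * FWHM_TO_SIGMA / zs  # z-slices
    stack = np.zeros((len(CHANNELS), nz, ny, nx), dtype=float)

    def to_idx3(xyz: np.ndarray) -> np.ndarray:
        # world nm -> fractional (z, y, x) indices
        return np.stack([xyz[:, 2] / zs, xyz[:, 1] / ps, xyz[:, 0] / ps], axis=1)

    # weight bookkeeping: a deposited line of linear density lam (weight per
    # xy-pixel of arclength) yields, after the PSF convolution, a ridge peak
    # of lam / (2*pi*sig_xy*sig_z)
    line_norm = 2 * math.pi * sig_xy * sig_z
    sample_step = ps / 4.0

    ch = {name: stack[i] for i, name in enumerate(CHANNELS)}

    amp = float(structure_amplitude)
    if amp > 0:
        # actin: filaments
        kind_peak = {"radiating": _FILAMENT_PEAK, "ventral": _FILAMENT_PEAK,
                     "interpodosomal": _FILAMENT_PEAK * 1.2}
        for f in scene.filament_segments:
            pts, ds = _sample_polyline(f.points, sample_step)
            if not len(pts):
                continue
            w = amp * kind_peak[f.kind] * line_norm * (ds / ps)
            _deposit3d(ch["actin"], to_idx3(pts), w)
        # vinculin: capsule rings near the membrane
        for r in scene.rings:
            pts2, = (_capsule_contour(r.p0, r.p1, r.radius, sample_step),)
            ds = np.full(len(pts2), sample_step)
            pts3 = np.column_stack([pts2, np.full(len(pts2), r.z)])
            w = amp * _RING_PEAK * line_norm * (ds / ps)
            _deposit3d(ch["vinculin"], to_idx3(pts3), w)
        # zyxin: per-core ring at the cap radius, axially higher
        for p in scene.podosomes:
            pts2 = _capsule_contour(p.center_xy, p.center_xy,
                                    p.zyxin_cap_radius, sample_step)
            ds = np.full(len(pts2), sample_step)
            pts3 = np.column_stack([pts2, np.full(len(pts2), p.zyxin_cap_z)])
            w = amp * _CAP_PEAK * line_norm * (ds / ps)
            _deposit3d(ch["zyxin"], to_idx3(pts3), w)
    for c in range(len(CHANNELS)):
        stack[c] = ndimage.gaussian_filter(stack[c], (sig_z, sig_xy, sig_xy),
                                           mode="constant")

    if amp > 0:
        # cores and beads rendered analytically: a point source deposited on
        # the grid would pick up extra width from the interpolation weights
        zz = np.arange(nz)[:, None, None] * zs
        yy = np.arange(ny)[None, :, None] * ps
        xx = np.arange(nx)[None, None, :] * ps
        sig_psf_xy = optics.lateral_fwhm * FWHM_TO_SIGMA
        sig_psf_z = optics.axial_fwhm * FWHM_TO_SIGMA
        bz = optics.bead_diameter / 2.0
        for b in scene.beads:
            r2 = ((xx - b[0]) ** 2 + (yy - b[1]) ** 2) / (2 * sig_psf_xy ** 2) \
                + (zz - bz) ** 2 / (2 * sig_psf_z ** 2)
            blob = amp * _BEAD_PEAK * np.exp(-r2)
            for c in range(len(CHANNELS)):
                stack[c] += blob
        for p in scene.podosomes:
            s_xy = math.hypot(p.core_diameter * FWHM_TO_SIGMA, sig_psf_xy)
            s_z = math.hypot(p.core_height * FWHM_TO_SIGMA, sig_psf_z)
            cx, cy = p.center_xy
            cz = p.core_height / 2.0
            r2 = ((xx - cx) ** 2 + (yy - cy) ** 2) / (2 * s_xy ** 2) \
                + (zz - cz) ** 2 / (2 * s_z ** 2)
            ch["actin"] += amp * _CORE_PEAK * np.exp(-r2)

    stack += optics.background
    if optics.noise_scale > 0:
        rng = np.random.default_rng([int(scene.seed) & 0x7FFFFFFF, 101])
        stack += rng.normal(0.0, 1.0, size=stack.shape) * (
            optics.noise_scale * np.sqrt(np.clip(stack, 0.0, None)))
    np.clip(stack, 0.0, None, out=stack)
    return stack


# ---------------------------------------------------------------------------
# SEM rendering
# ---------------------------------------------------------------------------

def sem_grid_shape(scene: GroundTruthScene, pad_px: int = 32) -> tuple[int, int]:
    fx, fy = scene.field_size_xy
    corners = np.array([[0, 0], [fx, 0], [0, fy], [fx, fy]], dtype=float)
    mapped = scene.affine_true.apply(corners)
    nx = int(math.ceil(mapped[:, 0].max())) + pad_px
    ny = int(math.ceil(mapped[:, 1].max())) + pad_px
    return ny, nx


def render_sem(scene: GroundTruthScene, sem: SEMSpec) -> np.ndarray:
    """Render the SEM-like 2D image on the SEM pixel grid.

    Filament polylines (projected to 2D) and core outlines are mapped
    through ``affine_true`` and drawn as bright ridges of
    ``filament_width`` FWHM; beads become bright filled discs.  An empty
    scene renders to pure background/noise.  Intensities are clipped to the
    declared bit depth.
    """
    if not scene.affine_true.is_invertible():
        raise SceneError("affine_true must be invertible for SEM rendering")
    ny, nx = sem_grid_shape(scene)
    img = np.zeros((ny, nx), dtype=float)
    T = scene.affine_true
    ps = sem.sem_pixel
    sig = sem.filament_width * FWHM_TO_SIGMA / ps  # px
    line_norm = math.sqrt(2 * math.pi) * sig  # ridge peak 1 per unit density
    step = ps  # world-space sampling step, nm

    def draw_line(points_xy: np.ndarray, peak: float) -> None:
        pts, ds = _sample_polyline(points_xy, step)
        if not len(pts):
            return
        mapped = T.apply(pts)
        # per-sample arclength in SEM px (scale varies slightly with direction)
        ds_px = ds * np.linalg.norm(T.A @ np.array([1.0, 0.0])) / 1.0
        # recompute exactly from consecutive mapped samples
        if len(mapped) > 1:
            seglen = np.linalg.norm(np.diff(mapped, axis=0), axis=1)
            ds_px = np.concatenate([seglen, seglen[-1:]])
        w = peak * line_norm * ds_px
        _deposit2d(img, mapped[:, ::-1], w)  # (y, x) order

    for f in scene.filament_segments:
        draw_line(f.points[:, :2], sem.edge_contrast)
    for p in scene.podosomes:
        contour = _capsule_contour(p.center_xy, p.center_xy,
                                   p.core_diameter / 2.0, step)
        contour = np.vstack([contour, contour[:1]])
        draw_line(contour, sem.edge_contrast * _SEM_CORE_FACTOR)

    img = ndimage.gaussian_filter(img, sig, mode="constant")

    # beads: filled discs (drawn after the ridge blur; lightly softened)
    if len(scene.beads):
        disc = np.zeros_like(img)
        r_px = 100.0 / ps  # 200 nm bead -> 100 nm radius
        yy, xx = np.mgrid[0:ny, 0:nx]
        for b in scene.beads:
            cx, cy = T.apply(b)
            x0, x1 = int(cx - r_px) - 2, int(cx + r_px) + 3
            y0, y1 = int(cy - r_px) - 2, int(cy + r_px) + 3
            x0, y0 = max(x0, 0), max(y0, 0)
            x1, y1 = min(x1, nx), min(y1, ny)
            if x0 >= x1 or y0 >= y1:
                continue
            sub = (xx[y0:y1, x0:x1] - cx) ** 2 + (yy[y0:y1, x0:x1] - cy) ** 2
            disc[y0:y1, x0:x1][sub <= r_px ** 2] = \
                sem.edge_contrast * _SEM_BEAD_FACTOR
        disc = ndimage.gaussian_filter(disc, 1.0, mode="constant")
        img += disc

    img += sem.background
    if sem.noise_scale > 0:
        rng = np.random.default_rng([int(scene.seed) & 0x7FFFFFFF, 202])
        img += rng.normal(0.0, sem.noise_scale, size=img.shape)
    np.clip(img, 0.0, float(2 ** sem.bit_depth - 1), out=img)
    return img
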