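"""Classification and quantification of closely associated podosomes.

Two (or more) podosomes are *closely associated* when their separate actin
cores are surrounded by one continuous vinculin ring -- the morphological
signature of an ongoing fission or fusion event.  On the registered SEM
image such pairs are typically joined by a thick bundle of parallel actin
filaments stretching from one core to the other; a simple ridge-intensity
score along the inter-core segment decides whether that bundle is present.

Continuity of a ring is operationalized on the binary vinculin mask: after
a single morphological closing (radius 1 px) a component counts as a
continuous ring when its filled footprint has an interior hole, and an
association event is an interior region containing >= 2 core centers.
Under cytochalasin D, where vinculin disappears, association falls back to
a core-distance criterion (centers closer than 1.5 um).
"""
from __future__ import annotations

import dataclasses
import math
from typing import Literal, Sequence

import numpy as np
from scipy import ndimage

from .profiling import CoreDetection

__all__ = [
    "AssociationEvent",
    "EventTally",
    "AssociationError",
    "find_associated",
    "find_associated_by_distance",
    "bundle_score",
    "tally",
]


class AssociationError(ValueError):
    pass


@dataclasses.dataclass
class AssociationEvent:
    core_ids: tuple[int, ...]
    ring_component_id: int
    bundle_score: float | None = None
    bundle_present: bool | None = None
    substrate: Literal["flat", "topographical"] = "flat"
    treatment: Literal["control", "cytoD"] = "control"


@dataclasses.dataclass(frozen=True)
class EventTally:
    """Counts of events with a detected interpodosomal bundle.

    ``percent`` is rounded half-up to an integer, matching the convention
    used when reporting fractions such as 41/44 -> 93%.
    """

    n_events: int
    n_with_bundle: int
    percent: int

    @classmethod
    def from_counts(cls, n_with_bundle: int, n_events: int) -> "EventTally":
        if n_events <= 0:
            raise AssociationError("tally needs at least one event")
        if not 0 <= n_with_bundle <= n_events:
            raise AssociationError("0 <= n_with_bundle <= n_events violated")
        pct = math.floor(100.0 * n_with_bundle / n_events + 0.5)
        return cls(n_events=int(n_events), n_with_bundle=int(n_with_bundle),
                   percent=int(pct))


def _centers_to_px(cores: Sequence, pixel_size: float) -> np.ndarray:
    pts = []
    for c in cores:
        xy = c.center_xy if isinstance(c, CoreDetection) else c
        pts.append((float(xy[0]), float(xy[1])))
    return np.asarray(pts, dtype=float) / pixel_size  # (n, 2) x, y in px


def find_associated(
    cores: Sequence,
    vinculin_mask: np.ndarray,
    pixel_size: float,
    closing_radius: int = 1,
) -> list[AssociationEvent]:
    """Find groups of cores sharing one continuous vinculin ring.

    ``cores`` is a list of :class:`CoreDetection` (or bare (x, y) nm
    tuples) on the same grid as the binary ``vinculin_mask``.  Small gaps
    in the mask are closed with one morphological closing step; each
    connected component is filled, and any interior hole containing two or
    more core centers yields one event listing those cores.  Cores inside
    disjoint single rings, or rings that are broken (no interior), produce
    no events.
    """
    if len(cores) == 0:
        return []
    mask = np.asarray(vinculin_mask, dtype=bool)
    if mask.ndim != 2:
        raise AssociationError("vinculin_mask must be 2D")
    pts_px = _centers_to_px(cores, pixel_size)
    cols = np.clip(np.round(pts_px[:, 0]).astype(int), 0, mask.shape[1] - 1)
    rows = np.clip(np.round(pts_px[:, 1]).astype(int), 0, mask.shape[0] - 1)

    if closing_radius > 0:
        r = int(closing_radius)
        yy, xx = np.mgrid[-r:r + 1, -r:r + 1]
        structure = (yy * yy + xx * xx) <= r * r
        closed = ndimage.binary_closing(mask, structure=structure)
    else:
        closed = mask
    labels, n_comp = ndimage.label(closed, structure=np.ones((3, 3), dtype=int))

    events: list[AssociationEvent] = []
    for lab in range(1, n_comp + 1):
        comp = labels == lab
        filled = ndimage.binary_fill_holes(comp)
        interior = filled & ~comp
        if not interior.any():
            continue  # broken ring: no enclosed interior
        holes, n_holes = ndimage.label(interior)  # 4-connectivity (dual of ring)
        by_hole: dict[int, list[int]] = {}
        for i, (rr, cc) in enumerate(zip(rows, cols)):
            h = holes[rr, cc]
            if h > 0:
                by_hole.setdefault(int(h), []).append(i)
        for members in by_hole.values():
            if len(members) >= 2:
                events.append(AssociationEvent(
                    core_ids=tuple(sorted(members)), ring_component_id=int(lab)))
    return events


def find_associated_by_distance(
    cores: Sequence,
    max_separation: float = 1500.0,
) -> list[AssociationEvent]:
    """Distance fallback for cytochalasin-D data where vinculin is absent.

    Cores whose centers lie within ``max_separation`` nm are grouped into
    one event (transitively)."""
    if len(cores) == 0:
        return []
    pts = _centers_to_px(cores, 1.0)  # nm
    n = len(pts)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if np.linalg.norm(pts[i] - pts[j]) <= max_separation:
                parent[find(i)] = find(j)
    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    return [
        AssociationEvent(core_ids=tuple(sorted(g)), ring_component_id=-1,
                         treatment="cytoD")
        for g in groups.values() if len(g) >= 2
    ]


def bundle_score(
    sem_registered: np.ndarray,
    core_a_nm: tuple[float, float],
    core_b_nm: tuple[float, float],
    pixel_size: float,
    core_diameter: float = 700.0,
    ridge_width: float = 50.0,
    threshold: float = 2.0,
) -> tuple[float, bool]:
    """Score the interpodosomal bundle between two cores on the SEM image.

    The image is ridge-enhanced with a difference of Gaussians tuned to the
    filament width (negative response clipped to zero); the score is the
    median enhanced intensity along the inter-core segment -- excluding the
    two core footprints -- divided by the local background, estimated as
    the median enhanced intensity along two parallel control segments
    offset by one core diameter.  The median is used on both sides because
    a true bundle runs continuously along the whole segment, whereas
    isolated filaments crossing it only touch a few samples.
    ``bundle_present`` is ``score > threshold`` (default 2x background).
    """
    img = np.asarray(sem_registered, dtype=float)
    if img.ndim != 2:
        raise AssociationError("sem_registered must be a 2D image")
    a = np.asarray(core_a_nm, dtype=float)
    b = np.asarray(core_b_nm, dtype=float)
    sep = float(np.linalg.norm(b - a))
    if sep <= core_diameter:
        raise AssociationError(
            f"core separation {sep:.0f} nm must exceed the core diameter "
            f"{core_diameter:.0f} nm")
    r_core = core_diameter / 2.0
    u = (b - a) / sep
    start = a + r_core * u
    end = b - r_core * u
    length = sep - core_diameter
    if length <= 0:
        raise AssociationError("degenerate inter-core segment")
    ny, nx = img.shape
    for p in (a, b):
        if not (0 <= p[0] / pixel_size < nx and 0 <= p[1] / pixel_size < ny):
            raise AssociationError("both cores must lie inside the image")

    s1 = ridge_width / 2.355 / pixel_size
    dog = ndimage.gaussian_filter(img, s1) - ndimage.gaussian_filter(img, 3.0 * s1)
    enhanced = np.clip(dog, 0.0, None)

    n_samp = max(8, int(round(length / pixel_size)))
    t = np.linspace(0.0, 1.0, n_samp)
    seg = start[None, :] + t[:, None] * (end - start)[None, :]

    def sample(points_nm: np.ndarray) -> np.ndarray:
        px = points_nm / pixel_size
        return ndimage.map_coordinates(enhanced, [px[:, 1], px[:, 0]],
                                       order=1, mode="nearest")

    seg_level = float(np.median(sample(seg)))
    nvec = np.array([-u[1], u[0]])
    bg_vals = np.concatenate([
        sample(seg + core_diameter * nvec),
        sample(seg - core_diameter * nvec),
    ])
    background = float(np.median(bg_vals))
    eps = 1e-2 * float(enhanced.max() + 1e-12)
    score = seg_level / (background + eps)
    return score, bool(score > threshold)


def tally(events: Sequence[AssociationEvent]) -> EventTally:
    """Count events with a detected bundle and the rounded percentage."""
    if not events:
        raise AssociationError("tally needs at least one event")
    n_with = sum(1 for e in events if e.bundle_present)
    return EventTally.from_counts(n_with, len(events))
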