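"""Radial fluorescence profile analysis of podosomes.

For each podosome core a ~3 um line through the center is rotated in 36
steps of 10 degrees; the (radius, z) slice sampled along each line is
averaged over all angles into a *radial orthogonal view*.  From that view,
x-y intensity profiles are read as rows (one per z-section) and z profiles
as columns at fixed radial offsets -- by convention 0 nm (core actin),
200 nm (zyxin), 360 nm (vinculin) and 1000 nm (network actin).  Profiles
are min-max normalized over all z-sections of a podosome/channel and
aggregated across podosomes as mean +- SEM.

Core centers are found semi-automatically: difference-of-Gaussians
band-pass on the actin sum projection, local maxima with a ~700 nm
minimum separation (the core size), sub-pixel refinement by local
intensity-weighted centroid, and an ``accepted`` flag for manual curation.
"""
from __future__ import annotations

import dataclasses
import math
from typing import Literal, Sequence

import numpy as np
from scipy import ndimage
from skimage.feature import peak_local_max

__all__ = [
    "CoreDetection",
    "RadialOrthogonalView",
    "ProfileSet",
    "AggregateProfiles",
    "ProfilingError",
    "detect_cores",
    "radial_view",
    "extract_xy_profile",
    "extract_z_profile",
    "build_profile_set",
    "normalize_profiles",
    "aggregate",
    "normalize_to_control",
    "DEFAULT_OFFSETS_NM",
]

#: radial offsets (nm) at which z profiles are read by default:
#: core actin, zyxin, vinculin, network actin
DEFAULT_OFFSETS_NM = (0.0, 200.0, 360.0, 1000.0)


class ProfilingError(ValueError):
    pass


@dataclasses.dataclass
class CoreDetection:
    center_xy: tuple[float, float]  # nm
    detection_score: float
    accepted: bool = True


@dataclasses.dataclass
class RadialOrthogonalView:
    """Angle-averaged (z, r) view around one podosome center.

    ``data[z, i]`` is the mean over all rotation angles of the intensity at
    signed radius ``r_coords[i]`` (nm, spanning -L/2..+L/2) in z-slice
    ``z``.  ``n_angles * angle_step == 360`` by construction.
    """

    data: np.ndarray  # (nz, nr)
    r_coords: np.ndarray  # nm, signed
    r_step: float  # nm
    z_step: float  # nm
    n_angles: int
    line_length: float  # nm
    channel: str | None = None

    @property
    def angle_step(self) -> float:
        return 360.0 / self.n_angles

    @property
    def n_z(self) -> int:
        return self.data.shape[0]


def detect_cores(
    actin_stack: np.ndarray,
    pixel_size: float,
    min_separation: float = 700.0,
    score_threshold: float | None = None,
    threshold_rel: float = 0.3,
    border_margin: float = 0.0,
) -> list[CoreDetection]:
    """Detect podosome core centers on the actin channel.

    Candidates are local maxima of a difference-of-Gaussians band-pass
    (150/500 nm) of the sum projection, separated by at least
    ``min_separation`` (two cores closer than that merge into a single
    detection); each candidate is refined to the intensity-weighted
    centroid of a core-sized window.  Returned sorted by score descending.
    """
    if pixel_size <= 0:
        raise ProfilingError("pixel_size must be positive")
    stack = np.asarray(actin_stack, dtype=float)
    if stack.ndim == 2:
        stack = stack[None]
    # skip the membrane-proximal slice: the ventral filament mat and
    # interpodosomal bundles live there and blur core peaks together
    proj = stack[1:].sum(axis=0) if stack.shape[0] > 1 else stack.sum(axis=0)
    dog = ndimage.gaussian_filter(proj, 150.0 / pixel_size) \
        - ndimage.gaussian_filter(proj, 400.0 / pixel_size)
    if dog.max() <= 0:
        return []
    # peak suppression uses a smaller window than min_separation (the ridge
    # joining closely associated cores otherwise swallows the weaker peak);
    # the separation contract is enforced on the refined centers below
    min_dist = max(1, int(round(0.5 * min_separation / pixel_size)))
    exclude = int(round(border_margin / pixel_size)) if border_margin else 0
    kw: dict = {"min_distance": min_dist, "exclude_border": exclude}
    if score_threshold is not None:
        kw["threshold_abs"] = score_threshold
    else:
        kw["threshold_rel"] = threshold_rel
    peaks = peak_local_max(dog, **kw)

    # sub-pixel refinement on the background-subtracted projection
    bg = np.median(proj)
    sub = np.clip(proj - bg, 0.0, None)
    half = max(1, int(round(350.0 / pixel_size)))
    detections: list[CoreDetection] = []
    for r, c in peaks:
        r0, r1 = max(r - half, 0), min(r + half + 1, proj.shape[0])
        c0, c1 = max(c - half, 0), min(c + half + 1, proj.shape[1])
        win = sub[r0:r1, c0:c1]
        total = win.sum()
        if total <= 0:
            cy, cx = float(r), float(c)
        else:
            rows, cols = np.mgrid[r0:r1, c0:c1]
            cy = float((rows * win).sum() / total)
            cx = float((cols * win).sum() / total)
        detections.append(CoreDetection(
            center_xy=(cx * pixel_size, cy * pixel_size),
            detection_score=float(dog[r, c])))
    detections.sort(key=lambda d: d.detection_score, reverse=True)
    # enforce the pairwise min_separation contract, keeping higher scores
    kept: list[CoreDetection] = []
    for d in detections:
        c = np.asarray(d.center_xy)
        if all(np.linalg.norm(c - np.asarray(k.center_xy)) >= min_separation
               for k in kept):
            kept.append(d)
    return kept


def radial_view(
    stack: np.ndarray,
    center_xy: tuple[float, float],
    pixel_size: float,
    z_step: float,
    n_angles: int = 36,
    line_length: float = 3000.0,
    r_step: float | None = None,
    channel: str | None = None,
) -> RadialOrthogonalView:
    """Average radial orthogonal view around ``center_xy``.

    For each of ``n_angles`` evenly spaced rotation angles, the stack is
    sampled by bilinear interpolation along the rotated line through the
    center at every z, giving one orthogonal (r, z) slice per angle; the
    view is their pixel-wise mean.  The center must be at least
    ``line_length / 2`` from every lateral border.
    """
    stack = np.asarray(stack, dtype=float)
    if stack.ndim != 3:
        raise ProfilingError("expected a (z, y, x) stack")
    if n_angles < 1:
        raise ProfilingError("n_angles must be >= 1")
    nz, ny, nx = stack.shape
    cx, cy = float(center_xy[0]), float(center_xy[1])
    half = line_length / 2.0
    for name, pos, hi in (("x", cx, (nx - 1) * pixel_size),
                          ("y", cy, (ny - 1) * pixel_size)):
        if pos - half < 0 or pos + half > hi:
            raise ProfilingError(
                f"center too close to the {name} border: needs {half:.0f} nm "
                f"margin but has {min(pos, hi - pos):.0f} nm")
    if r_step is None:
        r_step = pixel_size
    n_r = int(round(line_length / r_step)) + 1
    r = (np.arange(n_r) - (n_r - 1) / 2.0) * r_step  # signed radius, nm
    z_idx = np.arange(nz, dtype=float)

    acc = np.zeros((nz, r.size), dtype=float)
    for i in range(n_angles):
        th = math.radians(i * 360.0 / n_angles)
        xs = (cx + r * math.cos(th)) / pixel_size
        ys = (cy + r * math.sin(th)) / pixel_size
        coords = np.stack([
            np.repeat(z_idx, r.size),
            np.tile(ys, nz),
            np.tile(xs, nz),
        ])
        acc += ndimage.map_coordinates(stack, coords, order=1,
                                       mode="constant", cval=0.0
                                       ).reshape(nz, r.size)
    acc /= n_angles
    return RadialOrthogonalView(
        data=acc, r_coords=r, r_step=float(r_step), z_step=float(z_step),
        n_angles=int(n_angles), line_length=float(line_length),
        channel=channel)


def extract_xy_profile(view: RadialOrthogonalView, z_index: int) -> np.ndarray:
    """Intensity vs signed radius at one z-section (a row of the view)."""
    if not 0 <= z_index < view.n_z:
        raise ProfilingError(
            f"z_index {z_index} out of range [0, {view.n_z})")
    return view.data[z_index].copy()


def extract_z_profile(
    view: RadialOrthogonalView,
    radial_offset: float,
    side_policy: Literal["mean_of_both", "left", "right"] = "mean_of_both",
) -> np.ndarray:
    """Intensity vs z at a fixed radial offset (nm) from the center.

    The offset is snapped to the nearest sampled radius; by default the
    +r and -r columns are averaged (they are identical for a rotationally
    symmetric podosome).
    """
    if abs(radial_offset) > view.line_length / 2.0:
        raise ProfilingError(
            f"radial offset {radial_offset} nm beyond the +-"
            f"{view.line_length / 2:.0f} nm view")
    i_pos = int(np.argmin(np.abs(view.r_coords - abs(radial_offset))))
    i_neg = int(np.argmin(np.abs(view.r_coords + abs(radial_offset))))
    if side_policy == "right":
        return view.data[:, i_pos].copy()
    if side_policy == "left":
        return view.data[:, i_neg].copy()
    if side_policy == "mean_of_both":
        return 0.5 * (view.data[:, i_pos] + view.data[:, i_neg])
    raise ProfilingError(f"unknown side_policy {side_policy!r}")


# ---------------------------------------------------------------------------
# profile sets
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class ProfileSet:
    """Profiles of one podosome/channel on a fixed sampling grid.

    ``xy_profiles[z_index]`` is intensity vs ``r_coords``;
    ``z_profiles[offset_nm]`` is intensity vs z-slice.  ``normalization``
    records the (min, max) used when the set has been min-max normalized;
    ``degenerate`` flags a constant (max == min) input.
    """

    xy_profiles: dict
    z_profiles: dict
    r_coords: np.ndarray
    z_step: float
    channel: str | None = None
    normalization: tuple[float, float] | None = None
    degenerate: bool = False

    def _all_values(self) -> np.ndarray:
        parts = [np.asarray(v, dtype=float) for v in self.xy_profiles.values()]
        parts += [np.asarray(v, dtype=float) for v in self.z_profiles.values()]
        return np.concatenate([p.ravel() for p in parts]) if parts else np.zeros(0)

    def grid_signature(self) -> tuple:
        return (tuple(sorted(self.xy_profiles)), tuple(sorted(self.z_profiles)),
                tuple(np.round(self.r_coords, 6)), float(self.z_step))


@dataclasses.dataclass
class AggregateProfiles:
    """Pointwise mean +- SEM over podosomes (SEM = sd / sqrt(n), ddof=1)."""

    mean: ProfileSet
    sem: ProfileSet
    n: int


def build_profile_set(
    view: RadialOrthogonalView,
    z_indices: Sequence[int] | None = None,
    offsets_nm: Sequence[float] = DEFAULT_OFFSETS_NM,
    side_policy: Literal["mean_of_both", "left", "right"] = "mean_of_both",
) -> ProfileSet:
    """Read the standard x-y and z profiles out of one radial view.

    ``z_indices`` defaults to four evenly spaced sections from the membrane
    to the top of the stack.
    """
    if z_indices is None:
        z_indices = np.unique(np.linspace(0, view.n_z - 1, 4).round().astype(int))
    xy = {int(z): extract_xy_profile(view, int(z)) for z in z_indices}
    zp = {float(o): extract_z_profile(view, float(o), side_policy)
          for o in offsets_nm}
    return ProfileSet(xy_profiles=xy, z_profiles=zp,
                      r_coords=view.r_coords.copy(), z_step=view.z_step,
                      channel=view.channel)


def normalize_profiles(ps: ProfileSet) -> ProfileSet:
    """Min-max normalize using the global extrema over all z-sections.

    The minimum and maximum are taken jointly over every profile in the
    set, so relative amplitudes between z-sections are preserved.  A
    constant set maps to all zeros with ``degenerate=True``.  Normalizing
    an already-normalized set is the identity.
    """
    vals = ps._all_values()
    if vals.size == 0 or not np.any(np.isfinite(vals)):
        raise ProfilingError("profile set contains no finite values")
    vmin = float(np.nanmin(vals))
    vmax = float(np.nanmax(vals))
    degenerate = vmax == vmin

    def norm(v):
        v = np.asarray(v, dtype=float)
        return np.zeros_like(v) if degenerate else (v - vmin) / (vmax - vmin)

    return ProfileSet(
        xy_profiles={k: norm(v) for k, v in ps.xy_profiles.items()},
        z_profiles={k: norm(v) for k, v in ps.z_profiles.items()},
        r_coords=ps.r_coords.copy(), z_step=ps.z_step, channel=ps.channel,
        normalization=(vmin, vmax), degenerate=degenerate)


def aggregate(profile_sets: Sequence[ProfileSet]) -> AggregateProfiles:
    """Pointwise mean and standard error over podosomes."""
    if not profile_sets:
        raise ProfilingError("aggregate needs at least one profile set")
    sig = profile_sets[0].grid_signature()
    for ps in profile_sets[1:]:
        if ps.grid_signature() != sig:
            raise ProfilingError("profile sets use different sampling grids")
    n = len(profile_sets)

    def stats(key_getter):
        means, sems = {}, {}
        for key in key_getter(profile_sets[0]):
            arr = np.stack([np.asarray(key_getter(ps)[key], dtype=float)
                            for ps in profile_sets])
            means[key] = arr.mean(axis=0)
            sd = arr.std(axis=0, ddof=1) if n > 1 else np.zeros(arr.shape[1])
            sems[key] = sd / math.sqrt(n)
        return means, sems

    xy_mean, xy_sem = stats(lambda ps: ps.xy_profiles)
    z_mean, z_sem = stats(lambda ps: ps.z_profiles)
    base = profile_sets[0]
    mk = lambda xy, zp: ProfileSet(  # noqa: E731
        xy_profiles=xy, z_profiles=zp, r_coords=base.r_coords.copy(),
        z_step=base.z_step, channel=base.channel)
    return AggregateProfiles(mean=mk(xy_mean, z_mean), sem=mk(xy_sem, z_sem), n=n)


def normalize_to_control(
    treated: ProfileSet,
    control: ProfileSet,
    eps_fraction: float = 1e-3,
) -> tuple[ProfileSet, ProfileSet]:
    """Express treated profiles relative to an untreated control.

    Values are divided pointwise by the control profile; points where the
    control is below ``eps_fraction`` of its own maximum are undefined and
    returned as NaN in the ratio, with a boolean flag set in the second
    return value (same ProfileSet layout, True where the ratio is valid).
    Used to compare cytochalasin-D-treated membranes against controls.
    """
    if treated.grid_signature() != control.grid_signature():
        raise ProfilingError("treated and control profiles use different grids")
    if treated.channel != control.channel:
        raise ProfilingError(
            f"channel mismatch: {treated.channel!r} vs {control.channel!r}")
    cmax = float(np.nanmax(control._all_values()))
    eps = eps_fraction * max(abs(cmax), 1e-300)

    def ratio(t, c):
        t = np.asarray(t, dtype=float)
        c = np.asarray(c, dtype=float)
        valid = np.abs(c) > eps
        out = np.full_like(t, np.nan)
        out[valid] = t[valid] / c[valid]
        return out, valid

    xy_r, xy_v, z_r, z_v = {}, {}, {}, {}
    for k in treated.xy_profiles:
        xy_r[k], xy_v[k] = ratio(treated.xy_profiles[k], control.xy_profiles[k])
    for k in treated.z_profiles:
        z_r[k], z_v[k] = ratio(treated.z_profiles[k], control.z_profiles[k])
    mk = lambda xy, zp: ProfileSet(  # noqa: E731
        xy_profiles=xy, z_profiles=zp, r_coords=treated.r_coords.copy(),
        z_step=treated.z_step, channel=treated.channel)
    return mk(xy_r, z_r), mk(xy_v, z_v)
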