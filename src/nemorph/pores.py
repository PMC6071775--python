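"""In situ nuclear-envelope rim-curvature measurement.

Protocol, per pore: (1) a 3D clip around the pore is cropped from the
reconstruction, binned to a ~3 nm working grid and windowed to 8 bit;
(2) the clip is rotated about z so the membrane trace runs along x;
(3) the clip is rotated about x over a 10-degree grid until the pore
lumen is most circular in projection (the en-face view), the "by eye"
judgement being automated as isoperimetric circularity 4*pi*A/P^2 of
the thresholded lumen; (4) the clip is rotated back by 90 degrees so
the pore axis lies in the viewing plane; (5) at the depth where the
lumen is widest, the inner and outer membrane centre-lines are traced
as intensity minima along columns, their separation d(s) is followed
away from the pore axis on each side, and the rim diameter RD is read
off where d(s) has just become parallel (regression slope below
``parallel_tol`` over a ``parallel_window`` run); the pore diameter is
the midline-to-midline distance across the lumen. Curvature follows as
kappa = 2/RD per side.

Beam-induced section shrinkage is not corrected numerically; instead
:func:`angle_bias_check` reports Pearson correlations of the en-face
angle against rim and pore diameter as a QC gate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy import stats as sps
from matplotlib.path import Path as MplPath
from skimage.filters import threshold_otsu
from skimage.measure import find_contours

from .core import VoxelGrid, bin_volume, to_uint8

DEFAULT_BIN_FACTOR = 4
DEFAULT_STEP_DEG = 10.0
PARALLEL_TOL = 0.05  # dimensionless |dd/ds|
PARALLEL_WINDOW_NM = 15.0
PLANARITY_MAX_RATIO = 0.5  # sqrt-eigenvalue ratio thin/middle axis


class MeasurementError(RuntimeError):
    """A pore could not be measured (geometry not found in the clip)."""


@dataclass
class PoreClip:
    """A pore-centred subvolume with its rotation history."""

    grid: VoxelGrid
    center: tuple[float, float, float]  # nm, in the source volume
    applied_rotations: list[tuple[str, float]] = field(default_factory=list)
    provenance: str = ""
    aligned: bool = False
    perpendicular: bool = False


@dataclass
class PoreMeasurement:
    """Rim and pore diameters of one pore, with kappa = 2/RD per side."""

    pore_id: int
    en_face_angle: float  # degrees, modulo 180
    rim_diameter_i: float  # nm (side x < pore axis)
    rim_diameter_ii: float  # nm (side x > pore axis)
    pore_diameter: float  # nm
    qc_flags: list[str] = field(default_factory=list)

    @property
    def kappa_i(self) -> float:
        return 2.0 / self.rim_diameter_i

    @property
    def kappa_ii(self) -> float:
        return 2.0 / self.rim_diameter_ii


# --- rotations -------------------------------------------------------------

def _rotate(data: np.ndarray, angle_deg: float, axes: tuple[int, int]) -> np.ndarray:
    if abs(angle_deg) % 360.0 < 1e-9:
        return data.astype(np.float32, copy=True)
    bg = float(np.median(data))
    return ndimage.rotate(
        data.astype(np.float32), angle_deg, axes=axes, reshape=False,
        order=1, mode="constant", cval=bg,
    )


def rotate_about_x(data: np.ndarray, angle_deg: float) -> np.ndarray:
    """Rotate a (z, y, x) volume about its x axis (mixes z and y)."""
    return _rotate(data, angle_deg, axes=(0, 1))


def rotate_about_z(data: np.ndarray, angle_deg: float) -> np.ndarray:
    """Rotate a (z, y, x) volume about its z axis (mixes y and x)."""
    return _rotate(data, angle_deg, axes=(1, 2))


# --- pipeline stages -------------------------------------------------------

def extract_clip(
    volume: VoxelGrid,
    center_nm: tuple[float, float, float],
    half_extent_nm: float,
    bin_factor: int = DEFAULT_BIN_FACTOR,
    window: tuple[float, float] = (0.5, 99.5),
) -> PoreClip:
    """Crop a cube around a pore, bin it and window to 8 bit.

    Raises when the requested cube extends outside the volume: a pore
    not completely enclosed in the reconstruction cannot be measured.
    """
    vs = np.asarray(volume.voxel_size)
    c_idx = (np.asarray(center_nm) - np.asarray(volume.origin)) / vs
    half_idx = np.round(half_extent_nm / vs).astype(int)
    lo = np.round(c_idx).astype(int) - half_idx
    hi = np.round(c_idx).astype(int) + half_idx
    if (lo < 0).any() or (hi > np.asarray(volume.shape)).any():
        raise MeasurementError(
            f"clip around {tuple(center_nm)} extends outside the volume; "
            "pore not completely enclosed"
        )
    sub = VoxelGrid(
        volume.data[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]],
        volume.voxel_size,
    )
    sub = bin_volume(sub, bin_factor)
    sub = to_uint8(sub, *window)
    return PoreClip(grid=sub, center=tuple(float(v) for v in center_nm))


def _principal_normal(data: np.ndarray) -> tuple[np.ndarray, float]:
    """Normal of the dominant dark planar structure and its planarity ratio."""
    thr = threshold_otsu(data)
    dark = np.argwhere(data < thr).astype(float)
    if len(dark) < 50:
        raise MeasurementError("too few dark voxels; no membrane in clip")
    dark -= dark.mean(axis=0)
    cov = dark.T @ dark / len(dark)
    evals, evecs = np.linalg.eigh(cov)  # ascending
    ratio = float(np.sqrt(evals[0] / max(evals[1], 1e-12)))
    return evecs[:, 0], ratio


def align_envelope_to_x(clip: PoreClip) -> PoreClip:
    """Rotate about z so the membrane's in-plane trace runs along x.

    The in-plane (azimuth) orientation of the dark planar structure is
    estimated from the principal axes of below-threshold voxels and
    removed, leaving the residual envelope tilt purely about the x axis
    for the en-face search. Raises when no planar structure is present.
    """
    normal, ratio = _principal_normal(clip.grid.data)
    if ratio > PLANARITY_MAX_RATIO:
        raise MeasurementError(
            f"no planar membrane structure (planarity ratio {ratio:.2f})"
        )
    nz, ny, nx = normal
    if ny < 0:
        ny, nx = -ny, -nx
    phi = float(np.degrees(np.arctan2(-nx, ny)))
    rotated = rotate_about_z(clip.grid.data, phi)
    out = PoreClip(
        grid=VoxelGrid(rotated, clip.grid.voxel_size),
        center=clip.center,
        applied_rotations=clip.applied_rotations + [("z", phi)],
        provenance=clip.provenance,
        aligned=True,
    )
    return out


def lumen_circularity(slab: np.ndarray) -> float:
    """Isoperimetric circularity of the enclosed bright lumen of a 2D image.

    The lumen boundary is extracted at sub-pixel precision as the
    iso-intensity contour at the Otsu level; among closed contours
    enclosing the image centre the smallest (the lumen edge, inside the
    dark rim annulus) is scored as 4*pi*A/P^2 with polygon (shoelace)
    area and polyline perimeter. Returns 0.0 when no closed contour
    encloses the centre — an open ring is not an en-face pore.
    """
    # light smoothing equalises raster aliasing between grid-aligned
    # (en-face) and interpolated (oblique) views before contouring
    slab = ndimage.gaussian_filter(slab.astype(float), 1.0)
    thr = threshold_otsu(slab)
    center = (np.asarray(slab.shape, dtype=float) - 1.0) / 2.0
    best_area = np.inf
    best_circ = 0.0
    for contour in find_contours(slab, level=float(thr)):
        if len(contour) < 8 or not np.allclose(contour[0], contour[-1]):
            continue
        path = MplPath(contour)
        if not path.contains_point(center):
            continue
        y, x = contour[:, 0], contour[:, 1]
        area = 0.5 * abs(np.dot(y[:-1], np.diff(x)) - np.dot(x[:-1], np.diff(y)))
        perim = float(np.hypot(np.diff(y), np.diff(x)).sum())
        if perim == 0 or area == 0:
            continue
        if area < best_area:
            best_area = area
            best_circ = float(4.0 * np.pi * area / perim ** 2)
    return best_circ


def find_en_face_angle(
    clip: PoreClip,
    step_deg: float = DEFAULT_STEP_DEG,
    slab_half_nm: float = 4.0,
    refine_step_deg: float | None = None,
) -> tuple[float, list[tuple[float, float]]]:
    """Search rotation about x for the most circular (en-face) pore view.

    The clip is rotated over a ``step_deg`` grid spanning [0, 180); at
    each angle a thin central slab is averaged and scored by lumen
    circularity. In the en-face view this slab cuts the rim as a clean
    dark annulus around a bright circular lumen; off-angle the annulus
    opens or elongates, collapsing the score. Ties break toward the
    smaller angle.
    """
    if not clip.aligned:
        raise MeasurementError("clip must be aligned (align_envelope_to_x) first")
    v = clip.grid.voxel_size[0]
    k = max(1, int(round(slab_half_nm / v)))
    zc = clip.grid.shape[0] // 2
    profile = []
    for angle in np.arange(0.0, 180.0, step_deg):
        rot = rotate_about_x(clip.grid.data, angle)
        slab = rot[zc - k: zc + k + 1].mean(axis=0)
        profile.append((float(angle), lumen_circularity(slab)))
    # scores within 1e-4 are not meaningfully distinct (the circularity
    # response is flat near en face); quantise, then break ties toward
    # the smaller angle
    best_angle, best_c = max(profile, key=lambda t: (round(t[1], 4), -t[0]))
    if best_c <= 0.0:
        raise MeasurementError("no enclosed pore lumen found at any angle")
    if refine_step_deg is not None and refine_step_deg < step_deg:
        # optional local refinement around the grid optimum; off by
        # default so the default behaviour stays on the coarse protocol
        fine = []
        for angle in np.arange(best_angle - step_deg, best_angle + step_deg + 1e-9,
                               refine_step_deg):
            rot = rotate_about_x(clip.grid.data, float(angle))
            slab = rot[zc - k: zc + k + 1].mean(axis=0)
            fine.append((float(angle) % 180.0, lumen_circularity(slab)))
        profile = profile + fine
        best_angle, best_c = max(fine, key=lambda t: (round(t[1], 4), -t[0]))
    return best_angle, profile


def to_perpendicular_view(clip: PoreClip, en_face_angle: float) -> PoreClip:
    """Rotate back 90 degrees from en face: pore axis in the viewing plane."""
    if clip.perpendicular:
        raise MeasurementError("clip already rotated to the perpendicular view")
    angle = en_face_angle - 90.0
    rotated = rotate_about_x(clip.grid.data, angle)
    return PoreClip(
        grid=VoxelGrid(rotated, clip.grid.voxel_size),
        center=clip.center,
        applied_rotations=clip.applied_rotations + [("x", angle)],
        provenance=clip.provenance,
        aligned=clip.aligned,
        perpendicular=True,
    )


# --- measurement -----------------------------------------------------------

def _subpixel_min(profile: np.ndarray, idx: int) -> float:
    """Parabolic sub-voxel refinement of a local minimum position."""
    if idx <= 0 or idx >= len(profile) - 1:
        return float(idx)
    a, b, c = profile[idx - 1], profile[idx], profile[idx + 1]
    denom = a - 2 * b + c
    if denom <= 0:
        return float(idx)
    return float(idx + 0.5 * (a - c) / denom)


def _band_minimum(column: np.ndarray, lo: int, hi: int, thr: float) -> float | None:
    """Deepest sub-threshold minimum of ``column[lo:hi]``, subpixel, or None."""
    seg = column[lo:hi]
    if seg.size < 3:
        return None
    idx = int(np.argmin(seg))
    if seg[idx] >= thr:
        return None
    return _subpixel_min(column.astype(float), lo + idx)


def _lumen_run(dark_any: np.ndarray, xc: int):
    """Bounded membrane-free column run containing ``xc``, or None."""
    nx = dark_any.size
    if dark_any[xc]:
        return None
    xl = xc
    while xl > 0 and not dark_any[xl - 1]:
        xl -= 1
    xr = xc
    while xr < nx - 1 and not dark_any[xr + 1]:
        xr += 1
    if xl == 0 or xr == nx - 1:  # open to the border: not an enclosed lumen
        return None
    return xl, xr


def _widest_lumen_depth(data: np.ndarray, thr: float, yc: int, xc: int, search: int):
    """Slice with the widest enclosed lumen and its bounding columns.

    A lumen column holds no sub-threshold (membrane) intensity within
    the band-search window around the midplane; the lumen of a slice is
    the bounded run of such columns containing the pore axis. Restricting
    the run to membrane-free columns keeps the nearby rim-junction blobs
    — not the torus outer equator further out — as the bounds.
    """
    nz = data.shape[0]
    best = (None, -1, None, None)
    for z in range(nz // 4, nz - nz // 4):
        band = data[z, max(yc - search, 0): yc + search + 1, :]
        dark_any = (band < thr).any(axis=0)
        run = _lumen_run(dark_any, xc)
        if run is None:
            continue
        xl, xr = run
        width = xr - xl + 1
        if width > best[1] or (width == best[1] and abs(z - nz // 2) < abs(best[0] - nz // 2)):
            best = (z, width, xl, xr)
    if best[0] is None:
        raise MeasurementError("no pore: no enclosed membrane-free lumen found")
    return best[0], best[2], best[3]


def measure_rim_and_pore(
    clip: PoreClip,
    pore_id: int = 0,
    en_face_angle: float = float("nan"),
    parallel_tol: float = PARALLEL_TOL,
    parallel_window_nm: float = PARALLEL_WINDOW_NM,
) -> PoreMeasurement:
    """Measure rim diameters (both sides) and pore diameter; kappa = 2/RD.

    Requires the perpendicular view. The widest-lumen depth is located
    first; membrane centre-lines are then traced on that slice as
    sub-voxel intensity minima along columns, and the separation d(s)
    is scanned outwards on each side until it has just become parallel.
    """
    if not clip.perpendicular:
        raise MeasurementError("measurement requires the perpendicular view")
    data = clip.grid.data.astype(float)
    v = float(clip.grid.voxel_size[0])
    nz, ny, nx = data.shape
    yc, xc = ny // 2, nx // 2
    thr = float(threshold_otsu(data))
    search = max(4, int(round(25.0 / v)))  # covers rims up to ~40 nm spacing

    z_star, xl_run, xr_run = _widest_lumen_depth(data, thr, yc, xc, search)
    plane = data[z_star]

    # pore diameter: sub-voxel junction minima immediately bounding the
    # lumen run, on a thin midplane band (tolerates small residual tilt)
    midprof = plane[max(yc - 2, 0): yc + 3, :].min(axis=0)
    wl = slice(max(xl_run - 3, 0), xl_run + 1)
    wr = slice(xr_run, min(xr_run + 4, nx))
    x_left = _subpixel_min(midprof, wl.start + int(np.argmin(midprof[wl])))
    x_right = _subpixel_min(midprof, wr.start + int(np.argmin(midprof[wr])))
    pore_d = (x_right - x_left) * v
    x_axis = 0.5 * (x_left + x_right)  # pore axis, voxels

    # membrane separation d(x): two band minima above/below the midplane
    qc: list[str] = []
    d_profile = {}
    for x in range(nx):
        col = plane[:, x]
        y_top = _band_minimum(col, yc + 1, min(yc + search, ny), thr)
        y_bot = _band_minimum(col, max(yc - search, 0), yc, thr)
        if y_top is None or y_bot is None:
            continue
        d_profile[x] = (y_top - y_bot) * v

    def _rim_for_side(side: str) -> float:
        if side == "i":
            xs = sorted((x for x in d_profile if x < x_axis), key=lambda x: x_axis - x)
        else:
            xs = sorted((x for x in d_profile if x > x_axis), key=lambda x: x - x_axis)
        s = np.array([abs(x - x_axis) * v for x in xs])
        d = np.array([d_profile[x] for x in xs])
        if len(s) < 4:
            raise MeasurementError(f"membranes not traceable on side {side}")
        if len(d) >= 5:  # light smoothing against pixel noise
            d = ndimage.median_filter(d, size=3, mode="nearest")
        w = max(3, int(round(parallel_window_nm / v)))
        for k in range(0, len(s) - w):
            ss, dd = s[k:k + w + 1], d[k:k + w + 1]
            slope = np.polyfit(ss, dd, 1)[0]
            if abs(slope) < parallel_tol:
                return float(dd.mean())
        qc.append(f"no_plateau_{side}")
        return float("nan")

    rim_i = _rim_for_side("i")
    rim_ii = _rim_for_side("ii")
    if np.isnan(rim_i) or np.isnan(rim_ii):
        raise MeasurementError(
            f"membrane separation never became parallel (qc: {qc})"
        )
    return PoreMeasurement(
        pore_id=pore_id,
        en_face_angle=float(en_face_angle) % 180.0 if np.isfinite(en_face_angle) else en_face_angle,
        rim_diameter_i=rim_i,
        rim_diameter_ii=rim_ii,
        pore_diameter=float(pore_d),
        qc_flags=qc,
    )


def measure_pore(
    volume: VoxelGrid,
    center_nm: tuple[float, float, float],
    half_extent_nm: float = 120.0,
    bin_factor: int = DEFAULT_BIN_FACTOR,
    step_deg: float = DEFAULT_STEP_DEG,
    pore_id: int = 0,
) -> PoreMeasurement:
    """Full per-pore pipeline: clip, align, en-face search, measure."""
    clip = extract_clip(volume, center_nm, half_extent_nm, bin_factor=bin_factor)
    clip = align_envelope_to_x(clip)
    angle, _profile = find_en_face_angle(clip, step_deg=step_deg)
    perp = to_perpendicular_view(clip, angle)
    return measure_rim_and_pore(perp, pore_id=pore_id, en_face_angle=angle)


@dataclass
class AngleBiasResult:
    """Pearson QC for dependence of measurements on the en-face angle."""

    r_rim: float
    p_rim: float
    r_pore: float
    p_pore: float
    degenerate: bool = False


def angle_bias_check(measurements: list[PoreMeasurement]) -> AngleBiasResult:
    """Pearson correlation of en-face angle vs rim and pore diameter.

    A QC gate against orientation-dependent bias (e.g. anisotropic
    section shrinkage), not a correction. Requires >= 3 measurements
    with distinct angles; zero variance in either variable is flagged.
    """
    angles = np.array([m.en_face_angle for m in measurements], dtype=float)
    rims = np.array(
        [(m.rim_diameter_i + m.rim_diameter_ii) / 2.0 for m in measurements]
    )
    pores_d = np.array([m.pore_diameter for m in measurements])
    if len(measurements) < 3 or np.unique(angles).size < 3:
        raise ValueError("need >= 3 measurements with distinct en-face angles")
    nan = float("nan")
    if np.ptp(angles) == 0:
        return AngleBiasResult(nan, nan, nan, nan, degenerate=True)
    degenerate = False
    if np.ptp(rims) == 0:
        r1 = p1 = nan
        degenerate = True
    else:
        r1, p1 = sps.pearsonr(angles, rims)
    if np.ptp(pores_d) == 0:
        r2 = p2 = nan
        degenerate = True
    else:
        r2, p2 = sps.pearsonr(angles, pores_d)
    return AngleBiasResult(float(r1), float(p1), float(r2), float(p2), degenerate)
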