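"""Ground-truthed EM phantoms.

Two scene families are generated:

* telophase-like scenes — a nuclear-envelope (NE) double-membrane sheet
  with rectangular discontinuities (gaps) of known x-width and z-extent,
  plus spherical vesicle shells with known diameters, rendered as dark
  membrane density on a bright background;
* tomogram-like nuclear-pore volumes — an NE double membrane whose two
  midlines join through a half-toroidal rim around a circular
  fenestration, at a known tilt, for validating the rim-curvature
  measurement by parameter recovery.

Geometry conventions. In the envelope's own frame the two membrane
midlines are planes at ``ze = +-RD/2`` (RD: rim diameter, equal to the
midline-to-midline spacing where the membranes are parallel). Around a
pore the midline is the inner half of a torus of tube radius ``RD/2``
whose centre circle has radius ``R_t = pore_diameter/2 + RD/2``, so the
membranes close smoothly onto the planes and the lumen edge (where the
midlines meet) sits at radius ``pore_diameter/2``: the ground-truth pore
diameter is the midline-to-midline distance across the lumen at its
widest depth. Curvature follows as kappa = 2/RD.

A pore phantom generated with ``tilt_deg = 0`` is en face in the x-y
slices (envelope normal along z); ``tilt_deg`` rotates the envelope
about the x axis and ``azimuth_deg`` about z, in that order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .core import LabelVolume, VoxelGrid

BACKGROUND = 1.0
MEMBRANE = 0.0

NE_LABEL = 1
VESICLE_LABEL = 2

LEGEND = {NE_LABEL: "NE", VESICLE_LABEL: "vesicle"}


@dataclass
class SceneSpec:
    """Parameters of a synthetic scene; fixed seed gives identical output.

    All lengths in nm, angles in degrees. ``gap_specs`` entries are
    ``(dx, dz, (z_center, x_center))``; ``pore_specs`` entries are
    ``(rim_diameter, pore_diameter, tilt_deg, azimuth_deg)``.
    """

    volume_shape: tuple[int, int, int]
    voxel_size: tuple[float, float, float]
    membrane_thickness: float = 7.0
    perinuclear_spacing: float = 40.0
    vesicle_count: int = 0
    vesicle_diameter_mean: float = 57.0
    vesicle_diameter_sd: float = 8.0
    vesicle_diameter_lower: float = 20.0
    vesicle_shell_thickness: float | None = None  # inflate for DAB-halo emulation
    vesicle_distance_range: tuple[float, float] = (100.0, 1000.0)
    gap_specs: list = field(default_factory=list)
    pore_specs: list = field(default_factory=list)
    sheet_wave_amplitude: float = 15.0  # gentle sheet curvature, nm
    sheet_wave_length: float = 2000.0
    noise_sd: float = 0.05
    blur_sigma: float = 1.5  # nm
    seed: int = 0

    def validate(self):
        if any(s < 1 for s in self.volume_shape) or len(self.volume_shape) != 3:
            raise ValueError("volume_shape must be 3 positive integers")
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel_size components must be positive")
        if self.vesicle_diameter_mean <= 0:
            raise ValueError("vesicle_diameter_mean must be positive")
        for rd, pd_, _t, _a in self.pore_specs:
            if rd <= 0:
                raise ValueError("pore rim_diameter must be positive")
            if pd_ <= 0:
                raise ValueError("pore_diameter must be positive")


@dataclass
class GroundTruth:
    """Per-object truth tables for a rendered scene (nm / degrees)."""

    vesicles: pd.DataFrame
    gaps: pd.DataFrame
    pores: pd.DataFrame

    @staticmethod
    def empty() -> "GroundTruth":
        return GroundTruth(
            vesicles=pd.DataFrame(columns=["id", "z", "y", "x", "diameter"]),
            gaps=pd.DataFrame(columns=["id", "z", "x", "dx", "dz", "area"]),
            pores=pd.DataFrame(
                columns=["id", "z", "y", "x", "rim_diameter", "pore_diameter",
                         "tilt_deg", "azimuth_deg", "sub_resolution"]
            ),
        )


def sample_diameters(n: int, mean: float, sd: float, seed, lower: float = 14.0) -> np.ndarray:
    """Draw ``n`` vesicle diameters from Normal(mean, sd) truncated below.

    The lower truncation (default 14 nm, twice a rendered bilayer) keeps
    every drawn vesicle physically renderable as a closed shell.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    if mean <= 0:
        raise ValueError("mean must be positive")
    if sd < 0:
        raise ValueError("sd must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if n == 0:
        return np.empty(0)
    if sd == 0:
        return np.full(n, float(mean))
    out = np.empty(0)
    while out.size < n:
        draw = rng.normal(mean, sd, size=2 * (n - out.size) + 8)
        out = np.concatenate([out, draw[draw > lower]])
    return out[:n]


def _finalize_intensity(intensity: np.ndarray, spec: SceneSpec, rng) -> np.ndarray:
    sigma_vox = [spec.blur_sigma / v for v in spec.voxel_size]
    if spec.blur_sigma > 0:
        intensity = ndimage.gaussian_filter(intensity, sigma=sigma_vox)
    if spec.noise_sd > 0:
        intensity = intensity + rng.normal(0.0, spec.noise_sd, size=intensity.shape).astype(np.float32)
    return intensity.astype(np.float32)


def make_telophase_scene(spec: SceneSpec) -> tuple[VoxelGrid, LabelVolume, GroundTruth]:
    """Render a telophase-like scene: NE sheet, gaps, vesicle shells.

    The NE is a double-membrane sheet normal to y through the volume
    centre (optionally gently waved along x), with each gap spec carved
    out as a rectangular discontinuity in the x-z plane. Vesicles are
    spherical shells with centres placed uniformly at a stated distance
    range from the sheet midplane, rejecting overlaps; packing failure
    after bounded retries raises.

    Returns the noisy intensity grid, the noise-free label volume and
    the ground-truth tables.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    nz, ny, nx = spec.volume_shape
    vz, vy, vx = spec.voxel_size

    z_nm = (np.arange(nz, dtype=np.float32) * vz)[:, None, None]
    y_nm = (np.arange(ny, dtype=np.float32) * vy)[None, :, None]
    x_nm = (np.arange(nx, dtype=np.float32) * vx)[None, None, :]

    y_sheet = ny * vy / 2.0
    if spec.sheet_wave_amplitude > 0:
        y_mid = y_sheet + spec.sheet_wave_amplitude * np.sin(
            2 * np.pi * x_nm / spec.sheet_wave_length
        )
    else:
        y_mid = np.float32(y_sheet)

    half_sp = spec.perinuclear_spacing / 2.0
    half_t = spec.membrane_thickness / 2.0
    dy = y_nm - y_mid
    membrane = (np.abs(np.abs(dy) - half_sp) <= half_t)
    membrane = np.broadcast_to(membrane, (nz, ny, nx)).copy()

    gap_rows = []
    for gi, (dx, dz, (zc, xc)) in enumerate(spec.gap_specs):
        if dx <= 0 or dz <= 0:
            raise ValueError("gap dx and dz must be positive")
        in_x = (np.abs(x_nm[0, 0, :] - xc) < dx / 2.0)
        in_z = (np.abs(z_nm[:, 0, 0] - zc) < dz / 2.0)
        membrane[np.ix_(in_z, np.ones(ny, bool), in_x)] = False
        gap_rows.append(dict(id=gi, z=zc, x=xc, dx=dx, dz=dz, area=dx * dz))

    labels = np.zeros((nz, ny, nx), dtype=np.int32)
    labels[membrane] = NE_LABEL
    intensity = np.full((nz, ny, nx), BACKGROUND, dtype=np.float32)
    intensity[membrane] = MEMBRANE

    # --- vesicles ---------------------------------------------------------
    shell_t = spec.vesicle_shell_thickness or spec.membrane_thickness
    diam = sample_diameters(
        spec.vesicle_count, spec.vesicle_diameter_mean, spec.vesicle_diameter_sd,
        rng, lower=spec.vesicle_diameter_lower,
    )
    dmin, dmax = spec.vesicle_distance_range
    extent = (nz * vz, ny * vy, nx * vx)
    # keep rasterised shells separated: centre distance must exceed the
    # radii sum by at least one voxel diagonal
    sep_margin = float(np.linalg.norm(spec.voxel_size)) + 1.0
    centers = []
    max_tries = 200 * max(spec.vesicle_count, 1)
    tries = 0
    for d in diam:
        r = d / 2.0
        placed = False
        while tries < max_tries:
            tries += 1
            zc = rng.uniform(r + vz, extent[0] - r - vz)
            xc = rng.uniform(r + vx, extent[2] - r - vx)
            dist = rng.uniform(max(dmin, half_sp + half_t + r + 2), dmax)
            yc = y_sheet + dist
            if yc + r + vy >= extent[1]:
                continue
            ok = True
            for (pz, py, px, pr) in centers:
                if (zc - pz) ** 2 + (yc - py) ** 2 + (xc - px) ** 2 < (r + pr + sep_margin) ** 2:
                    ok = False
                    break
            if ok:
                centers.append((zc, yc, xc, r))
                placed = True
                break
        if not placed:
            raise RuntimeError(
                f"vesicle packing failed after {max_tries} tries "
                f"({len(centers)}/{spec.vesicle_count} placed); volume too small"
            )

    ves_rows = []
    zi_all = np.arange(nz) * vz
    yi_all = np.arange(ny) * vy
    xi_all = np.arange(nx) * vx
    for vid, ((zc, yc, xc, r), d) in enumerate(zip(centers, diam)):
        t_eff = max(shell_t, 1.2 * max(spec.voxel_size))
        zi = np.where(np.abs(zi_all - zc) <= r + vz)[0]
        yi = np.where(np.abs(yi_all - yc) <= r + vy)[0]
        xi = np.where(np.abs(xi_all - xc) <= r + vx)[0]
        dz_ = (zi_all[zi] - zc)[:, None, None]
        dy_ = (yi_all[yi] - yc)[None, :, None]
        dx_ = (xi_all[xi] - xc)[None, None, :]
        rad = np.sqrt(dz_ ** 2 + dy_ ** 2 + dx_ ** 2)
        shell = (rad <= r) & (rad > r - t_eff)
        sub = np.ix_(zi, yi, xi)
        lv = labels[sub]
        lv[shell] = VESICLE_LABEL
        labels[sub] = lv
        iv = intensity[sub]
        iv[shell] = MEMBRANE
        intensity[sub] = iv
        ves_rows.append(dict(id=vid, z=zc, y=yc, x=xc, diameter=d))

    intensity = _finalize_intensity(intensity, spec, rng)

    truth = GroundTruth.empty()
    if ves_rows:
        truth.vesicles = pd.DataFrame(ves_rows)
    if gap_rows:
        truth.gaps = pd.DataFrame(gap_rows)
    grid = VoxelGrid(intensity, spec.voxel_size)
    lab = LabelVolume(labels, spec.voxel_size, dict(LEGEND))
    return grid, lab, truth


def _rotation_matrix(tilt_deg: float, azimuth_deg: float) -> np.ndarray:
    """Envelope orientation: tilt about x, then azimuth about z (zyx order).

    The tilt sign is chosen so that rotating the rendered volume about x
    by ``+tilt_deg`` (measurement convention) restores the en-face view:
    ground-truth tilt and the recovered en-face angle share one scale.
    """
    t = -np.deg2rad(tilt_deg)
    a = np.deg2rad(azimuth_deg)
    # axes order (z, y, x); rotation about x mixes (z, y)
    rx = np.array([[np.cos(t), -np.sin(t), 0.0],
                   [np.sin(t), np.cos(t), 0.0],
                   [0.0, 0.0, 1.0]])
    # rotation about z mixes (y, x)
    rz = np.array([[1.0, 0.0, 0.0],
                   [0.0, np.cos(a), -np.sin(a)],
                   [0.0, np.sin(a), np.cos(a)]])
    return rz @ rx


def make_pore_volume(spec: SceneSpec) -> tuple[VoxelGrid, GroundTruth]:
    """Render nuclear-pore phantom(s) into one tomogram-like volume.

    Each pore is a circular fenestration through the NE double membrane
    whose midlines join via a half-toroidal rim of tube diameter equal
    to the requested rim diameter. The whole envelope is rotated by the
    (shared) tilt and azimuth of the pore specs before rasterisation;
    membranes render dark on a bright background, then Gaussian blur
    and additive Gaussian noise are applied.

    Pores with rim diameter below the largest voxel pitch are rendered
    anyway but flagged ``sub_resolution`` in the ground truth.
    """
    spec.validate()
    if not spec.pore_specs:
        raise ValueError("pore_specs must be nonempty")
    tilts = {(t, a) for (_rd, _pd, t, a) in spec.pore_specs}
    if len(tilts) > 1:
        raise ValueError("pores sharing one volume must share tilt/azimuth")
    tilt_deg, azimuth_deg = next(iter(tilts))

    rng = np.random.default_rng(spec.seed)
    nz, ny, nx = spec.volume_shape
    vz, vy, vx = spec.voxel_size
    extent = np.array([nz * vz, ny * vy, nx * vx], dtype=np.float64)
    max_rim_extent = max(rd + pd_ for (rd, pd_, _t, _a) in spec.pore_specs)
    if max_rim_extent > min(extent):
        raise ValueError("pore larger than volume")

    # centred physical coordinates, rotated back into the envelope frame
    rot = _rotation_matrix(tilt_deg, azimuth_deg)
    inv = rot.T
    # coordinates centred on the array centre (the rotation pivot used
    # downstream), so the envelope passes exactly through it
    z_nm = ((np.arange(nz, dtype=np.float32) - (nz - 1) / 2) * vz)[:, None, None]
    y_nm = ((np.arange(ny, dtype=np.float32) - (ny - 1) / 2) * vy)[None, :, None]
    x_nm = ((np.arange(nx, dtype=np.float32) - (nx - 1) / 2) * vx)[None, None, :]
    ze = inv[0, 0] * z_nm + inv[0, 1] * y_nm + inv[0, 2] * x_nm
    ye = inv[1, 0] * z_nm + inv[1, 1] * y_nm + inv[1, 2] * x_nm
    xe = inv[2, 0] * z_nm + inv[2, 1] * y_nm + inv[2, 2] * x_nm

    # pore in-plane positions: spread along envelope x
    n_pores = len(spec.pore_specs)
    if n_pores == 1:
        offsets = [0.0]
    else:
        pitch = min(extent) / n_pores
        offsets = [(k - (n_pores - 1) / 2) * pitch for k in range(n_pores)]

    half_t = spec.membrane_thickness / 2.0
    pore_rows = []
    # distance from the midline surface; start with the parallel planes
    first_r = spec.pore_specs[0][0] / 2.0
    dist = np.abs(np.abs(ze) - first_r).astype(np.float32)
    for pid, ((rd, pd_, _t, _a), xoff) in enumerate(zip(spec.pore_specs, offsets)):
        r = rd / 2.0
        r_t = pd_ / 2.0 + r
        rho = np.sqrt((xe - xoff) ** 2 + ye ** 2)
        in_disc = rho < r_t
        torus_d = np.abs(np.sqrt((r_t - rho) ** 2 + ze ** 2) - r)
        dist = np.where(in_disc, torus_d, dist).astype(np.float32)
        center = rot @ np.array([0.0, 0.0, xoff])
        half = np.array([(nz - 1) / 2 * vz, (ny - 1) / 2 * vy, (nx - 1) / 2 * vx])
        pore_rows.append(dict(
            id=pid,
            z=center[0] + half[0], y=center[1] + half[1], x=center[2] + half[2],
            rim_diameter=rd, pore_diameter=pd_,
            tilt_deg=tilt_deg, azimuth_deg=azimuth_deg,
            sub_resolution=bool(rd < max(spec.voxel_size)),
        ))

    intensity = np.where(dist <= half_t, MEMBRANE, BACKGROUND).astype(np.float32)
    intensity = _finalize_intensity(intensity, spec, rng)

    truth = GroundTruth.empty()
    truth.pores = pd.DataFrame(pore_rows)
    return VoxelGrid(intensity, spec.voxel_size), truth
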