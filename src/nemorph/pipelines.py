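"""End-to-end study pipelines over synthetic cohorts.

These functions reproduce the full measurement chains on phantom data:
vesicle scenes run detection + sphericity filtering + sizing on the
noise-free label volume; pore cohorts run the complete clip → align →
en-face search → back-rotation → rim/pore measurement protocol on
tomogram-like renders, one phantom per pore with a random orientation.

Default problem sizes mirror the study conditions: telophase scenes at
4.5 nm voxels; pore phantoms rendered at 1.5 nm voxel pitch and binned
by 2 onto the 3 nm working grid of the rim protocol, tilts drawn
uniformly up to 40 degrees, azimuths free.
"""

from __future__ import annotations

import numpy as np

from . import pores as pores_mod
from .synthetic import SceneSpec, make_pore_volume, make_telophase_scene
from .vesicles import apply_sphericity_filter, extract_candidates, summarize_diameters

VESICLE_LABEL_ID = 2


def vesicle_recovery(
    n_vesicles: int,
    true_mean: float,
    true_sd: float,
    seed: int,
    voxel_nm: float = 4.5,
    max_axis_ratio: float = 1.5,
) -> dict:
    """Generate a telophase scene and recover the vesicle mean diameter.

    The scene volume is scaled with the vesicle count so that packing
    at the study's vicinity distances stays feasible; sizing runs on
    the noise-free label volume (phantom segmentations play the role of
    the study's manual tracing).
    """
    # scale the sheet area with the count; y accommodates the 100-1000 nm
    # vesicle placement band above the envelope
    nx = nz = int(np.ceil(np.sqrt(max(n_vesicles, 1) / 500.0)) * 400)
    ny = 260
    spec = SceneSpec(
        volume_shape=(nz, ny, nx),
        voxel_size=(voxel_nm, voxel_nm, voxel_nm),
        vesicle_count=n_vesicles,
        vesicle_diameter_mean=true_mean,
        vesicle_diameter_sd=true_sd,
        vesicle_diameter_lower=20.0,
        vesicle_distance_range=(100.0, min(1000.0, (ny - 40) * voxel_nm / 2)),
        seed=seed,
    )
    _grid, labels, truth = make_telophase_scene(spec)
    records = extract_candidates(labels, VESICLE_LABEL_ID)
    apply_sphericity_filter(records, max_axis_ratio)
    mean, sem, hist = summarize_diameters(records)
    return {
        "n_true": n_vesicles,
        "n_detected": len(records),
        "n_accepted": sum(r.accepted for r in records),
        "mean_nm": mean,
        "sem_nm": sem,
        "true_mean_nm": float(truth.vesicles["diameter"].mean()),
        "histogram": hist,
        "records": records,
    }


def measure_pore_cohort(
    n_pores: int,
    rim_diameter: float,
    pore_diameter: float,
    seed: int,
    max_tilt_deg: float = 40.0,
    render_voxel_nm: float = 1.5,
    bin_factor: int = 2,
    half_extent_nm: float = 120.0,
    noise_sd: float = 0.1,
    step_deg: float = 10.0,
) -> list[pores_mod.PoreMeasurement]:
    """Measure ``n_pores`` single-pore phantoms at random orientations.

    Each pore is rendered in its own tomogram-like volume (render pitch
    ``render_voxel_nm``), then pushed through the full clip pipeline
    binned onto the ~3 nm working grid. Pores whose geometry cannot be
    measured raise only individually; they are skipped with a count in
    the returned list's ``qc_flags`` (none expected under defaults).
    """
    rng = np.random.default_rng(seed)
    # volume must enclose the clip after arbitrary rotation
    n_side = int(2 * round(half_extent_nm / render_voxel_nm)) + 1
    out: list[pores_mod.PoreMeasurement] = []
    for pid in range(n_pores):
        tilt = float(rng.uniform(0.0, max_tilt_deg))
        azim = float(rng.uniform(0.0, 360.0))
        spec = SceneSpec(
            volume_shape=(n_side, n_side, n_side),
            voxel_size=(render_voxel_nm,) * 3,
            pore_specs=[(rim_diameter, pore_diameter, tilt, azim)],
            noise_sd=noise_sd,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        volume, truth = make_pore_volume(spec)
        center = tuple(truth.pores.loc[0, ["z", "y", "x"]].astype(float))
        clip = pores_mod.extract_clip(
            volume, center, half_extent_nm, bin_factor=bin_factor
        )
        clip = pores_mod.align_envelope_to_x(clip)
        angle, _ = pores_mod.find_en_face_angle(clip, step_deg=step_deg)
        perp = pores_mod.to_perpendicular_view(clip, angle)
        m = pores_mod.measure_rim_and_pore(perp, pore_id=pid, en_face_angle=angle)
        m.qc_flags.append(f"true_tilt={tilt:.1f}")
        out.append(m)
    return out


def cohort_kappas(measurements: list[pores_mod.PoreMeasurement], per_pore_average: bool = False) -> np.ndarray:
    """Curvature sample from a cohort: two rim sides per pore by default."""
    if per_pore_average:
        return np.array([(m.kappa_i + m.kappa_ii) / 2.0 for m in measurements])
    return np.array(
        [k for m in measurements for k in (m.kappa_i, m.kappa_ii)]
    )
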