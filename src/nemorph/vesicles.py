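"""Vesicle identification and diameter measurement from label volumes.

Vesicles were defined operationally in the source segmentations as
circular membrane structures with similar x, y and z diameter; here the
criterion is quantified as a maximum ratio between the largest and
smallest physical bounding-box extents of each 3D connected component
(default 1.5). Components failing it are retained in the output with
``accepted=False`` so the filter is auditable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .core import LabelVolume, ResultTable

DEFAULT_MAX_AXIS_RATIO = 1.5
HISTOGRAM_BIN_NM = 5.0


@dataclass
class VesicleRecord:
    """One vesicle candidate (a 3D connected component of the vesicle label)."""

    id: int
    centroid: tuple[float, float, float]  # (z, y, x) nm
    axis_extents: tuple[float, float, float]  # (dz, dy, dx) nm
    diameter: float  # mean of the three axis extents, nm
    equivalent_diameter: float  # sphere of equal labelled volume, nm
    voxel_count: int
    accepted: bool = True
    reject_reason: str = ""


def extract_candidates(labels: LabelVolume, vesicle_label: int) -> list[VesicleRecord]:
    """One record per 26-connected component carrying ``vesicle_label``.

    Axis extents are physical bounding-box sizes (voxel span x pitch);
    centroids are physical centres of mass. An absent label yields an
    empty list.
    """
    mask = labels.labels == vesicle_label
    if not mask.any():
        return []
    structure = np.ones((3, 3, 3), dtype=bool)  # 26-connectivity
    comp, n = ndimage.label(mask, structure=structure)
    objects = ndimage.find_objects(comp)
    centroids = ndimage.center_of_mass(mask, comp, index=range(1, n + 1))
    vsize = np.asarray(labels.voxel_size)
    voxvol = float(np.prod(vsize))
    records = []
    for i, (sl, com) in enumerate(zip(objects, centroids)):
        extents = tuple(
            float((s.stop - s.start) * v) for s, v in zip(sl, vsize)
        )
        count = int((comp[sl] == i + 1).sum())
        eq_d = float(2.0 * (3.0 * count * voxvol / (4.0 * np.pi)) ** (1.0 / 3.0))
        records.append(
            VesicleRecord(
                id=i,
                centroid=tuple(float(c * v) for c, v in zip(com, vsize)),
                axis_extents=extents,
                diameter=float(np.mean(extents)),
                equivalent_diameter=eq_d,
                voxel_count=count,
            )
        )
    return records


def apply_sphericity_filter(
    records: list[VesicleRecord],
    max_axis_ratio: float = DEFAULT_MAX_AXIS_RATIO,
    ignore_z_axis: bool = False,
) -> list[VesicleRecord]:
    """Set ``accepted`` by the axis-extent ratio criterion (in place).

    ``ignore_z_axis`` drops the z extent from the test, for section
    stacks whose z pitch exceeds the object size (a ~57 nm vesicle spans
    a single 50-70 nm section, making its z extent uninformative).
    """
    if max_axis_ratio < 1:
        raise ValueError("max_axis_ratio must be >= 1")
    for rec in records:
        ext = rec.axis_extents[1:] if ignore_z_axis else rec.axis_extents
        ratio = max(ext) / min(ext)
        if ratio <= max_axis_ratio:
            rec.accepted = True
            rec.reject_reason = ""
        else:
            rec.accepted = False
            rec.reject_reason = "tubule-like"
    return records


def summarize_diameters(
    records: list[VesicleRecord], bin_nm: float = HISTOGRAM_BIN_NM
) -> tuple[float, float, pd.DataFrame]:
    """Mean diameter, SEM and a fixed-width histogram of accepted vesicles.

    With a single accepted vesicle the SEM is undefined and reported as
    0.0 (the caller can detect this from n=1 in the histogram total).
    """
    diam = np.array([r.diameter for r in records if r.accepted])
    if diam.size == 0:
        raise ValueError("no accepted vesicle records to summarize")
    mean = float(diam.mean())
    sem = float(diam.std(ddof=1) / np.sqrt(diam.size)) if diam.size > 1 else 0.0
    lo = np.floor(diam.min() / bin_nm) * bin_nm
    hi = np.ceil(diam.max() / bin_nm) * bin_nm
    edges = np.arange(lo, max(hi, lo + bin_nm) + 0.5 * bin_nm, bin_nm)
    counts, edges = np.histogram(diam, bins=edges)
    hist = pd.DataFrame(
        {"bin_low_nm": edges[:-1], "bin_high_nm": edges[1:], "count": counts}
    )
    return mean, sem, hist


def records_to_table(records: list[VesicleRecord]) -> ResultTable:
    rows = [
        dict(
            id=r.id,
            z_nm=r.centroid[0], y_nm=r.centroid[1], x_nm=r.centroid[2],
            dz_nm=r.axis_extents[0], dy_nm=r.axis_extents[1], dx_nm=r.axis_extents[2],
            diameter_nm=r.diameter,
            equivalent_diameter_nm=r.equivalent_diameter,
            voxel_count=r.voxel_count,
            accepted=r.accepted,
            reject_reason=r.reject_reason,
        )
        for r in records
    ]
    frame = pd.DataFrame(rows)
    units = {c: "nm" for c in frame.columns if c.endswith("_nm")}
    return ResultTable(frame, units)


def measure_scene(
    labels: LabelVolume,
    vesicle_label: int = 2,
    max_axis_ratio: float = DEFAULT_MAX_AXIS_RATIO,
    ignore_z_axis: bool = False,
) -> tuple[list[VesicleRecord], float, float]:
    """Full detection + sizing pipeline; returns (records, mean, sem)."""
    records = extract_candidates(labels, vesicle_label)
    apply_sphericity_filter(records, max_axis_ratio, ignore_z_axis)
    mean, sem, _ = summarize_diameters(records)
    return records, mean, sem
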