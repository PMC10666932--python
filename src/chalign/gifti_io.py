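"""GIFTI interop for meshes, masks, per-vertex maps, and data series.

GIFTI is the boundary format for real preprocessed surface data (e.g.,
template-registered spheres and per-vertex functional series); everything
internal lives in the HDF5 cohort container.  Real registration spheres are
rescaled to the nominal radius on load so mm searchlight radii behave as on
a real cortex.
"""

from __future__ import annotations

import numpy as np
import nibabel as nib
from nibabel import gifti

from .connectivity import TimeSeries
from .glm import ContrastMap
from .surface import SurfaceMesh


def export_mesh(path, mesh: SurfaceMesh) -> None:
    """Write coordinates + topology as a GIFTI surface file."""
    img = gifti.GiftiImage(
        darrays=[
            gifti.GiftiDataArray(
                mesh.coords.astype(np.float32), intent="NIFTI_INTENT_POINTSET"
            ),
            gifti.GiftiDataArray(
                mesh.faces.astype(np.int32), intent="NIFTI_INTENT_TRIANGLE"
            ),
        ]
    )
    img.meta["hemisphere"] = mesh.hemisphere
    img.meta["subdivision_order"] = str(mesh.subdivision_order)
    img.meta["nominal_radius_mm"] = str(mesh.nominal_radius_mm)
    nib.save(img, str(path))


def import_mesh(
    path, hemisphere: str | None = None, nominal_radius_mm: float = 100.0
) -> SurfaceMesh:
    """Read a GIFTI surface; vertices are rescaled onto the nominal sphere."""
    img = nib.load(str(path))
    coords = faces = None
    for da in img.darrays:
        if da.intent == nib.nifti1.intent_codes["NIFTI_INTENT_POINTSET"]:
            coords = np.asarray(da.data, dtype=float)
        elif da.intent == nib.nifti1.intent_codes["NIFTI_INTENT_TRIANGLE"]:
            faces = np.asarray(da.data, dtype=np.int64)
    if coords is None or faces is None:
        raise ValueError(f"{path}: GIFTI surface needs POINTSET and TRIANGLE arrays")
    if faces.min() < 0 or faces.max() >= len(coords):
        raise ValueError(f"{path}: triangle indices out of vertex range")
    meta = dict(img.meta)
    hemisphere = hemisphere or meta.get("hemisphere", "left")
    order = int(meta.get("subdivision_order", round(np.log((len(coords) - 2) / 10) / np.log(4))))
    radii = np.linalg.norm(coords, axis=1)
    coords = coords / radii[:, None] * nominal_radius_mm
    return SurfaceMesh(
        coords=coords,
        faces=faces,
        hemisphere=hemisphere,
        subdivision_order=order,
        nominal_radius_mm=nominal_radius_mm,
    )


def export_mask(path, mesh: SurfaceMesh) -> None:
    """Write the cortex mask as a GIFTI shape file (1 = cortical)."""
    img = gifti.GiftiImage(
        darrays=[
            gifti.GiftiDataArray(
                mesh.cortex_mask.astype(np.float32), intent="NIFTI_INTENT_SHAPE"
            )
        ]
    )
    nib.save(img, str(path))


def import_mask(path, n_vertices: int | None = None) -> np.ndarray:
    """Read a per-vertex 0/1 mask from GIFTI or a one-column text file."""
    path = str(path)
    if path.endswith(".gii"):
        img = nib.load(path)
        mask = np.asarray(img.darrays[0].data) != 0
    else:
        mask = np.loadtxt(path) != 0
    if n_vertices is not None and len(mask) != n_vertices:
        raise ValueError(f"mask has {len(mask)} vertices, mesh has {n_vertices}")
    return mask


def export_map(path, cmap: ContrastMap) -> None:
    """Write a contrast map as a single GIFTI per-vertex data array."""
    img = gifti.GiftiImage(
        darrays=[gifti.GiftiDataArray(cmap.values.astype(np.float32), intent="NIFTI_INTENT_NONE")]
    )
    img.meta["subject_id"] = cmap.subject_id
    img.meta["category"] = cmap.category
    img.meta["provenance"] = cmap.provenance
    img.meta["source_description"] = cmap.source_description
    nib.save(img, str(path))


def import_map(path, n_vertices: int | None = None) -> ContrastMap:
    img = nib.load(str(path))
    values = np.asarray(img.darrays[0].data, dtype=float)
    if n_vertices is not None and len(values) != n_vertices:
        raise ValueError(f"map has {len(values)} vertices, mesh has {n_vertices}")
    meta = dict(img.meta)
    return ContrastMap(
        subject_id=meta.get("subject_id", ""),
        category=meta.get("category", ""),
        values=values,
        provenance=meta.get("provenance", "own"),
        source_description=meta.get("source_description", ""),
    )


def export_timeseries(path, ts: TimeSeries) -> None:
    """Write a data series: one GIFTI darray per timepoint, run boundaries in metadata."""
    darrays = [
        gifti.GiftiDataArray(row.astype(np.float32), intent="NIFTI_INTENT_TIME_SERIES")
        for row in ts.data
    ]
    img = gifti.GiftiImage(darrays=darrays)
    img.meta["subject_id"] = ts.subject_id
    img.meta["condition_id"] = ts.condition_id
    img.meta["tr_s"] = str(ts.tr_s)
    img.meta["zscored"] = str(int(ts.zscored))
    img.meta["run_table"] = ";".join(f"{rid}:{n}" for rid, n in ts.run_table)
    nib.save(img, str(path))


def import_timeseries(path, n_vertices: int | None = None) -> TimeSeries:
    img = nib.load(str(path))
    data = np.vstack([np.asarray(da.data, dtype=float) for da in img.darrays])
    if n_vertices is not None and data.shape[1] != n_vertices:
        raise ValueError(f"series has {data.shape[1]} vertices, mesh has {n_vertices}")
    meta = dict(img.meta)
    run_table = [
        (part.split(":")[0], int(part.split(":")[1]))
        for part in meta["run_table"].split(";")
    ]
    return TimeSeries(
        subject_id=meta.get("subject_id", ""),
        condition_id=meta.get("condition_id", ""),
        run_table=run_table,
        data=data,
        tr_s=float(meta.get("tr_s", 2.0)),
        zscored=bool(int(meta.get("zscored", "0"))),
    )
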