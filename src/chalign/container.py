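"""Single-file HDF5 container for cohorts, transforms, and maps.

Layout::

    /mesh/{left,right}            coords, faces, mask (+ mesh attrs)
    /template                     loadings, tuning (+ categories, seed)
    /ground_truth/<sub>/<hemi>    rotation triplets + patch labels
    /subjects/<sub>/movie/<id>/run<k>
    /subjects/<sub>/localizer/run<k>
    /design                       localizer design + HRF (JSON attrs)
    /transforms/<src>_to_<tgt>/<hemi>/step<k>   sparse triplets + attrs
    /maps/<sub>/<category>/<provenance>
    /manifest                     generation parameters (JSON)

All arrays round-trip bitwise; sparse transforms round-trip as exact
(row, col, value) triplet sets.
"""

from __future__ import annotations

import json
from dataclasses import asdict

import h5py
import numpy as np
import scipy.sparse as sp

from .alignment import (
    AlignmentSchedule,
    ScheduleStep,
    TransformationMatrix,
    TransformChain,
    TransformStep,
)
from .connectivity import TimeSeries
from .glm import Block, HRFSpec, LocalizerDesign
from .surface import FULL, SurfaceMesh
from .synthetic import CohortBundle, CohortSpec, SubjectGroundTruth, TemplateModel


class ContainerSchemaError(RuntimeError):
    """The container is missing a required group or carries inconsistent arrays."""


def _require(handle, name: str):
    if name not in handle:
        raise ContainerSchemaError(f"container is missing required group '{name}'")
    return handle[name]


# ---------------------------------------------------------------------------
# meshes

def _write_mesh(group: h5py.Group, mesh: SurfaceMesh) -> None:
    group.create_dataset("coords", data=mesh.coords)
    group.create_dataset("faces", data=mesh.faces)
    group.create_dataset("mask", data=mesh.cortex_mask)
    group.attrs["hemisphere"] = mesh.hemisphere
    group.attrs["subdivision_order"] = mesh.subdivision_order
    group.attrs["nominal_radius_mm"] = mesh.nominal_radius_mm


def _read_mesh(group: h5py.Group) -> SurfaceMesh:
    return SurfaceMesh(
        coords=group["coords"][()],
        faces=group["faces"][()],
        hemisphere=str(group.attrs["hemisphere"]),
        subdivision_order=int(group.attrs["subdivision_order"]),
        nominal_radius_mm=float(group.attrs["nominal_radius_mm"]),
        cortex_mask=group["mask"][()],
    )


# ---------------------------------------------------------------------------
# time series

def _write_timeseries(group: h5py.Group, ts: TimeSeries) -> None:
    group.attrs["subject_id"] = ts.subject_id
    group.attrs["condition_id"] = ts.condition_id
    group.attrs["tr_s"] = ts.tr_s
    group.attrs["zscored"] = ts.zscored
    for (run_id, n), (_, sl) in zip(ts.run_table, ts.run_slices()):
        d = group.create_dataset(run_id, data=ts.data[sl])
        d.attrs["n_timepoints"] = n


def _read_timeseries(group: h5py.Group) -> TimeSeries:
    run_ids = sorted(group.keys(), key=lambda r: (len(r), r))
    blocks, run_table = [], []
    for run_id in run_ids:
        arr = group[run_id][()]
        blocks.append(arr)
        run_table.append((run_id, int(group[run_id].attrs["n_timepoints"])))
    return TimeSeries(
        subject_id=str(group.attrs["subject_id"]),
        condition_id=str(group.attrs["condition_id"]),
        run_table=run_table,
        data=np.vstack(blocks),
        tr_s=float(group.attrs["tr_s"]),
        zscored=bool(group.attrs["zscored"]),
    )


# ---------------------------------------------------------------------------
# design

def _design_to_json(design: LocalizerDesign) -> str:
    return json.dumps(
        {
            "categories": design.categories,
            "tr_s": design.tr_s,
            "n_timepoints": design.n_timepoints,
            "include_in_baseline": design.include_in_baseline,
            "runs": [
                [[b.category, b.onset_s, b.duration_s] for b in blocks]
                for blocks in design.runs
            ],
        }
    )


def _design_from_json(payload: str) -> LocalizerDesign:
    d = json.loads(payload)
    return LocalizerDesign(
        categories=d["categories"],
        runs=[[Block(c, o, dur) for c, o, dur in blocks] for blocks in d["runs"]],
        tr_s=d["tr_s"],
        n_timepoints=d["n_timepoints"],
        include_in_baseline=d.get("include_in_baseline", {}),
    )


# ---------------------------------------------------------------------------
# sparse transforms

def _write_sparse(group: h5py.Group, mat: sp.spmatrix) -> None:
    coo = mat.tocoo()
    group.create_dataset("row", data=coo.row)
    group.create_dataset("col", data=coo.col)
    group.create_dataset("value", data=coo.data)
    group.attrs["shape"] = coo.shape


def _read_sparse(group: h5py.Group) -> sp.csr_matrix:
    shape = tuple(group.attrs["shape"])
    return sp.coo_matrix(
        (group["value"][()], (group["row"][()], group["col"][()])), shape=shape
    ).tocsr()


def _schedule_to_json(schedule: AlignmentSchedule) -> str:
    return json.dumps(
        [
            [s.grid_order if s.grid_order == FULL else int(s.grid_order),
             s.averaging_radius_mm, s.alignment_radius_mm]
            for s in schedule.steps
        ]
    )


def _schedule_from_json(payload: str) -> AlignmentSchedule:
    steps = [
        ScheduleStep(g if g == FULL else int(g), avg, align)
        for g, avg, align in json.loads(payload)
    ]
    return AlignmentSchedule(steps=steps)


def write_transform_chain(handle: h5py.File, chain: TransformChain) -> None:
    """Store one directed pair's chain under /transforms/<src>_to_<tgt>."""
    name = f"transforms/{chain.source_subject}_to_{chain.target_subject}"
    if name in handle:
        del handle[name]
    pair = handle.create_group(name)
    pair.attrs["schedule"] = _schedule_to_json(chain.schedule)
    pair.attrs["source_subject"] = chain.source_subject
    pair.attrs["target_subject"] = chain.target_subject
    for step in chain.steps:
        for tm in step:
            g = pair.create_group(f"{tm.hemisphere}/step{step.step}")
            _write_sparse(g, tm.values)
            g.attrs["method"] = tm.method
            g.attrs["step"] = tm.step
            g.attrs["alignment_radius_mm"] = tm.alignment_radius_mm


def read_transform_chains(handle: h5py.File) -> dict:
    """All stored chains as ``{target: {source: TransformChain}}``."""
    root = _require(handle, "transforms")
    chains: dict = {}
    for pair_name in root:
        pair = root[pair_name]
        source = str(pair.attrs["source_subject"])
        target = str(pair.attrs["target_subject"])
        schedule = _schedule_from_json(pair.attrs["schedule"])
        step_ids = sorted(
            int(k[4:]) for k in pair["left"].keys() if k.startswith("step")
        )
        steps = []
        for k in step_ids:
            tms = {}
            for hemi in ("left", "right"):
                g = _require(pair, f"{hemi}/step{k}")
                tms[hemi] = TransformationMatrix(
                    source_subject=source,
                    target_subject=target,
                    hemisphere=hemi,
                    values=_read_sparse(g),
                    method=str(g.attrs["method"]),
                    step=int(g.attrs["step"]),
                    alignment_radius_mm=float(g.attrs["alignment_radius_mm"]),
                )
            steps.append(TransformStep(left=tms["left"], right=tms["right"], step=k))
        chains.setdefault(target, {})[source] = TransformChain(
            steps=steps,
            schedule=schedule,
            source_subject=source,
            target_subject=target,
        )
    return chains


# ---------------------------------------------------------------------------
# contrast maps

def write_map(handle: h5py.File, cmap) -> None:
    name = f"maps/{cmap.subject_id}/{cmap.category}/{cmap.provenance}"
    if name in handle:
        del handle[name]
    d = handle.create_dataset(name, data=cmap.values)
    d.attrs["source_description"] = cmap.source_description


def read_maps(handle: h5py.File) -> dict:
    """All stored maps as ``{(subject, category, provenance): ContrastMap}``."""
    from .glm import ContrastMap

    out = {}
    root = _require(handle, "maps")
    for sub in root:
        for cat in root[sub]:
            for prov in root[sub][cat]:
                d = root[sub][cat][prov]
                out[(sub, cat, prov)] = ContrastMap(
                    subject_id=sub,
                    category=cat,
                    values=d[()],
                    provenance=prov,
                    source_description=str(d.attrs["source_description"]),
                )
    return out


# ---------------------------------------------------------------------------
# cohorts

def write_cohort(path, cohort: CohortBundle, mode: str = "w") -> None:
    """Write a full cohort bundle (meshes, ground truth, data, design, manifest)."""
    with h5py.File(path, mode) as f:
        mesh_root = f.create_group("mesh")
        _write_mesh(mesh_root.create_group("left"), cohort.template.left_mesh)
        _write_mesh(mesh_root.create_group("right"), cohort.template.right_mesh)

        tpl = f.create_group("template")
        tpl.create_dataset("loadings", data=cohort.template.loadings)
        tpl.create_dataset("tuning", data=cohort.template.tuning)
        tpl.attrs["categories"] = json.dumps(cohort.template.categories)
        tpl.attrs["bump_width_mm"] = cohort.template.bump_width_mm
        tpl.attrs["seed"] = cohort.template.seed

        for subj in cohort.subjects:
            g = f.create_group(f"ground_truth/{subj.subject_id}")
            g.attrs["patch_order"] = subj.patch_order
            g.attrs["movie_noise_sd"] = subj.movie_noise_sd
            g.attrs["localizer_noise_sd"] = subj.localizer_noise_sd
            g.attrs["seed"] = subj.seed
            for hemi in ("left", "right"):
                hg = g.create_group(hemi)
                hg.create_dataset("patch_labels", data=subj.patch_labels[hemi])
                _write_sparse(hg.create_group("rotation"), subj.rotations[hemi])

        for (sid, movie_id), ts in cohort.movies.items():
            _write_timeseries(f.create_group(f"subjects/{sid}/movie/{movie_id}"), ts)
        for sid, runs in cohort.localizers.items():
            for k, run_ts in enumerate(runs):
                g = f.create_group(f"subjects/{sid}/localizer/run{k + 1}")
                _write_timeseries(g, run_ts)

        dg = f.create_group("design")
        dg.attrs["design"] = _design_to_json(cohort.design)
        dg.attrs["hrf"] = json.dumps(asdict(cohort.hrf))

        f.create_dataset("manifest", data=cohort.manifest_json())


def read_cohort(path) -> CohortBundle:
    """Read a cohort bundle back; arrays are bitwise what was written."""
    with h5py.File(path, "r") as f:
        mesh_root = _require(f, "mesh")
        left = _read_mesh(_require(mesh_root, "left"))
        right = _read_mesh(_require(mesh_root, "right"))

        tpl = _require(f, "template")
        template = TemplateModel(
            left_mesh=left,
            right_mesh=right,
            loadings=tpl["loadings"][()],
            tuning=tpl["tuning"][()],
            categories=json.loads(tpl.attrs["categories"]),
            bump_width_mm=float(tpl.attrs["bump_width_mm"]),
            seed=int(tpl.attrs["seed"]),
        )

        subjects = []
        gt_root = _require(f, "ground_truth")
        for sid in sorted(gt_root.keys()):
            g = gt_root[sid]
            subjects.append(
                SubjectGroundTruth(
                    subject_id=sid,
                    patch_order=int(g.attrs["patch_order"]),
                    patch_labels={h: g[h]["patch_labels"][()] for h in ("left", "right")},
                    rotations={h: _read_sparse(g[h]["rotation"]) for h in ("left", "right")},
                    movie_noise_sd=float(g.attrs["movie_noise_sd"]),
                    localizer_noise_sd=float(g.attrs["localizer_noise_sd"]),
                    seed=int(g.attrs["seed"]),
                )
            )

        movies, localizers = {}, {}
        sub_root = _require(f, "subjects")
        for sid in sorted(sub_root.keys()):
            if "movie" in sub_root[sid]:
                for movie_id in sub_root[sid]["movie"]:
                    movies[(sid, movie_id)] = _read_timeseries(
                        sub_root[sid][f"movie/{movie_id}"]
                    )
            if "localizer" in sub_root[sid]:
                runs = sorted(sub_root[sid]["localizer"].keys(), key=lambda r: (len(r), r))
                localizers[sid] = [
                    _read_timeseries(sub_root[sid][f"localizer/{r}"]) for r in runs
                ]

        dg = _require(f, "design")
        design = _design_from_json(dg.attrs["design"])
        hrf = HRFSpec(**json.loads(dg.attrs["hrf"]))

        manifest = json.loads(f["manifest"][()])
        spec_dict = dict(manifest["spec"])
        spec_dict["categories"] = tuple(spec_dict["categories"])
        spec_dict["movie_ids"] = tuple(spec_dict["movie_ids"])
        spec = CohortSpec(**spec_dict)

        n_total = left.n_vertices + right.n_vertices
        for key, ts in movies.items():
            if ts.n_vertices != n_total:
                raise ContainerSchemaError(
                    f"group 'subjects/{key[0]}/movie/{key[1]}' has {ts.n_vertices} "
                    f"vertices but /mesh implies {n_total}"
                )

    return CohortBundle(
        template=template,
        subjects=subjects,
        movies=movies,
        localizers=localizers,
        design=design,
        hrf=hrf,
        spec=spec,
        master_seed=int(manifest["master_seed"]),
    )
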