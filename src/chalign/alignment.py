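"""Searchlight Procrustes hyperalignment: pairwise, directional, coarse-to-fine.

For every geodesic searchlight, the source subject's connectivity profile
rows (CHA) or stimulus-locked response pattern rows (RHA) are rotated onto
the target subject's rows by the orthogonal Procrustes solution.  The
searchlight rotations are summed block-wise into one sparse vertex-space
transformation per hemisphere; the per-vertex scale this introduces is
absorbed by run-wise re-z-scoring of transformed data.  No common model
space is ever built: each transform maps one subject's cortex directly into
another's.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .connectivity import ConnectivityProfile, TimeSeries, connectivity_profile, zscore_runs
from .surface import FULL, SearchlightSet, SurfaceMesh, TargetGrid, build_searchlight_set, build_target_grid

HEMIS = ("left", "right")


# ---------------------------------------------------------------------------
# schedules

@dataclass(frozen=True)
class ScheduleStep:
    """One iterative step: target grid order, averaging radius, alignment radius."""

    grid_order: object  # int or FULL
    averaging_radius_mm: float | None
    alignment_radius_mm: float = 15.0


@dataclass
class AlignmentSchedule:
    """Ordered coarse-to-fine schedule of connectivity-target definitions."""

    steps: list

    def __post_init__(self):
        if len(self.steps) == 0:
            raise ValueError("an alignment schedule needs at least one step")

    def __len__(self) -> int:
        return len(self.steps)

    @classmethod
    def standard(cls) -> "AlignmentSchedule":
        """The six-step full-resolution schedule for order-5 hemisphere meshes.

        Steps 1-3 use the order-3 coarse grid (642 vertices per hemisphere
        before masking) with 13 mm averaging searchlights, steps 4-5 the
        order-4 grid (2562 per hemisphere) with 7 mm searchlights, and step 6
        every cortical vertex as its own target.  Alignment searchlights are
        15 mm throughout.
        """
        return cls(
            steps=[ScheduleStep(3, 13.0, 15.0)] * 3
            + [ScheduleStep(4, 7.0, 15.0)] * 2
            + [ScheduleStep(FULL, None, 15.0)]
        )

    @classmethod
    def synthetic_default(cls) -> "AlignmentSchedule":
        """Three-step coarse-to-fine schedule for order-3 synthetic meshes.

        Two subdivision octaves below the full-resolution schedule, keeping
        its averaging-radius-to-grid-spacing ratio (radius about equal to the
        inter-target spacing: order-1 grid / 55 mm, order-2 grid / 27 mm) and
        the fixed 15 mm alignment searchlights.
        """
        return cls(
            steps=[
                ScheduleStep(1, 55.0, 15.0),
                ScheduleStep(2, 27.0, 15.0),
                ScheduleStep(FULL, None, 15.0),
            ]
        )


# ---------------------------------------------------------------------------
# transforms

@dataclass
class TransformationMatrix:
    """Sparse vertex-space map for one hemisphere of one directed subject pair.

    Rows index the target subject's vertex space, columns the source
    subject's; nonzeros occur only where two vertices co-occur in some
    alignment searchlight.
    """

    source_subject: str
    target_subject: str
    hemisphere: str
    values: sp.csr_matrix
    method: str = "CHA"  # CHA or RHA
    step: int = 1
    alignment_radius_mm: float = 15.0


@dataclass
class TransformStep:
    """Both hemispheres' transformation matrices for one iterative step."""

    left: TransformationMatrix
    right: TransformationMatrix
    step: int = 1

    def __iter__(self):
        return iter((self.left, self.right))


@dataclass
class TransformChain:
    """Ordered per-step transforms of one directed subject pair (step 1 first)."""

    steps: list  # [TransformStep, ...]
    schedule: AlignmentSchedule
    source_subject: str
    target_subject: str

    def __post_init__(self):
        ks = [s.step for s in self.steps]
        if ks != sorted(set(ks)):
            raise ValueError("chain steps must be strictly increasing")

    def __len__(self) -> int:
        return len(self.steps)

    def prefix(self, n_steps: int) -> "TransformChain":
        """The chain truncated to its first ``n_steps`` steps."""
        return TransformChain(
            steps=self.steps[:n_steps],
            schedule=AlignmentSchedule(steps=self.schedule.steps[:n_steps]),
            source_subject=self.source_subject,
            target_subject=self.target_subject,
        )


def identity_chain(subject: str, target: str, mesh_pair) -> TransformChain:
    """An anatomical-alignment (AA) chain: identity transform on the template mesh."""
    left_mesh, right_mesh = mesh_pair
    tms = {}
    for hemi, mesh in zip(HEMIS, (left_mesh, right_mesh)):
        tms[hemi] = TransformationMatrix(
            source_subject=subject,
            target_subject=target,
            hemisphere=hemi,
            values=sp.identity(mesh.n_vertices, format="csr"),
            method="AA",
        )
    step = TransformStep(left=tms["left"], right=tms["right"], step=1)
    return TransformChain(
        steps=[step],
        schedule=AlignmentSchedule(steps=[ScheduleStep(FULL, None, 0.0)]),
        source_subject=subject,
        target_subject=target,
    )


# ---------------------------------------------------------------------------
# core operations

def orthogonal_procrustes(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Orthogonal matrix R minimizing ||R A - B||_F, from the SVD of B Aᵀ.

    Rows of ``A`` and ``B`` are the same anatomical vertices in the source
    and target subject; columns are shared features (connectivity targets,
    or timepoints for RHA).  Reflections are permitted; rank-deficient
    ``B Aᵀ`` still attains the minimum for any valid SVD.
    """
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    if A.shape != B.shape:
        raise ValueError(f"shape mismatch: {A.shape} vs {B.shape}")
    if A.ndim != 2 or A.shape[0] < 1 or A.shape[1] < 1:
        raise ValueError("inputs must be non-empty 2-D matrices")
    if not (np.isfinite(A).all() and np.isfinite(B).all()):
        raise ValueError("non-finite values in Procrustes input")
    U, _, Vt = np.linalg.svd(B @ A.T)
    return U @ Vt


def _aggregate_searchlight_blocks(
    source_rows: np.ndarray,
    target_rows: np.ndarray,
    searchlights: SearchlightSet,
    n_vertices: int,
) -> sp.csr_matrix:
    """Sum per-searchlight Procrustes rotations into one sparse vertex map.

    ``source_rows``/``target_rows`` are (n_vertices, n_features) with rows
    addressed by hemisphere-local vertex index (masked rows unused).
    """
    rows, cols, vals = [], [], []
    n_used = 0
    for members in searchlights.members:
        if len(members) == 0:
            warnings.warn("skipping empty searchlight", stacklevel=2)
            continue
        R = orthogonal_procrustes(source_rows[members], target_rows[members])
        grid_r, grid_c = np.meshgrid(members, members, indexing="ij")
        rows.append(grid_r.ravel())
        cols.append(grid_c.ravel())
        vals.append(R.ravel())
        n_used += 1
    if n_used == 0:
        raise ValueError("all alignment searchlights were empty")
    mat = sp.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n_vertices, n_vertices),
    )
    return mat.tocsr()


def fit_searchlight_transform(
    source_profile: ConnectivityProfile,
    target_profile: ConnectivityProfile,
    searchlights: SearchlightSet,
    n_vertices: int,
    step: int = 1,
) -> TransformationMatrix:
    """Fit one hemisphere's CHA transform from two subjects' connectivity profiles."""
    if source_profile.values.shape != target_profile.values.shape:
        raise ValueError("source and target profiles must share seed and target spaces")
    if source_profile.hemisphere != target_profile.hemisphere:
        raise ValueError("profiles are from different hemispheres")
    src = np.zeros((n_vertices, source_profile.values.shape[1]))
    tgt = np.zeros_like(src)
    src[source_profile.seed_indices] = source_profile.values
    tgt[target_profile.seed_indices] = target_profile.values
    values = _aggregate_searchlight_blocks(src, tgt, searchlights, n_vertices)
    return TransformationMatrix(
        source_subject=source_profile.subject_id,
        target_subject=target_profile.subject_id,
        hemisphere=source_profile.hemisphere,
        values=values,
        method="CHA",
        step=step,
        alignment_radius_mm=searchlights.radius_mm,
    )


def fit_rha_transform(
    source_ts: TimeSeries,
    target_ts: TimeSeries,
    searchlights: SearchlightSet,
    mesh_pair,
    hemisphere: str,
) -> TransformationMatrix:
    """Fit one hemisphere's RHA transform from time-locked response patterns.

    Both subjects must have watched the same stimulus: run lengths are
    checked, because response hyperalignment matches patterns timepoint by
    timepoint.
    """
    src_lens = [n for _, n in source_ts.run_table]
    tgt_lens = [n for _, n in target_ts.run_table]
    if src_lens != tgt_lens:
        raise ValueError(
            "RHA requires responses to the same stimulus: run lengths "
            f"{src_lens} vs {tgt_lens} differ"
        )
    left_mesh, right_mesh = mesh_pair
    mesh = {"left": left_mesh, "right": right_mesh}[hemisphere]
    offset = 0 if hemisphere == "left" else left_mesh.n_vertices
    if not source_ts.zscored:
        source_ts = zscore_runs(source_ts)
    if not target_ts.zscored:
        target_ts = zscore_runs(target_ts)
    src = source_ts.data[:, offset : offset + mesh.n_vertices].T  # vertices x time
    tgt = target_ts.data[:, offset : offset + mesh.n_vertices].T
    values = _aggregate_searchlight_blocks(src, tgt, searchlights, mesh.n_vertices)
    return TransformationMatrix(
        source_subject=source_ts.subject_id,
        target_subject=target_ts.subject_id,
        hemisphere=hemisphere,
        values=values,
        method="RHA",
        step=1,
        alignment_radius_mm=searchlights.radius_mm,
    )


def apply_transform(step: TransformStep, ts: TimeSeries, mesh_pair) -> TimeSeries:
    """Project a time series through one step's transforms and re-z-score.

    Each timepoint's vertex pattern is left-multiplied by the hemisphere's
    sparse matrix; both hemispheres are transformed independently and the
    result is run-wise z-scored (which absorbs the block-sum scale).
    """
    left_mesh, right_mesh = mesh_pair
    if ts.n_vertices != left_mesh.n_vertices + right_mesh.n_vertices:
        raise ValueError("time series vertex count does not match the mesh pair")
    if not ts.zscored:
        ts = zscore_runs(ts)
    nl = left_mesh.n_vertices
    out = np.empty_like(ts.data)
    for tm, sl in ((step.left, slice(0, nl)), (step.right, slice(nl, ts.n_vertices))):
        n = sl.stop - sl.start
        if tm.values.shape != (n, n):
            raise ValueError(
                f"{tm.hemisphere} transform is {tm.values.shape}, expected {(n, n)}"
            )
        out[:, sl] = ts.data[:, sl] @ tm.values.T
    annotated = f"{step.left.source_subject}->{step.left.target_subject}"
    result = TimeSeries(
        subject_id=annotated,
        condition_id=ts.condition_id,
        run_table=list(ts.run_table),
        data=out,
        tr_s=ts.tr_s,
        zscored=False,
        degenerate=ts.degenerate.copy(),
    )
    return zscore_runs(result)


def apply_chain(chain: TransformChain, ts: TimeSeries, mesh_pair) -> TimeSeries:
    """Apply a chain's steps in order, re-z-scoring runs between steps.

    The composition is the ordered chain with interleaved z-scoring, not one
    collapsed matrix product (see :func:`collapse_chain`).
    """
    if not ts.zscored:
        ts = zscore_runs(ts)
    if len(chain) == 0:
        warnings.warn("empty transform chain: returning z-scored input", stacklevel=2)
        return ts
    for step in chain.steps:
        ts = apply_transform(step, ts, mesh_pair)
    return ts


def collapse_chain(chain: TransformChain, hemisphere: str) -> sp.csr_matrix:
    """Single matrix product M_S ... M_1 for inspection only.

    Approximate: the canonical composition interleaves run-wise z-scoring
    between steps, which a plain product cannot represent.
    """
    mats = [getattr(s, hemisphere).values for s in chain.steps]
    out = mats[0]
    for m in mats[1:]:
        out = m @ out
    return out.tocsr()


# ---------------------------------------------------------------------------
# iterative CHA

class AlignmentWorkspace:
    """Caches target grids, alignment searchlights, and target-side profiles.

    Target-subject profiles depend only on (subject, condition, grid), so a
    cohort-level sweep over pairs re-uses them across source subjects.
    """

    def __init__(self, mesh_pair):
        self.mesh_pair = tuple(mesh_pair)
        self._grids: dict = {}
        self._searchlights: dict = {}
        self._profiles: dict = {}

    def grid(self, grid_order, averaging_radius_mm) -> TargetGrid:
        key = (grid_order, averaging_radius_mm)
        if key not in self._grids:
            self._grids[key] = build_target_grid(*self.mesh_pair, grid_order, averaging_radius_mm)
        return self._grids[key]

    def searchlights(self, radius_mm: float, hemisphere: str) -> SearchlightSet:
        key = (radius_mm, hemisphere)
        if key not in self._searchlights:
            mesh = self.mesh_pair[0] if hemisphere == "left" else self.mesh_pair[1]
            self._searchlights[key] = build_searchlight_set(mesh, None, radius_mm)
        return self._searchlights[key]

    def target_profile(self, ts: TimeSeries, grid_key, hemisphere: str) -> ConnectivityProfile:
        key = (ts.subject_id, ts.condition_id, grid_key, hemisphere)
        if key not in self._profiles:
            grid = self.grid(*grid_key)
            self._profiles[key] = connectivity_profile(ts, grid, *self.mesh_pair, hemisphere)
        return self._profiles[key]


def fit_iterative_cha(
    source_movie: TimeSeries,
    target_movie: TimeSeries,
    schedule: AlignmentSchedule,
    mesh_pair,
    workspace: AlignmentWorkspace | None = None,
) -> TransformChain:
    """Run the coarse-to-fine iterative CHA for one directed subject pair.

    The working source data start as the z-scored source movie; each step
    fits searchlight Procrustes transforms between the working data's
    connectivity profile and the (fixed, untransformed) target subject's
    profile, then pushes the working data through the new transforms.  The
    two movies may be different stimuli of different lengths: only
    connectivity structure is matched, never timepoints.
    """
    if workspace is None:
        workspace = AlignmentWorkspace(mesh_pair)
    mesh_pair = workspace.mesh_pair
    if source_movie.n_timepoints < 3 or target_movie.n_timepoints < 3:
        raise ValueError("movies need at least 3 timepoints")
    working = zscore_runs(source_movie) if not source_movie.zscored else source_movie
    target = zscore_runs(target_movie) if not target_movie.zscored else target_movie
    steps = []
    for k, st in enumerate(schedule.steps, start=1):
        try:
            grid_key = (st.grid_order, st.averaging_radius_mm)
            grid = workspace.grid(*grid_key)
            tms = {}
            for hemi, mesh in zip(HEMIS, mesh_pair):
                sls = workspace.searchlights(st.alignment_radius_mm, hemi)
                src_prof = connectivity_profile(working, grid, *mesh_pair, hemi)
                tgt_prof = workspace.target_profile(target, grid_key, hemi)
                tm = fit_searchlight_transform(
                    src_prof, tgt_prof, sls, mesh.n_vertices, step=k
                )
                tm.source_subject = source_movie.subject_id
                tm.target_subject = target_movie.subject_id
                tms[hemi] = tm
            step = TransformStep(left=tms["left"], right=tms["right"], step=k)
        except Exception as exc:
            raise RuntimeError(f"iterative CHA failed at step {k}: {exc}") from exc
        steps.append(step)
        working = apply_transform(step, working, mesh_pair)
    return TransformChain(
        steps=steps,
        schedule=schedule,
        source_subject=source_movie.subject_id,
        target_subject=target_movie.subject_id,
    )
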