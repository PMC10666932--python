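"""Run-wise standardization, target time courses, and seed x target connectivity profiles.

A connectivity profile is the Pearson-correlation matrix between one
hemisphere's cortical vertices (seeds) and a whole-brain set of connectivity
targets (searchlight-averaged coarse-grid time courses, or every vertex in
FULL mode), row-normalized to zero mean / unit variance per seed before
alignment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .surface import SurfaceMesh, TargetGrid


@dataclass
class TimeSeries:
    """Multi-run per-vertex time series, both hemispheres concatenated (left first).

    ``run_table`` is an ordered list of ``(run_id, n_timepoints)``; ``data``
    stacks the runs along time in that order.
    """

    subject_id: str
    condition_id: str
    run_table: list  # [(run_id, n_timepoints), ...]
    data: np.ndarray  # (sum n_timepoints, n_vertices)
    tr_s: float = 2.0
    zscored: bool = False
    degenerate: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        n_total = sum(n for _, n in self.run_table)
        if self.data.shape[0] != n_total:
            raise ValueError(
                f"data has {self.data.shape[0]} timepoints but run_table sums to {n_total}"
            )
        if not np.isfinite(self.data).all():
            raise ValueError("time series contains non-finite values")
        if self.degenerate is None:
            self.degenerate = np.zeros(self.data.shape[1], dtype=bool)

    @property
    def n_vertices(self) -> int:
        return self.data.shape[1]

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[0]

    def run_slices(self) -> list:
        out, start = [], 0
        for run_id, n in self.run_table:
            out.append((run_id, slice(start, start + n)))
            start += n
        return out


def zscore_runs(ts: TimeSeries) -> TimeSeries:
    """Standardize every vertex time course to mean 0, variance 1 within each run.

    Population (divisor ``n``) variance.  Vertices constant within any run
    become all-zero there and are recorded in ``degenerate``.
    """
    data = ts.data.copy()
    degen = ts.degenerate.copy()
    for _, sl in ts.run_slices():
        if sl.stop - sl.start < 2:
            raise ValueError("each run needs at least 2 timepoints to z-score")
        block = data[sl]
        mu = block.mean(axis=0)
        sd = block.std(axis=0)  # population convention
        const = sd == 0
        degen |= const
        sd_safe = np.where(const, 1.0, sd)
        data[sl] = (block - mu) / sd_safe
        data[sl][:, const] = 0.0
    return replace(ts, data=data, zscored=True, degenerate=degen)


def target_timeseries(ts: TimeSeries, grid: TargetGrid) -> np.ndarray:
    """Average each target's member vertices into one time course per target.

    Column ``j`` is the unweighted mean over member vertices of target ``j``'s
    averaging searchlight (FULL mode: the vertex's own time course).
    """
    out = np.empty((ts.n_timepoints, grid.n_targets))
    for j, members in enumerate(grid.member_lists):
        if len(members) == 0:
            raise ValueError(f"target {j} (vertex {grid.target_indices[j]}) has no members")
        out[:, j] = ts.data[:, members].mean(axis=1)
    return out


@dataclass
class ConnectivityProfile:
    """Row-normalized seed x target correlation matrix for one hemisphere."""

    subject_id: str
    condition_id: str
    hemisphere: str
    seed_indices: np.ndarray  # hemisphere-local vertex indices of the seeds
    target_grid: TargetGrid
    values: np.ndarray  # (n_seeds, n_targets)
    normalized: bool = True
    degenerate_seeds: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        if self.degenerate_seeds is None:
            self.degenerate_seeds = np.zeros(len(self.seed_indices), dtype=bool)


def _standardize_columns(x: np.ndarray):
    """Column-standardize (population convention); returns (z, degenerate cols)."""
    mu = x.mean(axis=0)
    sd = x.std(axis=0)
    const = sd == 0
    z = (x - mu) / np.where(const, 1.0, sd)
    z[:, const] = 0.0
    return z, const


def connectivity_profile(
    ts: TimeSeries,
    grid: TargetGrid,
    left_mesh: SurfaceMesh,
    right_mesh: SurfaceMesh,
    hemisphere: str,
    normalize: bool = True,
) -> ConnectivityProfile:
    """Correlate one hemisphere's cortical seeds with the whole-brain targets.

    Runs are z-scored independently, concatenated, and the Pearson
    correlation is taken over all timepoints.  Degenerate (constant) seeds or
    targets contribute correlation 0 with a warning.  When ``normalize`` each
    seed row is then standardized to zero mean and unit variance.
    """
    if ts.n_timepoints < 3:
        raise ValueError("need at least 3 total timepoints for a connectivity profile")
    mesh = {"left": left_mesh, "right": right_mesh}[hemisphere]
    offset = 0 if hemisphere == "left" else left_mesh.n_vertices
    seeds = mesh.cortical_indices
    if len(seeds) == 0:
        raise ValueError("empty seed set: hemisphere has no cortical vertices")
    if not ts.zscored:
        ts = zscore_runs(ts)
    seed_data = ts.data[:, offset + seeds]
    tgt_data = target_timeseries(ts, grid)

    zs, seed_degen = _standardize_columns(seed_data)
    zt, tgt_degen = _standardize_columns(tgt_data)
    if seed_degen.any() or tgt_degen.any():
        warnings.warn(
            f"{int(seed_degen.sum())} degenerate seeds and {int(tgt_degen.sum())} "
            "degenerate targets set to correlation 0",
            stacklevel=2,
        )
    values = (zs.T @ zt) / ts.n_timepoints  # correlation of standardized columns

    if normalize:
        mu = values.mean(axis=1, keepdims=True)
        sd = values.std(axis=1, keepdims=True)
        row_degen = sd[:, 0] == 0
        values = (values - mu) / np.where(sd == 0, 1.0, sd)
        values[row_degen] = 0.0
        seed_degen = seed_degen | row_degen
    return ConnectivityProfile(
        subject_id=ts.subject_id,
        condition_id=ts.condition_id,
        hemisphere=hemisphere,
        seed_indices=seeds,
        target_grid=grid,
        values=values,
        normalized=normalize,
        degenerate_seeds=seed_degen,
    )
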