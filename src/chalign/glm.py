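"""Block-design localizer GLM: design matrices, per-run t contrasts, topographies.

Category-selective topographies are unthresholded t maps for "target
category vs. all other categories" contrasts, fitted per run by ordinary
least squares and averaged across runs (and, for predicted topographies,
across source subjects whose localizer data were projected through
hyperalignment transforms).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from numpy.polynomial import legendre
from scipy.stats import gamma as gamma_dist

from .alignment import TransformChain, apply_chain
from .connectivity import TimeSeries, zscore_runs

#: sentinel t value for vertices with zero residual variance
LARGE_T = 1e6


@dataclass(frozen=True)
class Block:
    category: str
    onset_s: float
    duration_s: float


@dataclass
class LocalizerDesign:
    """Block-design localizer: per-run block lists on a common TR grid."""

    categories: list
    runs: list  # per run: list of Block
    tr_s: float
    n_timepoints: list  # per run
    include_in_baseline: dict = field(default_factory=dict)  # category -> bool

    def __post_init__(self):
        if len(self.categories) < 2:
            raise ValueError("need at least 2 categories")
        if len(self.runs) != len(self.n_timepoints):
            raise ValueError("runs and n_timepoints lengths differ")
        for r, blocks in enumerate(self.runs):
            cats = {b.category for b in blocks}
            if len(cats) < 2:
                raise ValueError(f"run {r} presents fewer than 2 distinct categories")
            span = sorted((b.onset_s, b.onset_s + b.duration_s) for b in blocks)
            for (s0, e0), (s1, _) in zip(span, span[1:]):
                if s1 < e0:
                    raise ValueError(f"run {r} has overlapping blocks")
            for b in blocks:
                if b.onset_s < 0:
                    raise ValueError("block onsets must be non-negative")
                if b.category not in self.categories:
                    raise ValueError(f"unknown category {b.category!r}")

    def baseline_categories(self, target: str) -> list:
        """Categories entering the "all others" side of a contrast on ``target``."""
        return [
            c
            for c in self.categories
            if c != target and self.include_in_baseline.get(c, True)
        ]


@dataclass
class HRFSpec:
    """Canonical double-gamma haemodynamic response (or ``none`` for boxcars).

    The kernel is the difference of two gamma densities (peak at about 5 s,
    undershoot at about 15 s), peak-normalized to 1, truncated at
    ``kernel_length_s``.
    """

    model: str = "double_gamma"
    peak_delay_s: float = 6.0
    undershoot_delay_s: float = 16.0
    peak_disp_s: float = 1.0
    undershoot_disp_s: float = 1.0
    undershoot_ratio: float = 6.0
    kernel_length_s: float = 32.0

    def kernel(self, dt_s: float) -> np.ndarray:
        """Sampled kernel at resolution ``dt_s`` (peak normalized to 1)."""
        if self.model == "none":
            return np.array([1.0])
        if self.model != "double_gamma":
            raise ValueError(f"unknown HRF model {self.model!r}")
        t = np.arange(0, self.kernel_length_s + dt_s / 2, dt_s)
        peak = gamma_dist.pdf(t, self.peak_delay_s / self.peak_disp_s, scale=self.peak_disp_s)
        under = gamma_dist.pdf(
            t, self.undershoot_delay_s / self.undershoot_disp_s, scale=self.undershoot_disp_s
        )
        h = peak - under / self.undershoot_ratio
        return h / h.max()


_OVERSAMPLE = 10


def convolved_regressors(
    design: LocalizerDesign, run_id: int, hrf: HRFSpec
) -> np.ndarray:
    """One HRF-convolved boxcar column per category, sampled at the TR grid."""
    blocks = design.runs[run_id]
    n_tp = design.n_timepoints[run_id]
    run_len_s = n_tp * design.tr_s
    dt = design.tr_s / _OVERSAMPLE
    n_fine = n_tp * _OVERSAMPLE
    t_fine = np.arange(n_fine) * dt
    kern = hrf.kernel(dt)
    out = np.zeros((n_tp, len(design.categories)))
    for ci, cat in enumerate(design.categories):
        box = np.zeros(n_fine)
        found = False
        for b in blocks:
            if b.category != cat:
                continue
            if b.onset_s + b.duration_s > run_len_s + 1e-9:
                raise ValueError(
                    f"block at {b.onset_s}s extends past run end ({run_len_s}s)"
                )
            box[(t_fine >= b.onset_s) & (t_fine < b.onset_s + b.duration_s)] = 1.0
            found = True
        if not found:
            warnings.warn(f"category {cat!r} has no blocks in run {run_id}", stacklevel=2)
        conv = np.convolve(box, kern)[:n_fine]
        out[:, ci] = conv[::_OVERSAMPLE]
    return out


def build_design_matrix(
    design: LocalizerDesign, run_id: int, hrf: HRFSpec, n_drift: int = 2
) -> np.ndarray:
    """Design matrix: category regressors, then intercept, then Legendre drifts."""
    if n_drift < 0:
        raise ValueError("n_drift must be non-negative")
    regs = convolved_regressors(design, run_id, hrf)
    n_tp = design.n_timepoints[run_id]
    x = np.linspace(-1.0, 1.0, n_tp)
    cols = [regs, np.ones((n_tp, 1))]
    for order in range(1, n_drift + 1):
        coef = np.zeros(order + 1)
        coef[order] = 1.0
        cols.append(legendre.legval(x, coef)[:, None])
    return np.hstack(cols)


@dataclass
class ContrastMap:
    """Per-vertex t statistics for one category contrast (NaN on masked vertices)."""

    subject_id: str
    category: str
    values: np.ndarray
    provenance: str = "own"  # own or predicted
    source_description: str = ""

    def finite_mask(self) -> np.ndarray:
        return np.isfinite(self.values)


def fit_contrast_tmap(
    run_ts: TimeSeries,
    X: np.ndarray,
    category: str,
    design: LocalizerDesign,
    cortex_mask: np.ndarray | None = None,
) -> ContrastMap:
    """OLS t map for ``category`` vs. the mean of all other (baseline) categories.

    Contrast weights are +1 on the target category and -1/(C-1) on each of
    the other baseline categories (zero-sum), 0 on nuisance columns;
    t = cᵀβ̂ / sqrt(σ̂² cᵀ(XᵀX)⁻¹c) with σ̂² = RSS/(n − rank X), unthresholded.
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if n != run_ts.n_timepoints:
        raise ValueError("design matrix and time series disagree on timepoints")
    rank = np.linalg.matrix_rank(X)
    if rank < p:
        raise ValueError(f"design matrix is rank deficient (rank {rank} < {p} columns)")
    others = design.baseline_categories(category)
    if category not in design.categories:
        raise ValueError(f"unknown category {category!r}")
    if not others:
        raise ValueError("no baseline categories for the contrast")
    c = np.zeros(p)
    c[design.categories.index(category)] = 1.0
    for cat in others:
        c[design.categories.index(cat)] = -1.0 / len(others)

    Y = run_ts.data
    xtx_inv = np.linalg.inv(X.T @ X)
    beta = xtx_inv @ (X.T @ Y)
    resid = Y - X @ beta
    dof = n - rank
    sigma2 = (resid**2).sum(axis=0) / dof
    denom2 = sigma2 * float(c @ xtx_inv @ c)
    cb = c @ beta
    # residuals at float-rounding scale mean the data sit in the model span
    zero_var = (denom2 <= 0) | (sigma2 < 1e-12 * (Y**2).mean(axis=0))
    n_flagged = int((zero_var & cortex_mask).sum()) if cortex_mask is not None else int(zero_var.sum())
    if n_flagged:
        warnings.warn(
            f"{n_flagged} cortical vertices with zero residual variance: "
            "t set to signed sentinel",
            stacklevel=2,
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        t = cb / np.sqrt(np.where(zero_var, 1.0, denom2))
    t[zero_var] = np.sign(cb[zero_var]) * LARGE_T
    if cortex_mask is not None:
        t = t.copy()
        t[~cortex_mask] = np.nan
    return ContrastMap(
        subject_id=run_ts.subject_id,
        category=category,
        values=t,
        provenance="own",
        source_description=f"single run GLM, condition {run_ts.condition_id}",
    )


def _mean_map(maps: list, subject_id: str, category: str, provenance: str, desc: str) -> ContrastMap:
    values = np.mean([m.values for m in maps], axis=0)
    return ContrastMap(
        subject_id=subject_id,
        category=category,
        values=values,
        provenance=provenance,
        source_description=desc,
    )


def own_topography(
    runs: list,
    design: LocalizerDesign,
    hrf: HRFSpec,
    category: str,
    n_drift: int = 2,
    cortex_mask: np.ndarray | None = None,
) -> ContrastMap:
    """A subject's own category-selective topography: per-run t maps averaged."""
    if len(runs) == 0:
        raise ValueError("need at least one localizer run")
    maps = []
    for run_id, run_ts in enumerate(runs):
        X = build_design_matrix(design, run_id, hrf, n_drift)
        maps.append(fit_contrast_tmap(run_ts, X, category, design, cortex_mask))
    return _mean_map(
        maps,
        runs[0].subject_id,
        category,
        "own",
        f"mean over {len(runs)} localizer runs",
    )


def _project_map_through_chain(
    values: np.ndarray, chain: TransformChain, mesh_pair, cortex_mask: np.ndarray
) -> np.ndarray:
    """Push a t map through a chain's matrices as a 1-timepoint pattern.

    The map is mean-centered over cortex before each multiplication; no
    z-scoring is interleaved (there is no run dimension to z-score).
    """
    left_mesh, right_mesh = mesh_pair
    nl = left_mesh.n_vertices
    v = np.where(np.isfinite(values) & cortex_mask, values, 0.0)
    for step in chain.steps:
        v = v - v[cortex_mask].mean()
        out = np.empty_like(v)
        out[:nl] = step.left.values @ v[:nl]
        out[nl:] = step.right.values @ v[nl:]
        v = out
    v = v.copy()
    v[~cortex_mask] = np.nan
    return v


def predicted_topography(
    target_subject: str,
    source_subjects: list,
    chains: dict,
    localizers: dict,
    design: LocalizerDesign,
    hrf: HRFSpec,
    category: str,
    mesh_pair,
    mode: str = "timeseries",
    n_drift: int = 2,
    cortex_mask: np.ndarray | None = None,
) -> ContrastMap:
    """Predict a target subject's topography from other subjects' localizer data.

    ``mode="timeseries"`` (canonical): every source localizer run is
    projected through the source→target chain, a per-run t map is fitted in
    the target's space, and all maps are averaged with equal weight across
    runs and sources.  ``mode="contrast_map"``: each source's native per-run
    t maps are pushed through the chain's matrices directly and averaged.
    Identity chains reproduce the anatomical-alignment (AA) baseline.
    """
    if len(source_subjects) == 0:
        raise ValueError("empty source subject set")
    if target_subject in source_subjects:
        raise ValueError("target subject must be excluded from the sources")
    if mode not in ("timeseries", "contrast_map"):
        raise ValueError(f"unknown prediction mode {mode!r}")
    left_mesh, right_mesh = mesh_pair
    if cortex_mask is None:
        cortex_mask = np.concatenate([left_mesh.cortex_mask, right_mesh.cortex_mask])
    maps = []
    for src in source_subjects:
        chain = chains[src]
        for run_id, run_ts in enumerate(localizers[src]):
            if mode == "timeseries":
                projected = apply_chain(chain, zscore_runs(run_ts), mesh_pair)
                X = build_design_matrix(design, run_id, hrf, n_drift)
                maps.append(fit_contrast_tmap(projected, X, category, design, cortex_mask))
            else:
                X = build_design_matrix(design, run_id, hrf, n_drift)
                native = fit_contrast_tmap(run_ts, X, category, design, cortex_mask)
                maps.append(
                    ContrastMap(
                        subject_id=src,
                        category=category,
                        values=_project_map_through_chain(
                            native.values, chain, mesh_pair, cortex_mask
                        ),
                        provenance="predicted",
                    )
                )
    method = chains[source_subjects[0]].steps[0].left.method
    return _mean_map(
        maps,
        target_subject,
        category,
        "predicted",
        f"mean over {len(source_subjects)} subjects x {len(maps) // len(source_subjects)}"
        f" runs, {method}, mode={mode}",
    )
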