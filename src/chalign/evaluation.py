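"""Prediction-fidelity and reliability metrics.

Whole-map and searchlight Pearson correlations between own and predicted
topographies, Cronbach's alpha across localizer runs (the noise ceiling),
cross-movie fine-connectome similarity, and Fisher-z paired comparisons
between methods.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .connectivity import ConnectivityProfile
from .glm import ContrastMap
from .surface import SearchlightSet


def _as_values(m) -> np.ndarray:
    return m.values if isinstance(m, ContrastMap) else np.asarray(m, dtype=float)


def map_pearson(own, predicted, mask: np.ndarray | None = None) -> float:
    """Pearson correlation between two whole-brain maps over cortical vertices.

    Zero variance on either side raises: a degenerate whole map signals a
    pipeline bug, not an expected condition.
    """
    a = _as_values(own)
    b = _as_values(predicted)
    if a.shape != b.shape:
        raise ValueError("maps have different vertex counts")
    valid = np.isfinite(a) & np.isfinite(b)
    if mask is not None:
        valid &= mask
    if valid.sum() < 3:
        raise ValueError("need at least 3 unmasked vertices")
    a, b = a[valid], b[valid]
    if a.std() == 0 or b.std() == 0:
        raise ValueError("zero variance map in whole-map correlation")
    return float(np.corrcoef(a, b)[0, 1])


def cronbach_alpha(run_maps: list, mask: np.ndarray | None = None) -> float:
    """Cronbach's alpha across runs (items), vertices as observations.

    alpha = k/(k-1) * (1 - sum_i Var(map_i) / Var(sum_i map_i)), population
    variances over unmasked vertices.  This is the reliability (noise
    ceiling) of a topography estimated from k localizer runs.
    """
    k = len(run_maps)
    if k < 2:
        raise ValueError("Cronbach's alpha needs at least 2 runs")
    arrs = [_as_values(m) for m in run_maps]
    valid = np.all([np.isfinite(a) for a in arrs], axis=0)
    if mask is not None:
        valid &= mask
    if valid.sum() < 3:
        raise ValueError("need at least 3 unmasked vertices")
    stacked = np.vstack([a[valid] for a in arrs])  # (k, n_vertices)
    item_var = stacked.var(axis=1).sum()
    total_var = stacked.sum(axis=0).var()
    if total_var == 0:
        raise ValueError("zero total variance across runs")
    return float(k / (k - 1) * (1.0 - item_var / total_var))


@dataclass
class SearchlightMap:
    """A statistic per searchlight center (NaN where locally degenerate)."""

    values: np.ndarray  # aligned with full vertex space; NaN off-center
    centers: np.ndarray
    radius_mm: float
    kind: str  # correlation | alpha | connectome_similarity
    hemisphere: str = "left"

    def center_values(self) -> np.ndarray:
        return self.values[self.centers]


def searchlight_statistic_map(
    a,
    b=None,
    searchlights: SearchlightSet = None,
    kind: str = "correlation",
    n_vertices: int | None = None,
    offset: int = 0,
) -> SearchlightMap:
    """Evaluate map_pearson or cronbach_alpha within every searchlight.

    ``kind="correlation"`` needs maps ``a`` and ``b``; ``kind="alpha"``
    needs ``a`` to be the list of run maps.  Centers whose searchlight has
    fewer than 3 members or degenerate variance yield NaN (local degeneracy
    is expected, e.g., flat maps far from any category-selective region).
    ``offset`` shifts hemisphere-local member indices into whole-brain maps.
    """
    if searchlights is None or searchlights.radius_mm <= 0:
        raise ValueError("need searchlights with a positive radius")
    if kind == "correlation":
        if b is None:
            raise ValueError("correlation maps need both a and b")
        arrs = (_as_values(a), _as_values(b))
    elif kind == "alpha":
        arrs = tuple(_as_values(m) for m in a)
        if len(arrs) < 2:
            raise ValueError("alpha maps need at least 2 run maps")
    else:
        raise ValueError(f"unknown searchlight statistic kind {kind!r}")
    if n_vertices is None:
        n_vertices = len(arrs[0])
    values = np.full(n_vertices, np.nan)
    for center, members in zip(searchlights.centers, searchlights.members):
        gm = members + offset
        try:
            if kind == "correlation":
                values[center + offset] = map_pearson(arrs[0][gm], arrs[1][gm])
            else:
                values[center + offset] = cronbach_alpha([m[gm] for m in arrs])
        except ValueError:
            pass  # NaN sentinel for degenerate centers
    return SearchlightMap(
        values=values,
        centers=searchlights.centers + offset,
        radius_mm=searchlights.radius_mm,
        kind=kind,
        hemisphere=searchlights.hemisphere,
    )


def connectome_similarity_map(
    profile_a: ConnectivityProfile,
    profile_b: ConnectivityProfile,
    searchlights: SearchlightSet,
) -> SearchlightMap:
    """Correlate two fine-grained connectomes within every searchlight.

    Per center, the Pearson correlation between the two vectorized
    (members x targets) profile blocks — e.g., the same subject's profiles
    from two different movies, or from split halves of one movie.
    """
    if profile_a.hemisphere != profile_b.hemisphere:
        raise ValueError("profiles are from different hemispheres")
    if profile_a.values.shape != profile_b.values.shape or not np.array_equal(
        profile_a.target_grid.target_indices, profile_b.target_grid.target_indices
    ):
        raise ValueError("profiles must share seed set and target grid")
    n_vertices = int(profile_a.seed_indices.max()) + 1
    pos = np.full(n_vertices, -1, dtype=np.int64)
    pos[profile_a.seed_indices] = np.arange(len(profile_a.seed_indices))
    values = np.full(n_vertices, np.nan)
    for center, members in zip(searchlights.centers, searchlights.members):
        rows = pos[members]
        rows = rows[rows >= 0]
        if len(rows) == 0:
            continue
        va = profile_a.values[rows].ravel()
        vb = profile_b.values[rows].ravel()
        if va.std() == 0 or vb.std() == 0:
            continue
        values[center] = np.corrcoef(va, vb)[0, 1]
    return SearchlightMap(
        values=values,
        centers=searchlights.centers,
        radius_mm=searchlights.radius_mm,
        kind="connectome_similarity",
        hemisphere=searchlights.hemisphere,
    )


@dataclass
class MethodComparison:
    """Fisher-z paired comparison of two methods' per-subject correlations."""

    method_a: str
    method_b: str
    mean_z_diff: float
    t_statistic: float
    p_value: float
    p_bonferroni: float
    n: int


def compare_methods(
    r_a,
    r_b,
    method_a: str = "A",
    method_b: str = "B",
    n_comparisons: int = 1,
) -> MethodComparison:
    """Paired two-sided t test on Fisher-z-transformed correlations.

    p values are Bonferroni-adjusted for the supplied family size.
    Correlations exactly at ±1 are clipped before atanh.
    """
    r_a = np.asarray(r_a, dtype=float)
    r_b = np.asarray(r_b, dtype=float)
    if r_a.shape != r_b.shape or r_a.ndim != 1:
        raise ValueError("need two paired 1-D correlation vectors")
    if len(r_a) < 3:
        raise ValueError("need at least 3 paired subjects")
    if (np.abs(r_a) >= 1).any() or (np.abs(r_b) >= 1).any():
        warnings.warn("correlations at |r| >= 1 clipped before Fisher z", stacklevel=2)
    clip = 1.0 - 1e-12
    z_a = np.arctanh(np.clip(r_a, -clip, clip))
    z_b = np.arctanh(np.clip(r_b, -clip, clip))
    if np.allclose(z_a, z_b):
        t_stat, p = 0.0, 1.0
    else:
        t_stat, p = stats.ttest_rel(z_a, z_b)
    return MethodComparison(
        method_a=method_a,
        method_b=method_b,
        mean_z_diff=float(np.mean(z_a - z_b)),
        t_statistic=float(t_stat),
        p_value=float(p),
        p_bonferroni=float(min(1.0, p * n_comparisons)),
        n=len(r_a),
    )


def evaluation_report(records: list) -> pd.DataFrame:
    """Long-format report from (subject, category, method, map_r, alpha) records."""
    df = pd.DataFrame.from_records(
        records, columns=["subject_id", "category", "method", "map_r", "alpha"]
    )
    return df


def summarize_report(df: pd.DataFrame) -> pd.DataFrame:
    """Mean and standard error of map_r per method x category."""
    g = df.groupby(["method", "category"])["map_r"]
    out = g.agg(["mean", "sem", "count"]).reset_index()
    return out.rename(columns={"mean": "mean_r", "sem": "sem_r", "count": "n"})
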