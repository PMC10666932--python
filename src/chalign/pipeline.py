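"""Cohort-level drivers: fit all pairwise chains, predict topographies, report.

These helpers orchestrate the per-pair operations across a whole cohort,
caching target-side profiles (which depend only on the target subject and
grid) and exposing the standard experiment: predict every subject's
category-selective maps from everyone else's localizer data under CHA, RHA
or the anatomical-alignment (AA) identity baseline, and score each
prediction against the subject's own-localizer map.
"""

from __future__ import annotations

import logging

import numpy as np

from .alignment import (
    HEMIS,
    AlignmentSchedule,
    AlignmentWorkspace,
    TransformChain,
    TransformStep,
    fit_iterative_cha,
    fit_rha_transform,
    identity_chain,
)
from .evaluation import cronbach_alpha, evaluation_report, map_pearson
from .glm import ContrastMap, fit_contrast_tmap, build_design_matrix, own_topography, predicted_topography
from .synthetic import CohortBundle

logger = logging.getLogger(__name__)


def fit_cohort_chains(
    cohort: CohortBundle,
    schedule: AlignmentSchedule | None = None,
    method: str = "cha",
    source_movie: str = "A",
    target_movie: str = "A",
    alignment_radius_mm: float = 15.0,
    workspace: AlignmentWorkspace | None = None,
    subjects: list | None = None,
    n_jobs: int = 1,
    _only_target: str | None = None,
) -> dict:
    """Fit chains for every ordered subject pair.

    Returns ``{target_id: {source_id: TransformChain}}``.  For CHA the
    source subjects' profiles come from ``source_movie`` and the target
    subject's from ``target_movie`` (different movies = cross-movie CHA).
    RHA requires ``source_movie == target_movie`` because it matches
    response patterns timepoint by timepoint.
    """
    method = method.lower()
    if method == "aa":
        subjects = subjects or cohort.subject_ids
        return {
            t: {s: identity_chain(s, t, cohort.mesh_pair) for s in subjects if s != t}
            for t in subjects
        }
    if method == "rha" and source_movie != target_movie:
        raise ValueError(
            "RHA requires the same stimulus for all subjects: response patterns "
            f"are matched timepoint by timepoint (got movies {source_movie!r} "
            f"vs {target_movie!r})"
        )
    if schedule is None:
        schedule = AlignmentSchedule.synthetic_default()
    subjects = subjects or cohort.subject_ids
    if n_jobs != 1:
        # pair fits are independent; per-target workers give results
        # identical to the serial loop
        from joblib import Parallel, delayed

        per_target = Parallel(n_jobs=n_jobs)(
            delayed(fit_cohort_chains)(
                cohort, schedule, method, source_movie, target_movie,
                alignment_radius_mm, None, subjects, 1, target,
            )
            for target in subjects
        )
        return {t: res[t] for t, res in zip(subjects, per_target)}
    ws = workspace or AlignmentWorkspace(cohort.mesh_pair)
    targets = [_only_target] if _only_target else subjects
    chains: dict = {t: {} for t in targets}
    for target in targets:
        tgt_ts = cohort.movies[(target, target_movie)]
        for source in subjects:
            if source == target:
                continue
            src_ts = cohort.movies[(source, source_movie)]
            if method == "cha":
                chain = fit_iterative_cha(src_ts, tgt_ts, schedule, cohort.mesh_pair, ws)
            elif method == "rha":
                sls = {h: ws.searchlights(alignment_radius_mm, h) for h in HEMIS}
                tms = {
                    h: fit_rha_transform(src_ts, tgt_ts, sls[h], cohort.mesh_pair, h)
                    for h in HEMIS
                }
                step = TransformStep(left=tms["left"], right=tms["right"], step=1)
                chain = TransformChain(
                    steps=[step],
                    schedule=AlignmentSchedule(steps=[schedule.steps[-1]]),
                    source_subject=source,
                    target_subject=target,
                )
            else:
                raise ValueError(f"unknown alignment method {method!r}")
            chains[target][source] = chain
        logger.info("fitted %s chains into %s", method.upper(), target)
    return chains


def own_topographies(cohort: CohortBundle, categories=None) -> dict:
    """Each subject's own-localizer maps: ``{(subject, category): ContrastMap}``."""
    categories = categories or default_map_categories(cohort)
    out = {}
    for sid in cohort.subject_ids:
        for cat in categories:
            out[(sid, cat)] = own_topography(
                cohort.localizers[sid],
                cohort.design,
                cohort.hrf,
                cat,
                cortex_mask=cohort.cortex_mask,
            )
    return out


def predicted_topographies(
    cohort: CohortBundle,
    chains: dict,
    categories=None,
    mode: str = "timeseries",
) -> dict:
    """Cross-subject predicted maps: ``{(target, category): ContrastMap}``."""
    categories = categories or default_map_categories(cohort)
    out = {}
    for target, per_source in chains.items():
        sources = sorted(per_source)
        for cat in categories:
            out[(target, cat)] = predicted_topography(
                target,
                sources,
                per_source,
                cohort.localizers,
                cohort.design,
                cohort.hrf,
                cat,
                cohort.mesh_pair,
                mode=mode,
                cortex_mask=cohort.cortex_mask,
            )
    return out


def default_map_categories(cohort: CohortBundle) -> list:
    """Categories that get topography maps: all but a trailing scrambled control."""
    return [c for c in cohort.design.categories if c != "scrambled"]


def run_alphas(cohort: CohortBundle, categories=None) -> dict:
    """Cronbach's alpha of each subject's per-run maps: ``{(subject, category): alpha}``."""
    categories = categories or default_map_categories(cohort)
    out = {}
    for sid in cohort.subject_ids:
        run_maps: dict = {cat: [] for cat in categories}
        for run_id, run_ts in enumerate(cohort.localizers[sid]):
            X = build_design_matrix(cohort.design, run_id, cohort.hrf)
            for cat in categories:
                run_maps[cat].append(
                    fit_contrast_tmap(run_ts, X, cat, cohort.design, cohort.cortex_mask)
                )
        for cat in categories:
            out[(sid, cat)] = cronbach_alpha(run_maps[cat], cohort.cortex_mask)
    return out


def prediction_report(
    cohort: CohortBundle,
    methods: dict,
    categories=None,
    own_maps: dict | None = None,
    alphas: dict | None = None,
    mode: str = "timeseries",
):
    """Score predicted vs own maps for several methods into a long DataFrame.

    ``methods`` maps a method label to its ``{target: {source: chain}}``
    chains (use :func:`fit_cohort_chains` with ``method="aa"`` for the
    anatomical baseline).
    """
    categories = categories or default_map_categories(cohort)
    own_maps = own_maps or own_topographies(cohort, categories)
    alphas = alphas if alphas is not None else run_alphas(cohort, categories)
    records = []
    for label, chains in methods.items():
        predicted = predicted_topographies(cohort, chains, categories, mode=mode)
        for (target, cat), pmap in predicted.items():
            r = map_pearson(own_maps[(target, cat)], pmap, cohort.cortex_mask)
            records.append((target, cat, label, r, alphas.get((target, cat), np.nan)))
    return evaluation_report(records)
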