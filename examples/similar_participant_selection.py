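"""Predict from the most- vs least-similar source participants.

Ranks source subjects by their fine-connectome similarity to the target
(median searchlight similarity between the target's movie-A profile and
each source's movie-A profile), then compares topography predictions built
from the top half vs the bottom half of the ranking.

Run: python examples/similar_participant_selection.py
"""

import numpy as np

from chalign.alignment import AlignmentSchedule, AlignmentWorkspace
from chalign.connectivity import connectivity_profile
from chalign.evaluation import connectome_similarity_map, map_pearson
from chalign.pipeline import fit_cohort_chains, own_topographies, predicted_topographies
from chalign.synthetic import CohortSpec, make_cohort


def main():
    cohort = make_cohort(CohortSpec(n_subjects=6), master_seed=42)
    ws = AlignmentWorkspace(cohort.mesh_pair)
    sched = AlignmentSchedule(steps=AlignmentSchedule.synthetic_default().steps[:1])
    chains = fit_cohort_chains(cohort, sched, "cha", workspace=ws)
    own = own_topographies(cohort)

    grid = ws.grid(1, 55.0)
    sls = ws.searchlights(15.0, "left")
    profiles = {
        sid: connectivity_profile(cohort.movies[(sid, "A")], grid, *cohort.mesh_pair, "left")
        for sid in cohort.subject_ids
    }

    target = cohort.subject_ids[0]
    others = [s for s in cohort.subject_ids if s != target]
    sims = {
        s: np.nanmedian(connectome_similarity_map(profiles[target], profiles[s], sls).values)
        for s in others
    }
    ranked = sorted(others, key=sims.get, reverse=True)
    half = len(ranked) // 2
    for label, group in (("most similar", ranked[:half]), ("least similar", ranked[half:])):
        sub_chains = {target: {s: chains[target][s] for s in group}}
        pred = predicted_topographies(cohort, sub_chains)
        rs = [
            map_pearson(own[key], pred[key], cohort.cortex_mask)
            for key in pred
        ]
        print(f"{label} sources {group}: mean prediction r = {np.mean(rs):.3f}")


if __name__ == "__main__":
    main()
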