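"""Prediction accuracy as a function of the number of source participants.

Run: python examples/group_size_sweep.py
"""

import numpy as np

from chalign.alignment import AlignmentSchedule, AlignmentWorkspace
from chalign.evaluation import map_pearson
from chalign.pipeline import fit_cohort_chains, own_topographies, predicted_topographies
from chalign.synthetic import CohortSpec, make_cohort


def main():
    cohort = make_cohort(CohortSpec(n_subjects=6), master_seed=43)
    ws = AlignmentWorkspace(cohort.mesh_pair)
    sched = AlignmentSchedule(steps=AlignmentSchedule.synthetic_default().steps[:1])
    chains = fit_cohort_chains(cohort, sched, "cha", workspace=ws)
    own = own_topographies(cohort)

    target = cohort.subject_ids[0]
    sources = sorted(chains[target])
    for k in range(1, len(sources) + 1):
        sub = {target: {s: chains[target][s] for s in sources[:k]}}
        pred = predicted_topographies(cohort, sub)
        rs = [map_pearson(own[key], pred[key], cohort.cortex_mask) for key in pred]
        print(f"{k} source subject(s): mean prediction r = {np.mean(rs):.3f}")


if __name__ == "__main__":
    main()
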