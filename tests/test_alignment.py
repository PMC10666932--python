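"""Procrustes solutions, searchlight aggregation, transform application, iterative CHA."""

import numpy as np
import pytest
import scipy.linalg
import scipy.sparse as sp
from scipy.stats import ortho_group

from chalign.alignment import (
    AlignmentSchedule,
    AlignmentWorkspace,
    ScheduleStep,
    TransformStep,
    TransformationMatrix,
    apply_chain,
    apply_transform,
    collapse_chain,
    fit_iterative_cha,
    fit_rha_transform,
    fit_searchlight_transform,
    identity_chain,
    orthogonal_procrustes,
)
from chalign.connectivity import ConnectivityProfile, TimeSeries, connectivity_profile, zscore_runs
from chalign.surface import FULL, SearchlightSet, build_icosphere, build_searchlight_set, build_target_grid


def _profile(values, hemisphere="left"):
    return ConnectivityProfile(
        subject_id="s",
        condition_id="m",
        hemisphere=hemisphere,
        seed_indices=np.arange(values.shape[0]),
        target_grid=None,
        values=values,
    )


def _ts(data, runs=None, subject="s"):
    runs = runs or [("run1", data.shape[0])]
    return TimeSeries(subject_id=subject, condition_id="m", run_table=runs, data=data)


@pytest.fixture(scope="module")
def pair0():
    return (build_icosphere(0, 100.0, "left"), build_icosphere(0, 100.0, "right"))


def _unit_variance_patterns(n_timepoints, n_vertices, rng):
    """Zero-mean, exactly unit-population-variance, mutually uncorrelated columns."""
    raw = rng.standard_normal((n_timepoints, n_vertices))
    raw -= raw.mean(axis=0)
    q, _ = np.linalg.qr(raw)
    return np.sqrt(n_timepoints) * q


class TestOrthogonalProcrustes:
    def test_identity_for_equal_inputs(self):
        a = np.random.default_rng(0).standard_normal((5, 20))
        np.testing.assert_allclose(orthogonal_procrustes(a, a), np.eye(5), atol=1e-10)

    def test_recovers_planted_rotation(self):
        rng = np.random.default_rng(1)
        a = rng.standard_normal((6, 30))
        g = ortho_group.rvs(6, random_state=rng)
        np.testing.assert_allclose(orthogonal_procrustes(a, g @ a), g, atol=1e-8)

    def test_orthogonal_and_beats_random_rotations(self):
        rng = np.random.default_rng(2)
        a = rng.standard_normal((6, 40))
        g = ortho_group.rvs(6, random_state=rng)
        b = g @ a + 0.05 * rng.standard_normal((6, 40))
        r = orthogonal_procrustes(a, b)
        assert np.abs(r.T @ r - np.eye(6)).max() < 1e-8
        resid = np.linalg.norm(r @ a - b)
        qs = ortho_group.rvs(6, size=200, random_state=rng)
        assert all(resid <= np.linalg.norm(q @ a - b) + 1e-12 for q in qs)

    def test_agrees_with_scipy_cross_check(self):
        rng = np.random.default_rng(3)
        a = rng.standard_normal((7, 25))
        b = rng.standard_normal((7, 25))
        ours = orthogonal_procrustes(a, b)
        # scipy solves min ||X R - Y|| over columns: transpose our row convention
        ref, _ = scipy.linalg.orthogonal_procrustes(a.T, b.T)
        np.testing.assert_allclose(ours, ref.T, atol=1e-10)

    def test_rank_deficient_input_still_orthogonal(self):
        a = np.ones((4, 10))
        r = orthogonal_procrustes(a, a)
        assert np.abs(r.T @ r - np.eye(4)).max() < 1e-8

    def test_bad_inputs_raise(self):
        with pytest.raises(ValueError, match="shape"):
            orthogonal_procrustes(np.zeros((2, 3)), np.zeros((3, 2)))
        bad = np.full((2, 2), np.nan)
        with pytest.raises(ValueError, match="finite"):
            orthogonal_procrustes(bad, bad)


class TestFitSearchlightTransform:
    def test_self_alignment_gives_diagonal_count_matrix(self):
        mesh = build_icosphere(2, 100.0, "left")
        sls = build_searchlight_set(mesh, None, 30.0)
        rng = np.random.default_rng(4)
        prof = _profile(rng.standard_normal((mesh.n_vertices, 50)))
        tm = fit_searchlight_transform(prof, prof, sls, mesh.n_vertices)
        dense = tm.values.toarray()
        counts = np.zeros(mesh.n_vertices)
        for m in sls.members:
            counts[m] += 1
        np.testing.assert_allclose(np.diag(dense), counts, atol=1e-7)
        np.testing.assert_allclose(dense - np.diag(np.diag(dense)), 0.0, atol=1e-7)

    def test_disjoint_planted_rotations_recovered_blockwise(self):
        rng = np.random.default_rng(5)
        blocks = [np.arange(0, 4), np.arange(4, 8), np.arange(8, 12)]
        sls = SearchlightSet(radius_mm=1.0, centers=np.array([0, 4, 8]), members=blocks)
        src = rng.standard_normal((12, 30))
        gs = [ortho_group.rvs(4, random_state=rng) for _ in blocks]
        tgt = np.vstack([g @ src[b] for g, b in zip(gs, blocks)])
        tm = fit_searchlight_transform(_profile(src), _profile(tgt), sls, 12)
        expected = sp.block_diag(gs).toarray()
        np.testing.assert_allclose(tm.values.toarray(), expected, atol=1e-8)

    def test_sparsity_confined_to_searchlight_comembership(self):
        mesh = build_icosphere(2, 100.0, "left")
        sls = build_searchlight_set(mesh, None, 30.0)
        rng = np.random.default_rng(6)
        a = _profile(rng.standard_normal((mesh.n_vertices, 40)))
        b = _profile(rng.standard_normal((mesh.n_vertices, 40)))
        tm = fit_searchlight_transform(a, b, sls, mesh.n_vertices)
        co = set()
        for m in sls.members:
            co.update((int(i), int(j)) for i in m for j in m)
        coo = tm.values.tocoo()
        assert set(zip(coo.row.tolist(), coo.col.tolist())) <= co


class TestApplyTransform:
    def _identity_step(self, pair0):
        tms = {
            h: TransformationMatrix("a", "b", h, sp.identity(12, format="csr"))
            for h in ("left", "right")
        }
        return TransformStep(left=tms["left"], right=tms["right"])

    def test_identity_transform_is_noop_on_zscored_data(self, pair0):
        rng = np.random.default_rng(7)
        ts = zscore_runs(_ts(rng.standard_normal((30, 24)), [("a", 15), ("b", 15)]))
        out = apply_transform(self._identity_step(pair0), ts, pair0)
        np.testing.assert_allclose(out.data, ts.data, atol=1e-12)
        assert out.subject_id == "a->b"

    def test_matches_dense_product_oracle(self, pair0):
        rng = np.random.default_rng(8)
        mats = {h: sp.random(12, 12, density=0.4, random_state=rng).tocsr() for h in ("left", "right")}
        step = TransformStep(
            left=TransformationMatrix("a", "b", "left", mats["left"]),
            right=TransformationMatrix("a", "b", "right", mats["right"]),
        )
        ts = zscore_runs(_ts(rng.standard_normal((20, 24))))
        out = apply_transform(step, ts, pair0)
        manual = np.hstack(
            [
                (mats["left"].toarray() @ ts.data[:, :12].T).T,
                (mats["right"].toarray() @ ts.data[:, 12:].T).T,
            ]
        )
        expected = zscore_runs(_ts(manual)).data
        np.testing.assert_allclose(out.data, expected, atol=1e-9)

    def test_dimension_mismatch_raises(self, pair0):
        step = TransformStep(
            left=TransformationMatrix("a", "b", "left", sp.identity(5, format="csr")),
            right=TransformationMatrix("a", "b", "right", sp.identity(12, format="csr")),
        )
        ts = zscore_runs(_ts(np.random.default_rng(9).standard_normal((10, 24))))
        with pytest.raises(ValueError, match="transform"):
            apply_transform(step, ts, pair0)


class TestRHA:
    def test_planted_blockwise_rotations_recovered(self, pair0):
        rng = np.random.default_rng(10)
        z = _unit_variance_patterns(60, 24, rng)
        blocks = [np.arange(0, 4), np.arange(4, 8), np.arange(8, 12)]
        gs = [ortho_group.rvs(4, random_state=rng) for _ in blocks]
        tgt = z.copy()
        for g, b in zip(gs, blocks):
            tgt[:, b] = z[:, b] @ g.T
        sls = SearchlightSet(radius_mm=1.0, centers=np.array([0, 4, 8]), members=blocks)
        tm = fit_rha_transform(_ts(z, subject="src"), _ts(tgt, subject="tgt"), sls, pair0, "left")
        np.testing.assert_allclose(tm.values.toarray(), sp.block_diag(gs).toarray(), atol=1e-6)
        assert tm.method == "RHA"

    def test_self_alignment_gives_diagonal_counts(self, pair0):
        rng = np.random.default_rng(11)
        ts = _ts(rng.standard_normal((40, 24)))
        sls = build_searchlight_set(pair0[0], None, 40.0)
        tm = fit_rha_transform(ts, ts, sls, pair0, "left")
        dense = tm.values.toarray()
        counts = np.zeros(12)
        for m in sls.members:
            counts[m] += 1
        np.testing.assert_allclose(np.diag(dense), counts, atol=1e-7)

    def test_mismatched_run_lengths_cite_same_stimulus_rule(self, pair0):
        rng = np.random.default_rng(12)
        a = _ts(rng.standard_normal((30, 24)))
        b = _ts(rng.standard_normal((40, 24)))
        sls = build_searchlight_set(pair0[0], None, 40.0)
        with pytest.raises(ValueError, match="same stimulus"):
            fit_rha_transform(a, b, sls, pair0, "left")


class TestIterativeCHA:
    def test_single_step_schedule_equals_plain_cha(self, tiny_cohort):
        sched = AlignmentSchedule(steps=[ScheduleStep(1, 55.0, 15.0)])
        ws = AlignmentWorkspace(tiny_cohort.mesh_pair)
        src = tiny_cohort.movies[("sub-01", "A")]
        tgt = tiny_cohort.movies[("sub-02", "A")]
        chain = fit_iterative_cha(src, tgt, sched, tiny_cohort.mesh_pair, ws)
        assert len(chain) == 1
        grid = ws.grid(1, 55.0)
        for hemi, mesh in zip(("left", "right"), tiny_cohort.mesh_pair):
            ps = connectivity_profile(zscore_runs(src), grid, *tiny_cohort.mesh_pair, hemi)
            pt = connectivity_profile(zscore_runs(tgt), grid, *tiny_cohort.mesh_pair, hemi)
            manual = fit_searchlight_transform(ps, pt, ws.searchlights(15.0, hemi), mesh.n_vertices)
            got = getattr(chain.steps[0], hemi).values
            np.testing.assert_allclose(got.toarray(), manual.values.toarray(), atol=1e-12)

    def test_self_pair_chain_preserves_own_data(self, tiny_cohort):
        sched = AlignmentSchedule(steps=[ScheduleStep(1, 55.0, 15.0)])
        movie = tiny_cohort.movies[("sub-01", "A")]
        chain = fit_iterative_cha(movie, movie, sched, tiny_cohort.mesh_pair)
        out = apply_chain(chain, zscore_runs(movie), tiny_cohort.mesh_pair)
        z = zscore_runs(movie)
        mask = tiny_cohort.cortex_mask & ~z.degenerate
        corr = (out.data[:, mask] * z.data[:, mask]).mean(axis=0)
        assert corr.min() > 0.999

    def test_cross_movie_pairs_need_no_time_locking(self, tiny_cohort):
        sched = AlignmentSchedule(steps=[ScheduleStep(1, 55.0, 15.0)])
        src = tiny_cohort.movies[("sub-01", "A")]
        tgt = tiny_cohort.movies[("sub-02", "B")]
        chain = fit_iterative_cha(src, tgt, sched, tiny_cohort.mesh_pair)
        assert chain.source_subject == "sub-01" and chain.target_subject == "sub-02"


class TestApplyChain:
    def test_identity_chain_is_noop(self, pair0):
        rng = np.random.default_rng(13)
        ts = zscore_runs(_ts(rng.standard_normal((20, 24))))
        chain = identity_chain("a", "b", pair0)
        out = apply_chain(chain, ts, pair0)
        np.testing.assert_allclose(out.data, ts.data, atol=1e-12)

    def test_two_step_chain_equals_manual_replay(self, tiny_cohort):
        sched = AlignmentSchedule(
            steps=[ScheduleStep(1, 55.0, 15.0), ScheduleStep(2, 27.0, 15.0)]
        )
        src = tiny_cohort.movies[("sub-01", "A")]
        tgt = tiny_cohort.movies[("sub-02", "A")]
        chain = fit_iterative_cha(src, tgt, sched, tiny_cohort.mesh_pair)
        ts = zscore_runs(tiny_cohort.localizers["sub-01"][0])
        out = apply_chain(chain, ts, tiny_cohort.mesh_pair)
        manual = ts
        for step in chain.steps:
            manual = apply_transform(step, manual, tiny_cohort.mesh_pair)
        np.testing.assert_allclose(out.data, manual.data, atol=1e-12)

    def test_empty_chain_warns_and_returns_zscored(self, pair0):
        chain = identity_chain("a", "b", pair0)
        chain.steps = []
        ts = _ts(np.random.default_rng(14).standard_normal((10, 24)))
        with pytest.warns(UserWarning, match="empty"):
            out = apply_chain(chain, ts, pair0)
        np.testing.assert_allclose(out.data, zscore_runs(ts).data, atol=1e-12)

    def test_collapse_chain_multiplies_in_order(self, pair0):
        rng = np.random.default_rng(15)
        steps = []
        mats = []
        for k in (1, 2):
            m = sp.random(12, 12, density=0.3, random_state=rng).tocsr()
            mats.append(m)
            steps.append(
                TransformStep(
                    left=TransformationMatrix("a", "b", "left", m),
                    right=TransformationMatrix("a", "b", "right", sp.identity(12, format="csr")),
                    step=k,
                )
            )
        chain = identity_chain("a", "b", pair0)
        chain.steps = steps
        collapsed = collapse_chain(chain, "left").toarray()
        np.testing.assert_allclose(collapsed, (mats[1] @ mats[0]).toarray(), atol=1e-12)
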