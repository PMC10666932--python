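"""Design matrices, HRF kernel, per-run t contrasts, own and predicted topographies."""

import math

import numpy as np
import pytest
from scipy import stats

from chalign.alignment import AlignmentSchedule, ScheduleStep, fit_iterative_cha, apply_chain
from chalign.connectivity import TimeSeries, zscore_runs
from chalign.evaluation import map_pearson
from chalign.glm import (
    LARGE_T,
    Block,
    HRFSpec,
    LocalizerDesign,
    build_design_matrix,
    convolved_regressors,
    fit_contrast_tmap,
    own_topography,
    predicted_topography,
)
from chalign.pipeline import fit_cohort_chains, own_topographies, predicted_topographies


def _design(tr=2.0, n_tp=60):
    runs = [
        [Block("faces", 8.0, 16.0), Block("houses", 40.0, 16.0), Block("faces", 72.0, 16.0), Block("houses", 96.0, 16.0)]
    ]
    return LocalizerDesign(categories=["faces", "houses"], runs=runs, tr_s=tr, n_timepoints=[n_tp])


def _ts(data, subject="s"):
    return TimeSeries(
        subject_id=subject, condition_id="localizer",
        run_table=[("run1", data.shape[0])], data=data,
    )


class TestDesignMatrix:
    def test_hrf_none_yields_plain_boxcar(self):
        design = _design()
        regs = convolved_regressors(design, 0, HRFSpec(model="none"))
        t = np.arange(60) * 2.0
        expected = ((t >= 8.0) & (t < 24.0)) | ((t >= 72.0) & (t < 88.0))
        np.testing.assert_allclose(regs[:, 0], expected.astype(float), atol=1e-12)

    def test_double_gamma_matches_independent_formula(self):
        hrf = HRFSpec()
        dt = 0.1
        kern = hrf.kernel(dt)
        t = np.arange(0, 32.0 + dt / 2, dt)

        def gpdf(x, shape, scale):
            with np.errstate(divide="ignore"):
                out = x ** (shape - 1) * np.exp(-x / scale) / (math.gamma(shape) * scale**shape)
            return np.nan_to_num(out)

        ref = gpdf(t, 6.0, 1.0) - gpdf(t, 16.0, 1.0) / 6.0
        ref = ref / ref.max()
        np.testing.assert_allclose(kern, ref, atol=1e-12)
        # canonical peak near 5 s (the mode of a gamma(6, 1) density)
        assert t[np.argmax(kern)] == pytest.approx(5.0, abs=0.2)
        assert kern.max() == pytest.approx(1.0)

    def test_column_layout_and_drifts(self):
        design = _design()
        X = build_design_matrix(design, 0, HRFSpec(model="none"), n_drift=2)
        assert X.shape == (60, 2 + 1 + 2)
        np.testing.assert_allclose(X[:, 2], 1.0)  # intercept after categories

    def test_category_without_blocks_warns_and_zero_column(self):
        design = _design()
        design.categories = ["faces", "houses", "tools"]
        with pytest.warns(UserWarning, match="tools"):
            regs = convolved_regressors(design, 0, HRFSpec(model="none"))
        assert (regs[:, 2] == 0).all()

    def test_block_past_run_end_raises(self):
        design = _design()
        design.runs[0].append(Block("faces", 118.0, 10.0))
        with pytest.raises(ValueError, match="past run end"):
            convolved_regressors(design, 0, HRFSpec(model="none"))

    def test_overlapping_blocks_rejected_at_construction(self):
        with pytest.raises(ValueError, match="overlap"):
            LocalizerDesign(
                categories=["a", "b"],
                runs=[[Block("a", 0.0, 10.0), Block("b", 5.0, 10.0)]],
                tr_s=2.0,
                n_timepoints=[30],
            )


class TestContrastTmap:
    def test_null_t_distribution_matches_student_t(self):
        rng = np.random.default_rng(0)
        design = _design()
        X = build_design_matrix(design, 0, HRFSpec(), n_drift=2)
        data = rng.standard_normal((60, 10_000))
        cmap = fit_contrast_tmap(_ts(data), X, "faces", design)
        dof = 60 - X.shape[1]
        stat = stats.kstest(cmap.values, stats.t(dof).cdf)
        assert stat.pvalue > 0.01

    def test_recovers_planted_effect(self):
        rng = np.random.default_rng(1)
        design = _design()
        X = build_design_matrix(design, 0, HRFSpec(), n_drift=1)
        beta = rng.standard_normal((X.shape[1], 50))
        data = X @ beta + 1e-4 * rng.standard_normal((60, 50))
        cmap = fit_contrast_tmap(_ts(data), X, "faces", design)
        # independent OLS oracle: the fitted contrast recovers the planted one,
        # and our t equals the oracle's effect / standard-error ratio
        beta_hat = np.linalg.lstsq(X, data, rcond=None)[0]
        c = np.zeros(X.shape[1])
        c[0], c[1] = 1.0, -1.0
        assert np.abs(c @ beta_hat - (beta[0] - beta[1])).max() < 1e-3
        resid = data - X @ beta_hat
        sigma2 = (resid**2).sum(axis=0) / (60 - X.shape[1])
        se = np.sqrt(sigma2 * (c @ np.linalg.inv(X.T @ X) @ c))
        np.testing.assert_allclose(cmap.values, (c @ beta_hat) / se, rtol=1e-6)

    def test_swapping_categories_exchanges_maps(self):
        rng = np.random.default_rng(2)
        design = _design()
        X = build_design_matrix(design, 0, HRFSpec(), n_drift=1)
        data = rng.standard_normal((60, 40)) + X[:, [0]] * rng.standard_normal(40)
        faces = fit_contrast_tmap(_ts(data), X, "faces", design)
        houses = fit_contrast_tmap(_ts(data), X, "houses", design)
        np.testing.assert_allclose(faces.values, -houses.values, atol=1e-10)

    def test_invariant_to_affine_data_rescaling(self):
        rng = np.random.default_rng(3)
        design = _design()
        X = build_design_matrix(design, 0, HRFSpec(), n_drift=1)
        data = rng.standard_normal((60, 30))
        t0 = fit_contrast_tmap(_ts(data), X, "faces", design).values
        t1 = fit_contrast_tmap(_ts(data * 3.7 + 11.0), X, "faces", design).values
        np.testing.assert_allclose(t0, t1, atol=1e-8)

    def test_zero_residual_variance_yields_signed_sentinel(self):
        design = _design()
        X = build_design_matrix(design, 0, HRFSpec(), n_drift=0)
        data = X @ np.array([[2.0], [-1.0], [0.0]])  # exactly in the model span
        with pytest.warns(UserWarning, match="zero residual variance"):
            cmap = fit_contrast_tmap(_ts(data), X, "faces", design)
        assert cmap.values[0] == LARGE_T

    def test_rank_deficient_design_raises(self):
        design = _design()
        X = build_design_matrix(design, 0, HRFSpec(), n_drift=0)
        X = np.hstack([X, X[:, [0]]])
        with pytest.raises(ValueError, match="rank deficient"):
            fit_contrast_tmap(_ts(np.zeros((60, 3))), X, "faces", design)

    def test_masked_vertices_are_nan(self):
        design = _design()
        X = build_design_matrix(design, 0, HRFSpec(), n_drift=1)
        rng = np.random.default_rng(4)
        mask = np.array([True, False, True])
        cmap = fit_contrast_tmap(_ts(rng.standard_normal((60, 3))), X, "faces", design, mask)
        assert np.isnan(cmap.values[1]) and np.isfinite(cmap.values[[0, 2]]).all()


class TestTopographies:
    def test_own_topography_is_mean_of_per_run_maps(self, tiny_cohort):
        runs = tiny_cohort.localizers["sub-01"]
        own = own_topography(runs, tiny_cohort.design, tiny_cohort.hrf, "faces",
                             cortex_mask=tiny_cohort.cortex_mask)
        per_run = [
            fit_contrast_tmap(
                run, build_design_matrix(tiny_cohort.design, k, tiny_cohort.hrf),
                "faces", tiny_cohort.design, tiny_cohort.cortex_mask,
            ).values
            for k, run in enumerate(runs)
        ]
        np.testing.assert_allclose(own.values, np.mean(per_run, axis=0), atol=1e-12)
        assert own.provenance == "own"

    def test_single_run_equals_plain_tmap(self, tiny_cohort):
        run = tiny_cohort.localizers["sub-02"][:1]
        own = own_topography(run, tiny_cohort.design, tiny_cohort.hrf, "scenes",
                             cortex_mask=tiny_cohort.cortex_mask)
        X = build_design_matrix(tiny_cohort.design, 0, tiny_cohort.hrf)
        single = fit_contrast_tmap(run[0], X, "scenes", tiny_cohort.design, tiny_cohort.cortex_mask)
        np.testing.assert_allclose(own.values, single.values, atol=1e-12)

    def test_self_chain_prediction_reproduces_own_map(self, tiny_cohort):
        sched = AlignmentSchedule(steps=[ScheduleStep(1, 55.0, 15.0)])
        movie = tiny_cohort.movies[("sub-01", "A")]
        chain = fit_iterative_cha(movie, movie, sched, tiny_cohort.mesh_pair)
        own = own_topography(
            tiny_cohort.localizers["sub-01"], tiny_cohort.design, tiny_cohort.hrf,
            "faces", cortex_mask=tiny_cohort.cortex_mask,
        )
        maps = []
        for k, run in enumerate(tiny_cohort.localizers["sub-01"]):
            proj = apply_chain(chain, zscore_runs(run), tiny_cohort.mesh_pair)
            X = build_design_matrix(tiny_cohort.design, k, tiny_cohort.hrf)
            maps.append(
                fit_contrast_tmap(proj, X, "faces", tiny_cohort.design, tiny_cohort.cortex_mask).values
            )
        pred = np.mean(maps, axis=0)
        assert map_pearson(own.values, pred, tiny_cohort.cortex_mask) > 0.999

    def test_identity_chains_reduce_to_cross_subject_average(self, tiny_cohort):
        aa = fit_cohort_chains(tiny_cohort, method="aa")
        pred = predicted_topography(
            "sub-01", ["sub-02", "sub-03"], aa["sub-01"], tiny_cohort.localizers,
            tiny_cohort.design, tiny_cohort.hrf, "faces", tiny_cohort.mesh_pair,
            cortex_mask=tiny_cohort.cortex_mask,
        )
        native = []
        for src in ("sub-02", "sub-03"):
            for k, run in enumerate(tiny_cohort.localizers[src]):
                X = build_design_matrix(tiny_cohort.design, k, tiny_cohort.hrf)
                native.append(
                    fit_contrast_tmap(zscore_runs(run), X, "faces", tiny_cohort.design,
                                      tiny_cohort.cortex_mask).values
                )
        mask = tiny_cohort.cortex_mask
        np.testing.assert_allclose(pred.values[mask], np.mean(native, axis=0)[mask], atol=1e-9)
        assert pred.provenance == "predicted"

    def test_source_order_does_not_change_prediction(self, tiny_cohort):
        aa = fit_cohort_chains(tiny_cohort, method="aa")
        kw = dict(
            chains=aa["sub-01"], localizers=tiny_cohort.localizers,
            design=tiny_cohort.design, hrf=tiny_cohort.hrf, category="bodies",
            mesh_pair=tiny_cohort.mesh_pair, cortex_mask=tiny_cohort.cortex_mask,
        )
        p1 = predicted_topography("sub-01", ["sub-02", "sub-03"], **kw)
        p2 = predicted_topography("sub-01", ["sub-03", "sub-02"], **kw)
        np.testing.assert_allclose(p1.values, p2.values, atol=1e-12)

    def test_target_in_sources_or_empty_sources_rejected(self, tiny_cohort):
        aa = fit_cohort_chains(tiny_cohort, method="aa")
        kw = dict(
            chains=aa["sub-01"], localizers=tiny_cohort.localizers,
            design=tiny_cohort.design, hrf=tiny_cohort.hrf, category="faces",
            mesh_pair=tiny_cohort.mesh_pair,
        )
        with pytest.raises(ValueError, match="excluded"):
            predicted_topography("sub-01", ["sub-01", "sub-02"], **kw)
        with pytest.raises(ValueError, match="empty"):
            predicted_topography("sub-01", [], **kw)

    def test_timeseries_and_contrast_map_modes_agree(self, small_cohort):
        sched = AlignmentSchedule(steps=[ScheduleStep(1, 55.0, 15.0)])
        chains = fit_cohort_chains(small_cohort, sched, "cha")
        own = own_topographies(small_cohort)
        rs = []
        for mode in ("timeseries", "contrast_map"):
            pred = predicted_topographies(small_cohort, chains, mode=mode)
            rs.append(pred)
        for key in rs[0]:
            r = map_pearson(rs[0][key], rs[1][key], small_cohort.cortex_mask)
            assert r >= 0.9, f"mode disagreement for {key}: r={r:.3f}"
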