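"""NPC assay: template fitting, segment counting, efficiency estimation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ryrflux._util import child_rng, pose_matrix
from ryrflux.locproc import reduce_localizations
from ryrflux.npc import (
    LabelingEfficiencyModel,
    NPCFitConfig,
    NPCTemplate,
    count_labeled_segments,
    detect_npc_candidates,
    estimate_labeling_efficiency,
    estimate_npc_geometry,
    fit_npc_template,
    predicted_segment_distribution,
    site_visit_rate,
)
from ryrflux.simulate import NPCSimConfig, VisitModel, make_npc_ensemble


def _subunit_df(points):
    return pd.DataFrame({"x": points[:, 0], "y": points[:, 1], "z": points[:, 2]})


class TestDetectCandidates:
    def test_two_separated_pores_found(self):
        template = NPCTemplate()
        a = template.sites()
        b = template.sites() + np.array([500.0, 0.0, 0.0])
        groups = detect_npc_candidates(_subunit_df(np.vstack([a, b])), group_eps=75.0)
        assert len(groups) == 2

    def test_small_groups_discarded(self):
        pts = np.array([[0.0, 0, 0], [1.0, 0, 0]])
        assert detect_npc_candidates(_subunit_df(pts), group_eps=75.0, min_points=6) == []

    def test_field_recovery_rate(self):
        cfg = NPCSimConfig(n_npcs=100, p_le=0.6, seed=21)
        gt, table = make_npc_ensemble(cfg)
        _, subunits = reduce_localizations(table)
        groups = detect_npc_candidates(subunits)
        pts = subunits[["x", "y", "z"]].to_numpy()
        hit = set()
        for idx in groups:
            c = pts[idx].mean(axis=0)
            hit.add(int(np.argmin(np.linalg.norm(gt.centers - c, axis=1))))
        assert len(hit) >= 95


class TestTemplateFit:
    def test_noise_free_exact_recovery(self):
        template = NPCTemplate()
        pose = pose_matrix(40.0, 25.0, 70.0)
        center = np.array([10.0, 20.0, 30.0])
        pts = template.sites() @ pose.T + center
        fit = fit_npc_template(pts, template, NPCFitConfig(free_geometry=True))
        true_axis = pose @ np.array([0.0, 0.0, 1.0])
        assert np.linalg.norm(fit.center - center) < 0.05
        assert np.degrees(np.arccos(abs(np.clip(true_axis @ fit.axis, -1, 1)))) < 0.1
        assert abs(fit.fitted_spacing - 50.0) < 0.2
        assert abs(fit.fitted_diameter - 107.0) < 0.2

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="unidentifiable"):
            fit_npc_template(np.zeros((3, 3)))

    def test_noisy_recovery_rate(self):
        """sigma = 2 nm, tilt 25 deg: axis < 5 deg and center < 2 nm in >= 95 of 100."""
        template = NPCTemplate()
        ok = 0
        for seed in range(100):
            rng = child_rng(seed, 60)
            pose = pose_matrix(rng.uniform(0, 360), 25.0, rng.uniform(0, 360))
            center = rng.uniform(-50, 50, 3)
            pts = template.sites() @ pose.T + center + rng.standard_normal((32, 3)) * 2.0
            fit = fit_npc_template(pts, template)
            true_axis = pose @ np.array([0.0, 0.0, 1.0])
            ang = np.degrees(np.arccos(abs(np.clip(true_axis @ fit.axis, -1, 1))))
            ok += (ang < 5.0) and (np.linalg.norm(fit.center - center) < 2.0)
        assert ok >= 95

    def test_equivariance_under_rigid_transform(self):
        template = NPCTemplate()
        rng = child_rng(1, 61)
        pts = template.sites() @ pose_matrix(10.0, 20.0, 30.0).T + rng.standard_normal((32, 3))
        fit1 = fit_npc_template(pts, template)
        q = pose_matrix(33.0, 12.0, 5.0)
        shift = np.array([100.0, -50.0, 25.0])
        fit2 = fit_npc_template(pts @ q.T + shift, template)
        assert np.linalg.norm(fit2.center - (q @ fit1.center + shift)) < 0.5
        moved_axis = q @ fit1.axis
        assert abs(abs(moved_axis @ fit2.axis) - 1.0) < 1e-4


class TestSegmentCounting:
    def test_full_labeling_counts_sixteen(self, clean_npc):
        cfg, gt, table = clean_npc
        pts = table[["x", "y", "z"]].to_numpy()
        fit = fit_npc_template(pts)
        labeled = count_labeled_segments(fit, pts)
        assert labeled.sum() == 16

    def test_single_ring_counts_at_most_eight(self):
        template = NPCTemplate()
        pts = template.sites()[:16]  # +z ring only
        fit = fit_npc_template(pts)
        labeled = count_labeled_segments(fit, pts)
        assert labeled.sum() <= 8

    def test_counts_match_ground_truth(self, noisy_npc_field):
        cfg, gt, table = noisy_npc_field
        _, subunits = reduce_localizations(table)
        groups = detect_npc_candidates(subunits)
        pts_all = subunits[["x", "y", "z"]].to_numpy()
        true_k = gt.labeled_segment_counts(16, 2)
        match = total = 0
        for idx in groups:
            pts = pts_all[idx]
            fit = fit_npc_template(pts)
            count_labeled_segments(fit, pts)
            k = int(np.argmin(np.linalg.norm(gt.centers - fit.center, axis=1)))
            match += fit.n_labeled_segments == true_k[k]
            total += 1
        assert match / total >= 0.95


class TestSegmentDistribution:
    def test_endpoints_are_point_masses(self):
        full = predicted_segment_distribution(1.0)
        assert full[16] == 1.0 and full[:16].sum() == 0.0
        empty = predicted_segment_distribution(0.0, kmin=0)
        assert empty[0] == 1.0

    def test_mean_at_p06(self):
        pmf = predicted_segment_distribution(0.6)
        mean = (np.arange(17) * pmf).sum()
        assert np.isclose(mean, 16 * 0.84)  # q = 1 - 0.4^2

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(
        st.floats(min_value=0.05, max_value=0.99),
        st.integers(min_value=0, max_value=8),
    )
    def test_sums_to_one(self, p, kmin):
        pmf = predicted_segment_distribution(p, kmin=kmin)
        assert np.isclose(pmf.sum(), 1.0)
        assert (pmf[:kmin] == 0.0).all()

    @pytest.mark.parametrize("p", [0.3, 0.6])
    def test_agrees_with_site_level_monte_carlo(self, p):
        rng = np.random.default_rng(123)
        n = 100_000
        sites = rng.random((n, 16, 2)) < p
        k = sites.any(axis=2).sum(axis=1)
        mc = np.bincount(k, minlength=17) / n
        tv = 0.5 * np.abs(mc - predicted_segment_distribution(p)).sum()
        assert tv < 0.01


class TestEfficiencyEstimator:
    def test_self_consistency_at_p06(self):
        hist = predicted_segment_distribution(0.6, kmin=1) * 10_000
        res = estimate_labeling_efficiency(hist, kmin=1)
        assert abs(res.p_le - 0.6) < 1e-3

    def test_boundary_all_sixteen(self):
        hist = np.zeros(17)
        hist[16] = 200
        res = estimate_labeling_efficiency(hist)
        assert res.p_le == 1.0 and res.stderr == 0.0 and res.boundary

    def test_monotone_in_histogram_shift(self):
        h1 = predicted_segment_distribution(0.4, kmin=1) * 1000
        h2 = predicted_segment_distribution(0.7, kmin=1) * 1000
        assert estimate_labeling_efficiency(h1).p_le < estimate_labeling_efficiency(h2).p_le

    def test_empty_histogram_rejected(self):
        with pytest.raises(ValueError):
            LabelingEfficiencyModel(np.zeros(17))

    def test_stderr_positive_and_small_for_large_n(self):
        hist = predicted_segment_distribution(0.5, kmin=1) * 10_000
        res = estimate_labeling_efficiency(hist)
        assert 0 < res.stderr < 0.01

    def test_summary_mentions_percent(self):
        hist = predicted_segment_distribution(0.5, kmin=1) * 500
        text = estimate_labeling_efficiency(hist).summary()
        assert "%" in text and "p_LE" in text


class TestGeometry:
    def test_spacing_discrimination(self):
        """Ensembles simulated at 50 vs 57.5 nm ring spacing separate by > 5 nm."""
        meds = {}
        for spacing in (50.0, 57.5):
            cfg = NPCSimConfig(n_npcs=25, p_le=0.6, ring_spacing=spacing, seed=33)
            gt, table = make_npc_ensemble(cfg)
            _, subunits = reduce_localizations(table)
            groups = detect_npc_candidates(subunits)
            pts_all = subunits[["x", "y", "z"]].to_numpy()
            fits = [
                fit_npc_template(pts_all[idx], fit_cfg=NPCFitConfig(free_geometry=True))
                for idx in groups
            ]
            meds[spacing] = estimate_npc_geometry(fits)["ring_spacing"]
        assert meds[57.5] - meds[50.0] > 5.0

    def test_single_fit_flagged(self):
        template = NPCTemplate()
        pts = template.sites() + child_rng(0, 62).standard_normal((32, 3))
        fit = fit_npc_template(pts, fit_cfg=NPCFitConfig(free_geometry=True))
        out = estimate_npc_geometry([fit])
        assert out.get("single_fit") and np.isnan(out["ring_spacing_se"])

    def test_no_fits_rejected(self):
        with pytest.raises(ValueError):
            estimate_npc_geometry([])


class TestVisitRate:
    def test_two_traces_per_segment_is_one_visit_per_site(self, clean_npc):
        cfg, gt, table = clean_npc
        pts = table[["x", "y", "z"]].to_numpy()
        fit = fit_npc_template(pts)
        count_labeled_segments(fit, pts, trace_counts=np.ones(len(pts), int))
        # full labeling: 2 sites/segment, 1 trace each -> 2 traces/segment
        assert site_visit_rate([fit]) == 1.0

    def test_recovers_conditional_visit_mean(self):
        cfg = NPCSimConfig(n_npcs=60, p_le=0.6, seed=55, visits=VisitModel(mean_visits=1.18))
        gt, table = make_npc_ensemble(cfg)
        _, subunits = reduce_localizations(table)
        groups = detect_npc_candidates(subunits)
        pts_all = subunits[["x", "y", "z"]].to_numpy()
        traces = subunits["n_traces"].to_numpy(int)
        fits = []
        for idx in groups:
            fit = fit_npc_template(pts_all[idx])
            count_labeled_segments(fit, pts_all[idx], trace_counts=traces[idx])
            fits.append(fit)
        rate = site_visit_rate(fits, p_le=0.6)
        assert abs(rate - 1.18) < 0.08

    def test_no_labeled_segments_rejected(self):
        with pytest.raises(ValueError):
            site_visit_rate([])
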