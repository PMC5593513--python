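"""Spherical seeds, nuisance-regressed connectivity maps, behavioral-regressor
group maps and the delta-FC / gain correlations."""

import numpy as np
import pytest

from sleepfc import synthetic_data as sd
from sleepfc.containers import default_affine
from sleepfc.seed_connectivity import (
    ROISpec,
    bonferroni_alpha,
    deltafc_behavior_correlation,
    group_seed_map,
    make_sphere_roi,
    roi_fc_map,
)

from conftest import toy_run


class TestSphereROI:
    def test_tiny_radius_keeps_single_voxel(self):
        aff = default_affine(2.0)
        roi = make_sphere_roi(ROISpec("r", (10.0, 10.0, 10.0), radius=0.5),
                              (12, 12, 12), aff)
        assert roi.sum() == 1
        assert roi[5, 5, 5]

    def test_6mm_sphere_on_2mm_grid_has_123_voxels(self):
        """Closed-ball membership: lattice points with i^2+j^2+k^2 <= 9."""
        aff = default_affine(2.0)
        roi = make_sphere_roi(ROISpec("r", (20.0, 20.0, 20.0), radius=6.0),
                              (21, 21, 21), aff)
        # brute-force lattice enumeration oracle
        count = sum(
            1
            for i in range(-3, 4)
            for j in range(-3, 4)
            for k in range(-3, 4)
            if i * i + j * j + k * k <= 9
        )
        assert count == 123
        assert roi.sum() == count

    def test_translation_equivariance(self):
        aff = default_affine(2.0)
        a = make_sphere_roi(ROISpec("r", (10, 10, 10), 6.0), (20, 20, 20), aff)
        b = make_sphere_roi(ROISpec("r", (12, 10, 10), 6.0), (20, 20, 20), aff)
        assert np.array_equal(np.roll(a, 1, axis=0), b)

    def test_center_outside_grid_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            make_sphere_roi(ROISpec("r", (-50, 0, 0), 6.0), (10, 10, 10),
                            default_affine(2.0))

    def test_bad_radius_rejected(self):
        with pytest.raises(ValueError, match="radius"):
            ROISpec("r", (0, 0, 0), radius=0.0)


class TestRoiFCMap:
    def test_self_connectivity_is_one(self):
        rng = np.random.default_rng(0)
        series = rng.normal(size=80)
        data = np.vstack([series, series, rng.normal(size=80)])
        run = toy_run(data)
        roi = np.zeros((1, 1, 3), dtype=bool)
        roi[0, 0, 0] = True
        fc = roi_fc_map(run, roi)
        assert fc.coef.ravel()[1] == pytest.approx(1.0, abs=1e-10)

    def test_matches_bruteforce_normal_equations(self):
        rng = np.random.default_rng(1)
        T = 60
        data = rng.normal(size=(3, T))
        run = toy_run(data, motion=rng.normal(size=(T, 6)))
        roi = np.zeros((1, 1, 3), dtype=bool)
        roi[0, 0, 0] = True
        fc = roi_fc_map(run, roi)
        # rebuild the design exactly as specified: roi, derivative, global,
        # 6 motion (all centered), intercept
        roi_series = data[0]
        deriv = np.concatenate([[0.0], np.diff(roi_series)])
        cols = [roi_series, deriv, data.mean(axis=0)] + list(run.motion.T)
        design = np.column_stack([c - np.mean(c) for c in cols] + [np.ones(T)])
        for v in range(3):
            b = np.linalg.solve(design.T @ design, design.T @ data[v])
            assert fc.coef.ravel()[v] == pytest.approx(b[0], abs=1e-10)

    def test_global_signal_copy_suppressed(self):
        """A voxel that is a pure copy of the injected global signal loses its
        apparent ROI coupling once nuisance regression is applied."""
        rng = np.random.default_rng(2)
        T = 200
        g = np.cumsum(rng.normal(size=T))
        g = (g - g.mean()) / g.std()
        roi_series = 0.6 * g + rng.normal(size=T)
        data = np.vstack([roi_series, g, rng.normal(size=T)])
        run = toy_run(data)
        roi = np.zeros((1, 1, 3), dtype=bool)
        roi[0, 0, 0] = True
        # without nuisance columns the global-copy voxel shows strong coupling
        run_plain = toy_run(np.vstack([roi_series, g]))
        roi_plain = np.zeros((1, 1, 2), dtype=bool)
        roi_plain[0, 0, 0] = True
        raw = roi_fc_map(run_plain, roi_plain).coef.ravel()[1]
        # with the global regressor (mean of all voxels approximates g badly
        # here, so inject masks): use wm mask holding the pure global copy
        wm = np.zeros((1, 1, 3), dtype=bool)
        wm[0, 0, 1] = True
        fc = roi_fc_map(run, roi, wm_mask=wm)
        assert abs(fc.coef.ravel()[1]) < 0.05 * abs(raw)

    def test_invariant_to_adding_nuisance_combinations(self):
        rng = np.random.default_rng(3)
        T = 80
        data = rng.normal(size=(4, T))
        motion = rng.normal(size=(T, 6))
        run = toy_run(data.copy(), motion=motion)
        roi = np.zeros((1, 1, 4), dtype=bool)
        roi[0, 0, 0] = True
        fc_a = roi_fc_map(run, roi)
        # add a fixed linear combination of motion regressors to non-ROI voxels
        contaminated = data.copy()
        bump = motion @ np.array([1.0, -2.0, 0.5, 0.0, 1.5, -1.0])
        contaminated[1:] += bump
        fc_b = roi_fc_map(toy_run(contaminated, motion=motion), roi)
        # ROI series unchanged (voxel 0 untouched); global mean shifts but the
        # shift is itself in the span of the nuisance set
        assert np.allclose(fc_a.coef.ravel()[1:], fc_b.coef.ravel()[1:],
                           atol=1e-8)

    def test_collinear_nuisance_named(self):
        rng = np.random.default_rng(4)
        T = 50
        data = rng.normal(size=(3, T))
        motion = rng.normal(size=(T, 6))
        motion[:, 5] = motion[:, 0]  # duplicate column
        run = toy_run(data, motion=motion)
        roi = np.zeros((1, 1, 3), dtype=bool)
        roi[0, 0, 0] = True
        with pytest.raises(ValueError, match="motion"):
            roi_fc_map(run, roi)


class TestGroupSeedMap:
    def test_bonferroni_for_twelve_rois(self):
        assert bonferroni_alpha(0.05, 12) == pytest.approx(0.0041667, abs=5e-8)

    def test_planted_slope_recovered(self):
        rng = np.random.default_rng(5)
        shape = (8, 8, 8)
        mask = np.ones(shape, dtype=bool)
        region = np.zeros(shape, dtype=bool)
        region[2:5, 2:5, 2:5] = True
        n = 16
        gains = rng.normal(0.03, 0.012, size=n)
        slope_true = 20.0
        msl, ctl = [], []
        for g in gains:
            base = rng.normal(0, 0.1, size=shape)
            m = base + rng.normal(0, 0.1, size=shape)
            m[region] += slope_true * g
            msl.append(m)
            ctl.append(base)
        res = group_seed_map(msl, ctl, gains, mask, n_permutations=200, seed=0)
        est = res.slope[region].mean()
        # 3 SE tolerance on the regional mean slope
        resid_sd = 0.1 * np.sqrt(2)
        se = resid_sd / (gains.std() * np.sqrt(n)) / np.sqrt(region.sum())
        assert abs(est - slope_true) < 3 * se
        assert len(res.clusters) and res.clusters["p"].min() <= 0.05

    def test_constant_gains_fall_back_to_mean_contrast(self):
        rng = np.random.default_rng(6)
        shape = (6, 6, 6)
        mask = np.ones(shape, dtype=bool)
        msl = [rng.normal(1.0, 0.1, size=shape) for _ in range(8)]
        ctl = [rng.normal(0.0, 0.1, size=shape) for _ in range(8)]
        with pytest.warns(RuntimeWarning, match="constant"):
            res = group_seed_map(msl, ctl, np.full(8, 0.5), mask,
                                 n_permutations=50, seed=0)
        assert res.degenerate_gains
        assert len(res.clusters) >= 1

    def test_gain_length_mismatch_rejected(self):
        maps = [np.zeros((4, 4, 4))] * 5
        with pytest.raises(ValueError, match="gains length"):
            group_seed_map(maps, maps, np.zeros(4), np.ones((4, 4, 4), bool))


class TestDeltaFC:
    @staticmethod
    def fc_dict(delta_by_subject, other=0.0):
        out = {}
        for s, d in delta_by_subject.items():
            out[(s, "RS3")] = np.full((3, 3, 3), other + d)
            out[(s, "RS1")] = np.full((3, 3, 3), other)
        return out

    def test_perfect_correlation_when_delta_equals_gains(self):
        subs = [f"s{i}" for i in range(8)]
        gains = {s: 0.01 * (i + 1) for i, s in enumerate(subs)}
        fc = self.fc_dict({s: gains[s] for s in subs})
        cluster = np.ones((3, 3, 3), dtype=bool)
        r, p = deltafc_behavior_correlation(fc, cluster, gains, ("RS3", "RS1"))
        assert r == pytest.approx(1.0)

    def test_sign_flip_antisymmetry(self):
        rng = np.random.default_rng(7)
        subs = [f"s{i}" for i in range(10)]
        deltas = {s: rng.normal() for s in subs}
        gains = {s: rng.normal() for s in subs}
        fc = self.fc_dict(deltas)
        cluster = np.ones((3, 3, 3), dtype=bool)
        r_pos, _ = deltafc_behavior_correlation(fc, cluster, gains,
                                                ("RS3", "RS1"))
        flipped = {s: -g for s, g in gains.items()}
        r_neg, _ = deltafc_behavior_correlation(fc, cluster, flipped,
                                                ("RS3", "RS1"))
        assert r_neg == pytest.approx(-r_pos, abs=1e-12)

    def test_generator_rho_recovered(self):
        g, b = sd.draw_coupling_gains(200, rho=0.69, seed=3)
        subs = [f"s{i}" for i in range(200)]
        fc = self.fc_dict({s: g[i] for i, s in enumerate(subs)})
        gains = {s: b[i] for i, s in enumerate(subs)}
        cluster = np.ones((3, 3, 3), dtype=bool)
        r, _ = deltafc_behavior_correlation(fc, cluster, gains, ("RS3", "RS1"))
        assert abs(r - 0.69) < 0.1

    def test_missing_contrast_runs_listed(self):
        fc = self.fc_dict({"s0": 0.1, "s1": 0.2})
        del fc[("s1", "RS1")]
        gains = {"s0": 0.1, "s1": 0.2, "s2": 0.3, "s3": 0.4}
        with pytest.raises(ValueError, match="missing runs"):
            deltafc_behavior_correlation(fc, np.ones((3, 3, 3), bool), gains,
                                         ("RS3", "RS1"))
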