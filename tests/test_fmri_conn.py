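import numpy as np
import pytest

from threatflow import fmri_conn as fc
from threatflow.stats_core import R_CLIP


def tiny_subject(rng, n_vox=5, n_frames=40):
    mask = np.zeros((5, 1, 1), bool)
    mask[:n_vox] = True
    data = rng.normal(size=(n_vox, n_frames))
    labels = np.array(["safe", "threat"] * (n_frames // 2))
    return fc.SubjectTimeseries(
        data=data, mask=mask, labels=labels,
        censor=np.zeros(n_frames, bool),
        motion=np.zeros((n_frames, 6)), run_index=np.zeros(n_frames, int),
    )


class TestCensoring:
    def test_direct_rule(self):
        motion = np.zeros((3, 6))
        motion[1, 0] = 0.6  # enorm jumps 0.6 then drops 0.6
        motion[2, 0] = 0.4
        flags = fc.censor_frames(motion, threshold=0.5)
        assert flags.tolist() == [False, True, False]

    def test_all_zero_motion(self):
        assert not fc.censor_frames(np.zeros((10, 6))).any()

    def test_zero_threshold_flags_any_motion(self):
        motion = np.cumsum(np.full((5, 6), 0.01), axis=0)
        flags = fc.censor_frames(motion, threshold=0.0)
        assert flags[1:].all() and not flags[0]

    def test_shock_censor_ten_frames(self):
        labels = np.array(["threat"] * 200)
        flags, counts = fc.shock_censor(labels, np.array([100]))
        assert np.flatnonzero(flags).tolist() == list(range(100, 110))
        assert counts["threat"] == 10

    def test_shock_censor_run_boundary(self):
        labels = np.array(["threat"] * 20)
        run_index = np.array([0] * 10 + [1] * 10)
        flags, _ = fc.shock_censor(labels, np.array([7]), run_index)
        assert np.flatnonzero(flags).tolist() == [7, 8, 9]

    def test_no_shocks_noop(self):
        base = np.zeros(10, bool)
        base[3] = True
        flags, counts = fc.shock_censor(
            np.array(["safe"] * 10), np.array([], int), base_censor=base
        )
        assert np.array_equal(flags, base)
        assert counts["safe"] == 0


class TestMatchedMotionCensor:
    def test_nearest_match(self):
        enorm = np.array([0.2, 0.4, 0.19, 0.41, 0.9])
        picked = fc.matched_motion_censor(
            np.array([0, 1]), np.array([2, 3, 4]), enorm
        )
        assert sorted(picked.tolist()) == [2, 3]

    def test_identical_pools_exact(self):
        enorm = np.array([0.1, 0.2, 0.3, 0.1, 0.2, 0.3])
        picked = fc.matched_motion_censor(
            np.array([0, 1, 2]), np.array([3, 4, 5]), enorm
        )
        assert np.abs(enorm[picked] - enorm[:3]).sum() == pytest.approx(0.0)

    def test_beats_random_selection(self, rng):
        enorm = np.concatenate([rng.uniform(0, 1, 30), rng.uniform(0, 2, 60)])
        threat = np.arange(30)
        pool = np.arange(30, 90)
        picked = fc.matched_motion_censor(threat, pool, enorm)
        greedy_cost = np.abs(
            np.sort(enorm[picked]) - np.sort(enorm[threat])
        ).mean()
        rand_costs = []
        for _ in range(100):
            sel = rng.choice(pool, size=30, replace=False)
            rand_costs.append(
                np.abs(np.sort(enorm[sel]) - np.sort(enorm[threat])).mean()
            )
        assert greedy_cost <= min(rand_costs) + 1e-12

    def test_insufficient_pool_error(self):
        with pytest.raises(ValueError):
            fc.matched_motion_censor(
                np.array([0, 1]), np.array([2]), np.array([0.1, 0.2, 0.3])
            )


class TestNuisanceRegress:
    def _subject(self, data, n_frames, motion=None):
        mask = np.ones((data.shape[0], 1, 1), bool)
        if motion is None:
            motion = (
                np.random.default_rng(7)
                .normal(size=(n_frames, 6))
                .cumsum(axis=0)
                * 0.01
            )
        return fc.SubjectTimeseries(
            data=data, mask=mask,
            labels=np.array(["safe"] * n_frames),
            censor=np.zeros(n_frames, bool),
            motion=motion,
            run_index=np.zeros(n_frames, int),
        )

    def test_cubic_trend_removed(self):
        n = 100
        x = np.linspace(-1, 1, n)
        data = (0.3 + x - 2 * x**2 + 0.5 * x**3)[None, :]
        resid = fc.nuisance_regress(self._subject(data, n)).data
        assert np.abs(resid).max() < 1e-8

    def test_variance_reduced(self, rng):
        n = 80
        data = rng.normal(size=(4, n))
        resid = fc.nuisance_regress(self._subject(data, n)).data
        assert (resid.var(axis=1) <= data.var(axis=1) + 1e-12).all()

    def test_motion_copy_removed(self):
        n = 60
        sub = self._subject(np.zeros((1, n)), n)
        sub.data = sub.motion[:, 2][None, :].copy()
        resid = fc.nuisance_regress(sub).data
        assert np.abs(resid).max() < 1e-8

    def test_rank_deficiency_error(self):
        n = 50
        motion = np.tile(np.linspace(0, 1, n)[:, None], (1, 6))  # rank 1
        with pytest.raises(ValueError, match="rank"):
            fc.nuisance_regress(self._subject(np.zeros((1, n)), n, motion))


class TestSmoothing:
    def test_constant_preserved(self):
        mask = np.zeros((8, 8, 8), bool)
        mask[2:6, 2:6, 2:6] = True
        vol = np.where(mask, 3.5, 0.0)
        out = fc.smooth_within_mask(vol, mask, fwhm_mm=6.0, voxel_size_mm=3.0)
        assert np.allclose(out[mask], 3.5, atol=1e-10)

    def test_impulse_matches_direct_kernel_oracle(self):
        mask = np.zeros((9, 9, 9), bool)
        mask[1:8, 1:8, 1:8] = True
        vol = np.zeros((9, 9, 9))
        vol[4, 4, 4] = 1.0
        fwhm, vox = 6.0, 3.0
        out = fc.smooth_within_mask(vol, mask, fwhm_mm=fwhm, voxel_size_mm=vox)
        # direct renormalized-kernel computation with explicit loops
        sigma = fwhm / (2 * np.sqrt(2 * np.log(2))) / vox
        coords = np.argwhere(mask)
        oracle = np.zeros_like(vol)
        for i, j, k in coords:
            dist2 = (i - 4) ** 2 + (j - 4) ** 2 + (k - 4) ** 2
            num = np.exp(-dist2 / (2 * sigma**2))
            den = sum(
                np.exp(
                    -((i - a) ** 2 + (j - b) ** 2 + (k - c) ** 2)
                    / (2 * sigma**2)
                )
                for a, b, c in coords
            )
            oracle[i, j, k] = num / den
        # scipy's truncated separable kernel vs the exact kernel: loose bound
        assert np.allclose(out[mask], oracle[mask], atol=2e-3)
        assert out[mask].sum() == pytest.approx(1.0, abs=0.02)

    def test_zero_fwhm_identity(self, rng):
        mask = np.ones((4, 4, 4), bool)
        vol = rng.normal(size=(4, 4, 4))
        out = fc.smooth_within_mask(vol, mask, fwhm_mm=0.0)
        assert np.array_equal(out, vol)

    def test_no_bleed_outside_mask(self, rng):
        mask = np.zeros((8, 8, 8), bool)
        mask[:4] = True
        vol = rng.normal(size=(8, 8, 8))
        out = fc.smooth_within_mask(vol, mask, fwhm_mm=6.0)
        assert np.all(out[~mask] == 0.0)


class TestGbc:
    def test_brute_force_oracle(self, rng):
        ts = tiny_subject(rng)
        cmap = fc.gbc_map(ts, "safe")
        frames = ts.condition_frames("safe")
        block = ts.data[:, frames]
        n = block.shape[0]
        oracle = np.empty(n)
        for v in range(n):
            zs = []
            for w in range(n):
                if w == v:
                    continue
                r = np.corrcoef(block[v], block[w])[0, 1]
                zs.append(np.arctanh(np.clip(r, -R_CLIP, R_CLIP)))
            oracle[v] = np.mean(zs)
        assert np.allclose(cmap.values, oracle, atol=1e-12)

    def test_orthogonal_sinusoids_zero(self):
        n = 40
        t = np.arange(n)
        data = np.vstack([np.sin(2 * np.pi * t / n), np.cos(2 * np.pi * t / n)])
        mask = np.ones((2, 1, 1), bool)
        ts = fc.SubjectTimeseries(
            data=data, mask=mask, labels=np.array(["safe"] * n),
            censor=np.zeros(n, bool), motion=np.zeros((n, 6)),
            run_index=np.zeros(n, int),
        )
        cmap = fc.gbc_map(ts, "safe")
        assert np.allclose(cmap.values, 0.0, atol=1e-10)

    def test_constant_voxel_error(self, rng):
        ts = tiny_subject(rng)
        ts.data[2] = 7.0
        with pytest.raises(ValueError, match="voxel"):
            fc.gbc_map(ts, "safe")

    def test_too_few_frames_error(self, rng):
        ts = tiny_subject(rng)
        ts.censor[:] = True
        with pytest.raises(ValueError, match="uncensored"):
            fc.gbc_map(ts, "safe")

    def test_affine_invariance(self, rng):
        ts = tiny_subject(rng)
        a = fc.gbc_map(ts, "safe").values
        scale = rng.uniform(0.5, 2.0, size=(ts.data.shape[0], 1))
        shift = rng.normal(size=(ts.data.shape[0], 1))
        ts.data = ts.data * scale + shift
        b = fc.gbc_map(ts, "safe").values
        assert np.allclose(a, b, atol=1e-10)

    def test_condition_symmetry(self, rng):
        ts = tiny_subject(rng)
        a_safe = fc.gbc_map(ts, "safe").values
        a_threat = fc.gbc_map(ts, "threat").values
        swapped = np.where(ts.labels == "safe", "threat", "safe")
        ts.labels = swapped
        assert np.allclose(fc.gbc_map(ts, "threat").values, a_safe)
        assert np.allclose(fc.gbc_map(ts, "safe").values, a_threat)

    def test_whole_brain_mean(self, rng):
        ts = tiny_subject(rng)
        cmap = fc.gbc_map(ts, "safe")
        assert fc.whole_brain_gbc(cmap) == pytest.approx(cmap.values.mean())
        cmap.values = np.full_like(cmap.values, 0.37)
        assert fc.whole_brain_gbc(cmap) == pytest.approx(0.37)


class TestSeedConnectivity:
    def test_single_voxel_roi_self_correlation(self, rng):
        ts = tiny_subject(rng)
        cmap = fc.seed_connectivity(ts, np.array([1]), "safe")
        assert cmap.values[1] == pytest.approx(np.arctanh(R_CLIP))
        assert cmap.roi_flags[1] and cmap.roi_flags.sum() == 1

    def test_brute_force_oracle(self, rng):
        ts = tiny_subject(rng)
        roi = np.array([0, 2])
        cmap = fc.seed_connectivity(ts, roi, "threat")
        frames = ts.condition_frames("threat")
        seed = ts.data[roi][:, frames].mean(axis=0)
        for v in range(5):
            r = np.corrcoef(seed, ts.data[v, frames])[0, 1]
            assert cmap.values[v] == pytest.approx(
                np.arctanh(np.clip(r, -R_CLIP, R_CLIP)), abs=1e-12
            )

    def test_orthogonal_seed_zero(self):
        n = 40
        t = np.arange(n)
        data = np.vstack([np.sin(2 * np.pi * t / n), np.cos(2 * np.pi * t / n)])
        mask = np.ones((2, 1, 1), bool)
        ts = fc.SubjectTimeseries(
            data=data, mask=mask, labels=np.array(["safe"] * n),
            censor=np.zeros(n, bool), motion=np.zeros((n, 6)),
            run_index=np.zeros(n, int),
        )
        cmap = fc.seed_connectivity(ts, np.array([0]), "safe")
        assert cmap.values[1] == pytest.approx(0.0, abs=1e-10)

    def test_empty_roi_error(self, rng):
        with pytest.raises(ValueError, match="ROI"):
            fc.seed_connectivity(tiny_subject(rng), np.array([], int), "safe")


class TestHubRecoverySmall:
    def test_peak_t_in_hub(self, small_fmri_cohort):
        _, subjects, truth = small_fmri_cohort
        diffs = []
        for ts in subjects:
            g_s = fc.gbc_map(ts, "safe").values
            g_t = fc.gbc_map(ts, "threat").values
            diffs.append(g_t - g_s)
        diffs = np.array(diffs)
        t_map = diffs.mean(axis=0) / (
            diffs.std(axis=0, ddof=1) / np.sqrt(len(subjects))
        )
        assert int(np.argmax(t_map)) in set(truth.hub_voxels.tolist())
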