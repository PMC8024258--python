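"""HRF kernel, design matrix construction, and first-level OLS fitting."""

import numpy as np
import pandas as pd
import pytest

from grapholearn.core import BoldRun
from grapholearn.design import CollinearityError, build_design, drift_basis, temporal_smooth
from grapholearn.firstlevel import FirstLevelGLM, smooth_volume, voxel_sizes_mm
from grapholearn.hrf import HRFSpec, canonical_hrf, hrf_kernel
from grapholearn.rdm import motor_rdm
from grapholearn.synth import box_roi, generate_bold, generate_stimuli, plant_patterns


class TestCanonicalHRF:
    def test_zero_at_origin(self):
        _, h = canonical_hrf(HRFSpec(), tr_seconds=2.0)
        assert h[0] == 0.0

    def test_peak_near_peak_delay(self):
        t, h = hrf_kernel(HRFSpec(), dt=0.01)
        assert abs(t[np.argmax(h)] - 6.0) <= 0.01

    def test_undershoot_window_is_negative(self):
        t, h = hrf_kernel(HRFSpec(), dt=0.01)
        window = h[(t >= 12) & (t <= 28)]
        assert window.min() < 0

    def test_peak_normalised(self):
        _, h = hrf_kernel(HRFSpec(), dt=0.1)
        assert np.max(np.abs(h)) == pytest.approx(1.0)


class TestDesign:
    def test_drift_basis_count_formula(self):
        for n_vol, tr, hp in [(100, 3.5, 120.0), (60, 2.0, 120.0), (200, 1.0, 100.0)]:
            expected = int(np.floor(2 * n_vol * tr / hp)) + 1
            assert drift_basis(n_vol, tr, hp).shape[1] == expected

    def test_no_events_gives_only_nuisance(self):
        events = pd.DataFrame(columns=["onset_s", "duration_s", "condition"])
        motion = np.random.default_rng(0).normal(size=(50, 6))
        d = build_design(events, 2.0, 50, HRFSpec(), motion=motion)
        assert d.task_columns == []
        assert "intercept" in d.columns
        assert sum(c.startswith("motion") for c in d.columns) == 6

    def test_identical_event_trains_raise_collinearity(self):
        events = pd.DataFrame(
            {
                "onset_s": [0.0, 10.0, 0.0, 10.0],
                "duration_s": 0.0,
                "word_id": ["wa", "wa", "wb", "wb"],
            }
        )
        with pytest.raises(CollinearityError) as err:
            build_design(events, 2.0, 40, HRFSpec(), per="word_id")
        assert "wb" in str(err.value)

    def test_temporal_smoothing_preserves_constants(self):
        const = np.ones((80, 1))
        assert np.allclose(temporal_smooth(const, 4.0, 2.0), const)

    def test_events_beyond_run_rejected(self):
        events = pd.DataFrame(
            {"onset_s": [500.0], "duration_s": [0.0], "condition": ["writing"]}
        )
        with pytest.raises(ValueError):
            build_design(events, 2.0, 50, HRFSpec())


@pytest.fixture(scope="module")
def noiseless_run():
    stim, _ = generate_stimuli(n_words=6, seed=1)
    shape = (7, 7, 7)
    affine = np.diag([2.0, 2.0, 2.0, 1.0])
    rois = {"planted": box_roi(shape, (1, 1, 1), (3, 3, 3))}
    pat = plant_patterns(motor_rdm(stim), 27, fidelity=1.0, seed=2)
    run = generate_bold(
        stim, {"planted": pat}, rois, affine, n_reps=2, noise_sd=0.0, seed=3
    )
    events = run.events.assign(word_period=run.events.word_id + "@" + run.events.period)
    design = build_design(
        events, run.tr_seconds, run.n_volumes, HRFSpec(), motion=run.motion, per="word_period"
    )
    return stim, rois, pat, run, design


class TestFirstLevelGLM:
    def test_noiseless_recovery_of_planted_patterns(self, noiseless_run):
        stim, rois, pat, run, design = noiseless_run
        res = FirstLevelGLM(run, design).fit()
        recovered = np.stack(
            [res.beta_map(f"{w}@study")[rois["planted"]] for w in sorted(stim.word_ids)]
        )
        assert np.max(np.abs(recovered - pat.values)) < 1e-8

    def test_scaling_equivariance(self, noiseless_run):
        stim, rois, pat, run, design = noiseless_run
        scaled = BoldRun(
            data=3.0 * run.data,
            affine=run.affine,
            tr_seconds=run.tr_seconds,
            events=run.events,
            motion=run.motion,
        )
        a = FirstLevelGLM(run, design).fit()
        b = FirstLevelGLM(scaled, design).fit()
        name = f"{stim[0].word_id}@study"
        assert np.allclose(b.beta_map(name), 3.0 * a.beta_map(name), atol=1e-9)

    def test_constant_shift_moves_only_intercept(self, noiseless_run):
        stim, rois, pat, run, design = noiseless_run
        shifted = BoldRun(
            data=run.data + 7.0,
            affine=run.affine,
            tr_seconds=run.tr_seconds,
            events=run.events,
            motion=run.motion,
        )
        a = FirstLevelGLM(run, design).fit()
        b = FirstLevelGLM(shifted, design).fit()
        for name in design.columns:
            if name == "intercept":
                assert np.allclose(b.beta_map(name) - a.beta_map(name), 7.0, atol=1e-8)
            else:
                assert np.allclose(b.beta_map(name), a.beta_map(name), atol=1e-8)

    def test_voxel_order_independence(self, noiseless_run):
        stim, rois, pat, run, design = noiseless_run
        name = f"{stim[1].word_id}@study"
        full = FirstLevelGLM(run, design).fit().beta_map(name)
        half_mask = np.zeros(run.data.shape[:3], dtype=bool)
        half_mask[::2] = True
        half = FirstLevelGLM(run, design, mask=half_mask).fit().beta_map(name)
        assert np.allclose(half[half_mask], full[half_mask])

    def test_beta_variance_matches_ols_theory(self, rng):
        # orthogonal design, white noise: var(beta) ~ sigma^2 (X'X)^-1 diagonal
        t = 60
        x = np.column_stack([np.ones(t), np.sin(2 * np.pi * np.arange(t) / 10)])
        sigma = 1.5
        theo = sigma**2 * np.diag(np.linalg.inv(x.T @ x))
        betas = []
        for _ in range(200):
            y = x @ np.array([1.0, 2.0]) + rng.normal(0, sigma, t)
            betas.append(np.linalg.lstsq(x, y, rcond=None)[0])
        emp = np.var(np.asarray(betas), axis=0, ddof=1)
        assert np.all(np.abs(emp - theo) / theo < 0.5)


class TestSmoothVolume:
    def test_zero_fwhm_is_identity(self, rng):
        vol = rng.random((6, 6, 6))
        affine = np.diag([2.0, 2.0, 2.0, 1.0])
        assert np.array_equal(smooth_volume(vol, affine, 0.0), vol)

    def test_sum_preserved_for_interior_impulse(self):
        vol = np.zeros((31, 31, 31))
        vol[15, 15, 15] = 1.0
        affine = np.diag([2.0, 2.0, 2.0, 1.0])
        out = smooth_volume(vol, affine, 5.0)
        assert out.sum() == pytest.approx(1.0, rel=1e-6)

    def test_impulse_response_matches_analytic_gaussian(self):
        vol = np.zeros((41, 41, 41))
        vol[20, 20, 20] = 1.0
        affine = np.diag([2.0, 2.0, 2.0, 1.0])
        fwhm = 6.0
        out = smooth_volume(vol, affine, fwhm)
        sigma_vox = fwhm / (2 * np.sqrt(2 * np.log(2))) / 2.0
        grid = np.arange(41) - 20
        g1 = np.exp(-(grid**2) / (2 * sigma_vox**2))
        g1 /= g1.sum()
        analytic = g1[:, None, None] * g1[None, :, None] * g1[None, None, :]
        rms = np.sqrt(np.mean((out - analytic) ** 2))
        assert rms < 1e-6

    def test_sheared_affine_rejected(self):
        affine = np.eye(4)
        affine[0, 1] = 0.5
        with pytest.raises(ValueError):
            voxel_sizes_mm(affine)
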