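"""Neural RDMs, RDM comparison, ROI RSA bookkeeping, searchlight."""

import numpy as np
import pytest
from scipy import stats

from grapholearn._utils import FISHER_EPS
from grapholearn.rdm import motor_rdm, semantic_rdm, syllabic_rdm
from grapholearn.rsa import neural_rdm, rdm_similarity, roi_rsa, rsa_anova, searchlight_rsa
from grapholearn.synth import generate_stimuli, gray_matter_map, plant_patterns


class TestNeuralRDM:
    def test_duplicated_row_gives_zero(self):
        pat = np.array([[1.0, 2.0, 5.0], [1.0, 2.0, 5.0], [3.0, 1.0, 2.0]])
        rdm = neural_rdm(pat)
        assert rdm.values[0, 1] == pytest.approx(0.0)

    def test_rank_reversal_gives_two(self):
        pat = np.array([[1.0, 2.0, 3.0], [3.0, 2.0, 1.0]])
        assert neural_rdm(pat).values[0, 1] == pytest.approx(2.0)

    def test_hand_computed_spearman(self):
        # ranks (1,2,3) vs (1,3,2): rho = 0.5 so dissimilarity 0.5
        pat = np.array([[1.0, 2.0, 3.0], [1.0, 3.0, 2.0]])
        assert neural_rdm(pat).values[0, 1] == pytest.approx(0.5)

    def test_constant_row_names_the_word(self):
        pat = np.array([[1.0, 1.0, 1.0], [3.0, 1.0, 2.0]])
        with pytest.raises(ValueError, match="w0"):
            neural_rdm(pat, word_ids=["w0", "w1"])

    def test_monotone_transform_invariance(self, rng):
        pat = rng.normal(size=(6, 40))
        a = neural_rdm(pat)
        b = neural_rdm(np.exp(2.0 * pat))  # strictly monotone, rowwise-uniform
        assert np.allclose(a.values, b.values)


class TestRdmSimilarity:
    def test_self_similarity_capped_z(self, small_stimuli):
        rdm = motor_rdm(small_stimuli[0])
        rho, z = rdm_similarity(
            neural_rdm(plant_patterns(rdm, 500, seed=0)), rdm
        )
        same_rho, same_z = rdm_similarity(rdm, rdm)
        assert same_rho == pytest.approx(1.0)
        assert same_z == pytest.approx(np.arctanh(1 - FISHER_EPS))

    def test_fisher_transform_closed_form(self, small_stimuli):
        stim, tax = small_stimuli
        rho, z = rdm_similarity(
            neural_rdm(plant_patterns(motor_rdm(stim), 80, fidelity=0.7, seed=1)),
            motor_rdm(stim),
        )
        assert z == pytest.approx(np.arctanh(rho))
        assert np.arctanh(0.5) == pytest.approx(0.5493, abs=1e-4)

    def test_only_lower_triangle_enters(self, small_stimuli):
        # the result must be a pure function of the two lower triangles
        stim, _ = small_stimuli
        theo = motor_rdm(stim)
        neural = neural_rdm(plant_patterns(theo, 60, seed=2))
        rho, _ = rdm_similarity(neural, theo)
        manual = stats.spearmanr(
            neural.values[np.tril_indices(len(theo), k=-1)],
            theo.values[np.tril_indices(len(theo), k=-1)],
        ).statistic
        assert rho == pytest.approx(float(manual), abs=1e-12)


@pytest.fixture(scope="module")
def rsa_inputs():
    stim, tax = generate_stimuli(n_words=8, seed=21)
    rdms = {
        "motor": motor_rdm(stim),
        "syllabic": syllabic_rdm(stim),
        "semantic": semantic_rdm(stim, tax),
    }
    shape = (6, 6, 6)
    roi = np.zeros(shape, dtype=bool)
    roi[1:4, 1:4, 1:4] = True
    word_ids = sorted(stim.word_ids)
    betas = {}
    groups = {}
    participants = [("b1", "blind"), ("b2", "blind"), ("s1", "sighted"), ("s2", "sighted")]
    for i, (p, g) in enumerate(participants):
        groups[p] = g
        for j, condition in enumerate(("writing", "no-writing")):
            for k, period in enumerate(("study", "test")):
                pat = plant_patterns(rdms["motor"], int(roi.sum()), fidelity=0.8,
                                     seed=100 * i + 10 * j + k)
                vols = np.zeros((len(word_ids),) + shape)
                vols[:, roi] = pat.values
                rng = np.random.default_rng(i + 50 * j + 900 * k)
                vols[:, ~roi] = rng.normal(size=(len(word_ids), int((~roi).sum())))
                betas[(p, condition, period)] = vols
    return stim, rdms, roi, word_ids, betas, groups


class TestRoiRSA:
    def test_bookkeeping_row_count(self, rsa_inputs):
        stim, rdms, roi, word_ids, betas, groups = rsa_inputs
        table = roi_rsa(betas, groups, {"roi1": roi}, rdms, word_ids)
        # participants x conditions x periods x rois x rdm levels
        assert len(table) == 4 * 2 * 2 * 1 * 3

    def test_planted_rdm_wins(self, rsa_inputs):
        stim, rdms, roi, word_ids, betas, groups = rsa_inputs
        table = roi_rsa(betas, groups, {"roi1": roi}, rdms, word_ids)
        mean_z = table.groupby("rdm_level")["z"].mean()
        assert mean_z["motor"] > mean_z["syllabic"]
        assert mean_z["motor"] > mean_z["semantic"]

    def test_small_roi_skipped_with_warning(self, rsa_inputs):
        stim, rdms, roi, word_ids, betas, groups = rsa_inputs
        tiny = np.zeros_like(roi)
        tiny[0, 0, 0] = True
        with pytest.warns(UserWarning, match="skipped"):
            table = roi_rsa(betas, groups, {"tiny": tiny}, rdms, word_ids)
        assert table.empty

    def test_label_shuffle_destroys_effect(self, rsa_inputs):
        stim, rdms, roi, word_ids, betas, groups = rsa_inputs
        key = ("b1", "writing", "study")
        pat = betas[key][:, roi]
        rng = np.random.default_rng(17)
        zs = []
        for _ in range(100):
            perm = rng.permutation(len(word_ids))
            _, z = rdm_similarity(neural_rdm(pat[perm], word_ids), rdms["motor"])
            zs.append(z)
        assert abs(np.mean(zs)) < 0.05


class TestRsaAnova:
    def test_location_shift_only_moves_intercept(self, rsa_inputs):
        stim, rdms, roi, word_ids, betas, groups = rsa_inputs
        table = roi_rsa(betas, groups, {"roi1": roi}, rdms, word_ids)
        a = rsa_anova(table)
        b = rsa_anova(table.assign(z=table["z"] + 1.0))
        for eff in ("condition", "group", "condition:group"):
            fa = a[a.effect == eff]["F"].to_numpy()
            fb = b[b.effect == eff]["F"].to_numpy()
            assert np.allclose(fa, fb)
        assert not np.allclose(
            a[a.effect == "intercept"]["F"], b[b.effect == "intercept"]["F"]
        )

    def test_crossover_interaction_detected(self):
        # z = +d for blind-writing, -d for sighted-writing on top of noise
        rng = np.random.default_rng(23)
        rows = []
        d = 1.0
        for i in range(16):
            grp = "blind" if i < 8 else "sighted"
            sgn = 1.0 if grp == "blind" else -1.0
            for condition, c in (("writing", 1.0), ("no-writing", -1.0)):
                rows.append(
                    {
                        "participant": f"p{i}",
                        "group": grp,
                        "condition": condition,
                        "period": "study",
                        "roi": "roi1",
                        "rdm_level": "syllabic",
                        "z": sgn * c * d / 2 + rng.normal(0, 1.0),
                    }
                )
        import pandas as pd

        out = rsa_anova(pd.DataFrame(rows))
        inter = out[(out.effect == "condition:group")].iloc[0]
        assert inter["p"] < 0.05


class TestSearchlight:
    def test_gm_threshold_too_high_is_diagnosed(self, rsa_inputs):
        stim, rdms, roi, word_ids, betas, groups = rsa_inputs
        gm = gray_matter_map((6, 6, 6)) * 0.5
        with pytest.raises(ValueError, match="no searchlight centres"):
            searchlight_rsa(betas[("b1", "writing", "study")], gm, rdms["motor"],
                            gm_threshold=1.0)

    def test_planted_sphere_is_localised(self):
        # full 40-word list: the rank geometry is stable enough to localise
        # the informative sphere to within one voxel in most draws
        stim, _ = generate_stimuli(n_words=40, seed=30)
        target = motor_rdm(stim)
        shape = (9, 9, 9)
        gm = np.ones(shape)
        center = (4, 4, 4)
        from grapholearn.rois import sphere_offsets

        offs = sphere_offsets(2.0) + np.array(center)
        hits = 0
        for s in range(3):
            rng = np.random.default_rng(31 + s)
            vols = rng.normal(size=(40,) + shape)
            pat = plant_patterns(target, len(offs), fidelity=1.0, seed=32 + s)
            vols[:, offs[:, 0], offs[:, 1], offs[:, 2]] += 3.0 * pat.values
            r_map, z_map = searchlight_rsa(vols, gm, target, radius_voxels=2.0)
            peak = np.unravel_index(np.nanargmax(r_map), shape)
            hits += np.linalg.norm(np.array(peak) - np.array(center)) <= 1.0
        assert hits >= 2
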