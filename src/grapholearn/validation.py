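"""Ground-truth recovery and calibration experiments for the whole pipeline.

Each function runs a self-contained simulation experiment against the
synthetic generator's planted truth and returns the measured quantity: the
rate at which the planted RDM wins the representational comparison, how often
the searchlight localises an informative sphere, the power and calibration of
the second-level ANOVAs, PPI detection and null rejection rates, and the
type-I error of the aligned-rank-transform ANOVA.  The problem sizes default
to the study's dimensions (40-word lists, 12 + 18 participants) with small
grids so everything runs on one CPU in minutes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ._utils import rng_for
from .art import art_effects_array, inverse_transform
from .core import RDM
from .design import build_design
from .firstlevel import FirstLevelGLM
from .hrf import HRFSpec
from .mixed_anova import MixedAnova
from .rdm import mantel_test, motor_rdm, semantic_rdm, syllabic_rdm
from .rois import sphere_offsets
from .rsa import neural_rdm, rdm_similarity, rsa_anova, searchlight_rsa
from .synth import (
    GroundTruth,
    box_roi,
    generate_bold,
    generate_stimuli,
    plant_patterns,
)


def rdm_selectivity_rate(
    n_seeds: int = 100,
    n_words: int = 40,
    n_voxels: int = 100,
    fidelity: float = 1.0,
    noise_sd: float = 0.1,
    seed: int = 0,
) -> float:
    """How often the planted RDM out-scores the two non-planted RDMs.

    Patterns encode the motor RDM at the given fidelity with measurement
    noise (noise_sd 0.1 on unit-variance signal = SNR 10); the winner is the
    RDM with the largest Fisher-z correlation to the neural RDM.
    """
    stimuli, taxonomy = generate_stimuli(n_words=n_words, seed=seed)
    rdms = {
        "motor": motor_rdm(stimuli),
        "syllabic": syllabic_rdm(stimuli),
        "semantic": semantic_rdm(stimuli, taxonomy),
    }
    wins = 0
    base = rng_for(seed, "selectivity")
    for _ in range(n_seeds):
        s = int(base.integers(2**31))
        pat = plant_patterns(rdms["motor"], n_voxels, fidelity=fidelity, noise_sd=noise_sd, seed=s)
        nrdm = neural_rdm(pat)
        zs = {lvl: rdm_similarity(nrdm, r)[1] for lvl, r in rdms.items()}
        wins += zs["motor"] > max(zs["syllabic"], zs["semantic"])
    return wins / n_seeds


def searchlight_localization_rate(
    n_seeds: int = 100,
    n_words: int = 40,
    n_participants: int = 6,
    shape: tuple[int, int, int] = (7, 7, 7),
    amplitude: float = 3.0,
    seed: int = 0,
) -> float:
    """Fraction of experiments whose group searchlight peak lands within one
    voxel of the centre of a planted informative 33-voxel sphere.

    Every participant gets an independent high-SNR pattern encoding the same
    stimulus RDM inside the sphere plus white noise elsewhere; the
    participant Fisher-z maps are averaged into the group map whose peak is
    scored, mirroring how the searchlight feeds second-level inference.
    """
    stimuli, _ = generate_stimuli(n_words=n_words, seed=seed)
    target = motor_rdm(stimuli)
    center = tuple(s // 2 for s in shape)
    offs = sphere_offsets(2.0) + np.array(center)
    gm = np.ones(shape)
    base = rng_for(seed, "searchlight_loc")
    hits = 0
    for _ in range(n_seeds):
        zmaps = []
        for _ in range(n_participants):
            s = int(base.integers(2**31))
            rng = np.random.default_rng(s)
            vols = rng.normal(size=(n_words,) + shape)
            pat = plant_patterns(target, len(offs), fidelity=1.0, seed=s)
            vols[:, offs[:, 0], offs[:, 1], offs[:, 2]] += amplitude * pat.values
            _, z_map = searchlight_rsa(vols, gm, target, radius_voxels=2.0)
            zmaps.append(z_map)
        group = np.nanmean(zmaps, axis=0)
        peak = np.unravel_index(np.nanargmax(group), shape)
        hits += np.linalg.norm(np.array(peak) - np.array(center)) <= 1.0
    return hits / n_seeds


def crossover_interaction_power(
    n_sims: int = 100,
    delta: float = 1.0,
    n_blind: int = 12,
    n_sighted: int = 18,
    seed: int = 0,
) -> float:
    """Power of the 2x2 mixed ANOVA to detect a crossover of size delta (in
    noise-SD units) in the Fisher-z table: +delta for blind-writing, -delta
    for sighted-writing."""
    base = rng_for(seed, "crossover")
    hits = 0
    for _ in range(n_sims):
        rng = np.random.default_rng(int(base.integers(2**31)))
        rows = []
        for i in range(n_blind + n_sighted):
            grp = "blind" if i < n_blind else "sighted"
            g = 1.0 if grp == "blind" else -1.0
            for condition, c in (("writing", 1.0), ("no-writing", -1.0)):
                rows.append(
                    {
                        "participant": f"p{i:02d}",
                        "group": grp,
                        "condition": condition,
                        "z": g * c * delta / 2.0 + rng.normal(0.0, 1.0),
                    }
                )
        res = MixedAnova(pd.DataFrame(rows), dv="z", within=["condition"], between="group").fit()
        hits += res.effect("condition:group")["p"] < 0.05
    return hits / n_sims


def fdr_calibration(
    n_sims: int = 500,
    n_rois: int = 6,
    n_blind: int = 12,
    n_sighted: int = 18,
    seed: int = 0,
) -> float:
    """Mean false-discovery proportion of the BH-corrected condition effects
    across ROIs under a complete null (z ~ N(0,1) everywhere)."""
    base = rng_for(seed, "fdr")
    fdp = 0.0
    for _ in range(n_sims):
        rng = np.random.default_rng(int(base.integers(2**31)))
        rows = []
        for i in range(n_blind + n_sighted):
            grp = "blind" if i < n_blind else "sighted"
            for condition in ("writing", "no-writing"):
                for roi in range(n_rois):
                    rows.append(
                        {
                            "participant": f"p{i:02d}",
                            "group": grp,
                            "condition": condition,
                            "period": "test",
                            "roi": f"roi{roi}",
                            "rdm_level": "syllabic",
                            "z": rng.normal(),
                        }
                    )
        out = rsa_anova(pd.DataFrame(rows))
        cond = out[out.effect == "condition"]
        fdp += float((cond["p_fdr"] <= 0.05).any())
    return fdp / n_sims


def mantel_null_pvalues(
    n_sims: int = 500, n: int = 9, n_permutations: int = 199, seed: int = 0
) -> np.ndarray:
    """Mantel p-values for independent random RDM pairs (should be uniform)."""
    base = rng_for(seed, "mantel_null")
    labels = [f"w{k}" for k in range(n)]
    pvals = []
    for _ in range(n_sims):
        s = int(base.integers(2**31))
        rng = np.random.default_rng(s)
        mats = []
        for _ in range(2):
            m = rng.random((n, n))
            m = (m + m.T) / 2
            np.fill_diagonal(m, 0)
            mats.append(RDM(labels, m, "motor"))
        _, p = mantel_test(mats[0], mats[1], n_permutations=n_permutations, seed=s)
        pvals.append(p)
    return np.asarray(pvals)


def glm_noiseless_recovery_error(n_words: int = 6, seed: int = 0) -> float:
    """Max absolute deviation between planted patterns and fitted betas on a
    noiseless synthetic run."""
    stimuli, _ = generate_stimuli(n_words=n_words, seed=seed)
    shape = (7, 7, 7)
    affine = np.diag([2.0, 2.0, 2.0, 1.0])
    rois = {"planted": box_roi(shape, (1, 1, 1), (3, 3, 3))}
    pat = plant_patterns(motor_rdm(stimuli), 27, fidelity=1.0, seed=seed + 1)
    run = generate_bold(
        stimuli, {"planted": pat}, rois, affine, n_reps=2, noise_sd=0.0, seed=seed + 2
    )
    events = run.events.assign(word_period=run.events.word_id + "@" + run.events.period)
    design = build_design(
        events, run.tr_seconds, run.n_volumes, HRFSpec(), motion=run.motion, per="word_period"
    )
    res = FirstLevelGLM(run, design).fit()
    recovered = np.stack(
        [res.beta_map(f"{w}@study")[rois["planted"]] for w in sorted(stimuli.word_ids)]
    )
    return float(np.max(np.abs(recovered - pat.values)))


def glm_null_pvalues(n_sims: int = 200, seed: int = 0) -> np.ndarray:
    """Voxelwise p of a task regressor fitted to pure-noise runs (uniform null).

    One independent voxel's p value is collected per simulated run.
    """
    from scipy import stats

    stimuli, _ = generate_stimuli(n_words=3, seed=seed)
    base = rng_for(seed, "glm_null")
    pvals = []
    shape = (3, 3, 3)
    affine = np.diag([2.0, 2.0, 2.0, 1.0])
    rois = {"roi": box_roi(shape, (0, 0, 0), (3, 3, 3))}
    for _ in range(n_sims):
        s = int(base.integers(2**31))
        pat = plant_patterns(motor_rdm(stimuli), 27, fidelity=0.0, seed=s)
        run = generate_bold(
            stimuli,
            {"roi": pat},
            rois,
            affine,
            n_reps=2,
            amplitude=0.0,  # null: no task signal
            noise_sd=1.0,
            ar_phi=0.0,
            seed=s,
        )
        design = build_design(
            run.events, run.tr_seconds, run.n_volumes, HRFSpec(), per="word_id",
            temporal_smooth_s=0.0,
        )
        res = FirstLevelGLM(run, design).fit()
        t, dof = res.t_map(sorted(stimuli.word_ids)[0])
        pvals.append(2 * stats.t.sf(abs(t[1, 1, 1]), dof))
    return np.asarray(pvals)


def _ppi_experiment(
    gain: float,
    n_blind: int,
    n_sighted: int,
    coupling: float,
    noise_sd: float,
    seed: int,
) -> tuple[float, float]:
    """(interaction p, interaction estimate) of one simulated PPI experiment."""
    from .ppi import build_ppi, eigenvariate, ppi_first_level

    stimuli, _ = generate_stimuli(n_words=4, seed=seed)
    shape = (8, 8, 8)
    affine = np.diag([2.0, 2.0, 2.0, 1.0])
    rois = {
        "seed": box_roi(shape, (0, 0, 0), (3, 3, 3)),
        "target": box_roi(shape, (5, 5, 5), (3, 3, 3)),
    }
    truth = GroundTruth(connectivity_gain=gain, connectivity_cell=("blind", "writing"))
    rows = []
    base = rng_for(seed, "ppi_exp")
    for i in range(n_blind + n_sighted):
        grp = "blind" if i < n_blind else "sighted"
        for condition in ("writing", "no-writing"):
            run = generate_bold(
                stimuli,
                {},
                rois,
                affine,
                n_reps=3,
                condition=condition,
                group=grp,
                noise_sd=noise_sd,
                connectivity=truth,
                seed_roi="seed",
                target_roi="target",
                coupling=coupling,
                seed=int(base.integers(2**31)),
            )
            ev = eigenvariate(run.data[rois["seed"]].T)
            design = build_ppi(
                ev, run.meta["period_labels"], {"study": -1.0, "test": 1.0}, nuisance=run.motion
            )
            betas = ppi_first_level(run.data[rois["target"]].T, design)
            rows.append(
                {
                    "participant": f"p{i:02d}",
                    "group": grp,
                    "condition": condition,
                    "beta": float(np.mean(betas)),
                }
            )
    res = MixedAnova(pd.DataFrame(rows), dv="beta", within=["condition"], between="group").fit()
    eff = res.effect("condition:group")
    return float(eff["p"]), float(eff["estimate"])


def ppi_detection_rate(
    n_seeds: int = 100,
    gain: float = 1.0,
    n_blind: int = 6,
    n_sighted: int = 6,
    coupling: float = 2.0,
    noise_sd: float = 0.2,
    seed: int = 0,
) -> float:
    """How often the planted condition x group connectivity gain is detected
    (interaction p < 0.05) in the target ROI; coupling/noise = SNR 10."""
    base = rng_for(seed, "ppi_detect")
    hits = 0
    for _ in range(n_seeds):
        p, _ = _ppi_experiment(
            gain, n_blind, n_sighted, coupling, noise_sd, int(base.integers(2**31))
        )
        hits += p < 0.05
    return hits / n_seeds


def ppi_null_rejection_rate(
    n_sims: int = 200,
    n_blind: int = 6,
    n_sighted: int = 6,
    coupling: float = 2.0,
    noise_sd: float = 0.2,
    seed: int = 0,
) -> float:
    """Interaction rejection rate with zero planted gain (should be ~alpha)."""
    base = rng_for(seed, "ppi_null")
    hits = 0
    for _ in range(n_sims):
        p, _ = _ppi_experiment(
            0.0, n_blind, n_sighted, coupling, noise_sd, int(base.integers(2**31))
        )
        hits += p < 0.05
    return hits / n_sims


ART_EFFECTS = (
    "condition",
    "timing",
    "group",
    "condition:timing",
    "condition:group",
    "timing:group",
    "condition:timing:group",
)


def art_type1_rates(
    n_sims: int = 1000, n_blind: int = 12, n_sighted: int = 18, seed: int = 0
) -> dict[str, float]:
    """Type-I error of every ART effect in the 2x2x2 mixed design under a
    continuous null (independent standard-normal responses)."""
    base = rng_for(seed, "art_null")
    groups = np.array([0] * n_blind + [1] * n_sighted)
    counts = dict.fromkeys(ART_EFFECTS, 0)
    for _ in range(n_sims):
        rng = np.random.default_rng(int(base.integers(2**31)))
        y = rng.normal(size=(n_blind + n_sighted, 2, 2))
        effects, _ = art_effects_array(y, ["condition", "timing"], groups=groups)
        for name in ART_EFFECTS:
            counts[name] += float(effects[name]["p"]) < 0.05
    return {k: v / n_sims for k, v in counts.items()}


def analyze_recall(table: pd.DataFrame, offset: float = 1.0):
    """Inverse transform + omnibus ART ANOVA of a recall-accuracy table."""
    from .art import art_anova

    transformed = table.assign(
        accuracy=inverse_transform(table["accuracy"].to_numpy(), offset=offset)
    )
    return art_anova(transformed)
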