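"""Configuration-driven orchestration: generate -> GLM -> PPI -> RSA -> behavior.

One top-level seed drives every stage through a documented derivation
(:func:`grapholearn._utils.rng_for`), so two runs with the same configuration
produce identical manifests.  Each enabled stage writes into its own
write-once subdirectory of the output directory and records the SHA-256 of
every file it produced in the run manifest.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, io
from ._utils import rng_for
from .art import art_anova, assumption_checks, inverse_transform, posthoc_by_group
from .design import build_design
from .firstlevel import FirstLevelGLM
from .group import factorial_anova
from .hrf import HRFSpec
from .ppi import build_ppi, eigenvariate, ppi_first_level, ppi_group_test
from .rdm import mantel_test, motor_rdm, semantic_rdm, syllabic_rdm
from .rsa import roi_rsa, rsa_anova, searchlight_rsa
from .synth import (
    GroundTruth,
    box_roi,
    generate_behavior,
    generate_bold,
    generate_stimuli,
    gray_matter_map,
    plant_patterns,
)


@dataclass
class PipelineConfig:
    """All pipeline parameters; the demo defaults run end-to-end in seconds."""

    out_dir: str = "pipeline_out"
    seed: int = 0
    stages: dict = field(
        default_factory=lambda: {"synth": True, "glm": True, "ppi": True, "rsa": True, "behav": True}
    )
    # synthetic experiment scale
    n_words: int = 8
    n_blind: int = 4
    n_sighted: int = 4
    grid: tuple = (12, 12, 12)
    n_reps: int = 2
    tr_seconds: float = 3.5
    fidelity: float = 1.0
    noise_sd: float = 0.5
    amplitude: float = 1.0
    connectivity_gain: float = 1.0
    coupling: float = 2.0
    planted_level: str = "motor"
    # analysis parameters
    semantic_measure: str = "wu_palmer"
    searchlight_radius_voxels: float = 2.0
    gm_threshold: float = 0.33
    min_sphere_voxels: int = 10
    art_offset: float = 1.0
    n_permutations: int = 200

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(**raw)
        cfg.grid = tuple(cfg.grid)
        return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _stage_dir(root: Path, name: str) -> Path:
    d = root / name
    if d.exists() and any(d.iterdir()):
        raise FileExistsError(f"stage directory {d} already has outputs (write-once)")
    d.mkdir(parents=True, exist_ok=True)
    return d


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")


def _participants(cfg: PipelineConfig) -> list[tuple[str, str]]:
    return [(f"b{i + 1:02d}", "blind") for i in range(cfg.n_blind)] + [
        (f"s{i + 1:02d}", "sighted") for i in range(cfg.n_sighted)
    ]


def _layout(cfg: PipelineConfig):
    """ROI layout on the configured grid: planted, seed, target, control boxes."""
    shape = tuple(cfg.grid)
    affine = np.diag([2.0, 2.0, 2.0, 1.0])
    affine[:3, 3] = -(np.array(shape) - 1.0)
    s = shape[0]
    q = max(s // 4, 2)
    rois = {
        "planted": box_roi(shape, (1, 1, 1), (q, q, q)),
        "seed": box_roi(shape, (s - q - 1, 1, 1), (q, q, q)),
        "target": box_roi(shape, (1, s - q - 1, 1), (q, q, q)),
        "control": box_roi(shape, (s - q - 1, s - q - 1, s - q - 1), (q, q, q)),
    }
    return shape, affine, rois


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the enabled stages in dependency order; return the manifest."""
    root = Path(config.out_dir)
    root.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "config": {k: (list(v) if isinstance(v, tuple) else v) for k, v in asdict(config).items()},
        "config_hash": hashlib.sha256(
            json.dumps(asdict(config), sort_keys=True, default=str).encode()
        ).hexdigest(),
        "stages": {},
    }
    state: dict = {}
    order = ["synth", "glm", "ppi", "rsa", "behav"]
    deps = {"glm": ["synth"], "ppi": ["synth"], "rsa": ["glm"], "behav": []}
    for stage in order:
        if not config.stages.get(stage, False):
            continue
        missing = [d for d in deps.get(stage, []) if not config.stages.get(d, False)]
        if missing:
            raise PipelineError(stage, ValueError(f"requires stages {missing}"))
        try:
            files = _STAGES[stage](config, root, state)
        except Exception as exc:  # noqa: BLE001 - name the failing stage
            raise PipelineError(stage, exc) from exc
        manifest["stages"][stage] = {
            "files": {str(p.relative_to(root)): _sha256(p) for p in sorted(files)}
        }
    with open(root / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def _stage_synth(cfg: PipelineConfig, root: Path, state: dict) -> list[Path]:
    out = _stage_dir(root, "synth")
    stimuli, taxonomy = generate_stimuli(n_words=cfg.n_words, seed=cfg.seed)
    rdms = {
        "motor": motor_rdm(stimuli),
        "syllabic": syllabic_rdm(stimuli),
        "semantic": semantic_rdm(stimuli, taxonomy, measure=cfg.semantic_measure),
    }
    shape, affine, rois = _layout(cfg)
    truth = GroundTruth(
        planted_rdm={"planted": cfg.planted_level},
        connectivity_gain=cfg.connectivity_gain,
        connectivity_cell=("blind", "writing"),
        seed=cfg.seed,
    )
    files = [
        io.save_stimuli(stimuli, out / "stimuli.csv"),
        io.save_taxonomy(taxonomy, out / "taxonomy.csv"),
    ]
    for level, rdm in rdms.items():
        files.append(io.save_rdm(rdm, out / f"rdm_{level}.csv"))
    runs = {}
    for pi, (participant, group) in enumerate(_participants(cfg)):
        pat = plant_patterns(
            rdms[cfg.planted_level],
            int(rois["planted"].sum()),
            fidelity=cfg.fidelity,
            seed=int(rng_for(cfg.seed, "pattern", participant).integers(2**31)),
        )
        for condition in ("writing", "no-writing"):
            run = generate_bold(
                stimuli,
                {"planted": pat},
                rois,
                affine,
                tr_seconds=cfg.tr_seconds,
                n_reps=cfg.n_reps,
                condition=condition,
                group=group,
                amplitude=cfg.amplitude,
                noise_sd=cfg.noise_sd,
                connectivity=truth,
                seed_roi="seed",
                target_roi="target",
                coupling=cfg.coupling,
                seed=int(rng_for(cfg.seed, "run", participant, condition).integers(2**31)),
            )
            name = f"{participant}_{condition.replace('-', '')}"
            files.extend(io.save_run(run, out, name).values())
            runs[(participant, group, condition)] = run
    state.update(
        stimuli=stimuli,
        taxonomy=taxonomy,
        rdms=rdms,
        rois=rois,
        affine=affine,
        runs=runs,
        truth=truth,
    )
    return files


def _stage_glm(cfg: PipelineConfig, root: Path, state: dict) -> list[Path]:
    out = _stage_dir(root, "glm")
    files = []
    betas: dict[tuple[str, str, str], np.ndarray] = {}
    groups: dict[str, str] = {}
    word_order = sorted(state["stimuli"].word_ids)
    for (participant, group, condition), run in state["runs"].items():
        groups[participant] = group
        # one joint model with a regressor per word x period
        events = run.events.assign(
            word_period=run.events["word_id"] + "@" + run.events["period"]
        )
        design = build_design(
            events,
            run.tr_seconds,
            run.n_volumes,
            HRFSpec(),
            motion=run.motion,
            per="word_period",
        )
        res = FirstLevelGLM(run, design).fit()
        for period in ("study", "test"):
            vols = np.stack([res.beta_map(f"{w}@{period}") for w in word_order])
            betas[(participant, condition, period)] = vols
            path = out / f"{participant}_{condition.replace('-', '')}_{period}_wordbetas.nii.gz"
            files.append(io.save_volume(np.moveaxis(vols, 0, -1), run.affine, path))
    state.update(betas=betas, groups=groups, word_order=word_order)
    return files


def _stage_ppi(cfg: PipelineConfig, root: Path, state: dict) -> list[Path]:
    out = _stage_dir(root, "ppi")
    rois, affine = state["rois"], state["affine"]
    participants = sorted({p for (p, _, _) in state["runs"]})
    maps = []
    groups01 = []
    for participant in participants:
        per_cond = []
        for condition in ("writing", "no-writing"):
            key = next(k for k in state["runs"] if k[0] == participant and k[2] == condition)
            run = state["runs"][key]
            seed_ts = run.data[rois["seed"]].T
            ev = eigenvariate(seed_ts)
            design = build_ppi(
                ev,
                run.meta["period_labels"],
                {"study": -1.0, "test": 1.0},
                nuisance=run.motion,
            )
            per_cond.append(ppi_first_level(run.data, design))
            groups01.append(0 if key[1] == "blind" else 1)
        maps.append(np.stack(per_cond))
    interaction = np.stack(maps)
    groups = np.array(groups01[::2])
    result = ppi_group_test(
        interaction,
        groups,
        affine,
        roi_masks={"target": rois["target"], "control": rois["control"]},
        n_permutations=cfg.n_permutations,
        seed=cfg.seed,
    )
    files = [
        io.save_volume(result["interaction"].values, affine, out / "ppi_interaction_F.nii.gz")
    ]
    result["screen"].to_csv(out / "ppi_clusters.tsv", sep="\t", index=False)
    files.append(out / "ppi_clusters.tsv")
    roi_rows = [
        {"roi": name, **{k: v for k, v in res.items() if not isinstance(v, tuple)}}
        for name, res in result["roi"].items()
    ]
    pd.DataFrame(roi_rows).to_csv(out / "ppi_roi.tsv", sep="\t", index=False)
    files.append(out / "ppi_roi.tsv")
    state["ppi_result"] = result
    return files


def _stage_rsa(cfg: PipelineConfig, root: Path, state: dict) -> list[Path]:
    out = _stage_dir(root, "rsa")
    rois, affine = state["rois"], state["affine"]
    table = roi_rsa(
        state["betas"],
        state["groups"],
        {"planted": rois["planted"], "control": rois["control"]},
        state["rdms"],
        state["word_order"],
        min_voxels=cfg.min_sphere_voxels,
    )
    table.to_csv(out / "rsa_table.tsv", sep="\t", index=False)
    anova = rsa_anova(table)
    anova.to_csv(out / "rsa_anova.tsv", sep="\t", index=False)
    files = [out / "rsa_table.tsv", out / "rsa_anova.tsv"]
    # searchlight on the planted RDM, study period, first participant per group
    gm = gray_matter_map(tuple(cfg.grid))
    zmaps = []
    for (participant, condition, period), vols in state["betas"].items():
        if period != "study" or condition != "writing":
            continue
        _, z = searchlight_rsa(
            vols,
            gm,
            state["rdms"][cfg.planted_level],
            radius_voxels=cfg.searchlight_radius_voxels,
            gm_threshold=cfg.gm_threshold,
            min_voxels=cfg.min_sphere_voxels,
        )
        zmaps.append(np.nan_to_num(z))
    mean_z = np.mean(zmaps, axis=0)
    files.append(io.save_volume(mean_z, affine, out / "searchlight_mean_z.nii.gz"))
    state.update(rsa_table=table, rsa_anova=anova, searchlight_mean_z=mean_z)
    return files


def _stage_behav(cfg: PipelineConfig, root: Path, state: dict) -> list[Path]:
    out = _stage_dir(root, "behav")
    table = generate_behavior(n_blind=cfg.n_blind, n_sighted=cfg.n_sighted, seed=cfg.seed)
    io.save_behavior(table, out / "behavior.csv")
    transformed = table.assign(
        accuracy=inverse_transform(table["accuracy"].to_numpy(), offset=cfg.art_offset)
    )
    res = art_anova(transformed)
    res.table.to_csv(out / "art_anova.tsv", sep="\t", index=False)
    checks = assumption_checks(table)
    with open(out / "assumption_checks.json", "w") as fh:
        json.dump(checks, fh, indent=2)
    posthoc = posthoc_by_group(transformed)
    rows = []
    for group, entry in posthoc.items():
        for r in entry["anova"].table.itertuples():
            rows.append({"group": group, "scope": "omnibus", "effect": r.effect, "F": r.F, "p": r.p})
        for timing, sub in entry["per_timing"].items():
            for r in sub.table.itertuples():
                rows.append({"group": group, "scope": timing, "effect": r.effect, "F": r.F, "p": r.p})
    pd.DataFrame(rows).to_csv(out / "art_posthoc.tsv", sep="\t", index=False)
    state.update(behavior=table, art=res, checks=checks)
    return [
        out / "behavior.csv",
        out / "art_anova.tsv",
        out / "assumption_checks.json",
        out / "art_posthoc.tsv",
    ]


_STAGES = {
    "synth": _stage_synth,
    "glm": _stage_glm,
    "ppi": _stage_ppi,
    "rsa": _stage_rsa,
    "behav": _stage_behav,
}
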