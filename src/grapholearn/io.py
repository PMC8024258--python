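"""Reading and writing the pipeline's on-disk formats.

BOLD runs are NIfTI-1 (.nii.gz) with tab-separated event tables and
whitespace motion files alongside; stimuli and behavior are comma-separated
tables; taxonomies are two-column parent-child edge lists; RDMs are square
CSV matrices with a word-id header (plus an optional long form).
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .core import RDM, BoldRun, StimulusSet, Taxonomy

EVENT_COLUMNS = ["onset_s", "duration_s", "word_id", "condition", "period"]


def save_run(run: BoldRun, out_dir: str | Path, name: str) -> dict[str, Path]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "bold": out / f"{name}_bold.nii.gz",
        "events": out / f"{name}_events.tsv",
        "motion": out / f"{name}_motion.txt",
    }
    nib.save(nib.Nifti1Image(run.data.astype(np.float32), run.affine), paths["bold"])
    run.events[EVENT_COLUMNS].to_csv(paths["events"], sep="\t", index=False)
    np.savetxt(paths["motion"], run.motion, fmt="%.6f")
    return paths


def load_run(out_dir: str | Path, name: str, tr_seconds: float) -> BoldRun:
    out = Path(out_dir)
    img = nib.load(out / f"{name}_bold.nii.gz")
    events = pd.read_csv(out / f"{name}_events.tsv", sep="\t")
    motion = np.loadtxt(out / f"{name}_motion.txt")
    return BoldRun(
        data=np.asarray(img.dataobj, dtype=float),
        affine=img.affine,
        tr_seconds=tr_seconds,
        events=events,
        motion=motion,
    )


def save_volume(volume: np.ndarray, affine: np.ndarray, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    nib.save(nib.Nifti1Image(np.asarray(volume, dtype=np.float32), affine), path)
    return path


def save_stimuli(stimuli: StimulusSet, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    stimuli.to_frame().to_csv(path, index=False)
    return path


def load_stimuli(path: str | Path) -> StimulusSet:
    return StimulusSet.from_frame(pd.read_csv(path))


def save_taxonomy(taxonomy: Taxonomy, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    taxonomy.to_edges().to_csv(path, index=False)
    return path


def load_taxonomy(path: str | Path) -> Taxonomy:
    return Taxonomy.from_edges(pd.read_csv(path))


def save_rdm(rdm: RDM, path: str | Path, long_form: bool = False) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if long_form:
        rdm.to_long().to_csv(path, index=False)
    else:
        rdm.to_frame().to_csv(path, index=False)
    return path


def load_rdm(path: str | Path, level: str) -> RDM:
    return RDM.from_frame(pd.read_csv(path), level)


def save_behavior(table: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, index=False)
    return path


def load_behavior(path: str | Path) -> pd.DataFrame:
    """Behavioral recall table: participant, group, condition, timing, accuracy."""
    table = pd.read_csv(path)
    missing = {"participant", "group", "condition", "timing", "accuracy"} - set(table.columns)
    if missing:
        raise ValueError(f"behavior table is missing columns: {sorted(missing)}")
    return table
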