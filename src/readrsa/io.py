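"""File-format plumbing: NIfTI volumes, BIDS-style event tables, study trees."""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .glm import BoldRun, validate_events
from .simulate import SyntheticDataset

__all__ = ["load_bold_run", "load_mask", "load_events", "write_study", "load_study_runs"]


def load_mask(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    img = nib.load(str(path))
    return np.asarray(img.dataobj) > 0, img.affine


def load_bold_run(
    bold_path: str | Path, mask_path: str | Path, tr: float | None = None
) -> BoldRun:
    img = nib.load(str(bold_path))
    mask, _ = load_mask(mask_path)
    if tr is None:
        tr = float(img.header.get_zooms()[3])
    return BoldRun(
        np.asarray(img.dataobj, dtype=np.float32),
        tr,
        mask,
        img.affine,
        run_id=Path(bold_path).stem.split(".")[0],
    )


def load_events(path: str | Path) -> pd.DataFrame:
    return validate_events(pd.read_csv(path, sep="\t"))


def write_study(dataset: SyntheticDataset, directory: str | Path) -> Path:
    """Write a synthetic study as a self-contained directory tree.

    Layout: `lexicon/`, `mask.nii.gz`, per subject `sub-XX/run-YY_bold.nii.gz`
    + `run-YY_events.tsv`, per condition model RDM TSVs, and a JSON manifest
    with seeds, plant specs and achieved correlations.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    dataset.lexicon.save(directory / "lexicon")
    nib.save(
        nib.Nifti1Image(dataset.mask.astype(np.uint8), dataset.affine),
        directory / "mask.nii.gz",
    )
    for sub in dataset.subjects:
        sub_dir = directory / sub.subject
        sub_dir.mkdir(exist_ok=True)
        for run, events in zip(sub.runs, sub.events):
            hdr_img = nib.Nifti1Image(run.data, dataset.affine)
            hdr_img.header.set_zooms(hdr_img.header.get_zooms()[:3] + (run.tr,))
            nib.save(hdr_img, sub_dir / f"{run.run_id}_bold.nii.gz")
            events.to_csv(sub_dir / f"{run.run_id}_events.tsv", sep="\t", index=False)
        for cond, rdms in sub.model_rdms.items():
            for measure, rdm in rdms.items():
                rdm.save(sub_dir / f"{cond}_{measure}_rdm.tsv")
    (directory / "manifest.json").write_text(json.dumps(dataset.manifest, indent=2))
    return directory


def load_study_runs(
    directory: str | Path, subject: str
) -> tuple[list[BoldRun], list[pd.DataFrame]]:
    """Load one subject's runs and event tables from a study directory."""
    directory = Path(directory)
    sub_dir = directory / subject
    runs, events = [], []
    for bold_path in sorted(sub_dir.glob("run-*_bold.nii.gz")):
        run_id = bold_path.name.replace("_bold.nii.gz", "")
        runs.append(load_bold_run(bold_path, directory / "mask.nii.gz"))
        events.append(load_events(sub_dir / f"{run_id}_events.tsv"))
    return runs, events
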