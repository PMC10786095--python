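"""NIfTI / TSV / JSON artifact writers shared by the pipeline stages."""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = ["save_nifti", "load_nifti", "save_masked_map", "save_events_tsv",
           "save_nuisance_tsv", "save_json"]

_AFFINE = np.diag([2.0, 2.0, 2.0, 1.0])  # 2 mm isotropic voxel grid


def save_nifti(data: np.ndarray, path: str | Path,
               sidecar: dict | None = None) -> None:
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float32), _AFFINE)
    nib.save(img, str(path))
    if sidecar is not None:
        Path(str(path).replace(".nii.gz", "").replace(".nii", "")
             + ".json").write_text(json.dumps(sidecar, indent=2, default=_coerce))


def load_nifti(path: str | Path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).dataobj)


def save_masked_map(values: np.ndarray, mask: np.ndarray, path: str | Path,
                    sidecar: dict | None = None, fill: float = 0.0) -> None:
    """Write a masked-voxel vector (or (V, P) stack) as a (grid[, P]) NIfTI."""
    values = np.asarray(values)
    shape = mask.shape + (() if values.ndim == 1 else values.shape[1:])
    grid = np.full(shape, fill, dtype=np.float32)
    grid[mask] = values
    save_nifti(grid, path, sidecar)


def save_events_tsv(timeline, path: str | Path) -> None:
    """BIDS-style events table (onset, duration, trial_type)."""
    rows = [{"onset": on, "duration": dur,
             "trial_type": "fixation" if sid is None else f"stim_{sid}"}
            for sid, on, dur in timeline.events]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def save_nuisance_tsv(nuisance: np.ndarray, path: str | Path) -> None:
    cols = {f"motion_{i}": nuisance[i] for i in range(nuisance.shape[0])}
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False)


def save_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=_coerce))


def _coerce(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    raise TypeError(f"not JSON serializable: {type(x)}")
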