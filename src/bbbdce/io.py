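"""NIfTI / sidecar / TSV input-output.

Image data travel as NIfTI-1 (via nibabel) with acquisition parameters in a
JSON sidecar validated against :class:`AcquisitionParams`.  Tabular results
(AIF, per-region kinetics, region summaries, cohort tables) are plain TSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .aif import Aif
from .relaxometry import AcquisitionParams, DynamicSeries, VfaStack

__all__ = [
    "save_nifti", "load_nifti",
    "save_acquisition_sidecar", "load_acquisition_sidecar",
    "save_dynamic_series", "load_dynamic_series",
    "save_vfa_stack", "load_vfa_stack",
    "save_aif_tsv", "load_aif_tsv",
    "save_cohort_tsv", "load_cohort_tsv",
]


def save_nifti(data: np.ndarray, path: str | Path, affine: np.ndarray | None = None) -> None:
    img = nib.Nifti1Image(np.asarray(data), affine if affine is not None else np.eye(4))
    nib.save(img, str(path))


def load_nifti(path: str | Path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).get_fdata())


def save_acquisition_sidecar(params: AcquisitionParams, path: str | Path) -> None:
    Path(path).write_text(json.dumps(params.model_dump(), indent=1))


def load_acquisition_sidecar(path: str | Path) -> AcquisitionParams:
    return AcquisitionParams.model_validate(json.loads(Path(path).read_text()))


def save_dynamic_series(series: DynamicSeries, stem: str | Path) -> None:
    stem = Path(stem)
    save_nifti(series.signal, stem.with_suffix(".nii"))
    save_acquisition_sidecar(series.params, stem.with_suffix(".json"))


def load_dynamic_series(stem: str | Path) -> DynamicSeries:
    stem = Path(stem)
    return DynamicSeries(
        signal=load_nifti(stem.with_suffix(".nii")),
        params=load_acquisition_sidecar(stem.with_suffix(".json")),
    )


def save_vfa_stack(stack: VfaStack, stem: str | Path) -> None:
    stem = Path(stem)
    save_nifti(stack.signals, stem.with_suffix(".nii"))
    meta = {"flips_deg": list(stack.flips_deg), "tr_ms": stack.tr_ms}
    stem.with_suffix(".json").write_text(json.dumps(meta, indent=1))


def load_vfa_stack(stem: str | Path) -> VfaStack:
    stem = Path(stem)
    meta = json.loads(stem.with_suffix(".json").read_text())
    return VfaStack(
        signals=load_nifti(stem.with_suffix(".nii")),
        flips_deg=meta["flips_deg"],
        tr_ms=meta["tr_ms"],
    )


def save_aif_tsv(aif: Aif, path: str | Path) -> None:
    pd.DataFrame({"time_min": aif.time_min, "conc_mM": aif.conc_mM}).to_csv(
        path, sep="\t", index=False
    )


def load_aif_tsv(path: str | Path) -> Aif:
    df = pd.read_csv(path, sep="\t")
    ca = df["conc_mM"].to_numpy()
    return Aif(
        conc_mM=ca,
        time_min=df["time_min"].to_numpy(),
        source_voxel=-1,
        peak_frame=int(np.nanargmax(ca)),
    )


def save_cohort_tsv(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False)


def load_cohort_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
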