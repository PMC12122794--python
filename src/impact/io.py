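"""Readers and writers for the package's on-disk formats: NIfTI volumes and
atlases (via nibabel), ROI/ICA/dFC feature bundles as TSV + JSON metadata,
motion-parameter text files, and model checkpoints (npz weights with a JSON
config sidecar)."""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .features import (AtlasLabelImage, BoldVolumeSeries, DfcSequence,
                       IcaTimeSeries, RoiTimeSeries, SubjectFeatures)
from .model import ImpactModel, ModelConfig

__all__ = [
    "read_nifti_volume", "read_atlas", "read_motion_params",
    "write_roi_tsv", "read_roi_tsv", "write_features", "read_features",
    "save_checkpoint", "load_checkpoint",
]


def read_nifti_volume(path: str | Path, subject_id: str | None = None,
                      tr_seconds: float | None = None) -> BoldVolumeSeries:
    import nibabel as nib

    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float64)
    if tr_seconds is None:
        zooms = img.header.get_zooms()
        tr_seconds = float(zooms[3]) if len(zooms) > 3 else 1.0
    sid = subject_id or Path(path).name.split(".")[0].replace("_bold", "")
    return BoldVolumeSeries(data=data, tr_seconds=tr_seconds,
                            affine=np.asarray(img.affine), subject_id=sid)


def read_atlas(label_path: str | Path, names_path: str | Path) -> AtlasLabelImage:
    """Atlas label image plus its (label, name) table, ordered by label."""
    import nibabel as nib

    img = nib.load(str(label_path))
    labels = np.asarray(img.dataobj).astype(np.int32)
    table = pd.read_csv(names_path, sep="\t", header=None,
                        names=["label", "name"], comment="#")
    table = table.sort_values("label")
    return AtlasLabelImage(labels, [str(n) for n in table["name"]])


def read_motion_params(path: str | Path) -> np.ndarray:
    """T x 6 rigid-body series (3 translations mm, 3 rotations rad)."""
    arr = np.loadtxt(path)
    if arr.ndim != 2 or arr.shape[1] != 6:
        raise ValueError(f"expected a T x 6 motion file, got shape {arr.shape}")
    return arr


# ----------------------------------------------------------- feature bundles

def write_roi_tsv(ts: RoiTimeSeries, path: str | Path) -> None:
    pd.DataFrame(ts.values, columns=ts.region_names).to_csv(
        path, sep="\t", index=False, float_format="%.10g")


def read_roi_tsv(path: str | Path, tr_seconds: float = 2.0,
                 normalized: bool = False) -> RoiTimeSeries:
    df = pd.read_csv(path, sep="\t")
    return RoiTimeSeries(df.to_numpy(dtype=np.float64), list(df.columns),
                         tr_seconds, normalized=normalized)


def write_features(features: SubjectFeatures, out_dir: str | Path) -> Path:
    """Per-subject bundle: roi.tsv, ica.tsv, dfc.tsv and dfc_meta.json."""
    out = Path(out_dir) / features.subject_id
    out.mkdir(parents=True, exist_ok=True)
    write_roi_tsv(features.roi, out / "roi.tsv")
    pd.DataFrame(features.ica.values,
                 columns=[f"ic{c:02d}" for c in range(features.ica.n_components)]
                 ).to_csv(out / "ica.tsv", sep="\t", index=False,
                          float_format="%.10g")
    pd.DataFrame(features.dfc.vectors).to_csv(out / "dfc.tsv", sep="\t",
                                              index=False, header=False,
                                              float_format="%.10g")
    meta = {
        "subject_id": features.subject_id,
        "label": features.label,
        "tr_seconds": features.roi.tr_seconds,
        "window_starts": features.dfc.window_starts,
        "window_width": features.dfc.window_width,
        "stride": features.dfc.stride,
        "n_regions": features.dfc.n_regions,
        "ica_mixing": features.ica.mixing.tolist(),
        "ica_mean": features.ica.mean.tolist(),
    }
    (out / "dfc_meta.json").write_text(json.dumps(meta))
    return out


def read_features(subject_dir: str | Path) -> SubjectFeatures:
    subject_dir = Path(subject_dir)
    meta = json.loads((subject_dir / "dfc_meta.json").read_text())
    roi = read_roi_tsv(subject_dir / "roi.tsv", meta["tr_seconds"], normalized=True)
    ica_df = pd.read_csv(subject_dir / "ica.tsv", sep="\t")
    ica = IcaTimeSeries(ica_df.to_numpy(dtype=np.float64),
                        mixing=np.array(meta["ica_mixing"]),
                        mean=np.array(meta["ica_mean"]))
    vectors = pd.read_csv(subject_dir / "dfc.tsv", sep="\t",
                          header=None).to_numpy(dtype=np.float64)
    dfc = DfcSequence(vectors, meta["window_starts"], meta["window_width"],
                      meta["stride"], meta["n_regions"])
    return SubjectFeatures(meta["subject_id"], roi, ica, dfc, label=meta["label"])


# --------------------------------------------------------------- checkpoints

def save_checkpoint(model: ImpactModel, path: str | Path) -> None:
    """Weights as npz plus the model config echoed as a JSON sidecar."""
    path = Path(path)
    state = {k.replace(".", "/"): v for k, v in model.state_dict().items()}
    np.savez(path, **state)
    sidecar = path.with_suffix(".json")
    sidecar.write_text(json.dumps(model.cfg.to_dict(), indent=2))


def load_checkpoint(path: str | Path) -> ImpactModel:
    path = Path(path)
    cfg_dict = json.loads(path.with_suffix(".json").read_text())
    cfg_dict["modalities"] = tuple(cfg_dict["modalities"])
    model = ImpactModel(ModelConfig(**cfg_dict))
    with np.load(path.with_suffix(".npz") if path.suffix != ".npz" else path) as z:
        state = {k.replace("/", "."): z[k] for k in z.files}
    model.load_state_dict(state)
    model.eval()
    return model
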