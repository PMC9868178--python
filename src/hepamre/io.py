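"""Readers and writers for the pipeline's on-disk formats.

Proteome tables are TSV (UTF-8, '.' decimal, one enzyme-id column plus one
column per sample); intensities are converted to ratios against the cohort
per-enzyme mean on read.  Volumetric data travel as NIfTI-1, with complex
wave fields stored as paired real/imaginary float32 volumes stacked along a
trailing axis.  Truth records and PET metadata use JSON sidecars.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
from importlib import resources

from .liverkin.model import ProteomeProfile
from .waveinv import ParameterMap, WaveFieldSet

__all__ = [
    "read_proteome_tsv",
    "write_proteome_tsv",
    "write_wavefield_nifti",
    "read_wavefield_nifti",
    "write_map_nifti",
    "read_map_nifti",
    "write_mask_nifti",
    "read_mask_nifti",
    "load_table1",
    "write_json",
    "read_json",
]

ENZYME_COLUMN = "enzyme"


def read_proteome_tsv(path) -> list[ProteomeProfile]:
    """Read an LFQ-style intensity table into per-sample abundance ratios.

    Each enzyme's intensities are divided by the enzyme's mean over all
    samples, so every enzyme's sample-mean ratio is 1.  Zero or missing
    intensities fall back to ratio 1 with a warning (absent evidence keeps
    the reference activity).
    """
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    if df.columns[0] != ENZYME_COLUMN:
        raise ValueError(f"first column must be {ENZYME_COLUMN!r}, got {df.columns[0]!r}")
    enzymes = df[ENZYME_COLUMN]
    if enzymes.duplicated().any():
        dup = sorted(enzymes[enzymes.duplicated()].unique())
        raise ValueError(f"duplicate enzyme ids: {dup}")
    sample_cols = list(df.columns[1:])
    if not sample_cols:
        raise ValueError("proteome table has no sample columns")
    values = df[sample_cols].apply(pd.to_numeric, errors="coerce")
    for col in sample_cols:
        bad = df[values[col].isna() & df[col].notna()]
        if len(bad):
            raise ValueError(
                f"non-numeric cell(s) in column {col!r}, "
                f"enzyme(s) {bad[ENZYME_COLUMN].tolist()}"
            )
    usable = values.where(values > 0)
    means = usable.mean(axis=1)
    ratios = usable.div(means, axis=0)
    n_missing = int(ratios.isna().to_numpy().sum())
    if n_missing:
        warnings.warn(
            f"{n_missing} missing/zero intensity cell(s); ratio 1 assumed",
            stacklevel=2,
        )
    ratios = ratios.fillna(1.0)
    profiles = []
    for col in sample_cols:
        profiles.append(
            ProteomeProfile(
                sample_id=str(col),
                ratios=dict(zip(enzymes, ratios[col].tolist())),
            )
        )
    return profiles


def write_proteome_tsv(path, profiles: list[ProteomeProfile]) -> None:
    enzymes = sorted({e for p in profiles for e in p.ratios})
    df = pd.DataFrame({ENZYME_COLUMN: enzymes})
    for p in profiles:
        df[p.sample_id] = [p.ratios.get(e, 1.0) for e in enzymes]
    df.to_csv(path, sep="\t", index=False)


def _affine(spacing_mm) -> np.ndarray:
    # NIfTI stores (x, y, z) fastest-first; our arrays are (z, y, x)
    aff = np.diag([spacing_mm[2], spacing_mm[1], spacing_mm[0], 1.0])
    return aff


def write_wavefield_nifti(path, wfs: WaveFieldSet) -> None:
    """Store a complex field set as float32 pairs plus a JSON sidecar."""
    f = np.asarray(wfs.fields)
    # (freq, enc, z, y, x) complex -> (x, y, z, freq, enc, 2) float32
    stacked = np.stack([f.real, f.imag], axis=-1).astype(np.float32)
    data = np.transpose(stacked, (4, 3, 2, 0, 1, 5))
    img = nib.Nifti1Image(data, _affine(wfs.voxel_spacing_mm))
    img.header.set_zooms(
        (wfs.voxel_spacing_mm[2], wfs.voxel_spacing_mm[1], wfs.voxel_spacing_mm[0])
        + (1.0,) * (data.ndim - 3)
    )
    nib.save(img, str(path))
    sidecar = Path(str(path)).with_suffix("").with_suffix("")  # strip .nii.gz
    write_json(
        str(sidecar) + ".json",
        {
            "frequencies_hz": list(wfs.frequencies_hz),
            "encoding_directions": list(wfs.encoding_directions),
            "voxel_spacing_mm": list(wfs.voxel_spacing_mm),
        },
    )


def read_wavefield_nifti(path) -> WaveFieldSet:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    sidecar = Path(str(path)).with_suffix("").with_suffix("")
    meta = read_json(str(sidecar) + ".json")
    fields = np.transpose(data, (3, 4, 2, 1, 0, 5))
    fields = fields[..., 0] + 1j * fields[..., 1]
    return WaveFieldSet(
        fields=fields,
        frequencies_hz=tuple(meta["frequencies_hz"]),
        voxel_spacing_mm=tuple(meta["voxel_spacing_mm"]),
        encoding_directions=tuple(meta["encoding_directions"]),
    )


def write_map_nifti(path, pmap: ParameterMap, spacing_mm) -> None:
    data = np.transpose(np.asarray(pmap.values, dtype=np.float32), (2, 1, 0))
    img = nib.Nifti1Image(data, _affine(spacing_mm))
    nib.save(img, str(path))


def read_map_nifti(path, kind: str = "SWS") -> ParameterMap:
    img = nib.load(str(path))
    zooms = img.header.get_zooms()[:3]
    if any(z <= 0 for z in zooms):
        raise ValueError(f"{path}: voxel spacing missing or non-positive")
    values = np.transpose(np.asarray(img.dataobj, dtype=float), (2, 1, 0))
    return ParameterMap(values=values, kind=kind, mask=np.isfinite(values))


def write_mask_nifti(path, mask: np.ndarray, spacing_mm) -> None:
    data = np.transpose(np.asarray(mask, dtype=np.uint8), (2, 1, 0))
    nib.save(nib.Nifti1Image(data, _affine(spacing_mm)), str(path))


def read_mask_nifti(path) -> np.ndarray:
    img = nib.load(str(path))
    return np.transpose(np.asarray(img.dataobj), (2, 1, 0)).astype(bool)


def write_json(path, obj) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_json(path):
    with open(path, "r", encoding="utf-8") as fh:
        return json.load(fh)


def load_table1() -> pd.DataFrame:
    """The packaged per-animal cohort table (weight, BG, SWS, PR, SUV)."""
    with resources.files("hepamre.fixtures").joinpath("table1.csv").open() as fh:
        return pd.read_csv(fh)
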