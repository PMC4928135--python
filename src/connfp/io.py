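"""Readers and writers for the on-disk formats.

All tabular formats are TSV with header rows and region labels.  The
voxel-count input is one whitespace-delimited matrix file per seed region
per subject (rows = voxels, columns = the atlas's m regions in atlas
order — the probtrackx classification-targets matrix exported to text),
tied together by a manifest TSV with columns subject, region, path
(paths relative to the manifest's directory).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .fingerprint import FingerprintMatrix, RegionAtlas, VoxelCounts
from .grouptest import GroupDesign


# ---------------------------------------------------------------- atlas

def read_atlas(path: str | Path) -> RegionAtlas:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "label" not in df.columns:
        raise ValueError(f"{path}: atlas file needs a 'label' column")
    hemis = tuple(df["hemisphere"]) if "hemisphere" in df.columns else ()
    return RegionAtlas(labels=tuple(df["label"]), hemispheres=hemis)


def write_atlas(atlas: RegionAtlas, path: str | Path) -> None:
    df = pd.DataFrame({"label": atlas.labels})
    if atlas.hemispheres:
        df["hemisphere"] = atlas.hemispheres
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------- design

def read_design(path: str | Path) -> tuple[tuple[str, ...], GroupDesign]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("subject", "group"):
        if col not in df.columns:
            raise ValueError(f"{path}: design file needs a '{col}' column")
    return tuple(df["subject"]), GroupDesign(labels=tuple(df["group"]))


def write_design(subjects, design: GroupDesign, path: str | Path) -> None:
    pd.DataFrame({"subject": subjects, "group": design.labels}).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------- counts

def read_voxel_counts(path: str | Path, atlas: RegionAtlas, seed: int) -> VoxelCounts:
    try:
        counts = np.loadtxt(path, dtype=np.int64, ndmin=2)
    except ValueError as exc:
        raise ValueError(
            f"corrupted count file for region {atlas.labels[seed]}: {path} ({exc})"
        ) from exc
    if counts.shape[1] != atlas.m:
        raise ValueError(
            f"{path}: {counts.shape[1]} columns but atlas has {atlas.m} regions"
        )
    return VoxelCounts(seed=seed, counts=counts)


def read_counts_manifest(
    manifest_path: str | Path, atlas: RegionAtlas
) -> dict[str, list[VoxelCounts]]:
    """Per-subject voxel counts in atlas region order."""
    manifest_path = Path(manifest_path)
    df = pd.read_csv(manifest_path, sep="\t", dtype=str)
    for col in ("subject", "region", "path"):
        if col not in df.columns:
            raise ValueError(f"{manifest_path}: manifest needs a '{col}' column")
    root = manifest_path.parent
    out: dict[str, list[VoxelCounts]] = {}
    for subject, sub_df in df.groupby("subject", sort=False):
        regions = list(sub_df["region"])
        if sorted(regions) != sorted(atlas.labels):
            missing = sorted(set(atlas.labels) - set(regions))
            extra = sorted(set(regions) - set(atlas.labels))
            raise ValueError(
                f"subject {subject}: manifest regions do not match atlas "
                f"(missing {missing}, unknown {extra})"
            )
        by_region = dict(zip(sub_df["region"], sub_df["path"]))
        out[str(subject)] = [
            read_voxel_counts(root / by_region[label], atlas, seed)
            for seed, label in enumerate(atlas.labels)
        ]
    return out


def read_region_counts(path: str | Path) -> tuple[np.ndarray, tuple[str, ...]]:
    """Region x region count matrix with label header row and column."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if list(df.index) != list(df.columns):
        raise ValueError(f"{path}: row and column labels differ")
    return df.to_numpy(dtype=float), tuple(df.columns)


# ---------------------------------------------------------------- tables

def write_fingerprints(fm: FingerprintMatrix, path: str | Path) -> None:
    from .fingerprint import fingerprints_to_frame

    fingerprints_to_frame(fm).to_csv(path, sep="\t")


def read_fingerprints(path: str | Path) -> pd.DataFrame:
    # round_trip parsing so cached fingerprints reload bit-exactly
    return pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def write_similarity(S: np.ndarray, alpha: float, labels, out_dir: str | Path) -> None:
    """One TSV per node: the subject x subject similarity matrix."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for k, label in enumerate(labels):
        pd.DataFrame(S[k]).to_csv(out / f"{label}.tsv", sep="\t", index=False)
    (out / "alpha.json").write_text(json.dumps({"alpha": alpha}) + "\n")


# ------------------------------------------------------------- clinical

def read_clinical(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if "subject" not in df.columns:
        raise ValueError(f"{path}: clinical file needs a 'subject' column")
    return df.set_index("subject")


# ------------------------------------------------------------- manifest

def file_hash(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_run_manifest(manifest: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")


def read_run_manifest(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
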