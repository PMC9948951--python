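"""NIfTI readers/writers and tabular output.

Volumes are exchanged as NIfTI-1 (.nii/.nii.gz) via nibabel; sidecar label
and bundle tables are two-column TSV (integer id, name).  Result tables are
TSV with a header row and all floats serialized with 12 significant digits so
repeated runs produce byte-identical files.
"""

from __future__ import annotations

import os
from pathlib import Path
from typing import Mapping, Sequence

import nibabel as nib
import numpy as np
import pandas as pd

from .types import (
    ActivationResult,
    BoldRun,
    GridMismatchError,
    RegionAtlas,
    TaskDesign,
)

__all__ = [
    "read_bold_run",
    "write_bold_run",
    "read_atlas",
    "write_atlas",
    "write_results",
    "read_label_table",
    "write_label_table",
]

FLOAT_FMT = "%.12g"


def _load(path: str | os.PathLike) -> nib.Nifti1Image:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    return nib.load(str(path))


def read_bold_run(
    path: str | os.PathLike,
    design: TaskDesign,
    subject_id: str,
    condition: str,
) -> BoldRun:
    """Load a 4D BOLD run and validate its length against the design.

    Task runs must have exactly ``design.n_total_samples`` volumes; resting
    runs only need >= 2.
    """
    img = _load(path)
    data = np.asanyarray(img.dataobj)
    if data.ndim != 4:
        raise ValueError(f"{path}: not a 4D series (got {data.ndim}D)")
    return BoldRun(
        data=data.astype(np.float64),
        design=design,
        subject_id=subject_id,
        condition=condition,
        affine=img.affine,
    )


def write_bold_run(run: BoldRun, path: str | os.PathLike) -> None:
    img = nib.Nifti1Image(run.data.astype(np.float32), run.affine)
    img.header.set_zooms((*img.header.get_zooms()[:3], run.design.tr))
    nib.save(img, str(path))


def read_label_table(path: str | os.PathLike) -> dict[int, str]:
    """Read a two-column (id, name) TSV sidecar."""
    df = pd.read_csv(path, sep="\t", header=None, names=["id", "name"],
                     dtype={"id": int, "name": str})
    return dict(zip(df["id"], df["name"]))


def write_label_table(table: Mapping[int, str], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for key in sorted(table):
            fh.write(f"{key}\t{table[key]}\n")


def read_atlas(
    gm_path: str | os.PathLike,
    wm_paths: Mapping[str, str | os.PathLike],
    mask_path: str | os.PathLike,
    gm_label_table: str | os.PathLike | None = None,
) -> RegionAtlas:
    """Load parcellation, density maps and mask; enforce a common grid."""
    gm_img = _load(gm_path)
    mask_img = _load(mask_path)
    gm = np.asanyarray(gm_img.dataobj)
    if gm.ndim != 3:
        raise ValueError(f"{gm_path}: parcellation must be 3D")
    mask = np.asanyarray(mask_img.dataobj).astype(bool)
    if mask.shape != gm.shape or not np.allclose(
        mask_img.affine, gm_img.affine, atol=1e-4
    ):
        raise GridMismatchError("brain mask grid differs from parcellation grid")
    density = {}
    for name, path in wm_paths.items():
        img = _load(path)
        vol = np.asanyarray(img.dataobj).astype(np.float64)
        if vol.shape != gm.shape or not np.allclose(
            img.affine, gm_img.affine, atol=1e-4
        ):
            raise GridMismatchError(
                f"density map '{name}' grid differs from parcellation grid"
            )
        density[name] = vol
    names = read_label_table(gm_label_table) if gm_label_table else None
    return RegionAtlas(
        gm_labels=np.round(gm).astype(np.int32),
        wm_density=density,
        brain_mask=mask,
        affine=gm_img.affine,
        gm_names=names,
    )


def write_atlas(atlas: RegionAtlas, out_dir: str | os.PathLike) -> dict[str, Path]:
    """Write parcellation, mask, density maps and sidecar tables to a directory.

    Returns the paths written, keyed by role ('gm', 'mask', bundle names...).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    gm_path = out / "gm_labels.nii.gz"
    nib.save(nib.Nifti1Image(atlas.gm_labels.astype(np.int32), atlas.affine),
             str(gm_path))
    paths["gm"] = gm_path
    mask_path = out / "brain_mask.nii.gz"
    nib.save(nib.Nifti1Image(atlas.brain_mask.astype(np.uint8), atlas.affine),
             str(mask_path))
    paths["mask"] = mask_path
    wm_dir = out / "wm_density"
    wm_dir.mkdir(exist_ok=True)
    for name in atlas.bundle_names:
        p = wm_dir / f"{name}.nii.gz"
        nib.save(
            nib.Nifti1Image(atlas.wm_density[name].astype(np.float32),
                            atlas.affine),
            str(p),
        )
        paths[name] = p
    gm_table = {i: atlas.gm_region_name(i) for i in atlas.gm_label_ids}
    write_label_table(gm_table, out / "gm_labels.tsv")
    with open(out / "wm_bundles.tsv", "w") as fh:
        for i, name in enumerate(atlas.bundle_names):
            fh.write(f"{i}\t{name}\n")
    return paths


def read_atlas_dir(atlas_dir: str | os.PathLike) -> RegionAtlas:
    """Load an atlas directory produced by :func:`write_atlas`."""
    atlas_dir = Path(atlas_dir)
    wm_dir = atlas_dir / "wm_density"
    wm_paths = {p.name.removesuffix(".nii.gz"): p
                for p in sorted(wm_dir.glob("*.nii.gz"))} if wm_dir.exists() else {}
    table = atlas_dir / "gm_labels.tsv"
    return read_atlas(
        atlas_dir / "gm_labels.nii.gz",
        wm_paths,
        atlas_dir / "brain_mask.nii.gz",
        gm_label_table=table if table.exists() else None,
    )


def results_frame(results: Sequence[ActivationResult]) -> pd.DataFrame:
    rows = [
        {
            "region_id": r.region_id,
            "tissue": r.tissue,
            "observed_power": r.observed_power,
            "p_value": r.p_value,
            "q_value": r.q_value,
            "significant": bool(r.significant),
        }
        for r in results
    ]
    df = pd.DataFrame(rows)
    return df.sort_values(["tissue", "region_id"], kind="stable").reset_index(
        drop=True
    )


def write_results(
    results: Sequence[ActivationResult],
    out_dir: str | os.PathLike,
    task: str = "task",
) -> dict[str, Path]:
    """Write the activation table and the epoch-response table for one task.

    Rows are ordered by (tissue, region_id) so identical inputs always yield
    byte-identical files.
    """
    if not results:
        raise ValueError("results list is empty")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    df = results_frame(results)
    act_path = out / f"activation_{task}.tsv"
    df.to_csv(act_path, sep="\t", index=False, float_format=FLOAT_FMT)
    paths = {"activation": act_path}

    ordered = sorted(results, key=lambda r: (r.tissue, r.region_id))
    with_epoch = [r for r in ordered if r.epoch_response is not None]
    if with_epoch:
        n_t = len(with_epoch[0].epoch_response)
        epoch_df = pd.DataFrame(
            [np.asarray(r.epoch_response, dtype=float) for r in with_epoch],
            index=[r.region_id for r in with_epoch],
            columns=[f"t{j}" for j in range(n_t)],
        )
        epoch_df.insert(0, "tissue", [r.tissue for r in with_epoch])
        epoch_df.index.name = "region_id"
        epoch_path = out / f"epoch_response_{task}.tsv"
        epoch_df.to_csv(epoch_path, sep="\t", float_format=FLOAT_FMT)
        paths["epoch"] = epoch_path
    return paths
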