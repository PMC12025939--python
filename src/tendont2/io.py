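"""NIfTI and tabular I/O helpers.

Images are stored one NIfTI per echo (``echo_00.nii.gz`` ...) with the
voxel spacing encoded in the affine; echo times travel in a JSON sidecar
(``echo_times.json``) or on the command line.  Profiles and cohort tables
are plain CSV.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
import pandas as pd

from .phantom import MultiEchoImage
from .profiling import SEGMENT_NAMES, T2Profile
from .relaxometry import T2Map

__all__ = [
    "save_nifti",
    "load_nifti",
    "save_multi_echo",
    "load_multi_echo",
    "save_t2_map",
    "load_t2_map",
    "profile_to_frame",
    "save_profile_csv",
    "load_profile_csv",
]


def _affine(spacing: Sequence[float]) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1] = spacing[0], spacing[1]
    return aff


def save_nifti(array: np.ndarray, path: Path, spacing: Sequence[float]) -> None:
    img = nib.Nifti1Image(np.asarray(array, dtype=np.float64), _affine(spacing))
    nib.save(img, str(path))


def load_nifti(path: Path) -> tuple[np.ndarray, tuple[float, float]]:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj, dtype=np.float64)
    zooms = img.header.get_zooms()
    return data, (float(zooms[0]), float(zooms[1]))


def save_multi_echo(image: MultiEchoImage, outdir: Path) -> list[Path]:
    """Write one NIfTI per echo plus an ``echo_times.json`` sidecar."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for k, echo in enumerate(image.echoes):
        p = outdir / f"echo_{k:02d}.nii.gz"
        save_nifti(echo, p, image.voxel_spacing)
        paths.append(p)
    (outdir / "echo_times.json").write_text(
        json.dumps({"echo_times_ms": list(image.echo_train)}, indent=2)
    )
    return paths


def load_multi_echo(
    echo_dir: Path, echo_train: Sequence[float] | None = None
) -> MultiEchoImage:
    """Read ``echo_*.nii*`` volumes; TEs from argument or JSON sidecar."""
    echo_dir = Path(echo_dir)
    paths = sorted(echo_dir.glob("echo_*.nii*"))
    if not paths:
        raise FileNotFoundError(f"no echo_*.nii* volumes under {echo_dir}")
    if echo_train is None:
        sidecar = echo_dir / "echo_times.json"
        if not sidecar.exists():
            raise FileNotFoundError(
                "echo times not given and no echo_times.json sidecar found"
            )
        echo_train = json.loads(sidecar.read_text())["echo_times_ms"]
    echoes, spacing = [], None
    for p in paths:
        data, sp = load_nifti(p)
        echoes.append(data)
        spacing = sp
    return MultiEchoImage(
        echoes=echoes, echo_train=tuple(float(t) for t in echo_train),
        voxel_spacing=spacing,
    )


def save_t2_map(t2map: T2Map, outdir: Path, stem: str = "t2map") -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sp = t2map.voxel_spacing
    save_nifti(t2map.t2, outdir / f"{stem}_t2.nii.gz", sp)
    save_nifti(t2map.s0, outdir / f"{stem}_s0.nii.gz", sp)
    save_nifti(t2map.r2, outdir / f"{stem}_r2.nii.gz", sp)
    save_nifti(t2map.valid.astype(np.float64), outdir / f"{stem}_valid.nii.gz", sp)
    (outdir / f"{stem}_meta.json").write_text(
        json.dumps({"echo_times_ms": list(t2map.echo_train)}, indent=2)
    )


def load_t2_map(outdir: Path, stem: str = "t2map") -> T2Map:
    outdir = Path(outdir)
    t2, sp = load_nifti(outdir / f"{stem}_t2.nii.gz")
    s0, _ = load_nifti(outdir / f"{stem}_s0.nii.gz")
    r2, _ = load_nifti(outdir / f"{stem}_r2.nii.gz")
    valid, _ = load_nifti(outdir / f"{stem}_valid.nii.gz")
    meta = json.loads((outdir / f"{stem}_meta.json").read_text())
    return T2Map(
        t2=t2, s0=s0, r2=r2, valid=valid > 0.5,
        echo_train=tuple(meta["echo_times_ms"]), voxel_spacing=sp,
    )


def profile_to_frame(profile: T2Profile, labels_by_center: bool = True) -> pd.DataFrame:
    """Tabulate a profile: bin_center_pct, mean_t2_ms, n_voxels, segment."""
    third = 100.0 / 3.0
    seg_idx = np.minimum((profile.bin_centers / third).astype(int), 2)
    return pd.DataFrame(
        {
            "bin_center_pct": profile.bin_centers,
            "mean_t2_ms": profile.bin_means,
            "n_voxels": profile.bin_counts,
            "segment": [SEGMENT_NAMES[i] for i in seg_idx],
        }
    )


def save_profile_csv(profile: T2Profile, path: Path) -> None:
    profile_to_frame(profile).to_csv(path, index=False, float_format="%.6f")


def load_profile_csv(path: Path) -> T2Profile:
    df = pd.read_csv(path)
    return T2Profile(
        bin_centers=df["bin_center_pct"].to_numpy(dtype=float),
        bin_means=df["mean_t2_ms"].to_numpy(dtype=float),
        bin_counts=df["n_voxels"].to_numpy(dtype=int),
    )
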