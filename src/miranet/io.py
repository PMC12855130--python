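"""Reading and writing cohorts, paired datasets and model archives.

Images persist as 16-bit grayscale PNG (or NIfTI volumes of stacked slices);
a JSON manifest records paths, modality tags, degradation specs, partitions
and seeds.  Model parameters persist as a compressed ``.npz`` archive with a
JSON sidecar carrying the architecture config and training seed.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import imageio.v3 as iio
import nibabel as nib
import numpy as np

from .degradations import DegradationSpec, PairedSample
from .image import ImageSlice
from .model import MiraNet, ModelConfig

_U16 = 65535.0


def write_png(image: ImageSlice, path: str | Path) -> None:
    lo, hi = image.intensity_range
    scaled = np.round((image.pixels - lo) / (hi - lo) * _U16)
    iio.imwrite(Path(path), scaled.clip(0, _U16).astype(np.uint16))


def read_png(path: str | Path, modality_tag: str = "mri_like",
             intensity_range: tuple[float, float] = (0.0, 1.0)) -> ImageSlice:
    raw = np.asarray(iio.imread(Path(path))).astype(np.float64)
    if raw.ndim == 3:  # collapse any color channels
        raw = raw.mean(axis=-1)
    denom = _U16 if raw.max() > 255 else 255.0
    lo, hi = intensity_range
    return ImageSlice(pixels=lo + raw / denom * (hi - lo),
                      modality_tag=modality_tag, intensity_range=intensity_range)


def write_nifti(images: list[ImageSlice], path: str | Path) -> None:
    """Stack equally shaped slices into one NIfTI volume."""
    vol = np.stack([im.pixels for im in images], axis=-1)
    nib.save(nib.Nifti1Image(vol.astype(np.float32), affine=np.eye(4)), str(path))


def read_nifti_slices(path: str | Path, modality_tag: str = "mri_like",
                      intensity_range: tuple[float, float] = (0.0, 1.0)
                      ) -> list[ImageSlice]:
    vol = np.asanyarray(nib.load(str(path)).dataobj).astype(np.float64)
    if vol.ndim == 2:
        vol = vol[:, :, None]
    return [ImageSlice(pixels=np.clip(vol[:, :, k], *intensity_range),
                       modality_tag=modality_tag, intensity_range=intensity_range)
            for k in range(vol.shape[2])]


def write_paired_dataset(samples: list[PairedSample], out_dir: str | Path,
                         partition: str = "train", seed: int | None = None) -> Path:
    """Write LQ/HQ PNG pairs plus a JSON manifest; returns the manifest path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    entries = []
    for i, s in enumerate(samples):
        lq = f"{partition}_{i:04d}_lq.png"
        hq = f"{partition}_{i:04d}_hq.png"
        write_png(s.low_quality, out / lq)
        write_png(s.high_quality, out / hq)
        entries.append({"low_quality": lq, "high_quality": hq,
                        "modality_tag": s.high_quality.modality_tag,
                        "degradation": dataclasses.asdict(s.spec_used),
                        "partition": partition})
    manifest = out / f"manifest_{partition}.json"
    manifest.write_text(json.dumps(
        {"seed": seed, "partition": partition, "samples": entries}, indent=1))
    return manifest


def read_paired_dataset(manifest_path: str | Path) -> list[PairedSample]:
    manifest_path = Path(manifest_path)
    meta = json.loads(manifest_path.read_text())
    root = manifest_path.parent
    samples = []
    for e in meta["samples"]:
        spec = DegradationSpec(**e["degradation"])
        lq = read_png(root / e["low_quality"], e["modality_tag"])
        hq = read_png(root / e["high_quality"], e["modality_tag"])
        samples.append(PairedSample(low_quality=lq, high_quality=hq,
                                    degradation_label=spec.kind, spec_used=spec))
    return samples


def save_model(model: MiraNet, path: str | Path, seed: int | None = None) -> None:
    """Parameter archive (.npz) plus a JSON sidecar with the config."""
    path = Path(path)
    np.savez_compressed(path, **model.state_dict())
    sidecar = {"config": dataclasses.asdict(model.config), "seed": seed}
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def load_model(path: str | Path) -> MiraNet:
    path = Path(path)
    if not path.suffix:
        path = path.with_suffix(".npz")
    sidecar = json.loads(path.with_suffix(".json").read_text())
    config = ModelConfig(**sidecar["config"])
    model = MiraNet(config, seed=sidecar.get("seed") or 0)
    with np.load(path) as archive:
        model.load_state_dict({k: archive[k] for k in archive.files})
    return model
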