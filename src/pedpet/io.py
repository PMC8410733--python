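"""NIfTI / JSON persistence for phantoms and reconstructed images.

A phantom is stored as a 3-volume NIfTI (activity, attenuation, region
labels) plus a JSON sidecar with patient metadata and the label legend.
Reconstructions are stored as a single NIfTI volume with provenance in a
JSON sidecar.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .phantom import PatientMeta, PhantomImage
from .recon import ReconResult

__all__ = ["save_phantom", "load_phantom", "save_recon_image", "load_recon_image"]

_BODY_LABEL = 1
_LIVER_LABEL = 2
_LESION_BASE = 10


def _sidecar(path: Path) -> Path:
    return path.with_suffix("").with_suffix(".json") if path.suffix == ".gz" \
        else path.with_suffix(".json")


def save_phantom(phantom: PhantomImage, path) -> None:
    path = Path(path)
    labels = np.zeros(phantom.shape, dtype=np.int16)
    labels[phantom.masks["body"]] = _BODY_LABEL
    labels[phantom.masks["liver"]] = _LIVER_LABEL
    lesion_names = sorted(k for k in phantom.masks if k.startswith("lesion_"))
    for i, name in enumerate(lesion_names):
        labels[phantom.masks[name]] = _LESION_BASE + i
    vol = np.stack(
        [phantom.activity_map, phantom.mu_map, labels.astype(float)], axis=-1
    )
    affine = np.diag([phantom.voxel_size[1], phantom.voxel_size[0], 1.0, 1.0])
    nib.save(nib.Nifti1Image(vol, affine), str(path))
    meta = None
    if phantom.meta is not None:
        m = phantom.meta
        meta = {
            "patient_id": m.patient_id, "weight": m.weight, "height": m.height,
            "bmi": m.bmi, "injected_activity": m.injected_activity,
            "age": m.age, "sex": m.sex, "n_lesions": m.n_lesions,
        }
    sidecar = {
        "voxel_size": list(phantom.voxel_size),
        "lesions": lesion_names,
        "meta": meta,
        "labels": {"body": _BODY_LABEL, "liver": _LIVER_LABEL,
                   "lesion_base": _LESION_BASE},
    }
    _sidecar(path).write_text(json.dumps(sidecar, indent=1))


def load_phantom(path) -> PhantomImage:
    path = Path(path)
    vol = np.asarray(nib.load(str(path)).dataobj)
    sidecar = json.loads(_sidecar(path).read_text())
    labels = vol[..., 2].astype(np.int16)
    masks = {"body": labels >= _BODY_LABEL, "liver": labels == _LIVER_LABEL}
    for i, name in enumerate(sidecar["lesions"]):
        masks[name] = labels == _LESION_BASE + i
    meta = PatientMeta(**sidecar["meta"]) if sidecar.get("meta") else None
    return PhantomImage(
        activity_map=vol[..., 0],
        mu_map=vol[..., 1],
        voxel_size=tuple(sidecar["voxel_size"]),
        masks=masks,
        meta=meta,
    )


def save_recon_image(result: ReconResult, path) -> None:
    path = Path(path)
    affine = np.diag([result.voxel_size, result.voxel_size, 1.0, 1.0])
    nib.save(nib.Nifti1Image(result.image, affine), str(path))
    sidecar = {
        "variant": result.params.variant,
        "iterations": result.params.n_iterations,
        "subsets": result.params.subsets,
        "postfilter_fwhm": result.params.postfilter_fwhm,
        "psf_fwhm": result.params.psf_fwhm,
        "count_level": result.count_level,
        "voxel_size": result.voxel_size,
        "zero_count_warning": result.zero_count_warning,
    }
    _sidecar(path).write_text(json.dumps(sidecar, indent=1))


def load_recon_image(path) -> tuple[np.ndarray, dict]:
    path = Path(path)
    img = np.asarray(nib.load(str(path)).dataobj)
    return img, json.loads(_sidecar(path).read_text())
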