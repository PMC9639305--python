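"""Slice bundle file formats.

Each slice is stored as an uncompressed NIfTI intensity image, a labeled
NIfTI mask (0 background, 1 myocardium, 2 infarct, 3 MVO) and a JSON
sidecar holding the contours (vertex lists) and the generating spec.
Round-trips are lossless for masks and contours and float32-exact for
images.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import nibabel as nib
import numpy as np

from ..myogeometry import Contour
from ..phantom import PhantomSlice, PhantomSpec

LABEL_BACKGROUND = 0
LABEL_MYOCARDIUM = 1
LABEL_INFARCT = 2
LABEL_MVO = 3


def _affine(pixel_spacing: float) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0] = aff[1, 1] = pixel_spacing
    return aff


def _spec_to_jsonable(spec: PhantomSpec) -> dict:
    d = dataclasses.asdict(spec)
    if d.get("center") is not None:
        d["center"] = list(d["center"])
    return d


def spec_from_dict(d: dict) -> PhantomSpec:
    d = dict(d)
    if d.get("center") is not None:
        d["center"] = tuple(d["center"])
    return PhantomSpec(**d)


def labels_from_slice(sl: PhantomSlice) -> np.ndarray:
    labels = np.zeros(sl.image.shape, dtype=np.uint8)
    labels[sl.myo_mask] = LABEL_MYOCARDIUM
    labels[sl.truth_infarct_mask] = LABEL_INFARCT
    labels[sl.truth_mvo_mask] = LABEL_MVO
    return labels


def write_slice_bundle(sl: PhantomSlice, out_dir: str | Path, slice_id: str) -> dict[str, str]:
    """Write one slice; returns a mapping of role -> relative file name."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    spacing = sl.spec.pixel_spacing if sl.spec is not None else 1.0
    aff = _affine(spacing)

    img_name = f"{slice_id}.nii"
    labels_name = f"{slice_id}_labels.nii"
    meta_name = f"{slice_id}_meta.json"

    nib.save(nib.Nifti1Image(sl.image.astype(np.float32), aff), out_dir / img_name)
    nib.save(nib.Nifti1Image(labels_from_slice(sl), aff), out_dir / labels_name)

    meta = {
        "slice_id": slice_id,
        "site_label": sl.site_label,
        "endo_contour": sl.endo_contour.vertices.tolist(),
        "epi_contour": sl.epi_contour.vertices.tolist(),
        "spec": _spec_to_jsonable(sl.spec) if sl.spec is not None else None,
    }
    (out_dir / meta_name).write_text(json.dumps(meta, indent=1))
    return {"image": img_name, "labels": labels_name, "meta": meta_name}


def read_slice_bundle(
    image_path: str | Path,
    meta_path: str | Path,
    labels_path: str | Path | None = None,
) -> PhantomSlice:
    """Reconstruct a slice from files.

    ``labels_path`` may be omitted for externally supplied images without a
    reference delineation: the truth masks are then marked absent (``None``)
    and only segmentation (no error statistics) is possible downstream.
    """
    image_path, meta_path = Path(image_path), Path(meta_path)
    for p in (image_path, meta_path):
        if not p.exists():
            raise FileNotFoundError(str(p))
    image = np.asarray(nib.load(str(image_path)).dataobj, dtype=np.float32).astype(float)
    if image.ndim != 2:
        image = np.squeeze(image)
    meta = json.loads(meta_path.read_text())
    endo = Contour(np.asarray(meta["endo_contour"], dtype=float))
    epi = Contour(np.asarray(meta["epi_contour"], dtype=float))
    spec = spec_from_dict(meta["spec"]) if meta.get("spec") else None

    myo = infarct = mvo = None
    if labels_path is not None:
        labels_path = Path(labels_path)
        if not labels_path.exists():
            raise FileNotFoundError(str(labels_path))
        labels = np.asarray(nib.load(str(labels_path)).dataobj)
        if labels.ndim != 2:
            labels = np.squeeze(labels)
        if labels.shape != image.shape:
            raise ValueError(
                f"shape mismatch between {image_path.name} {image.shape} and "
                f"{labels_path.name} {labels.shape}"
            )
        myo = labels >= LABEL_MYOCARDIUM
        infarct = labels >= LABEL_INFARCT
        mvo = labels == LABEL_MVO
    sl = PhantomSlice(
        image=image,
        endo_contour=endo,
        epi_contour=epi,
        myo_mask=myo,
        truth_infarct_mask=infarct,
        truth_mvo_mask=mvo,
        spec=spec,
    )
    sl.slice_id = meta.get("slice_id")
    if spec is None and meta.get("site_label"):
        sl.site_label_override = meta["site_label"]
    return sl


def write_cohort(slices, out_dir: str | Path) -> list[dict[str, str]]:
    """Write every slice of a cohort; returns the per-slice file mappings."""
    entries = []
    for i, sl in enumerate(slices):
        slice_id = f"slice_{i:04d}"
        files = write_slice_bundle(sl, out_dir, slice_id)
        files["slice_id"] = slice_id
        entries.append(files)
    return entries


def read_cohort(cohort_dir: str | Path) -> list[PhantomSlice]:
    """Load every slice bundle found in a cohort directory (sorted order)."""
    cohort_dir = Path(cohort_dir)
    metas = sorted(cohort_dir.glob("*_meta.json"))
    if not metas:
        raise FileNotFoundError(f"no slice bundles in {cohort_dir}")
    slices = []
    for meta_path in metas:
        stem = meta_path.name[: -len("_meta.json")]
        labels = cohort_dir / f"{stem}_labels.nii"
        slices.append(
            read_slice_bundle(
                cohort_dir / f"{stem}.nii",
                meta_path,
                labels if labels.exists() else None,
            )
        )
    return slices
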