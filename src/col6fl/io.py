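"""Dataset persistence: 8-bit RGB PNG images plus a CSV manifest.

The manifest schema is ``image_path,patient_id,site_id,class_label`` with
class_label one of the four canonical strings.  A directory written by
:func:`write_dataset` round-trips through :func:`read_dataset` up to 8-bit
quantization; :func:`read_dataset` equally accepts user-supplied image
directories that follow the same manifest schema.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .phenotypes import PathogenicClass
from .simulate import FederatedDataset, LabeledImage

__all__ = ["write_dataset", "read_dataset", "MANIFEST_COLUMNS"]

MANIFEST_COLUMNS = ["image_path", "patient_id", "site_id", "class_label"]


def write_dataset(dataset: FederatedDataset, out_dir: str | Path) -> Path:
    """Write all images as PNG under per-site subdirectories and return the
    manifest path (``<out_dir>/manifest.csv``)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for site_id, images in dataset.sites.items():
        site_dir = out / site_id
        site_dir.mkdir(exist_ok=True)
        for i, im in enumerate(images):
            rel = Path(site_id) / f"{im.patient_id}_{i:04d}.png"
            arr = np.clip(np.round(im.pixels * 255.0), 0, 255).astype(np.uint8)
            Image.fromarray(arr, mode="RGB").save(out / rel)
            rows.append(
                {
                    "image_path": str(rel),
                    "patient_id": im.patient_id,
                    "site_id": site_id,
                    "class_label": im.label.label,
                }
            )
    manifest = out / "manifest.csv"
    pd.DataFrame(rows, columns=MANIFEST_COLUMNS).to_csv(manifest, index=False)
    return manifest


def read_dataset(path: str | Path) -> FederatedDataset:
    """Load a dataset directory (or a manifest CSV path) back into memory."""
    p = Path(path)
    manifest = p if p.suffix == ".csv" else p / "manifest.csv"
    if not manifest.exists():
        raise FileNotFoundError(f"manifest not found: {manifest}")
    root = manifest.parent
    df = pd.read_csv(manifest)
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"manifest missing columns {missing}")
    sites: dict[str, list[LabeledImage]] = {}
    for row in df.itertuples(index=False):
        arr = np.asarray(Image.open(root / row.image_path).convert("RGB"))
        sites.setdefault(str(row.site_id), []).append(
            LabeledImage(
                pixels=arr.astype(float) / 255.0,
                label=PathogenicClass.from_label(str(row.class_label)),
                patient_id=str(row.patient_id),
                site_id=str(row.site_id),
            )
        )
    return FederatedDataset(sites)
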