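"""Regenerate the texture-descriptor normalization constants.

The descriptor ships with fixed per-feature center/scale constants
(``col6fl/data/descriptor_norm.json``), computed once from a reference
batch of the packaged scenario: a fixed-seed grid of renders covering all
four phenotype classes at both default sites.  Normalizing with frozen
constants keeps feature extraction stateless and node-independent (no
training-data statistics cross the privacy boundary) while conditioning
the linear head's optimization.  Gradient-magnitude features keep a zero
center so they remain exactly zero on constant images.

Run from the repository root:  python scripts/calibrate_descriptor.py
"""

import json
from pathlib import Path

import numpy as np

from col6fl.augment import resize_normalize
from col6fl.features import feature_names, _texture_descriptor
from col6fl.phenotypes import PathogenicClass, sample_texture_params
from col6fl.scenario import default_scenario
from col6fl.simulate import render_image

REFERENCE_SEED = 20240401
PER_CELL = 10  # images per (class, site) cell


def main() -> None:
    scenario = default_scenario()
    rows = []
    k = 0
    for site in scenario.sites:
        for cls in PathogenicClass:
            for i in range(PER_CELL):
                ss = np.random.SeedSequence(REFERENCE_SEED, spawn_key=(k,))
                rng = np.random.default_rng(ss)
                params = sample_texture_params(cls, rng, scenario.texture_bounds)
                img = resize_normalize(render_image(params, site, rng))
                rows.append(_texture_descriptor(img))
                k += 1
    X = np.stack(rows)
    center = X.mean(axis=0)
    scale = X.std(axis=0)
    scale[scale < 1e-3] = 1.0
    names = feature_names()
    for i, name in enumerate(names):
        if name.startswith("grad_"):
            center[i] = 0.0
    out = {
        "reference_seed": REFERENCE_SEED,
        "n_reference_images": len(rows),
        "names": names,
        "center": [round(float(v), 6) for v in center],
        "scale": [round(float(v), 6) for v in scale],
    }
    path = Path(__file__).resolve().parents[1] / "src/col6fl/data/descriptor_norm.json"
    path.write_text(json.dumps(out, indent=1))
    print(f"wrote {path} ({len(rows)} reference images, d={X.shape[1]})")


if __name__ == "__main__":
    main()
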