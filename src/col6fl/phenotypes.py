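"""Pathogenic-mechanism classes and their procedural texture phenotypes.

Collagen-VI immunofluorescence images of cultured fibroblast matrix fall
into four phenotype classes: healthy controls and three dominant-negative
variant mechanisms (glycine substitution in the Gly-X-Y triple-helix motif,
the recurrent COL6A1 intron-11 pseudoexon insertion, and in-frame exon
skipping).  The synthetic generator encodes each class as an interval box
over six interpretable texture parameters; an image's parameters are drawn
uniformly from its class box.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, fields

import numpy as np

__all__ = [
    "PathogenicClass",
    "TextureParams",
    "TextureBounds",
    "sample_texture_params",
]


class PathogenicClass(enum.Enum):
    """The four phenotype classes, indexed 1..4 in the canonical order."""

    control = 1
    glycine_substitution = 2
    pseudoexon_insertion = 3
    exon_skipping = 4

    @property
    def index(self) -> int:
        """1-based class index (control=1, ..., exon_skipping=4)."""
        return self.value

    @property
    def label(self) -> str:
        return self.name

    @classmethod
    def from_label(cls, label: str) -> "PathogenicClass":
        try:
            return cls[label]
        except KeyError:
            raise ValueError(
                f"unknown pathogenic class label {label!r}; expected one of "
                f"{[c.name for c in cls]}"
            ) from None


# unit ranges for validation: (lo, hi, hi_inclusive)
_FIELD_RANGES = {
    "filament_density": (0.0, np.inf),
    "orientation_coherence": (0.0, 1.0),
    "bead_spacing": (1e-9, np.inf),
    "bead_contrast": (0.0, 1.0),
    "fragmentation": (0.0, 1.0),
    "puncta_rate": (0.0, np.inf),
}


@dataclass(frozen=True)
class TextureParams:
    """Parameters of one rendered matrix texture.

    filament_density and puncta_rate are expected counts per 10^4 px^2;
    bead_spacing is the period (px) of intensity beading along a fibril;
    orientation_coherence in [0, 1] is the mean resultant length of the
    (axial) fibril orientation distribution; fragmentation is the
    probability that a fibril is broken into segments; bead_contrast in
    [0, 1] is the depth of the beading modulation.
    """

    filament_density: float
    orientation_coherence: float
    bead_spacing: float
    bead_contrast: float
    fragmentation: float
    puncta_rate: float

    def __post_init__(self) -> None:
        for f in fields(self):
            lo, hi = _FIELD_RANGES[f.name]
            v = getattr(self, f.name)
            if not np.isfinite(v) or v < lo or v > hi:
                raise ValueError(
                    f"TextureParams.{f.name}={v} outside allowed range [{lo}, {hi}]"
                )


#: mapping class -> {field name -> (lo, hi)} uniform sampling box
TextureBounds = dict


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def sample_texture_params(
    cls: PathogenicClass,
    rng_seed,
    bounds: TextureBounds | None = None,
) -> TextureParams:
    """Draw texture parameters uniformly from the class-conditional box.

    Parameters
    ----------
    cls
        Phenotype class (a :class:`PathogenicClass` or its label string).
    rng_seed
        Integer seed, ``SeedSequence`` or ``Generator``.  Deterministic for
        a given seed.
    bounds
        Class-conditional interval box; defaults to the packaged scenario's
        bounds.

    Raises
    ------
    ValueError
        If the class label is unknown.
    """
    if isinstance(cls, str):
        cls = PathogenicClass.from_label(cls)
    if not isinstance(cls, PathogenicClass):
        raise ValueError(f"unknown pathogenic class: {cls!r}")
    if bounds is None:
        from .scenario import default_scenario

        bounds = default_scenario().texture_bounds
    box = bounds[cls]
    rng = _as_rng(rng_seed)
    values = {}
    # fixed field order => reproducible draws
    for f in fields(TextureParams):
        lo, hi = box[f.name]
        values[f.name] = float(rng.uniform(lo, hi))
    return TextureParams(**values)
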