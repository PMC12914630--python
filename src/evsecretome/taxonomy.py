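"""Size-based taxonomy of extracellular vesicles.

Extracellular vesicles (EVs) are classified here purely by hydrodynamic
radius into four canonical classes: exomeres (15-30 nm radius), exosomes
(25-75 nm), microvesicles (50-500 nm) and apoptotic cell bodies
(500-2500 nm). The class intervals deliberately overlap at 25-30 nm,
50-75 nm and at the single point 500 nm; a radius falling in an overlap
belongs to *every* containing class, so counts at such radii are
intentionally double-counted when profiles are binned per class.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable

__all__ = [
    "SizeClass",
    "Taxonomy",
    "DEFAULT_CLASSES",
    "default_taxonomy",
    "classify_radius",
    "classify_diameter",
]

CLASS_NAMES = ("exomere", "exosome", "microvesicle", "apoptotic_body")


@dataclass(frozen=True)
class SizeClass:
    """A named, closed hydrodynamic-radius interval [r_min, r_max] in nm."""

    name: str
    r_min: float
    r_max: float

    def __post_init__(self) -> None:
        if not (self.r_min > 0 and math.isfinite(self.r_min) and math.isfinite(self.r_max)):
            raise ValueError(f"size class {self.name!r}: bounds must be positive and finite")
        if not self.r_min < self.r_max:
            raise ValueError(f"size class {self.name!r}: r_min must be < r_max")

    def contains(self, r: float) -> bool:
        """Closed-interval membership: r_min <= r <= r_max."""
        return self.r_min <= r <= self.r_max


DEFAULT_CLASSES: tuple[SizeClass, ...] = (
    SizeClass("exomere", 15.0, 30.0),
    SizeClass("exosome", 25.0, 75.0),
    SizeClass("microvesicle", 50.0, 500.0),
    SizeClass("apoptotic_body", 500.0, 2500.0),
)


@dataclass(frozen=True)
class Taxonomy:
    """An ordered collection of size classes, smallest first.

    The default taxonomy covers [15, 2500] nm with overlaps at [25, 30],
    [50, 75] and the point 500 nm. Custom (e.g. non-overlapping) taxonomies
    are allowed; order should be ascending in r_min.
    """

    classes: tuple[SizeClass, ...] = field(default=DEFAULT_CLASSES)

    def __post_init__(self) -> None:
        if not self.classes:
            raise ValueError("taxonomy needs at least one size class")
        names = [c.name for c in self.classes]
        if len(set(names)) != len(names):
            raise ValueError("size class names must be unique")
        object.__setattr__(self, "classes", tuple(self.classes))

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(c.name for c in self.classes)

    def classify_radius(self, r: float) -> set[str]:
        return classify_radius(r, self)

    def classify_diameter(self, d: float) -> set[str]:
        return classify_diameter(d, self)

    @classmethod
    def from_dict(cls, spec: Iterable[dict]) -> "Taxonomy":
        """Build from a list of {'name':…, 'r_min':…, 'r_max':…} mappings."""
        return cls(tuple(SizeClass(d["name"], float(d["r_min"]), float(d["r_max"])) for d in spec))


def default_taxonomy() -> Taxonomy:
    return Taxonomy()


def _check_positive(x: float, what: str) -> float:
    x = float(x)
    if not math.isfinite(x) or x <= 0:
        raise ValueError(f"{what} must be positive and finite, got {x!r}")
    return x


def classify_radius(r: float, taxonomy: Taxonomy | None = None) -> set[str]:
    """Return the names of every class whose closed interval contains r (nm).

    A radius in an inter-class overlap region (e.g. 62.443 nm, inside both
    the exosome and the microvesicle intervals) maps to multiple classes and
    is consequently counted once per class downstream. Radii outside all
    classes return the empty set.
    """
    r = _check_positive(r, "radius")
    taxonomy = taxonomy or default_taxonomy()
    return {c.name for c in taxonomy.classes if c.contains(r)}


def classify_diameter(d: float, taxonomy: Taxonomy | None = None) -> set[str]:
    """Classify a particle by diameter (nm): identical to classify_radius(d/2)."""
    d = _check_positive(d, "diameter")
    return classify_radius(d / 2.0, taxonomy)
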