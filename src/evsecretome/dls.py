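"""DLS profile containers, CSV I/O and per-class binning.

A dynamic-light-scattering (DLS) run exports a relative particle count rate
on an ascending hydrodynamic-radius grid (15 nm to 5 µm here). This module
reads and writes those profiles in a plain-text CSV dialect, and bins the
per-radius counts into the four EV size classes. Grid points that fall in
an overlap between two class intervals contribute their full count to each
containing class (the double-count rule); points outside every class are
kept in an ``unclassified`` bucket so that totals remain auditable.

CSV dialect: UTF-8, LF line endings, leading ``# key=value`` comment lines
carrying the sample metadata, then a ``radius_nm,count_rate`` header and one
row per grid point.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict, replace
from pathlib import Path

import numpy as np

from .taxonomy import Taxonomy, default_taxonomy

__all__ = [
    "SampleMetadata",
    "DLSProfile",
    "ClassCounts",
    "ProfileFormatError",
    "read_profile",
    "write_profile",
    "bin_profile",
    "default_grid",
]

REGIONS = ("cortex", "hippocampus", "brainstem")
PLATFORMS = ("petri", "neurofluidic")
COMPARTMENTS = ("dish", "culture_well", "peripheric_channel")
CONDITIONS = ("pre", "sham", "oa")

# The instrument grid radius reported to land inside the exosome/microvesicle
# overlap; inserted into the default simulation grid so the double-count path
# is always exercised.
OVERLAP_GRID_RADIUS_NM = 62.443


class ProfileFormatError(ValueError):
    """Raised when a profile file violates the CSV dialect."""


@dataclass(frozen=True)
class SampleMetadata:
    sample_id: str
    region: str
    platform: str
    compartment: str
    div: int
    condition: str
    timepoint_h: float
    n_bio: int
    n_meas: int
    cell_seed_density: float  # cells/mL
    collection_interval_days: float

    def __post_init__(self) -> None:
        if self.region not in REGIONS:
            raise ValueError(f"unknown region {self.region!r}")
        if self.platform not in PLATFORMS:
            raise ValueError(f"unknown platform {self.platform!r}")
        if self.compartment not in COMPARTMENTS:
            raise ValueError(f"unknown compartment {self.compartment!r}")
        if self.platform == "petri" and self.compartment != "dish":
            raise ValueError("petri platform implies compartment='dish'")
        if self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}")
        if not 1 <= int(self.n_meas) <= 7:
            raise ValueError("n_meas must be in 1..7")
        if self.collection_interval_days <= 0:
            raise ValueError("collection_interval_days must be > 0")
        if self.cell_seed_density <= 0:
            raise ValueError("cell_seed_density must be > 0")

    def to_dict(self) -> dict:
        return asdict(self)


_META_TYPES = {
    "sample_id": str,
    "region": str,
    "platform": str,
    "compartment": str,
    "div": int,
    "condition": str,
    "timepoint_h": float,
    "n_bio": int,
    "n_meas": int,
    "cell_seed_density": float,
    "collection_interval_days": float,
}


@dataclass(frozen=True)
class DLSProfile:
    """Per-radius relative count rates for one DLS measurement."""

    metadata: SampleMetadata
    grid: np.ndarray  # ascending radii, nm
    count_rate: np.ndarray  # same length, >= 0, instrument-relative units

    def __post_init__(self) -> None:
        grid = np.asarray(self.grid, dtype=float)
        cr = np.asarray(self.count_rate, dtype=float)
        if grid.ndim != 1 or cr.shape != grid.shape:
            raise ValueError("grid and count_rate must be 1-D arrays of equal length")
        if grid.size == 0:
            raise ValueError("profile grid is empty")
        if not np.all(np.isfinite(grid)) or not np.all(np.diff(grid) > 0):
            raise ValueError("grid must be finite and strictly increasing")
        if not np.all(np.isfinite(cr)) or np.any(cr < 0):
            raise ValueError("count_rate must be finite and non-negative")
        object.__setattr__(self, "grid", grid)
        object.__setattr__(self, "count_rate", cr)

    @property
    def total(self) -> float:
        return float(self.count_rate.sum())

    def scaled(self, factor: float) -> "DLSProfile":
        return replace(self, count_rate=self.count_rate * float(factor))


@dataclass(frozen=True)
class ClassCounts:
    """Raw class-summed count rates for one profile."""

    metadata: SampleMetadata
    counts: dict[str, float]
    unclassified: float

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.counts.values()) or self.unclassified < 0:
            raise ValueError("class counts must be non-negative")

    @property
    def total(self) -> float:
        return sum(self.counts.values()) + self.unclassified


def default_grid(n: int = 200, r_min: float = 15.0, r_max: float = 5000.0) -> np.ndarray:
    """Log-spaced analysis grid with the 62.443 nm overlap radius inserted."""
    grid = np.geomspace(r_min, r_max, n)
    grid = np.unique(np.concatenate([grid, [OVERLAP_GRID_RADIUS_NM]]))
    return grid


def _fmt(x: float) -> str:
    # repr gives the shortest round-tripping decimal for a float
    return repr(float(x))


def write_profile(profile: DLSProfile, path: str | Path) -> None:
    """Write a profile in the package CSV dialect (canonical formatting)."""
    lines = []
    for key in _META_TYPES:
        lines.append(f"# {key}={getattr(profile.metadata, key)}")
    lines.append("radius_nm,count_rate")
    for r, c in zip(profile.grid, profile.count_rate):
        lines.append(f"{_fmt(r)},{_fmt(c)}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8", newline="\n")


def read_profile(path: str | Path) -> DLSProfile:
    """Parse and validate a profile file; errors name the offending line."""
    path = Path(path)
    meta_raw: dict[str, str] = {}
    radii: list[float] = []
    counts: list[float] = []
    header_seen = False
    with path.open("r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if "=" not in body:
                    raise ProfileFormatError(f"{path}:{lineno}: malformed metadata comment {line!r}")
                key, _, value = body.partition("=")
                meta_raw[key.strip()] = value.strip()
                continue
            if not header_seen:
                if line.strip() != "radius_nm,count_rate":
                    raise ProfileFormatError(
                        f"{path}:{lineno}: expected header 'radius_nm,count_rate', got {line!r}"
                    )
                header_seen = True
                continue
            parts = line.split(",")
            if len(parts) != 2:
                raise ProfileFormatError(f"{path}:{lineno}: expected 2 fields, got {len(parts)}")
            try:
                r, c = float(parts[0]), float(parts[1])
            except ValueError as exc:
                raise ProfileFormatError(f"{path}:{lineno}: non-numeric row {line!r}") from exc
            if not (math.isfinite(r) and math.isfinite(c)):
                raise ProfileFormatError(f"{path}:{lineno}: non-finite value in {line!r}")
            if c < 0:
                raise ProfileFormatError(f"{path}:{lineno}: negative count_rate {c}")
            if radii and r <= radii[-1]:
                raise ProfileFormatError(f"{path}:{lineno}: grid not strictly increasing at {r}")
            radii.append(r)
            counts.append(c)

    missing = set(_META_TYPES) - set(meta_raw)
    if missing:
        raise ProfileFormatError(f"{path}: missing metadata keys: {sorted(missing)}")
    if not radii:
        raise ProfileFormatError(f"{path}: no data rows")
    try:
        meta = SampleMetadata(**{k: t(meta_raw[k]) for k, t in _META_TYPES.items()})
    except ValueError as exc:
        raise ProfileFormatError(f"{path}: invalid metadata: {exc}") from exc
    return DLSProfile(metadata=meta, grid=np.array(radii), count_rate=np.array(counts))


def bin_profile(profile: DLSProfile, taxonomy: Taxonomy | None = None) -> ClassCounts:
    """Sum count rates per size class, double-counting overlap radii.

    counts[c] = sum of count_rate over grid points whose radius lies in the
    closed interval of class c; a point inside k classes contributes to all
    k of them. Points outside every class go to ``unclassified``.
    """
    taxonomy = taxonomy or default_taxonomy()
    counts = {name: 0.0 for name in taxonomy.names}
    unclassified = 0.0
    for r, c in zip(profile.grid, profile.count_rate):
        hit = False
        for cls in taxonomy.classes:
            if cls.contains(r):
                counts[cls.name] += c
                hit = True
        if not hit:
            unclassified += c
    return ClassCounts(metadata=profile.metadata, counts=counts, unclassified=unclassified)
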