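"""Cryo-EM vesicle census: exclusive size-class composition summaries.

Unlike DLS binning, a cryo-EM census assigns every imaged vesicle to
exactly one class (the composition percentages must sum to ~100), so a
diameter falling in an interval overlap is resolved to the smaller class.
Percentages are integers rounded half-up; membrane thickness is averaged
per lamellarity group, ignoring unmeasured (zero) entries.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path

from .taxonomy import Taxonomy, classify_diameter, default_taxonomy

__all__ = ["VesicleRecord", "CensusSummary", "census", "read_vesicles"]

LAMELLARITIES = ("single_leaflet", "unilamellar", "multilamellar", "unknown")


@dataclass(frozen=True)
class VesicleRecord:
    diameter_nm: float
    lamellarity: str = "unknown"
    membrane_thickness_nm: float = 0.0  # 0 = unmeasured
    electron_dense_lumen: bool = False

    def __post_init__(self) -> None:
        if not math.isfinite(self.diameter_nm) or self.diameter_nm <= 0:
            raise ValueError("diameter_nm must be positive and finite")
        if self.lamellarity not in LAMELLARITIES:
            raise ValueError(f"unknown lamellarity {self.lamellarity!r}")
        if self.membrane_thickness_nm < 0 or self.membrane_thickness_nm >= self.diameter_nm:
            raise ValueError("membrane thickness must be in [0, diameter)")


@dataclass(frozen=True)
class CensusSummary:
    counts: dict[str, int]  # per class, plus 'unclassified' when non-empty
    percent: dict[str, int]  # integer, rounded half-up
    total: int
    mean_thickness_by_lamellarity: dict[str, float]


def _pct(count: int, total: int) -> int:
    frac = Decimal(100 * count) / Decimal(total)
    return int(frac.quantize(Decimal(1), rounding=ROUND_HALF_UP))


def census(records, taxonomy: Taxonomy | None = None) -> CensusSummary:
    """Exclusive class composition of a vesicle population.

    Each vesicle goes to the smallest-radius class containing diameter/2
    (overlap ties break toward the smaller class); vesicles outside every
    class interval are tallied as 'unclassified'.
    """
    records = list(records)
    if not records:
        raise ValueError("census requires at least one vesicle record")
    taxonomy = taxonomy or default_taxonomy()
    counts: dict[str, int] = {}
    thick: dict[str, list[float]] = {}
    for rec in records:
        classes = classify_diameter(rec.diameter_nm, taxonomy)
        if classes:
            # taxonomy order is ascending: first containing class is smallest
            name = next(n for n in taxonomy.names if n in classes)
        else:
            name = "unclassified"
        counts[name] = counts.get(name, 0) + 1
        if rec.membrane_thickness_nm > 0:
            thick.setdefault(rec.lamellarity, []).append(rec.membrane_thickness_nm)
    total = len(records)
    percent = {name: _pct(c, total) for name, c in counts.items()}
    mean_thick = {lam: sum(v) / len(v) for lam, v in thick.items()}
    return CensusSummary(counts=counts, percent=percent, total=total,
                         mean_thickness_by_lamellarity=mean_thick)


def read_vesicles(path: str | Path) -> list[VesicleRecord]:
    """Read a headerless CSV: diameter_nm,lamellarity,membrane_thickness_nm,electron_dense_lumen."""
    records = []
    with Path(path).open("r", encoding="utf-8", newline="") as fh:
        for lineno, row in enumerate(csv.reader(fh), start=1):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) != 4:
                raise ValueError(f"{path}:{lineno}: expected 4 fields, got {len(row)}")
            records.append(VesicleRecord(
                diameter_nm=float(row[0]),
                lamellarity=row[1].strip(),
                membrane_thickness_nm=float(row[2]),
                electron_dense_lumen=row[3].strip().lower() in ("1", "true", "yes"),
            ))
    return records
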