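"""Normalization of class counts to relative per-cell per-day secretion rates.

The DLS instrument sees only a diluted aliquot of the EV isolate, which in
turn came from an aliquot of the conditioned media. The volume chain undoes
that sampling: a DLS reading is multiplied by
(media/collected) x (resuspension/aliquot) x dilution to obtain the
whole-culture equivalent, then divided by the plated cell density and the
number of conditioning days. The result is a *relative* secretion rate
(instrument-relative counts per cell-density unit per day); absolute
particle concentrations are out of scope, and the volume factor cancels in
all within-study ratio comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass

from .dls import ClassCounts, SampleMetadata

__all__ = ["VolumeChain", "SecretionRecord", "volume_scale", "normalize"]


@dataclass(frozen=True)
class VolumeChain:
    """Collection/isolation/dilution volumes, µL (defaults follow the study
    protocol: 500 µL collected of 2 mL media, pellet resuspended in 50 µL,
    10 µL aliquot measured at a 1:50 dilution)."""

    media_volume_uL: float = 2000.0
    collected_uL: float = 500.0
    resuspension_uL: float = 50.0
    aliquot_uL: float = 10.0
    dls_dilution: float = 50.0

    def __post_init__(self) -> None:
        vals = (self.media_volume_uL, self.collected_uL, self.resuspension_uL,
                self.aliquot_uL, self.dls_dilution)
        if any(v <= 0 for v in vals):
            raise ValueError("all volume-chain entries must be positive")
        if self.collected_uL > self.media_volume_uL:
            raise ValueError("collected volume exceeds media volume")
        if self.aliquot_uL > self.resuspension_uL:
            raise ValueError("aliquot exceeds resuspension volume")


@dataclass(frozen=True)
class SecretionRecord:
    """Per-class relative secretion rates (relative count / cell density / day)."""

    metadata: SampleMetadata
    rates: dict[str, float]
    unclassified_rate: float = 0.0

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.rates.values()):
            raise ValueError("rates must be non-negative")


def volume_scale(chain: VolumeChain) -> float:
    """Dimensionless factor rescaling a DLS reading to the whole culture.

    With the default chain: (2000/500) x (50/10) x 50 = 1000.
    """
    return (chain.media_volume_uL / chain.collected_uL) \
        * (chain.resuspension_uL / chain.aliquot_uL) \
        * chain.dls_dilution


def normalize(counts: ClassCounts, chain: VolumeChain | None = None) -> SecretionRecord:
    """Convert raw class counts to relative per-cell-density per-day rates.

    rate[c] = counts[c] * volume_scale(chain) / (cell_seed_density * days).
    Unclassified counts are normalized the same way but reported separately.
    """
    chain = chain or VolumeChain()
    meta = counts.metadata
    if meta.cell_seed_density <= 0 or meta.collection_interval_days <= 0:
        raise ValueError("cell density and collection interval must be positive")
    denom = meta.cell_seed_density * meta.collection_interval_days
    factor = volume_scale(chain) / denom
    rates = {name: v * factor for name, v in counts.counts.items()}
    return SecretionRecord(metadata=meta, rates=rates,
                           unclassified_rate=counts.unclassified * factor)
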