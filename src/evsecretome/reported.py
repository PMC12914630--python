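"""Worked-example group medians from the published secretion study.

Each entry records a pair of printed group medians (relative secretion-rate
units) together with the fold change the study reports for that contrast
and the number of decimals it was printed with. They serve as inputs for
fold-change worked examples: ``fold_change(baseline, comparison)`` should
reproduce the printed value. Several printed sham-handling folds are
inconsistent with their own printed medians and are excluded here.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["ReportedContrast", "REPORTED_CONTRASTS"]


@dataclass(frozen=True)
class ReportedContrast:
    key: str
    region: str
    platform: str
    compartment: str
    ev_class: str
    contrast: str  # baseline -> comparison
    median_baseline: float
    median_comparison: float
    printed_fold: float
    printed_decimals: int
    direction: str


REPORTED_CONTRASTS: tuple[ReportedContrast, ...] = (
    ReportedContrast("cortex_petri_exomere_maturation", "cortex", "petri", "dish",
                     "exomere", "3 DIV -> 9 DIV", 6.69e6, 4.02e6, 1.66, 2, "decrease"),
    ReportedContrast("cortex_petri_apoptotic_maturation", "cortex", "petri", "dish",
                     "apoptotic_body", "3 DIV -> 9 DIV", 2.67e6, 9.52e5, 2.8, 1, "decrease"),
    ReportedContrast("brainstem_petri_exosome_maturation", "brainstem", "petri", "dish",
                     "exosome", "3 DIV -> 9 DIV", 3.83e7, 1.53e7, 2.5, 1, "decrease"),
    ReportedContrast("cortex_petri_oa_exosome_24h", "cortex", "petri", "dish",
                     "exosome", "24 h sham -> 24 h OA", 2.2e8, 8.27e7, 2.66, 2, "decrease"),
    ReportedContrast("hippocampus_petri_oa_microvesicle_12h", "hippocampus", "petri", "dish",
                     "microvesicle", "12 h sham -> 12 h OA", 6.21e7, 1.59e7, 3.9, 1, "decrease"),
    ReportedContrast("hippocampus_cw_microvesicle_maturation", "hippocampus", "neurofluidic",
                     "culture_well", "microvesicle", "3 DIV -> 9 DIV",
                     7.21e4, 3.18e5, 4.41, 2, "increase"),
    ReportedContrast("hippocampus_pc_exosome_maturation", "hippocampus", "neurofluidic",
                     "peripheric_channel", "exosome", "3 DIV -> 9 DIV",
                     6.16e4, 2.45e5, 3.98, 2, "increase"),
    ReportedContrast("brainstem_pc_exomere_maturation", "brainstem", "neurofluidic",
                     "peripheric_channel", "exomere", "3 DIV -> 9 DIV",
                     9.81e4, 3.30e4, 2.97, 2, "decrease"),
    ReportedContrast("cortex_cw_oa_exomere_12h_to_24h", "cortex", "neurofluidic",
                     "culture_well", "exomere", "12 h OA -> 24 h OA",
                     2.54e6, 7.84e5, 3.24, 2, "decrease"),
    ReportedContrast("hippocampus_cw_oa_exosome_12h", "hippocampus", "neurofluidic",
                     "culture_well", "exosome", "12 h sham -> 12 h OA",
                     3.43e5, 1.56e6, 4.55, 2, "increase"),
)
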