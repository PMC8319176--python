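"""Strain-level lipid screen: internal-standard ratios and producer calls.

Each strain's SAL signal is the LC-MS peak area of the SAL species divided by
the peak area of a phosphatidylglycerol internal standard (IS) spiked at a
fixed concentration.  Ratios are reported both raw and as a proportion of the
cohort maximum; a strain is called a producer when its IS-relative ratio
exceeds a (configurable) detection threshold.
"""

from __future__ import annotations

import warnings

import pandas as pd

__all__ = [
    "DEFAULT_PRODUCER_THRESHOLD",
    "relative_abundance",
    "normalize_to_max",
    "call_producers",
    "screen_strains",
]

#: default IS-relative detection threshold; the instrument's limit of
#: detection is assay-specific, so this is config, not chemistry
DEFAULT_PRODUCER_THRESHOLD = 0.01


def relative_abundance(sal_area: float, is_area: float) -> float:
    """SAL peak area over internal-standard peak area."""
    if is_area <= 0:
        raise ValueError(
            f"internal-standard area must be positive (IS failure?), got {is_area}"
        )
    if sal_area < 0:
        raise ValueError(f"negative SAL peak area: {sal_area}")
    return sal_area / is_area


def normalize_to_max(ratios) -> list[float]:
    """Each ratio as a proportion of the cohort maximum (max strain -> 1.0)."""
    ratios = list(ratios)
    if not ratios:
        raise ValueError("empty cohort")
    peak = max(ratios)
    if peak <= 0:
        warnings.warn("all-zero cohort: max-normalized abundances undefined, returning zeros")
        return [0.0 for _ in ratios]
    return [r / peak for r in ratios]


def call_producers(ratios, threshold: float = DEFAULT_PRODUCER_THRESHOLD) -> list[bool]:
    """Producer iff IS-relative abundance exceeds the threshold."""
    if threshold < 0:
        raise ValueError(f"threshold must be non-negative, got {threshold}")
    return [r > threshold for r in ratios]


def screen_strains(
    table: pd.DataFrame, threshold: float = DEFAULT_PRODUCER_THRESHOLD
) -> pd.DataFrame:
    """Full screen over a strain table.

    Input columns: ``strain_id``, ``sal_peak_area``, ``is_peak_area``.
    Output adds ``relative_abundance``, ``max_normalized``, ``producer``.
    """
    required = {"strain_id", "sal_peak_area", "is_peak_area"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"strain table missing columns: {sorted(missing)}")
    out = table.copy()
    out["relative_abundance"] = [
        relative_abundance(s, i)
        for s, i in zip(out["sal_peak_area"], out["is_peak_area"])
    ]
    out["max_normalized"] = normalize_to_max(out["relative_abundance"])
    out["producer"] = call_producers(out["relative_abundance"], threshold)
    return out
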