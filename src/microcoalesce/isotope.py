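"""Nitrogen stable-isotope computations: delta-15N and trophic level.

delta-15N is the per-mil deviation of a sample's 15N/14N ratio from standard
atmospheric nitrogen. Trophic level follows the standard enrichment model:
each step up the food web enriches delta-15N by a fixed amount (3.4 per mil
by default), anchored to a reference organism of known level (a primary
consumer, level 2, by default).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


class IsotopeError(ValueError):
    """Raised for invalid isotope parameters."""


@dataclass
class TrophicParams:
    """Parameters of the trophic-level model.

    enrichment : per-mil delta-15N increase per trophic level (default 3.4).
    reference_delta15n : delta-15N of the reference organism.
    reference_level : trophic level of the reference (1 = primary producer,
        2 = primary consumer).
    group_threshold : trophic level separating the low and high groups.
    """

    enrichment: float = 3.4
    reference_delta15n: float = 0.0
    reference_level: float = 2.0
    group_threshold: float = 2.8

    def __post_init__(self) -> None:
        if self.enrichment <= 0:
            raise IsotopeError("enrichment must be positive")
        if self.reference_level not in (1, 2):
            raise IsotopeError("reference_level must be 1 (producer) or 2 (primary consumer)")


def delta15n(r_sample: float, r_standard: float) -> float:
    """delta-15N (per mil) = (R_sample - R_standard) / R_standard * 1000."""
    if r_standard <= 0:
        raise IsotopeError("standard isotope ratio must be positive")
    if r_sample < 0:
        raise IsotopeError("sample isotope ratio must be non-negative")
    return (r_sample - r_standard) / r_standard * 1000.0


def trophic_level(delta_consumer: float, params: TrophicParams) -> float:
    """TL = (delta15N_consumer - delta15N_reference) / enrichment + reference level."""
    return (delta_consumer - params.reference_delta15n) / params.enrichment + params.reference_level


def trophic_group(tl: float, threshold: float = 2.8) -> str:
    """Binary trophic grouping: 'high' when TL >= threshold, else 'low'."""
    if not np.isfinite(tl):
        raise IsotopeError("trophic level must be finite")
    return "high" if tl >= threshold else "low"


def trophic_table(
    delta_values: dict[str, float], params: TrophicParams
) -> pd.DataFrame:
    """Per-sample delta-15N, trophic level, and binary group as a DataFrame."""
    rows = []
    for sid, d in delta_values.items():
        tl = trophic_level(d, params)
        rows.append(
            {"sample_id": sid, "delta15N": d, "trophic_level": tl,
             "trophic_group": trophic_group(tl, params.group_threshold)}
        )
    return pd.DataFrame(rows).set_index("sample_id")
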