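"""Immunoblot densitometry: total-protein-normalized CRISPR editing ratios.

The editing ratio of a lane estimates the fraction of *TARDBP* alleles
carrying a fluorescent-tag insertion: the combined signal of the
high-molecular-weight (~72/74 kDa) tagged TDP-43 bands divided by the
combined signal of all TDP-43 bands, after each band is normalized to the
lane's total-protein stain.  A ratio of 1.0 indicates complete insertion
across all alleles; 0.5 indicates tagging of half of the alleles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

TAGGED = "tagged_72_74kDa"
UNTAGGED = "untagged_43kDa"
OTHER = "other"

_BAND_LABELS = {TAGGED, UNTAGGED, OTHER}


@dataclass
class LaneTable:
    """Densitometry readings for one immunoblot lane.

    ``bands`` maps each band to a ``(label, signal)`` pair where label is one
    of :data:`TAGGED`, :data:`UNTAGGED` or :data:`OTHER`, and
    ``total_protein_signal`` is the lane's total-protein stain used for
    loading normalization.
    """

    lane_id: str
    bands: list[tuple[str, float]] = field(default_factory=list)
    total_protein_signal: float = 1.0

    def __post_init__(self) -> None:
        if not self.bands:
            raise ValueError("lane must contain at least one band")
        if not (self.total_protein_signal > 0 and math.isfinite(self.total_protein_signal)):
            raise ValueError("total_protein_signal must be positive and finite")
        for label, signal in self.bands:
            if label not in _BAND_LABELS:
                raise ValueError(f"unknown band label {label!r}")
            if not (math.isfinite(signal) and signal >= 0):
                raise ValueError("band signals must be finite and nonnegative")


def editing_ratio(lane: LaneTable, include_other: bool = False) -> float:
    """Tagged fraction of total TDP-43 signal for one lane.

    Each band signal is divided by the lane's total-protein signal before
    the ratio is formed, so the result is invariant to uniform loading
    differences.  Bands labelled ``other`` (e.g. lower-molecular-weight
    degradation products) are excluded unless ``include_other`` is set, in
    which case they enter the denominator only.

    Returns NaN when the lane carries no TDP-43 signal at all.
    """
    norm = lane.total_protein_signal
    tagged = sum(s / norm for lab, s in lane.bands if lab == TAGGED)
    untagged = sum(s / norm for lab, s in lane.bands if lab == UNTAGGED)
    other = sum(s / norm for lab, s in lane.bands if lab == OTHER)
    denom = tagged + untagged + (other if include_other else 0.0)
    if denom == 0.0:
        return math.nan
    return tagged / denom


def lanes_from_frame(df: pd.DataFrame) -> list[LaneTable]:
    """Build lane tables from a tidy frame.

    Expected columns: ``lane``, ``band_label``, ``signal``,
    ``total_protein_signal`` (constant within a lane).
    """
    required = {"lane", "band_label", "signal", "total_protein_signal"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    lanes = []
    for lane_id, grp in df.groupby("lane", sort=False):
        totals = grp["total_protein_signal"].unique()
        if len(totals) != 1:
            raise ValueError(f"lane {lane_id!r} has inconsistent total_protein_signal")
        lanes.append(
            LaneTable(
                lane_id=str(lane_id),
                bands=list(zip(grp["band_label"], grp["signal"].astype(float))),
                total_protein_signal=float(totals[0]),
            )
        )
    return lanes


def ratios_frame(lanes: list[LaneTable], include_other: bool = False) -> pd.DataFrame:
    """Editing ratio per lane, as a tidy frame."""
    return pd.DataFrame(
        {
            "lane": [ln.lane_id for ln in lanes],
            "editing_ratio": [editing_ratio(ln, include_other=include_other) for ln in lanes],
        }
    )
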