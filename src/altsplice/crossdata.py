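"""Cross-dataset overlap of differential-splicing calls with trend agreement.

Used for the tissue vs cell-line comparison and reusable for any external
validation set (e.g. splicing-factor knockdown re-analyses): events are
joined on their dialect-independent signatures and the sign of the PSI
change is compared between datasets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class TrendRecord:
    """One dataset's differential call for one event."""

    event_key: str  # event signature (or host gene when keying by gene)
    dataset: str
    delta_psi: float
    event_type: str = ""

    @property
    def trend_sign(self) -> int:
        return int(np.sign(self.delta_psi))


def _to_frame(records, side: str) -> pd.DataFrame:
    rows = [
        {
            "event_key": r.event_key,
            "event_type": r.event_type,
            f"{side}_delta_psi": r.delta_psi,
            f"{side}_sign": r.trend_sign,
        }
        for r in records
    ]
    df = pd.DataFrame(
        rows,
        columns=["event_key", "event_type", f"{side}_delta_psi", f"{side}_sign"],
    )
    dups = df["event_key"][df["event_key"].duplicated()]
    if len(dups):
        raise ValueError(
            f"duplicate event keys within the {side} dataset: "
            f"{sorted(set(dups))[:5]}"
        )
    return df


def overlap_and_judge(tissue, external) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Join two datasets' trend records and judge trend agreement.

    Returns ``(table, per_type)`` where ``table`` has one row per event seen
    in either dataset with ``in_both`` and ``same_trend`` flags (same_trend
    is missing for events not in both), and ``per_type`` counts overlapping
    and same-trend events per event type.
    """
    t = _to_frame(tissue, "tissue")
    x = _to_frame(external, "external")
    merged = t.merge(
        x, on="event_key", how="outer", suffixes=("", "_ext"), sort=True
    )
    if "event_type_ext" in merged.columns:
        merged["event_type"] = merged["event_type"].fillna(
            merged.pop("event_type_ext")
        )
    merged["in_both"] = (
        merged["tissue_sign"].notna() & merged["external_sign"].notna()
    )
    merged["same_trend"] = pd.array(
        [
            (ts == xs) if ok else None
            for ok, ts, xs in zip(
                merged["in_both"], merged["tissue_sign"], merged["external_sign"]
            )
        ],
        dtype="boolean",
    )
    both = merged[merged["in_both"]]
    per_type = (
        both.groupby("event_type")
        .agg(
            in_both=("in_both", "sum"),
            same_trend=("same_trend", lambda s: int(s.sum())),
        )
        .astype(int)
        .reset_index()
        if len(both)
        else pd.DataFrame(columns=["event_type", "in_both", "same_trend"])
    )
    return merged, per_type
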