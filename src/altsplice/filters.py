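"""Significance cascade for differential splicing calls.

An event is called significant in one tumor/normal pair when the Bayes
factor exceeds 5, |delta PSI| exceeds 0.2 and both samples have more than 10
informative reads (all inequalities strict).  Event-level retention then
requires recurrence (significant in at least ``min_pairs`` pairs) and trend
consistency (every significant pair agrees on the sign of delta PSI).
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd

from altsplice.psi import PairComparison

BF_MIN = 5.0
DPSI_MIN = 0.2
MIN_PAIRS = 3


def call_significant(
    c: PairComparison, bf_min: float = BF_MIN, dpsi_min: float = DPSI_MIN
) -> bool:
    """Per-pair significance: BF > bf_min, |dPSI| > dpsi_min, reads_ok."""
    return (c.bayes_factor > bf_min) and (abs(c.delta_psi) > dpsi_min) and c.reads_ok


@dataclass
class EventCallMatrix:
    """Per-(event, pair) significance calls plus per-event aggregates.

    ``calls`` has one row per (event_id, pair_id) with columns delta_psi,
    bayes_factor, reads_ok, significant, sign.  ``events`` has one row per
    event_id with n_significant_pairs, trend_consistent, trend_sign and the
    median delta PSI over significant pairs.
    """

    calls: pd.DataFrame
    events: pd.DataFrame

    def retained_ids(self, min_pairs: int = MIN_PAIRS) -> list[str]:
        ev = self.events
        keep = (ev["n_significant_pairs"] >= min_pairs) & ev["trend_consistent"]
        return sorted(ev.index[keep])


def build_call_matrix(
    comparisons: Iterable[PairComparison],
    bf_min: float = BF_MIN,
    dpsi_min: float = DPSI_MIN,
) -> EventCallMatrix:
    """Apply per-pair significance calls and aggregate per event.

    Trend consistency is evaluated over significant pairs only:
    sub-threshold wobble in non-significant pairs does not veto an event.
    Ties (delta PSI exactly 0 in a significant pair) cannot occur because
    significance requires |delta PSI| > dpsi_min > 0.
    """
    rows = [
        {
            "event_id": c.event_id,
            "pair_id": c.pair_id,
            "delta_psi": c.delta_psi,
            "bayes_factor": c.bayes_factor,
            "reads_ok": c.reads_ok,
            "significant": call_significant(c, bf_min, dpsi_min),
        }
        for c in comparisons
    ]
    calls = pd.DataFrame(
        rows,
        columns=[
            "event_id",
            "pair_id",
            "delta_psi",
            "bayes_factor",
            "reads_ok",
            "significant",
        ],
    )
    calls["sign"] = np.sign(calls["delta_psi"]).astype(int)

    if calls.empty:
        events = pd.DataFrame(
            columns=[
                "n_significant_pairs",
                "trend_consistent",
                "trend_sign",
                "median_delta_psi",
            ]
        )
        events.index.name = "event_id"
        return EventCallMatrix(calls=calls, events=events)

    def _aggregate(grp: pd.DataFrame) -> pd.Series:
        sig = grp[grp["significant"]]
        n_sig = len(sig)
        signs = set(sig["sign"])
        consistent = len(signs) <= 1
        trend = signs.pop() if len(signs) == 1 else 0
        median_dpsi = float(sig["delta_psi"].median()) if n_sig else float("nan")
        return pd.Series(
            {
                "n_significant_pairs": n_sig,
                "trend_consistent": consistent,
                "trend_sign": trend,
                "median_delta_psi": median_dpsi,
            }
        )

    events = calls.groupby("event_id").apply(_aggregate, include_groups=False)
    events["n_significant_pairs"] = events["n_significant_pairs"].astype(int)
    events["trend_consistent"] = events["trend_consistent"].astype(bool)
    events["trend_sign"] = events["trend_sign"].astype(int)
    return EventCallMatrix(calls=calls, events=events)


def trend_and_recurrence_filter(
    matrix: EventCallMatrix, min_pairs: int = MIN_PAIRS
) -> list[str]:
    """Event ids retained: significant in >= min_pairs pairs, one shared sign."""
    return matrix.retained_ids(min_pairs)


def round_half_away(value: float, decimals: int = 1) -> float:
    """Display rounding, half away from zero (numpy/python round are half-even)."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class TallyReport:
    """Per-type counts along the cascade, with recomputed percentages.

    ``significant_events`` counts unique events significant in at least one
    pair; ``significant_incidences`` counts (event, pair) hits -- both
    readings of "significant" are reported side by side.
    """

    per_type: pd.DataFrame
    detected_total: int
    significant_events: int
    significant_incidences: int
    retained_total: int

    def to_dict(self) -> dict:
        return {
            "detected_total": self.detected_total,
            "significant_events": self.significant_events,
            "significant_incidences": self.significant_incidences,
            "retained_total": self.retained_total,
            "pct_significant": percentage(self.significant_events, self.detected_total)
            if self.detected_total
            else 0.0,
            "per_type": self.per_type.reset_index().to_dict(orient="records"),
        }


def percentage(count: int, denominator: int) -> float:
    """Unrounded percentage 100 * count / denominator."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    return 100.0 * count / denominator


def display_percentage(count: int, denominator: int, decimals: int = 1) -> float:
    """Percentage rounded for display, half away from zero."""
    return round_half_away(percentage(count, denominator), decimals)


def tally(
    matrix: EventCallMatrix,
    event_types: Mapping[str, str],
    retained_ids: Optional[Iterable[str]] = None,
) -> TallyReport:
    """Per-type detected / significant / retained counts and percentages.

    ``event_types`` maps every detected event_id to its type; events in the
    call matrix but absent from the map raise.  Percentages are stored
    unrounded with a display rounding (1 decimal, half away from zero)
    alongside.
    """
    import warnings

    unknown = set(matrix.events.index) - set(event_types)
    if unknown:
        raise ValueError(f"events missing from type map: {sorted(unknown)[:5]}")
    retained = set(retained_ids) if retained_ids is not None else set()

    detected = pd.Series(dict(event_types), name="event_type")
    sig_ids = set(matrix.events.index[matrix.events["n_significant_pairs"] >= 1])
    rows = []
    order = ["SE", "RI", "MXE", "A3SS", "A5SS"]
    types_present = [t for t in order if t in set(detected.values)] + sorted(
        set(detected.values) - set(order)
    )
    for etype in types_present:
        ids = set(detected.index[detected == etype])
        n_det = len(ids)
        n_sig = len(ids & sig_ids)
        n_ret = len(ids & retained)
        rows.append(
            {
                "event_type": etype,
                "detected": n_det,
                "significant": n_sig,
                "retained": n_ret,
                "pct_significant_of_detected": percentage(n_sig, n_det)
                if n_det
                else 0.0,
                "pct_retained_of_detected": percentage(n_ret, n_det)
                if n_det
                else 0.0,
            }
        )
    per_type = pd.DataFrame(
        rows,
        columns=[
            "event_type",
            "detected",
            "significant",
            "retained",
            "pct_significant_of_detected",
            "pct_retained_of_detected",
        ],
    ).set_index("event_type")
    total_detected = int(per_type["detected"].sum())
    if total_detected == 0:
        warnings.warn("tally over an empty event universe", stacklevel=2)
        per_type["pct_of_detected_total"] = 0.0
        per_type["pct_of_significant_total"] = 0.0
    else:
        per_type["pct_of_detected_total"] = [
            percentage(n, total_detected) for n in per_type["detected"]
        ]
        total_sig = int(per_type["significant"].sum())
        per_type["pct_of_significant_total"] = [
            percentage(n, total_sig) if total_sig else 0.0
            for n in per_type["significant"]
        ]
    per_type["pct_display"] = [
        round_half_away(v, 1) for v in per_type["pct_of_significant_total"]
    ]
    n_incidences = int(matrix.calls["significant"].sum()) if len(matrix.calls) else 0
    return TallyReport(
        per_type=per_type,
        detected_total=total_detected,
        significant_events=len(sig_ids),
        significant_incidences=n_incidences,
        retained_total=len(retained),
    )


def retained_events_frame(
    matrix: EventCallMatrix,
    retained_ids: Iterable[str],
    event_types: Mapping[str, str],
) -> pd.DataFrame:
    """Retained-events table: per-event aggregates plus per-pair dPSI/BF columns."""
    retained = list(retained_ids)
    ev = matrix.events.loc[retained].copy()
    ev.insert(0, "event_type", [event_types[e] for e in retained])
    wide_dpsi = matrix.calls.pivot(
        index="event_id", columns="pair_id", values="delta_psi"
    ).add_prefix("dpsi_")
    wide_bf = matrix.calls.pivot(
        index="event_id", columns="pair_id", values="bayes_factor"
    ).add_prefix("bf_")
    return ev.join(wide_dpsi, how="left").join(wide_bf, how="left")
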