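#!/usr/bin/env python
"""Overlap tissue-retained events with cell-line differential events.

The single cell-line pair uses the same per-pair thresholds but is exempt
from the >= 3-pair recurrence rule (impossible with one pair).  Writes
results/overlap.tsv with in-both and same-trend flags.
"""

import argparse

import pandas as pd

from altsplice import filters
from altsplice.crossdata import TrendRecord, overlap_and_judge
from altsplice.events import event_signature, read_event_gff

from importlib import import_module

load_comparisons = import_module("03_filter_events").load_comparisons


def trend_records(matrix, ids, events, label):
    return [
        TrendRecord(
            event_key=event_signature(events[eid]),
            dataset=label,
            delta_psi=float(matrix.events.loc[eid, "median_delta_psi"]),
            event_type=events[eid].event_type,
        )
        for eid in ids
    ]


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--fixture", default="results/fixture")
    ap.add_argument("--comparisons", default="results/comparisons.tsv")
    ap.add_argument("--retained", default="results/retained.tsv")
    args = ap.parse_args()

    events = read_event_gff(f"{args.fixture}/events.gff3")
    pairing = pd.read_csv(f"{args.fixture}/pairing.tsv", sep="\t")
    tissue = set(pairing[pairing["dataset"] == "tissue"]["pair_id"])
    cell = set(pairing[pairing["dataset"] == "cell_line"]["pair_id"])

    t_matrix = filters.build_call_matrix(
        load_comparisons(args.comparisons, tissue)
    )
    retained = list(pd.read_csv(args.retained, sep="\t")["event_id"])
    c_matrix = filters.build_call_matrix(load_comparisons(args.comparisons, cell))
    cl_sig = c_matrix.retained_ids(min_pairs=1)

    table, per_type = overlap_and_judge(
        trend_records(t_matrix, retained, events, "tissue"),
        trend_records(c_matrix, cl_sig, events, "cell_line"),
    )
    table.to_csv("results/overlap.tsv", sep="\t", index=False)
    n_both = int(table["in_both"].sum())
    n_same = int(table["same_trend"].sum())
    print(
        f"{len(retained)} tissue-retained vs {len(cl_sig)} cell-line "
        f"significant events: {n_both} overlap, {n_same} with the same "
        f"delta-PSI trend -> results/overlap.tsv"
    )
    if len(per_type):
        print(per_type.to_string(index=False))


if __name__ == "__main__":
    main()
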