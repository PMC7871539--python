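#!/usr/bin/env python
"""Significance cascade on the tissue pairs: calls, trend, recurrence, tally.

Writes results/retained.tsv (events surviving every filter) and
results/tally.json (per-type counts and percentages).
"""

import argparse
import json

import pandas as pd

from altsplice import filters
from altsplice.events import read_event_gff
from altsplice.psi import PairComparison


def load_comparisons(path: str, tissue_pairs: set[str]) -> list[PairComparison]:
    frame = pd.read_csv(path, sep="\t")
    return [
        PairComparison(
            event_id=r.event_id, pair_id=r.pair_id, psi_tumor=r.psi_tumor,
            psi_normal=r.psi_normal, delta_psi=r.delta_psi,
            bayes_factor=r.bayes_factor, reads_ok=bool(r.reads_ok),
            n_mc=0, seed=0,
        )
        for r in frame.itertuples(index=False)
        if r.pair_id in tissue_pairs
    ]


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--fixture", default="results/fixture")
    ap.add_argument("--comparisons", default="results/comparisons.tsv")
    args = ap.parse_args()

    pairing = pd.read_csv(f"{args.fixture}/pairing.tsv", sep="\t")
    tissue = set(pairing[pairing["dataset"] == "tissue"]["pair_id"])
    comparisons = load_comparisons(args.comparisons, tissue)
    events = read_event_gff(f"{args.fixture}/events.gff3")
    types = {ev.event_id: ev.event_type for ev in events}

    matrix = filters.build_call_matrix(comparisons)
    retained = filters.trend_and_recurrence_filter(matrix)
    report = filters.tally(matrix, types, retained)
    filters.retained_events_frame(matrix, retained, types).to_csv(
        "results/retained.tsv", sep="\t"
    )
    with open("results/tally.json", "w") as fh:
        json.dump(report.to_dict(), fh, indent=1, sort_keys=True)
    print(
        f"{report.detected_total} events; {report.significant_events} "
        f"significant in >= 1 pair ({report.significant_incidences} "
        f"event-pair incidences); {len(retained)} retained after trend + "
        f">= 3-pair recurrence -> results/retained.tsv"
    )


if __name__ == "__main__":
    main()
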