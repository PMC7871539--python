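#!/usr/bin/env python
"""Re-annotate retained events against the two transcript-annotation dialects.

Applies criteria (i)-(v) per event type against the Ensembl-style GTF and
the RefSeq-style GFF3 (accession names mapped through the alias table),
classifies coding status, and writes results/reannotation.tsv plus a
support/coding summary.
"""

import argparse
import json

import pandas as pd

from altsplice import reannotation as reanno
from altsplice.events import read_event_gff


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--fixture", default="results/fixture")
    ap.add_argument("--retained", default="results/retained.tsv")
    args = ap.parse_args()

    retained_ids = list(pd.read_csv(args.retained, sep="\t")["event_id"])
    events = read_event_gff(f"{args.fixture}/events.gff3")
    ens = reanno.build_index(f"{args.fixture}/ensembl.gtf", "ensembl_gtf")
    ref = reanno.build_index(
        f"{args.fixture}/refseq.gff3", "refseq_gff",
        reanno.read_alias_table(f"{args.fixture}/alias.tsv"),
    )
    results = reanno.validate_all([events[e] for e in retained_ids], ens, ref)
    reanno.results_to_frame(results).to_csv(
        "results/reannotation.tsv", sep="\t", index=False
    )
    summary = reanno.partition_by_support(results)
    coding = {"coding": 0, "noncoding": 0, "unassessed": 0}
    for r in results:
        coding[r.coding_status] += 1
    summary["coding"] = coding
    with open("results/reannotation_summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
    s = summary["support"]
    print(
        f"{summary['total']} retained events: {s['both']} valid in both "
        f"annotations, {s['ensembl_only']} Ensembl-only, "
        f"{s['refseq_only']} RefSeq-only, {s['neither']} in neither; "
        f"{coding['coding']} coding / {coding['noncoding']} non-coding"
    )


if __name__ == "__main__":
    main()
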