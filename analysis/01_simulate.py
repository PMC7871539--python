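#!/usr/bin/env python
"""Generate the synthetic study: annotations, events, read counts, FPKM.

Emulates the target design -- 15 tumor/normal tissue pairs plus one
cell-line pair, five event types, planted differential splicing and planted
factor-PSI correlations -- and writes every input the downstream stages
consume under results/fixture/.
"""

import argparse
import json

from altsplice import synthetic


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--outdir", default="results/fixture")
    args = ap.parse_args()

    truth = synthetic.default_fixture(args.seed, args.outdir)
    n_diff = sum(t.differential for t in truth.events.values())
    n_invalid = sum(
        t.invalid_reason is not None for t in truth.events.values()
    )
    print(
        json.dumps(
            {
                "outdir": args.outdir,
                "events": len(truth.events),
                "tissue_pairs": len(truth.tissue_pairs),
                "planted_differential": n_diff,
                "planted_invalid": n_invalid,
                "planted_factor_targets": len(truth.factors),
            },
            indent=1,
        )
    )


if __name__ == "__main__":
    main()
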