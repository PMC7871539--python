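# altsplice

Differential alternative-splicing analysis for paired tumor/normal RNA-seq
cohorts, at the event level: skipped exons (SE), retained introns (RI),
mutually exclusive exons (MXE), and alternative 3'/5' splice sites
(A3SS/A5SS).

The package is written for transcriptomics analysts who already have
per-event inclusion/exclusion junction-read counts (e.g. from an
exon-centric quantifier) plus gene-level FPKM, and who want the downstream
statistics as a reusable, tested pipeline:

1. **Bayesian PSI estimation.** Per sample, the percent-spliced-in Ψ of an
   event with `k` inclusion and `m` exclusion reads gets the conjugate
   posterior Ψ | data ~ Beta(α₀ + k, β₀ + m) (uniform prior by default),
   with closed-form mean and central 95% credible interval.
2. **Per-pair differential calls.** For each tumor/normal pair,
   ΔΨ = E[Ψ_T] − E[Ψ_N] and a Savage–Dickey Bayes factor against ΔΨ = 0:
   BF = p(ΔΨ = 0) / p(ΔΨ = 0 | data), prior density in closed form,
   posterior density from Monte Carlo draws of the two independent
   posteriors. A pair is significant when BF > 5, |ΔΨ| > 0.2, and both
   samples have more than 10 informative reads (all strict).
3. **Trend and recurrence filtering.** An event is retained when it is
   significant in ≥ 3 pairs and every significant pair agrees on the sign
   of ΔΨ.
4. **Re-annotation.** Retained events are validated against Ensembl-style
   GTF and RefSeq-style GFF3 transcript models (accession chromosome names
   mapped through an alias table) with one criterion per event type —
   e.g. an SE is valid iff all three exons occur in one transcript's exon
   chain; an MXE needs 1-2-4 and 1-3-4 isoforms and no transcript carrying
   all four exons — and classified coding vs non-coding from matched
   transcript biotypes.
5. **Cross-dataset overlap.** Retained events are joined to an external
   differential set (e.g. a cell-line pair) on dialect-independent event
   signatures and judged for ΔΨ trend agreement.
6. **Regulatory network.** Spearman correlation of splicing-factor FPKM
   with event PSI and host-gene FPKM across samples (exact permutation
   P for n ≤ 9, t approximation otherwise); edges with P < 0.05 form a
   bipartite factor→target graph with per-factor subnetworks and
   top-target selection (0.5 < |ρ| < 1, ranked by P).

A synthetic-data generator (`altsplice.synthetic`) emulates the full study
design — 15 tumor/normal pairs plus one cell-line pair, binomial junction
reads from planted per-sample Ψ, annotation fixtures with deliberately
invalid events, Gaussian-copula factor–PSI links — so the entire pipeline
runs and is validated without any external data.

## Worked example

Run the numbered analysis scripts from the repository root (each is a thin
driver over the library and writes under `results/`):

```sh
python analysis/01_simulate.py --seed 1
python analysis/02_quantify_psi.py --seed 1
python analysis/03_filter_events.py
python analysis/04_reannotate.py
python analysis/05_overlap_cell_line.py
python analysis/06_build_network.py
```

which prints, stage by stage:

```
{"events": 250, "tissue_pairs": 15, "planted_differential": 44,
 "planted_invalid": 21, "planted_factor_targets": 5, ...}
4000 comparisons over 16 pairs; 707 pass BF > 5, |dPSI| > 0.2, reads > 10
250 events; 46 significant in >= 1 pair (662 event-pair incidences);
    44 retained after trend + >= 3-pair recurrence
44 retained events: 38 valid in both annotations, 2 Ensembl-only,
    2 RefSeq-only, 2 in neither; 28 coding / 14 non-coding
44 tissue-retained vs 45 cell-line significant events: 44 overlap,
    35 with the same delta-PSI trend
5 factors x 42 events over 30 samples: 209 factor-event and 7 factor-gene
    edges at P < 0.05; 174 top-target edges with 0.5 < |rho| < 1
```

Reading the numbers: all 44 events planted with |ΔΨ| = 0.4 effects pass the
significance cascade and none of the 206 null events do; the re-annotation
verdicts reproduce the planted valid/invalid/single-source structure
exactly; 35 of the 44 overlapping events keep their ΔΨ sign in the
cell-line pair (the generator flips ~20% on purpose); and each of the five
planted factor–event regulations appears among the network edges. The
dense factor–event edge count is expected: tumor state shifts PSI in every
differential event, so factors tracking one differential event correlate
with many (see `docs/methods.md`).

The same stages are available as subcommands of the `altsplice` console
script (`altsplice simulate`, `altsplice psi`, `altsplice filter`,
`altsplice run-all --config run.cfg`), and as library calls
(`altsplice.pipeline.run_all`).

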