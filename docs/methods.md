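# Methods

## The PSI model

Each event is reduced to its two-isoform special case: inclusion and
exclusion junction reads are treated as a binomial sample of the true
percent-spliced-in Ψ, with equal effective lengths for the two isoforms.
With a Beta(α₀, β₀) prior (default uniform, α₀ = β₀ = 1) the posterior is
Beta(α₀ + inclusion, β₀ + exclusion); point estimate is the posterior mean
and the interval is the central 95% credible interval from the Beta
quantile function. An `effective length ratio` parameter (default 1)
divides the inclusion count for users whose inclusion isoform spans more
informative positions; the default deliberately matches the synthetic read
model so that parameter-recovery tests measure pipeline correctness, not
model misspecification.

This is a simplification of full isoform-deconvolution models, which
integrate over read assignments across transcript structures. The
downstream pipeline only consumes Ψ, ΔΨ and a Bayes factor, so nothing
else depends on the generative details.

## Per-pair differential statistic

For a tumor/normal pair, ΔΨ = E[Ψ_T | data] − E[Ψ_N | data] (posterior
means, closed form; orientation fixed as tumor − normal throughout). The
evidence against ΔΨ = 0 is a Savage–Dickey density ratio

BF = p_prior(ΔΨ = 0) / p_post(ΔΨ = 0),

where the prior density of the difference of two independent Beta(α₀, β₀)
variates at zero is B(2α₀−1, 2β₀−1)/B(α₀, β₀)² (finite for α₀, β₀ > ½;
exactly 1 for the uniform prior), and the posterior density is estimated
from n_mc paired posterior draws (default 10,000, fixed per-comparison
seed) by counting draws with |ΔΨ| ≤ 0.01 — a centered histogram window of
half-width 0.01. When no draw lands in the window the BF is reported as
the cap 10⁶; BF values are therefore bounded and reproducible. n_mc below
1,000 is rejected because the window estimate becomes unstable.

Monte Carlo resolution: with ~200 expected draws in the window, the BF
carries ~7% relative noise at the default n_mc. This is far below the
8-fold gap between typical null BF values (≲ 1) and the calling threshold
(5), so calls are stable; tests that assert BF ≈ 1 identities raise n_mc
instead of loosening tolerances.

## The significance cascade

A pair call requires BF > 5 AND |ΔΨ| > 0.2 AND read support, with every
inequality strict. Read support demands inclusion + exclusion > 10 in
*both* samples — the stricter per-sample reading of the "sum of reads
above 10" rule, chosen so that both posteriors entering ΔΨ are informative.
Event-level retention requires significance in ≥ 3 pairs ("recurrence")
and a single ΔΨ sign across all significant pairs ("trend consistency");
sub-threshold pairs may wobble without vetoing an event, since their noise
should not overrule replicated calls. Ties are impossible because
significant pairs have |ΔΨ| > 0.2. The three per-pair conditions commute,
and the retained set is monotone non-increasing in each threshold.

Counts are tallied per event type with percentages always recomputed from
the stored counts; display rounding is one decimal, half away from zero.
Because "significant" can mean unique events or (event, pair) incidences,
the tally reports both readings side by side.

## Re-annotation criteria

Events are validated against two annotation dialects independently: an
Ensembl-style GTF (attributes `gene_id`, `transcript_id`,
`gene_biotype`/`transcript_biotype`) and a RefSeq-style GFF3 whose
accession sequence names (NC_…) are translated through a two-column alias
table before indexing — building the RefSeq index without an alias for
accession-named records is an error rather than a silent chromosome
mismatch. Matching is exact on both exon boundaries (slack 0 by default;
a `boundary_slack` option exists for event sources not built from
annotated exons), per type:

* **SE** — all three exons occur in one transcript's chain (membership,
  not necessarily consecutive).
* **RI** — both flanking exons occur chain-consecutively: no exon of that
  same transcript lies between them. "Between" is always evaluated within
  the matched transcript's own chain, not genome-wide.
* **MXE** — with exons 1–4 in genomic order, some transcript carries
  1-2-4 chain-consecutively, some transcript carries 1-3-4, and *no*
  transcript contains all four exons. "Adjacent" is read as
  chain-consecutive.
* **A3SS / A5SS** — the constitutive exon plus either variable form (long
  or short) occur chain-consecutively; the no-exon-between requirement is
  applied to whichever form matched.

Verdicts are `valid`, `invalid`, or `unmatched` (chromosome or span not
covered — not an error). Events are partitioned by support (both /
ensembl-only / refseq-only / neither) and classified `coding` when any
matched transcript, union over sources, has a protein-coding biotype;
`noncoding` when matches exist but none is coding; `unassessed` without
any match. Matches spanning multiple genes (paralogs) are all reported and
flagged rather than resolved. UCSC-derived annotations are intentionally
not a source; their transcript content derives from the other two.

An interval tree over transcript spans provides candidate lookup; it is a
pure optimization and correctness never depends on it.

## Cross-dataset overlap

Datasets are joined on a dialect-independent event signature (type,
chromosome, strand, ordered coordinates, alternative boundaries), so the
same event printed in colon or dash-range notation joins correctly; a
`--key gene` alternative exists for host-gene joins. A tissue event's
trend sign is the shared sign of its significant pairs (unique by
construction after the trend filter), with the median significant-pair ΔΨ
as its representative value; the external side contributes its own ΔΨ
sign. A single external pair (e.g. one cell-line comparison) uses the same
per-pair thresholds but is exempt from the ≥ 3-pair recurrence rule, which
is unsatisfiable with one pair.

## Network stage

Candidate edges are every (factor, event) and (factor, host gene of a
retained event) pair. Spearman ρ uses midranks; the two-sided P-value is
exact — full enumeration of the n! rank pairings, feasible to n = 9 —
for n ≤ 9 complete pairs and the t approximation otherwise (the two agree
within 0.01 at n = 9 on random data). Pairs with missing PSI entries are
dropped per edge; fewer than 6 complete pairs, or a constant vector, yields
no edge. Edges with raw P < 0.05 are kept — no multiple-testing
correction by default, with an optional FDR flag — in a bipartite graph
exported as TSV, SIF and GraphML. PSI columns pool tumor and normal
samples (2 per pair), maximizing n; a tumor-only mode exists.

Top-target selection keeps factor–event edges with 0.5 < |ρ| < 1 (both
bounds strict, so a perfectly monotone edge is excluded), sorts by
ascending P then descending |ρ| then event id, and truncates at k = 36.

Note an intentional property visible in the default synthetic run: tumor
state shifts PSI in every differential event, so a factor tracking one
differential event correlates with many others through that shared
dichotomy. The dense edge set is a faithful consequence of raw-P
filtering under a confounded design, not an artifact; the planted-edge
recovery test therefore uses an unconfounded design (independent
per-sample PSI) where the false-edge rate can be compared to α.

## Synthetic data

The generator plants every structure the stages assume, on a fictitious
`chrS1…chrSk` genome that cannot collide with real annotations:

* **Design**: 15 tumor/normal tissue pairs plus one cell-line pair;
  ~100 informative reads per event and sample (Poisson-distributed);
  50 events per type; 20% of events differential with |ΔΨ| = 0.4 and
  random sign; 10% of events planted invalid; 10% of valid events present
  in only one annotation dialect; 20% of genes non-coding (lincRNA);
  5 factors with one planted target each at |ρ| = 0.9. Differential
  events keep their sign in the cell-line pair except a 20% flipped
  fraction, exercising the trend-agreement logic.
* **PSI truth**: tumor Ψ = normal Ψ + ΔΨ_true, clipped to [0, 1]. Null
  events hold one base value with small (σ = 0.05) between-pair wobble;
  differential events draw each pair's normal Ψ wide, giving per-sample
  spread for the rank-correlation stage.
* **Reads**: total ~ Poisson(coverage), inclusion ~ Binomial(total, Ψ) —
  exactly the inference model; a length-bias flag produces a deliberately
  misspecified variant for robustness checks.
* **Expression**: log-normal FPKM; planted factors are built from the
  Gaussian scores of their target event's true-PSI ranks at the planted
  correlation (Gaussian copula), so the rank-space link is exact.
* **Defects**: RI with an intervening exon in the host transcript; MXE
  with an added four-exon transcript; SE/A3SS/A5SS with a 1-bp boundary
  shift. Each planted-invalid event violates exactly one criterion.

What the generator does *not* emulate — and hence what passing tests do
not certify about real data: isoform length bias and positional read
nonuniformity, overdispersed (non-binomial) junction counts, shared
splicing programs across events beyond the tumor/normal shift, annotation
incompleteness beyond the planted single-source events, and batch or
library-size effects in FPKM.

## Determinism and numerical choices

One master seed drives everything; per-pair, per-event and per-stage
sub-streams derive from it by hashing the labels (CRC32, folded below
2³¹), so results are independent of iteration order and reproduce byte
for byte. Thresholds are compared strictly (>, <) exactly as stated.
Percentages are stored unrounded and rounded only for display (half away
from zero). Degenerate inputs are defined rather than special-cased:
zero-read samples return the prior; empty event universes tally with a
warning; an unmatched chromosome is a verdict, not an error.

## Problem sizes

Default analysis and test sizes — 250 events, 16 pairs, coverage 100,
2,000-replicate calibration loops, exact permutation P at n ≤ 7 in
oracle cross-checks — were chosen so each stage's statistical claims are
testable with comfortable margins while the full suite stays fast on a
single CPU.

## Known limitations

Two-isoform events only (no multi-way Ψ vectors); no read-level or
paired-end modeling; no multiple-testing correction in the default
pipeline (mirroring raw-P edge filtering); exact Spearman P limited to
n ≤ 9; re-annotation requires exact exon boundaries unless slack is
requested; the Savage–Dickey window estimator caps extreme Bayes factors
at 10⁶ rather than resolving them.
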