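"""Self-contained synthetic fixtures with the structure every stage assumes.

The generator emulates the study design the pipeline targets: a paired
tumor/normal cohort (15 pairs by default) plus one immortalized/transformed
cell-line pair, five event types built from toy multi-transcript gene
models on a fictitious ``chrS*`` genome (so nothing can collide with real
annotations), binomial junction-read counts driven by planted per-sample
PSI with planted tumor-normal effects, and log-normal factor expression
rank-correlated with target-event PSI through a Gaussian copula.

Planted defects let the re-annotation criteria be tested by construction:

* ``intervening_exon``  -- an RI whose host transcript gained an exon inside
  the retained intron (criterion ii must reject);
* ``four_exon_mxe``     -- an MXE whose gene carries a transcript with all
  four exons (criterion iii must reject);
* ``boundary_shift``    -- an SE/A3SS/A5SS event with one boundary off by
  1 bp from every annotated exon (exact matching must reject);
* single-source events  -- valid events omitted from one annotation dialect
  to populate the ensembl-only / refseq-only support classes;
* non-coding genes      -- a fraction of genes annotated as lincRNA so the
  coding classifier sees both outcomes.

The binomial read model matches the inference model exactly (no length
bias), so parameter-recovery tests isolate pipeline correctness from model
misspecification; a length-bias flag provides a deliberately misspecified
variant for robustness checks.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from altsplice.events import ASEvent, EventSet, GenomicInterval
from altsplice.psi import derive_seed

EVENT_TYPE_ORDER = ("SE", "RI", "MXE", "A3SS", "A5SS")

# study-design defaults: 15 tumor/normal pairs plus one cell-line pair,
# ~100 informative reads per event per sample, |delta PSI| = 0.4 effects
# in 20% of events, 50 events per type with 10% planted-invalid, 20%
# non-coding genes and 5 planted factor regulations at |rho| = 0.9
N_PAIRS = 15
COVERAGE = 100.0
EVENTS_PER_TYPE = 50
INVALID_FRACTION = 0.10
NONCODING_FRACTION = 0.20
SINGLE_SOURCE_FRACTION = 0.10
DIFF_FRACTION = 0.20
EFFECT = 0.4
N_FACTORS = 5
RHO_TRUE = 0.9
CELL_LINE_FLIP_FRACTION = 0.2

GENES_PER_CHROM = 40


@dataclass
class EventTruth:
    """Ground truth for one synthetic event."""

    event_id: str
    event_type: str
    gene_id: str
    gene_symbol: str
    transcript_ids: list[str]
    valid_ensembl: bool
    valid_refseq: bool
    invalid_reason: Optional[str]  # None or the planted defect name
    in_ensembl: bool
    in_refseq: bool
    coding: bool
    differential: bool
    delta_psi_true: float  # tumor - normal, tissue pairs
    cell_line_delta: float  # tumor - normal in the cell-line pair
    psi_true: dict[str, float] = field(default_factory=dict)  # sample -> PSI


@dataclass
class SyntheticTruth:
    """Everything planted by the generator, serializable alongside outputs."""

    seed: int
    n_pairs: int
    coverage: float = COVERAGE
    pairs: list[dict] = field(default_factory=list)
    events: dict[str, EventTruth] = field(default_factory=dict)
    factors: dict[str, dict] = field(default_factory=dict)
    params: dict = field(default_factory=dict)

    @property
    def samples(self) -> list[str]:
        out = []
        for p in self.pairs:
            out.extend([p["normal_sample"], p["tumor_sample"]])
        return out

    @property
    def tissue_pairs(self) -> list[dict]:
        return [p for p in self.pairs if p["dataset"] == "tissue"]

    def to_json(self, path: str) -> None:
        payload = {
            "seed": self.seed,
            "n_pairs": self.n_pairs,
            "coverage": self.coverage,
            "pairs": self.pairs,
            "factors": self.factors,
            "params": self.params,
            "events": {
                eid: dataclasses.asdict(ev) for eid, ev in self.events.items()
            },
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)


@dataclass
class _Gene:
    gene_id: str
    symbol: str
    chrom: str
    strand: str
    biotype: str
    transcripts: dict[str, tuple[GenomicInterval, ...]]
    sources: tuple[str, ...]  # dialects that carry this gene


def _exon(chrom: str, strand: str, start: int, length: int) -> GenomicInterval:
    return GenomicInterval(chrom, start, start + length - 1, strand)


def _build_gene(
    rng: np.random.Generator,
    etype: str,
    gene_id: str,
    symbol: str,
    chrom: str,
    offset: int,
    defect: Optional[str],
) -> tuple[_Gene, ASEvent, int]:
    """One toy gene whose transcript chains support (or defeat) one event."""
    strand = rng.choice(["+", "-"])
    exon_len = lambda: int(rng.integers(80, 300))
    intron_len = lambda: int(rng.integers(200, 1500))
    pos = offset

    def next_exon() -> GenomicInterval:
        nonlocal pos
        e = _exon(chrom, strand, pos, exon_len())
        pos = e.end + 1 + intron_len()
        return e

    tx: dict[str, tuple[GenomicInterval, ...]] = {}
    alt_boundaries = None
    alt_side = None

    if etype == "SE":
        e1, e2, e3 = next_exon(), next_exon(), next_exon()
        tx["T1"] = (e1, e2, e3)
        tx["T2"] = (e1, e3)
        exons = [e1, e2, e3]
        if defect == "boundary_shift":
            exons[1] = dataclasses.replace(e2, start=e2.start + 1)
    elif etype == "RI":
        x, y = next_exon(), next_exon()
        if defect == "intervening_exon":
            gap_mid = x.end + (y.start - x.end) // 2
            mid = _exon(chrom, strand, gap_mid - 20, 40)
            tx["T1"] = (x, mid, y)
        else:
            tx["T1"] = (x, y)
        tx["T2"] = (_exon(chrom, strand, x.start, y.end - x.start + 1),)
        exons = [x, y]
    elif etype == "MXE":
        e1, e2, e3, e4 = next_exon(), next_exon(), next_exon(), next_exon()
        tx["T1"] = (e1, e2, e4)
        tx["T2"] = (e1, e3, e4)
        if defect == "four_exon_mxe":
            tx["T3"] = (e1, e2, e3, e4)
        exons = [e1, e2, e3, e4]
    elif etype in ("A3SS", "A5SS"):
        left, right = next_exon(), next_exon()
        # donor sites vary at the transcript-3' end of the upstream exon:
        # genomic end of the left exon on '+', genomic start of the right
        # exon on '-'; acceptor geometry is the mirror image
        end_side = (etype == "A5SS") == (strand == "+")
        shift = int(rng.integers(30, 70))
        if end_side:
            alt_side = "end"
            p_long, p_short = left.end, left.end - shift
            alt_boundaries = (p_short, p_long)
            tx["T1"] = (left, right)
            tx["T2"] = (dataclasses.replace(left, end=p_short), right)
        else:
            alt_side = "start"
            s_long, s_short = right.start, right.start + shift
            alt_boundaries = (s_long, s_short)
            tx["T1"] = (left, right)
            tx["T2"] = (left, dataclasses.replace(right, start=s_short))
        exons = [left, right]
        if defect == "boundary_shift":
            const_idx = 1 if end_side else 0
            c = exons[const_idx]
            exons[const_idx] = dataclasses.replace(c, end=c.end + 1)
    else:
        raise ValueError(f"unknown event type {etype!r}")

    event = ASEvent(
        event_id=f"{gene_id}.{etype}",
        event_type=etype,
        exons=tuple(exons),
        alt_boundaries=alt_boundaries,
        alt_side=alt_side,
        host_gene=symbol,
    )
    gene = _Gene(
        gene_id=gene_id,
        symbol=symbol,
        chrom=chrom,
        strand=strand,
        biotype="protein_coding",
        transcripts=tx,
        sources=("ensembl", "refseq"),
    )
    return gene, event, pos + 2000


_DEFECT_BY_TYPE = {
    "SE": "boundary_shift",
    "RI": "intervening_exon",
    "MXE": "four_exon_mxe",
    "A3SS": "boundary_shift",
    "A5SS": "boundary_shift",
}


def generate_annotation(
    seed: int,
    events_per_type: int = EVENTS_PER_TYPE,
    invalid_fraction: float = INVALID_FRACTION,
    noncoding_fraction: float = NONCODING_FRACTION,
    single_source_fraction: float = SINGLE_SOURCE_FRACTION,
    n_pairs: int = N_PAIRS,
    diff_fraction: float = DIFF_FRACTION,
    effect: float = EFFECT,
    include_cell_line: bool = True,
    cell_line_flip_fraction: float = CELL_LINE_FLIP_FRACTION,
    outdir: Optional[str] = None,
) -> tuple[EventSet, SyntheticTruth, list["_Gene"]]:
    """Toy genome, annotations in two dialects, events, and planted PSI truth.

    Writes ``ensembl.gtf``, ``refseq.gff3``, ``alias.tsv``, ``events.gff3``
    and ``truth.json`` under ``outdir`` when given.  Same seed, same output,
    byte for byte.
    """
    if not 0 <= invalid_fraction < 1:
        raise ValueError("invalid_fraction must be in [0, 1)")
    rng = np.random.default_rng(derive_seed(seed, "annotation"))
    truth = SyntheticTruth(
        seed=seed,
        n_pairs=n_pairs,
        params={
            "events_per_type": events_per_type,
            "invalid_fraction": invalid_fraction,
            "noncoding_fraction": noncoding_fraction,
            "single_source_fraction": single_source_fraction,
            "diff_fraction": diff_fraction,
            "effect": effect,
            "cell_line_flip_fraction": cell_line_flip_fraction,
        },
    )
    for i in range(n_pairs):
        truth.pairs.append(
            {
                "pair_id": f"P{i + 1:02d}",
                "tumor_sample": f"P{i + 1:02d}_T",
                "normal_sample": f"P{i + 1:02d}_N",
                "dataset": "tissue",
            }
        )
    if include_cell_line:
        truth.pairs.append(
            {
                "pair_id": "CL1",
                "tumor_sample": "CL1_T",
                "normal_sample": "CL1_N",
                "dataset": "cell_line",
            }
        )

    events = EventSet(source_label="synthetic")
    genes: list[_Gene] = []
    gene_no = 0
    offset = 10_000
    valid_rank = 0  # drives the alternating one-source assignment
    for etype in EVENT_TYPE_ORDER:
        for _ in range(events_per_type):
            gene_no += 1
            chrom = f"chrS{(gene_no - 1) // GENES_PER_CHROM + 1}"
            if (gene_no - 1) % GENES_PER_CHROM == 0:
                offset = 10_000
            gene_id = f"SG{gene_no:04d}"
            symbol = f"SGENE{gene_no}"
            invalid = rng.random() < invalid_fraction
            defect = _DEFECT_BY_TYPE[etype] if invalid else None
            gene, event, offset = _build_gene(
                rng, etype, gene_id, symbol, chrom, offset, defect
            )
            if rng.random() < noncoding_fraction:
                gene.biotype = "lincRNA"
            sources = ("ensembl", "refseq")
            if not invalid and rng.random() < single_source_fraction:
                sources = ("ensembl",) if valid_rank % 2 == 0 else ("refseq",)
                valid_rank += 1
            gene.sources = sources
            genes.append(gene)
            events.add(event)

            differential = rng.random() < diff_fraction
            sign = 1 if rng.random() < 0.5 else -1
            delta = sign * effect if differential else 0.0
            cl_delta = delta
            if differential and rng.random() < cell_line_flip_fraction:
                cl_delta = -delta
            ev_truth = EventTruth(
                event_id=event.event_id,
                event_type=etype,
                gene_id=gene_id,
                gene_symbol=symbol,
                transcript_ids=[f"{gene_id}.{t}" for t in gene.transcripts],
                valid_ensembl=not invalid and "ensembl" in sources,
                valid_refseq=not invalid and "refseq" in sources,
                invalid_reason=defect,
                in_ensembl="ensembl" in sources,
                in_refseq="refseq" in sources,
                coding=gene.biotype == "protein_coding",
                differential=differential,
                delta_psi_true=delta,
                cell_line_delta=cl_delta,
            )
            _plant_psi(rng, ev_truth, truth, effect)
            truth.events[event.event_id] = ev_truth

    if outdir is not None:
        os.makedirs(outdir, exist_ok=True)
        write_annotation_files(genes, outdir)
        from altsplice.events import write_event_gff

        write_event_gff(list(events), os.path.join(outdir, "events.gff3"))
        truth.to_json(os.path.join(outdir, "truth.json"))
    return events, truth, genes


def _plant_psi(
    rng: np.random.Generator,
    ev: EventTruth,
    truth: SyntheticTruth,
    effect: float,
) -> None:
    """Per-sample true PSI: tumor = normal + planted delta, clipped to [0, 1].

    Differential events draw each pair's normal PSI wide (uniform on the
    side that keeps tumor in range) so per-sample PSI has spread for the
    rank-correlation stage; null events sit at one base value with small
    between-pair wobble.
    """
    base = float(rng.uniform(0.05, 0.95))
    for pair in truth.pairs:
        delta = (
            ev.delta_psi_true if pair["dataset"] == "tissue" else ev.cell_line_delta
        )
        if ev.differential:
            if delta >= 0:
                normal = float(rng.uniform(0.05, 0.95 - delta))
            else:
                normal = float(rng.uniform(0.05 - delta, 0.95))
        else:
            normal = float(np.clip(base + rng.normal(0, 0.05), 0.01, 0.99))
        tumor = float(np.clip(normal + delta, 0.0, 1.0))
        ev.psi_true[pair["normal_sample"]] = normal
        ev.psi_true[pair["tumor_sample"]] = tumor


# ---------------------------------------------------------------------------
# annotation serialization


def write_annotation_files(genes: list[_Gene], outdir: str) -> dict[str, str]:
    """Ensembl-dialect GTF, RefSeq-dialect GFF3 (accession names) + alias TSV."""
    paths = {
        "ensembl": os.path.join(outdir, "ensembl.gtf"),
        "refseq": os.path.join(outdir, "refseq.gff3"),
        "alias": os.path.join(outdir, "alias.tsv"),
    }
    chroms = sorted({g.chrom for g in genes}, key=lambda c: int(c[4:]))
    alias = {f"NC_9{i + 1:05d}.1": c for i, c in enumerate(chroms)}
    acc_of = {c: a for a, c in alias.items()}

    with open(paths["ensembl"], "w") as fh:
        fh.write("#!genome-build synthetic-S1\n")
        for g in genes:
            if "ensembl" not in g.sources:
                continue
            lo = min(e.start for t in g.transcripts.values() for e in t)
            hi = max(e.end for t in g.transcripts.values() for e in t)
            base = (
                f'gene_id "{g.gene_id}"; gene_name "{g.symbol}"; '
                f'gene_biotype "{g.biotype}";'
            )
            fh.write(
                f"{g.chrom}\tsynthetic\tgene\t{lo}\t{hi}\t.\t{g.strand}\t.\t{base}\n"
            )
            for tname, chain in g.transcripts.items():
                tid = f"{g.gene_id}.{tname}"
                tlo, thi = chain[0].start, chain[-1].end
                tattr = (
                    f'{base} transcript_id "{tid}"; '
                    f'transcript_biotype "{g.biotype}";'
                )
                fh.write(
                    f"{g.chrom}\tsynthetic\ttranscript\t{tlo}\t{thi}\t.\t"
                    f"{g.strand}\t.\t{tattr}\n"
                )
                for e in chain:
                    fh.write(
                        f"{g.chrom}\tsynthetic\texon\t{e.start}\t{e.end}\t.\t"
                        f"{g.strand}\t.\t{tattr}\n"
                    )

    feature_of = {"protein_coding": "mRNA", "lincRNA": "lnc_RNA"}
    with open(paths["refseq"], "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            if "refseq" not in g.sources:
                continue
            acc = acc_of[g.chrom]
            lo = min(e.start for t in g.transcripts.values() for e in t)
            hi = max(e.end for t in g.transcripts.values() for e in t)
            fh.write(
                f"{acc}\tsynthetic\tgene\t{lo}\t{hi}\t.\t{g.strand}\t.\t"
                f"ID=gene-{g.gene_id};Name={g.symbol};gene={g.symbol};"
                f"gene_biotype={g.biotype}\n"
            )
            ftype = feature_of.get(g.biotype, "transcript")
            for tname, chain in g.transcripts.items():
                tid = f"rna-{g.gene_id}.{tname}"
                tlo, thi = chain[0].start, chain[-1].end
                fh.write(
                    f"{acc}\tsynthetic\t{ftype}\t{tlo}\t{thi}\t.\t{g.strand}\t.\t"
                    f"ID={tid};Parent=gene-{g.gene_id}\n"
                )
                for k, e in enumerate(chain, 1):
                    fh.write(
                        f"{acc}\tsynthetic\texon\t{e.start}\t{e.end}\t.\t"
                        f"{g.strand}\t.\tID=exon-{tid}-{k};Parent={tid}\n"
                    )

    with open(paths["alias"], "w") as fh:
        fh.write("accession\tchrom\n")
        for acc, chrom in sorted(alias.items()):
            fh.write(f"{acc}\t{chrom}\n")
    return paths


# ---------------------------------------------------------------------------
# read counts


def simulate_counts(
    truth: SyntheticTruth,
    coverage: float = COVERAGE,
    seed: Optional[int] = None,
    length_bias: float = 1.0,
    outdir: Optional[str] = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Binomial junction reads from planted PSI.

    Per (event, sample): total reads ~ Poisson(coverage) and inclusion ~
    Binomial(total, PSI).  ``length_bias`` != 1 deliberately mis-specifies
    the read model (inclusion probability psi*L / (psi*L + 1 - psi)).
    Returns the counts and pairing tables; writes ``counts.tsv`` and
    ``pairing.tsv`` under ``outdir`` when given.
    """
    truth.coverage = coverage
    seed = truth.seed if seed is None else seed
    rng = np.random.default_rng(derive_seed(seed, "counts"))
    samples = truth.samples
    rows = []
    for eid in sorted(truth.events):
        psi_true = truth.events[eid].psi_true
        for sample in samples:
            psi = psi_true[sample]
            if length_bias != 1.0:
                psi = psi * length_bias / (psi * length_bias + 1 - psi)
            n = int(rng.poisson(coverage))
            incl = int(rng.binomial(n, psi)) if n else 0
            rows.append((eid, sample, incl, n - incl))
    counts = pd.DataFrame(
        rows, columns=["event_id", "sample_id", "inclusion_reads", "exclusion_reads"]
    )
    pairing = pd.DataFrame(truth.pairs)[
        ["pair_id", "tumor_sample", "normal_sample", "dataset"]
    ]
    if outdir is not None:
        os.makedirs(outdir, exist_ok=True)
        counts.to_csv(os.path.join(outdir, "counts.tsv"), sep="\t", index=False)
        pairing.to_csv(os.path.join(outdir, "pairing.tsv"), sep="\t", index=False)
    return counts, pairing


# ---------------------------------------------------------------------------
# expression


def simulate_expression(
    truth: SyntheticTruth,
    n_factors: int = N_FACTORS,
    seed: Optional[int] = None,
    rho_true: float = RHO_TRUE,
    outdir: Optional[str] = None,
) -> tuple[pd.DataFrame, list[str]]:
    """Log-normal FPKM for factors and host genes with planted rank links.

    Each factor is assigned one differential target event; the factor's
    log-expression is built from the Gaussian scores of the event's
    per-sample true-PSI ranks at correlation ``rho_true`` (random sign), so
    the planted Spearman correlation holds exactly in rank space.  All
    other genes are independent.  Returns the genes x samples FPKM matrix
    and the factor list; writes ``fpkm.tsv`` and ``factors.tsv`` under
    ``outdir`` when given.
    """
    if not -1 < rho_true < 1:
        raise ValueError("rho_true must be in (-1, 1)")
    seed = truth.seed if seed is None else seed
    rng = np.random.default_rng(derive_seed(seed, "expression"))
    samples = truth.samples
    n = len(samples)

    differential = [
        eid for eid in sorted(truth.events) if truth.events[eid].differential
    ]
    if n_factors > len(differential):
        raise ValueError(
            f"cannot plant {n_factors} factor targets: only "
            f"{len(differential)} differential events"
        )
    targets = list(rng.choice(differential, size=n_factors, replace=False))

    records: dict[str, np.ndarray] = {}
    truth.factors = {}
    for i, target in enumerate(targets):
        factor = f"SF{i + 1:02d}"
        sign = 1 if rng.random() < 0.5 else -1
        psi = np.array([truth.events[target].psi_true[s] for s in samples])
        z_psi = stats.norm.ppf((stats.rankdata(psi) - 0.5) / n)
        z = sign * rho_true * z_psi + np.sqrt(1 - rho_true**2) * rng.normal(size=n)
        mu = rng.uniform(1.0, 3.0)
        records[factor] = np.exp(mu + 0.6 * z)
        truth.factors[factor] = {
            "target_event": target,
            "rho_true": sign * rho_true,
        }
    for eid in sorted(truth.events):
        sym = truth.events[eid].gene_symbol
        if sym not in records:
            mu = rng.uniform(1.0, 3.0)
            records[sym] = np.exp(mu + 0.6 * rng.normal(size=n))

    fpkm = pd.DataFrame.from_dict(records, orient="index", columns=samples)
    fpkm.index.name = "gene"
    factor_list = sorted(truth.factors)
    if outdir is not None:
        os.makedirs(outdir, exist_ok=True)
        fpkm.to_csv(os.path.join(outdir, "fpkm.tsv"), sep="\t")
        with open(os.path.join(outdir, "factors.tsv"), "w") as fh:
            fh.write("factor\n")
            for f in factor_list:
                fh.write(f"{f}\n")
    return fpkm, factor_list


def default_fixture(seed: int, outdir: str) -> SyntheticTruth:
    """Generate the full default-condition fixture into ``outdir``."""
    events, truth, genes = generate_annotation(seed, outdir=outdir)
    simulate_expression(truth, outdir=outdir)
    simulate_counts(truth, outdir=outdir)
    truth.to_json(os.path.join(outdir, "truth.json"))
    return truth
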