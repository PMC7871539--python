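"""Re-annotation of splicing events against transcript annotations.

Each retained event is checked against the exon chains of an Ensembl-style
GTF and a RefSeq-style GFF3 (whose accession chromosome names are translated
through an alias table first).  The validity criteria, one per event type:

(i)   SE: all three exons appear in a single transcript's exon chain;
(ii)  RI: both flanking exons appear in one transcript with no other chain
      exon between them;
(iii) MXE: with exons numbered 1-4 in genomic order, one transcript carries
      exons 1-2-4 chain-consecutively and another carries 1-3-4, while no
      single transcript contains all four exons;
(iv)  A3SS: the constitutive exon and either variable form (long or short)
      appear in one transcript with no chain exon between them;
(v)   A5SS: as (iv) for the alternative 5' splice-site geometry.

Exon matching is exact on both boundaries by default (events are built from
annotated exons); a boundary-slack option exists for other event sources.
Events whose matched transcripts include at least one protein-coding
biotype are classified coding; events matched only to non-coding biotypes
are noncoding; unmatched events are unassessed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import gffutils
import pandas as pd
from intervaltree import IntervalTree

from altsplice.events import ASEvent, GenomicInterval

log = logging.getLogger(__name__)

CRITERION_BY_TYPE = {"SE": "i", "RI": "ii", "MXE": "iii", "A3SS": "iv", "A5SS": "v"}

#: feature types that introduce a transcript in RefSeq-style GFF3
_REFSEQ_TX_TYPES = (
    "mRNA",
    "transcript",
    "lnc_RNA",
    "ncRNA",
    "primary_transcript",
    "miRNA",
    "snoRNA",
    "snRNA",
    "rRNA",
    "tRNA",
)
#: fallback biotype per RefSeq feature type when no attribute says otherwise
_REFSEQ_BIOTYPE_BY_TYPE = {
    "mRNA": "protein_coding",
    "lnc_RNA": "lncRNA",
    "ncRNA": "ncRNA",
    "primary_transcript": "miRNA",
    "miRNA": "miRNA",
    "snoRNA": "snoRNA",
    "snRNA": "snRNA",
    "rRNA": "rRNA",
    "tRNA": "tRNA",
}


@dataclass
class TranscriptModel:
    """One transcript: ordered, non-overlapping exon chain plus biotype."""

    transcript_id: str
    gene_id: str
    gene_symbol: str
    biotype: str
    chrom: str
    strand: str
    exon_chain: tuple[GenomicInterval, ...]

    def __post_init__(self) -> None:
        starts = [e.start for e in self.exon_chain]
        if starts != sorted(starts):
            raise ValueError(f"exon chain of {self.transcript_id} not sorted")
        for a, b in zip(self.exon_chain, self.exon_chain[1:]):
            if a.end >= b.start:
                raise ValueError(
                    f"overlapping exons in chain of {self.transcript_id}"
                )

    @property
    def coords(self) -> tuple[tuple[int, int], ...]:
        return tuple((e.start, e.end) for e in self.exon_chain)

    @property
    def span(self) -> tuple[int, int]:
        return self.exon_chain[0].start, self.exon_chain[-1].end


@dataclass
class TranscriptIndex:
    """Transcripts keyed by id with a per-chromosome interval lookup."""

    source: str
    transcripts: dict[str, TranscriptModel] = field(default_factory=dict)
    _trees: dict[str, IntervalTree] = field(default_factory=dict)

    def add(self, tx: TranscriptModel) -> None:
        if tx.transcript_id in self.transcripts:
            raise ValueError(f"duplicate transcript id {tx.transcript_id!r}")
        self.transcripts[tx.transcript_id] = tx
        lo, hi = tx.span
        self._trees.setdefault(tx.chrom, IntervalTree()).addi(
            lo, hi + 1, tx.transcript_id
        )

    def candidates(self, chrom: str, start: int, end: int, strand: str):
        """Transcripts on ``chrom``/``strand`` overlapping [start, end]."""
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        hits = [self.transcripts[iv.data] for iv in tree.overlap(start, end + 1)]
        return sorted(
            (t for t in hits if t.strand == strand), key=lambda t: t.transcript_id
        )

    def covers_chrom(self, chrom: str) -> bool:
        return chrom in self._trees

    def __len__(self) -> int:
        return len(self.transcripts)


def read_alias_table(path: str) -> dict[str, str]:
    """Accession -> chromosome-name map from a two-column TSV (with header)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"alias table {path!r} needs two columns")
    acc, chrom = df.columns[:2]
    mapping = dict(zip(df[acc], df[chrom]))
    if len(set(mapping.values())) != len(mapping):
        raise ValueError("alias table is not a bijection on mapped names")
    return mapping


def _first_attr(attrs, *names: str) -> Optional[str]:
    for name in names:
        if name in attrs:
            return attrs[name][0]
    return None


def build_index(
    path: str,
    dialect: str,
    alias_table: Optional[Mapping[str, str]] = None,
) -> TranscriptIndex:
    """Parse a transcript annotation into a :class:`TranscriptIndex`.

    ``dialect`` is ``ensembl_gtf`` (attributes gene_id / transcript_id /
    gene_biotype or transcript_biotype) or ``refseq_gff`` (GFF3 hierarchy
    gene -> RNA feature -> exon, accession-named chromosomes translated via
    ``alias_table``).
    """
    if dialect not in ("ensembl_gtf", "refseq_gff"):
        raise ValueError(f"unknown annotation dialect {dialect!r}")
    db = gffutils.create_db(
        path,
        ":memory:",
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
        keep_order=True,
    )
    index = TranscriptIndex(source="ensembl" if dialect == "ensembl_gtf" else "refseq")
    if dialect == "ensembl_gtf":
        _load_ensembl(db, index)
    else:
        _load_refseq(db, index, alias_table)
    return index


def _load_ensembl(db, index: TranscriptIndex) -> None:
    tx_meta: dict[str, dict] = {}
    exons: dict[str, list[GenomicInterval]] = {}
    for feat in db.all_features():
        tid = _first_attr(feat.attributes, "transcript_id")
        if feat.featuretype == "transcript":
            if tid is None:
                raise ValueError(
                    f"transcript record without transcript_id at "
                    f"{feat.seqid}:{feat.start}"
                )
            tx_meta[tid] = {
                "gene_id": _first_attr(feat.attributes, "gene_id") or tid,
                "gene_symbol": _first_attr(feat.attributes, "gene_name") or "",
                "biotype": _first_attr(
                    feat.attributes, "transcript_biotype", "gene_biotype"
                )
                or "unknown",
            }
        elif feat.featuretype == "exon":
            if tid is None:
                raise ValueError(
                    f"exon without transcript_id at {feat.seqid}:{feat.start}"
                )
            exons.setdefault(tid, []).append(
                GenomicInterval(feat.seqid, feat.start, feat.end, feat.strand)
            )
    orphans = sorted(set(exons) - set(tx_meta))
    if orphans:
        raise ValueError(f"exons reference unknown transcripts: {orphans[:5]}")
    for tid, meta in tx_meta.items():
        chain = tuple(sorted(exons.get(tid, []), key=lambda e: e.start))
        if not chain:
            continue
        index.add(
            TranscriptModel(
                transcript_id=tid,
                gene_id=meta["gene_id"],
                gene_symbol=meta["gene_symbol"],
                biotype=meta["biotype"],
                chrom=chain[0].chrom,
                strand=chain[0].strand,
                exon_chain=chain,
            )
        )


def _load_refseq(
    db, index: TranscriptIndex, alias_table: Optional[Mapping[str, str]]
) -> None:
    genes: dict[str, dict] = {}
    for feat in db.features_of_type("gene"):
        genes[feat.id] = {
            "gene_id": feat.id,
            "gene_symbol": _first_attr(feat.attributes, "gene", "Name") or "",
            "biotype": _first_attr(feat.attributes, "gene_biotype"),
        }
    tx_meta: dict[str, dict] = {}
    for ftype in _REFSEQ_TX_TYPES:
        for feat in db.features_of_type(ftype):
            parent = _first_attr(feat.attributes, "Parent")
            gene = genes.get(parent, {})
            biotype = (
                _first_attr(feat.attributes, "transcript_biotype")
                or gene.get("biotype")
                or _REFSEQ_BIOTYPE_BY_TYPE.get(ftype, "unknown")
            )
            tx_meta[feat.id] = {
                "gene_id": gene.get("gene_id", parent or feat.id),
                "gene_symbol": gene.get("gene_symbol", ""),
                "biotype": biotype,
            }
    exons: dict[str, list[GenomicInterval]] = {}
    unmapped: set[str] = set()
    for feat in db.features_of_type("exon"):
        parent = _first_attr(feat.attributes, "Parent")
        if parent is None or parent not in tx_meta:
            raise ValueError(
                f"exon without known parent transcript at {feat.seqid}:{feat.start}"
            )
        chrom = feat.seqid
        if alias_table is not None:
            if chrom not in alias_table:
                unmapped.add(chrom)
                continue
            chrom = alias_table[chrom]
        exons.setdefault(parent, []).append(
            GenomicInterval(chrom, feat.start, feat.end, feat.strand)
        )
    if unmapped:
        raise ValueError(
            f"accession chromosome names without alias mapping: {sorted(unmapped)}"
        )
    if alias_table is None:
        accession_like = {
            chain[0].chrom
            for chain in exons.values()
            if chain and chain[0].chrom.startswith(("NC_", "NT_", "NW_"))
        }
        if accession_like:
            raise ValueError(
                "RefSeq annotation uses accession chromosome names "
                f"{sorted(accession_like)[:3]} but no alias table was given"
            )
    for tid, chain_list in exons.items():
        meta = tx_meta[tid]
        chain = tuple(sorted(chain_list, key=lambda e: e.start))
        index.add(
            TranscriptModel(
                transcript_id=tid,
                gene_id=meta["gene_id"],
                gene_symbol=meta["gene_symbol"],
                biotype=meta["biotype"],
                chrom=chain[0].chrom,
                strand=chain[0].strand,
                exon_chain=chain,
            )
        )


# ---------------------------------------------------------------------------
# criteria (i)-(v)


@dataclass
class SourceVerdict:
    """Per-annotation-source outcome of validating one event."""

    verdict: str  # "valid" | "invalid" | "unmatched"
    criterion: str
    matched_transcripts: tuple[str, ...] = ()


@dataclass
class ValidationResult:
    """Combined two-source verdict for one event."""

    event_id: str
    event_type: str
    ensembl: SourceVerdict
    refseq: SourceVerdict
    coding_status: str = "unassessed"  # "coding" | "noncoding" | "unassessed"
    matched_genes: tuple[str, ...] = ()

    @property
    def support_class(self) -> str:
        e = self.ensembl.verdict == "valid"
        r = self.refseq.verdict == "valid"
        if e and r:
            return "both"
        if e:
            return "ensembl_only"
        if r:
            return "refseq_only"
        return "neither"


def _chain_pos(coords, exon: GenomicInterval, slack: int) -> Optional[int]:
    for i, (s, e) in enumerate(coords):
        if abs(s - exon.start) <= slack and abs(e - exon.end) <= slack:
            return i
    return None


def _contains_consecutive(coords, exon_list, slack: int) -> bool:
    """All exons present, chain-consecutive, in order."""
    positions = [_chain_pos(coords, x, slack) for x in exon_list]
    if any(p is None for p in positions):
        return False
    return all(b == a + 1 for a, b in zip(positions, positions[1:]))


def _contains_all(coords, exon_list, slack: int) -> bool:
    return all(_chain_pos(coords, x, slack) is not None for x in exon_list)


def validate_event(
    event: ASEvent, index: TranscriptIndex, boundary_slack: int = 0
) -> SourceVerdict:
    """Apply the type's criterion against one annotation source.

    Returns ``unmatched`` when the index does not cover the event's
    chromosome or no transcript overlaps its span; otherwise ``valid`` or
    ``invalid`` per criteria (i)-(v), with every transcript supporting the
    match recorded.
    """
    criterion = CRITERION_BY_TYPE[event.event_type]
    if not index.covers_chrom(event.chrom):
        return SourceVerdict("unmatched", criterion)
    lo, hi = event.span
    cands = index.candidates(event.chrom, lo, hi, event.strand)
    if not cands:
        return SourceVerdict("unmatched", criterion)

    matched: list[str] = []
    if event.event_type == "SE":
        for tx in cands:
            if _contains_all(tx.coords, event.exons, boundary_slack):
                matched.append(tx.transcript_id)
    elif event.event_type == "RI":
        for tx in cands:
            if _contains_consecutive(tx.coords, event.exons, boundary_slack):
                matched.append(tx.transcript_id)
    elif event.event_type == "MXE":
        e1, e2, e3, e4 = event.exons
        has_124: list[str] = []
        has_134: list[str] = []
        has_all_four = False
        for tx in cands:
            if _contains_all(tx.coords, event.exons, boundary_slack):
                has_all_four = True
            if _contains_consecutive(tx.coords, (e1, e2, e4), boundary_slack):
                has_124.append(tx.transcript_id)
            if _contains_consecutive(tx.coords, (e1, e3, e4), boundary_slack):
                has_134.append(tx.transcript_id)
        if has_124 and has_134 and not has_all_four:
            matched = sorted(set(has_124) | set(has_134))
        else:
            matched = []
    else:  # A3SS / A5SS
        var_idx = event.variable_exon_index()
        const_exon = event.exons[1 - var_idx]
        long_form, short_form = event.variable_forms()
        for tx in cands:
            for form in (long_form, short_form):
                pair = sorted((const_exon, form), key=lambda e: e.start)
                if _contains_consecutive(tx.coords, pair, boundary_slack):
                    matched.append(tx.transcript_id)
                    break
    matched = sorted(set(matched))
    return SourceVerdict(
        "valid" if matched else "invalid", criterion, tuple(matched)
    )


CODING_BIOTYPES = frozenset({"protein_coding", "mRNA"})


def classify_coding(
    ensembl_verdict: SourceVerdict,
    refseq_verdict: SourceVerdict,
    ensembl_index: Optional[TranscriptIndex],
    refseq_index: Optional[TranscriptIndex],
) -> str:
    """Coding iff any matched transcript (union over sources) is protein-coding."""
    biotypes: set[str] = set()
    for verdict, index in (
        (ensembl_verdict, ensembl_index),
        (refseq_verdict, refseq_index),
    ):
        if index is None or verdict.verdict != "valid":
            continue
        for tid in verdict.matched_transcripts:
            biotypes.add(index.transcripts[tid].biotype)
    if not biotypes:
        return "unassessed"
    return "coding" if biotypes & CODING_BIOTYPES else "noncoding"


def validate_all(
    events: Iterable[ASEvent],
    ensembl_index: TranscriptIndex,
    refseq_index: TranscriptIndex,
    boundary_slack: int = 0,
) -> list[ValidationResult]:
    """Validate every event against both annotation sources."""
    results = []
    for ev in events:
        ve = validate_event(ev, ensembl_index, boundary_slack)
        vr = validate_event(ev, refseq_index, boundary_slack)
        genes: set[str] = set()
        for verdict, idx in ((ve, ensembl_index), (vr, refseq_index)):
            for tid in verdict.matched_transcripts:
                sym = idx.transcripts[tid].gene_symbol or idx.transcripts[tid].gene_id
                genes.add(sym)
        results.append(
            ValidationResult(
                event_id=ev.event_id,
                event_type=ev.event_type,
                ensembl=ve,
                refseq=vr,
                coding_status=classify_coding(ve, vr, ensembl_index, refseq_index),
                matched_genes=tuple(sorted(genes)),
            )
        )
    return results


def partition_by_support(results: Iterable[ValidationResult]) -> dict:
    """Disjoint, exhaustive partition of events by annotation support.

    Returns support counts plus per-type before/after tallies, where "after"
    counts events valid in at least one source.
    """
    results = list(results)
    counts = {"both": 0, "ensembl_only": 0, "refseq_only": 0, "neither": 0}
    per_type: dict[str, dict[str, int]] = {}
    for r in results:
        counts[r.support_class] += 1
        slot = per_type.setdefault(r.event_type, {"before": 0, "after": 0})
        slot["before"] += 1
        if r.support_class != "neither":
            slot["after"] += 1
    for slot in per_type.values():
        slot["retained_pct"] = (
            100.0 * slot["after"] / slot["before"] if slot["before"] else 0.0
        )
    assert sum(counts.values()) == len(results)
    return {"support": counts, "per_type": per_type, "total": len(results)}


def results_to_frame(results: Iterable[ValidationResult]) -> pd.DataFrame:
    """Tabulate validation results with the documented output columns."""
    rows = []
    for r in results:
        rows.append(
            {
                "event_id": r.event_id,
                "event_type": r.event_type,
                "criterion": r.ensembl.criterion,
                "ensembl_verdict": r.ensembl.verdict,
                "ensembl_transcripts": ",".join(r.ensembl.matched_transcripts),
                "refseq_verdict": r.refseq.verdict,
                "refseq_transcripts": ",".join(r.refseq.matched_transcripts),
                "support_class": r.support_class,
                "coding_status": r.coding_status,
                "matched_genes": ",".join(r.matched_genes),
                "multi_gene_support": len(r.matched_genes) > 1,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "event_id",
            "event_type",
            "criterion",
            "ensembl_verdict",
            "ensembl_transcripts",
            "refseq_verdict",
            "refseq_transcripts",
            "support_class",
            "coding_status",
            "matched_genes",
            "multi_gene_support",
        ],
    )
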