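"""Alternative-splicing event model: parsing, validation, serialization.

Events are one of five classical types -- skipped exon (SE), retained intron
(RI), mutually exclusive exons (MXE), alternative 3' splice site (A3SS) and
alternative 5' splice site (A5SS) -- each described by the genomic exons that
participate in the choice.  Event identifiers in the wild come in several
typographic dialects of the same colon/at-sign scheme, e.g.::

    chr1:150,483,352:150,483,674:+@chr1:150,483,933:150,484,307:+@...
    chr10:24,833,910-24,834,032:+@chr10:24,834,756-24,836,772:+
    chr7:134,617,739:134,618,141|134,618,828:+@chr7:134,620,439:134,620,516:+

with exon blocks separated by ``@``, coordinates either colon-separated or
dash-ranged, optional thousands separators, en-dashes, stray spaces, and (for
A3SS/A5SS) a ``p1|p2`` pair marking the two alternative boundaries of the
variable exon.  All coordinates are 1-based fully closed intervals.

The parser normalizes every dialect into one canonical representation;
:func:`event_signature` gives a stable key for cross-dataset joins.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Optional

import gffutils

EVENT_TYPES = ("SE", "RI", "MXE", "A3SS", "A5SS")

#: exon-count requirement per event type
_EXONS_PER_TYPE = {"SE": 3, "RI": 2, "MXE": 4, "A3SS": 2, "A5SS": 2}

# en dash, minus sign, figure dash, non-breaking hyphen -> ASCII hyphen
_DASH_RE = re.compile("[‒–—−‑]")
_STRAND_RE = re.compile(r"^([+-])\s*([A-Za-z0-9_.\-]+)?$")
_INT_RE = re.compile(r"^\d+$")


class EventParseError(ValueError):
    """Raised when an event identifier or event file cannot be parsed."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """1-based, fully closed genomic interval on a stranded chromosome."""

    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.start > self.end:
            raise ValueError(
                f"start > end in interval {self.chrom}:{self.start}-{self.end}"
            )

    def __len__(self) -> int:
        return self.end - self.start + 1

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.end
            and other.start <= self.end
        )


@dataclass(frozen=True)
class ASEvent:
    """A typed alternative-splicing event.

    ``exons`` are stored in ascending genomic order regardless of strand;
    transcript order for minus-strand events is obtained by reversing.  For
    A3SS/A5SS the variable exon is stored in its *long* form and
    ``alt_boundaries`` carries the two alternative positions of the boundary
    that varies (``alt_side`` says whether that is the exon's start or end).
    """

    event_id: str
    event_type: str
    exons: tuple[GenomicInterval, ...]
    alt_boundaries: Optional[tuple[int, int]] = None
    alt_side: Optional[str] = None  # "start" | "end", A3SS/A5SS only
    host_gene: Optional[str] = None

    def __post_init__(self) -> None:
        if self.event_type not in EVENT_TYPES:
            raise ValueError(f"unknown event type {self.event_type!r}")
        want = _EXONS_PER_TYPE[self.event_type]
        if len(self.exons) != want:
            raise ValueError(
                f"{self.event_type} event needs {want} exons, got {len(self.exons)}"
            )
        chroms = {e.chrom for e in self.exons}
        strands = {e.strand for e in self.exons}
        if len(chroms) != 1 or len(strands) != 1:
            raise ValueError("all exons must share one chromosome and strand")
        starts = [e.start for e in self.exons]
        if starts != sorted(starts):
            raise ValueError("exons must be in ascending genomic order")
        for a, b in zip(self.exons, self.exons[1:]):
            if a.end >= b.start:
                raise ValueError(
                    f"overlapping exons {a.start}-{a.end} and {b.start}-{b.end}"
                )
        if self.event_type == "RI":
            a, b = self.exons
            if b.start - a.end - 1 < 1:
                raise ValueError("RI exons must be separated by a gap >= 1 bp")
        if self.event_type in ("A3SS", "A5SS"):
            if self.alt_boundaries is None or len(self.alt_boundaries) != 2:
                raise ValueError(
                    f"{self.event_type} event requires exactly 2 alt_boundaries"
                )
            if self.alt_side not in ("start", "end"):
                raise ValueError("A3SS/A5SS event requires alt_side 'start' or 'end'")
        elif self.alt_boundaries is not None:
            raise ValueError(f"{self.event_type} event must not carry alt_boundaries")

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def span(self) -> tuple[int, int]:
        """Outermost genomic span covered by the event's exons."""
        return self.exons[0].start, self.exons[-1].end

    def variable_exon_index(self) -> int:
        """Index (in genomic order) of the variable exon of an A3SS/A5SS event."""
        if self.alt_boundaries is None:
            raise ValueError("only A3SS/A5SS events have a variable exon")
        lo, hi = self.alt_boundaries
        for i, e in enumerate(self.exons):
            if self.alt_side == "end" and e.end == hi:
                return i
            if self.alt_side == "start" and e.start == lo:
                return i
        raise ValueError("alt_boundaries do not match any exon boundary")

    def variable_forms(self) -> tuple[GenomicInterval, GenomicInterval]:
        """Long and short form of the A3SS/A5SS variable exon."""
        i = self.variable_exon_index()
        exon = self.exons[i]
        lo, hi = self.alt_boundaries  # type: ignore[misc]
        if self.alt_side == "end":
            long_form = replace(exon, end=hi)
            short_form = replace(exon, end=lo)
        else:
            long_form = replace(exon, start=lo)
            short_form = replace(exon, start=hi)
        return long_form, short_form


@dataclass
class EventSet:
    """A keyed collection of events from one dataset."""

    events: dict[str, ASEvent] = field(default_factory=dict)
    source_label: str = ""

    def add(self, event: ASEvent) -> None:
        if event.event_id in self.events:
            raise ValueError(f"duplicate event_id {event.event_id!r}")
        self.events[event.event_id] = event

    def __len__(self) -> int:
        return len(self.events)

    def __iter__(self) -> Iterator[ASEvent]:
        return iter(self.events.values())

    def __contains__(self, event_id: str) -> bool:
        return event_id in self.events

    def __getitem__(self, event_id: str) -> ASEvent:
        return self.events[event_id]


# ---------------------------------------------------------------------------
# identifier parsing


def _parse_coord(token: str, block: str):
    """One coordinate field: a plain integer or an 'a|b' alternative pair."""
    token = token.replace(",", "").replace(" ", "")
    if "|" in token:
        parts = token.split("|")
        if len(parts) != 2 or not all(_INT_RE.match(p) for p in parts):
            raise EventParseError(f"malformed alternative boundary in block {block!r}")
        return ("alt", int(parts[0]), int(parts[1]))
    if not _INT_RE.match(token):
        raise EventParseError(f"malformed coordinate {token!r} in block {block!r}")
    return int(token)


def _parse_block(raw: str):
    """Parse one exon block -> (chrom, start_item, end_item, strand, gene).

    start/end items are ints or ('alt', p1, p2) pairs; at most one may be an
    alternative pair.
    """
    block = _DASH_RE.sub("-", raw).strip()
    tokens = [t.strip() for t in block.split(":")]
    if len(tokens) < 3:
        raise EventParseError(f"malformed block {raw!r}: expected chrom:coords:strand")
    chrom = tokens[0].replace(" ", "")
    if not chrom:
        raise EventParseError(f"empty chromosome in block {raw!r}")
    m = _STRAND_RE.match(tokens[-1])
    if m is None:
        raise EventParseError(f"malformed strand field {tokens[-1]!r} in block {raw!r}")
    strand, gene = m.group(1), m.group(2)

    coords: list = []
    for token in tokens[1:-1]:
        token = token.replace(",", "").replace(" ", "")
        # dash-range dialect: "start-end" in a single field
        if "-" in token and "|" not in token:
            left, sep, right = token.partition("-")
            coords.append(_parse_coord(left, raw))
            coords.append(_parse_coord(right, raw))
        elif "-" in token:
            # e.g. "a-b|c": range whose second coordinate is an alt pair
            left, sep, right = token.partition("-")
            coords.append(_parse_coord(left, raw))
            coords.append(_parse_coord(right, raw))
        else:
            coords.append(_parse_coord(token, raw))
    if len(coords) != 2:
        raise EventParseError(
            f"block {raw!r} has {len(coords)} coordinates, expected start and end"
        )
    n_alt = sum(1 for c in coords if isinstance(c, tuple))
    if n_alt > 1:
        raise EventParseError(f"block {raw!r} has more than one alternative boundary")
    return chrom, coords[0], coords[1], strand, gene


def _infer_ss_type(alt_side: str, strand: str) -> str:
    """Which splice-site family varies, given the varying exon side and strand.

    A donor (5') site sits at the transcript-3' end of the upstream exon:
    genomic end on '+', genomic start on '-'.  An acceptor (3') site is the
    mirror image.
    """
    if alt_side == "end":
        return "A5SS" if strand == "+" else "A3SS"
    return "A3SS" if strand == "+" else "A5SS"


def parse_event_id(
    id_string: str, declared_type: Optional[str] = None
) -> ASEvent:
    """Parse an event identifier string in any supported dialect.

    Type is inferred from the block count and the presence of an ``a|b``
    alternative-boundary pair when ``declared_type`` is not given: 3 blocks
    make an SE, 4 an MXE, 2 with a pair an A3SS or A5SS (disambiguated by
    strand and by which end of the variable exon carries the pair), and 2
    plain blocks an RI.  A trailing gene symbol after the final strand sign
    is accepted and stored as ``host_gene``.
    """
    if declared_type is not None and declared_type not in EVENT_TYPES:
        raise EventParseError(f"unknown declared type {declared_type!r}")
    raw_blocks = [b for b in id_string.split("@") if b.strip()]
    if len(raw_blocks) not in (2, 3, 4):
        raise EventParseError(
            f"event id has {len(raw_blocks)} exon blocks, expected 2-4: {id_string!r}"
        )
    parsed = [_parse_block(b) for b in raw_blocks]

    chroms = {p[0] for p in parsed}
    strands = {p[3] for p in parsed}
    if len(chroms) != 1:
        raise EventParseError(f"inconsistent chromosomes {sorted(chroms)} across blocks")
    if len(strands) != 1:
        raise EventParseError(f"inconsistent strands {sorted(strands)} across blocks")
    chrom, strand = chroms.pop(), strands.pop()
    host_gene = next((p[4] for p in parsed if p[4]), None)

    exons: list[GenomicInterval] = []
    alt_boundaries: Optional[tuple[int, int]] = None
    alt_side: Optional[str] = None
    for raw, (c, start_item, end_item, s, g) in zip(raw_blocks, parsed):
        if isinstance(start_item, tuple):
            p1, p2 = start_item[1], start_item[2]
            alt_boundaries = (min(p1, p2), max(p1, p2))
            alt_side = "start"
            start = min(p1, p2)  # long form
            end = end_item
        elif isinstance(end_item, tuple):
            p1, p2 = end_item[1], end_item[2]
            alt_boundaries = (min(p1, p2), max(p1, p2))
            alt_side = "end"
            start = start_item
            end = max(p1, p2)  # long form
        else:
            start, end = start_item, end_item
        if start > end:
            raise EventParseError(f"start > end in block {raw!r}")
        try:
            exons.append(GenomicInterval(chrom, start, end, strand))
        except ValueError as exc:
            raise EventParseError(f"invalid block {raw!r}: {exc}") from exc
    exons.sort(key=lambda e: (e.start, e.end))

    n = len(exons)
    if n == 3:
        inferred = "SE"
    elif n == 4:
        inferred = "MXE"
    elif alt_boundaries is not None:
        inferred = _infer_ss_type(alt_side, strand)  # type: ignore[arg-type]
    else:
        inferred = "RI"
    if declared_type is not None:
        compatible = (
            _EXONS_PER_TYPE[declared_type] == n
            and (declared_type in ("A3SS", "A5SS")) == (alt_boundaries is not None)
        )
        if not compatible:
            raise EventParseError(
                f"declared type {declared_type} incompatible with "
                f"{n} blocks (inferred {inferred})"
            )
        event_type = declared_type
    else:
        event_type = inferred

    if event_type not in ("A3SS", "A5SS"):
        alt_boundaries = None
        alt_side = None

    event = ASEvent(
        event_id="",  # filled below from the canonical form
        event_type=event_type,
        exons=tuple(exons),
        alt_boundaries=alt_boundaries,
        alt_side=alt_side,
        host_gene=host_gene,
    )
    return replace(event, event_id=format_event_id(event))


def format_event_id(event: ASEvent) -> str:
    """Canonical identifier: colon dialect, no thousands separators."""
    var_idx = (
        event.variable_exon_index() if event.alt_boundaries is not None else None
    )
    blocks = []
    for i, e in enumerate(event.exons):
        start: str = str(e.start)
        end: str = str(e.end)
        if i == var_idx:
            lo, hi = event.alt_boundaries  # type: ignore[misc]
            if event.alt_side == "end":
                end = f"{lo}|{hi}"
            else:
                start = f"{lo}|{hi}"
        blocks.append(f"{e.chrom}:{start}:{end}:{e.strand}")
    return "@".join(blocks)


def event_signature(event: ASEvent) -> str:
    """Stable dialect-independent key: type, chrom, strand, ordered coords.

    Two events share a signature iff they have identical type, chromosome,
    strand, ordered exon coordinates and alternative boundaries.
    """
    coords = ",".join(f"{e.start}-{e.end}" for e in event.exons)
    alt = ""
    if event.alt_boundaries is not None:
        alt = f"|{event.alt_side}:{event.alt_boundaries[0]}/{event.alt_boundaries[1]}"
    return f"{event.event_type}|{event.chrom}({event.strand})|{coords}{alt}"


# ---------------------------------------------------------------------------
# GFF3 serialization (exon-centric event records)


def write_event_gff(events: Iterable[ASEvent], path: str) -> None:
    """Write events as an exon-centric GFF3: gene -> mRNA -> exon per event."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for ev in events:
            lo, hi = ev.span
            attrs = [f"ID={ev.event_id}", f"event_type={ev.event_type}"]
            if ev.host_gene:
                attrs.append(f"gene_symbol={ev.host_gene}")
            if ev.alt_boundaries is not None:
                attrs.append(
                    f"alt_boundaries={ev.alt_boundaries[0]},{ev.alt_boundaries[1]}"
                )
                attrs.append(f"alt_side={ev.alt_side}")
            fh.write(
                f"{ev.chrom}\taltsplice\tgene\t{lo}\t{hi}\t.\t{ev.strand}\t.\t"
                + ";".join(attrs)
                + "\n"
            )
            mrna_id = f"{ev.event_id}.iso"
            fh.write(
                f"{ev.chrom}\taltsplice\tmRNA\t{lo}\t{hi}\t.\t{ev.strand}\t.\t"
                f"ID={mrna_id};Parent={ev.event_id}\n"
            )
            for e in ev.exons:
                fh.write(
                    f"{e.chrom}\taltsplice\texon\t{e.start}\t{e.end}\t.\t"
                    f"{e.strand}\t.\tParent={mrna_id}\n"
                )


def read_event_gff(path: str, source_label: str = "") -> EventSet:
    """Read an exon-centric event GFF3 written by :func:`write_event_gff`."""
    try:
        db = gffutils.create_db(
            path,
            ":memory:",
            merge_strategy="error",
            keep_order=True,
        )
    except Exception as exc:  # sqlite IntegrityError on duplicate IDs etc.
        raise EventParseError(f"cannot parse event GFF3 {path!r}: {exc}") from exc

    # every exon must resolve to an mRNA that resolves to a gene
    known_mrnas = {f.id for f in db.features_of_type("mRNA")}
    for exon in db.features_of_type("exon"):
        parents = exon.attributes.get("Parent", [])
        if not parents or parents[0] not in known_mrnas:
            raise EventParseError(
                f"exon at {exon.seqid}:{exon.start}-{exon.end} references "
                f"unknown parent {parents!r}"
            )

    out = EventSet(source_label=source_label)
    for gene in db.features_of_type("gene"):
        event_type = gene.attributes["event_type"][0]
        host = gene.attributes.get("gene_symbol", [None])[0]
        alt_boundaries = None
        alt_side = None
        if "alt_boundaries" in gene.attributes:
            vals = [int(v) for v in gene.attributes["alt_boundaries"]]
            alt_boundaries = (min(vals), max(vals))
            alt_side = gene.attributes["alt_side"][0]
        exons = []
        for mrna in db.children(gene, featuretype="mRNA"):
            for exon in db.children(mrna, featuretype="exon"):
                exons.append(
                    GenomicInterval(exon.seqid, exon.start, exon.end, exon.strand)
                )
        exons.sort(key=lambda e: (e.start, e.end))
        event = ASEvent(
            event_id=gene.id,
            event_type=event_type,
            exons=tuple(exons),
            alt_boundaries=alt_boundaries,
            alt_side=alt_side,
            host_gene=host,
        )
        out.add(event)
    return out


def write_event_tsv(events: Iterable[ASEvent], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("event_id\tevent_type\tgene_symbol\n")
        for ev in events:
            fh.write(f"{ev.event_id}\t{ev.event_type}\t{ev.host_gene or ''}\n")
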