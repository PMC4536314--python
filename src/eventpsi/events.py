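"""Enumeration of binary alternative-splicing events from gene models.

Seven event types are detected, each a local, two-form variation of the
exon-intron structure:

======  =========================================================
SE      skipping (cassette) exon
A5/A3   alternative 5' (donor) / 3' (acceptor) splice site
MX      mutually exclusive exons
RI      retained intron
AF/AL   alternative first / last exon
======  =========================================================

Every event carries two disjoint transcript sets: ``f1``, the transcripts
realizing the form whose inclusion level (PSI) is reported, and ``f2``, the
transcripts realizing the alternative form. The reported form follows fixed
conventions:

* SE  — the form that includes the middle exon;
* A5/A3 — the form that minimizes the intron length;
* MX  — the form containing the alternative exon with the smallest start
  coordinate (the genomically left-most exon), regardless of strand;
* RI  — the form that retains the intron;
* AF/AL — the form that maximizes the intron length.

Events are keyed by their splice-junction coordinates: transcripts whose
outer (non-junction) exon boundaries differ still pool into the same event,
so the two transcript sets are as large as the annotation allows. A5/A3 and
AF/AL labels are strand-aware (a donor-side variation on the minus strand
lies at the genomic right end); the MX left-most rule alone is strand
agnostic.

Event identifiers follow the template
``<gene_id>;<type>:<seqname>:<coordinates>:<strand>`` where the coordinate
block lists the junctions (``end-start`` pairs) and, for RI/AF/AL, the outer
exon boundaries that frame them.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

from eventpsi.annotation import Gene, Transcript


class EventType(str, Enum):
    SE = "SE"
    A5 = "A5"
    A3 = "A3"
    MX = "MX"
    RI = "RI"
    AF = "AF"
    AL = "AL"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


ALL_EVENT_TYPES: tuple[EventType, ...] = tuple(EventType)


class IoeParseError(ValueError):
    """An ioe file row or header could not be parsed."""


class EventValidationError(ValueError):
    """An event violates a structural invariant."""


@dataclass(frozen=True)
class Event:
    """One binary splicing event.

    ``signature`` holds the defining genomic coordinates flat, in the order
    they are rendered in the event identifier.
    """

    event_type: EventType
    gene_id: str
    seqname: str
    strand: str
    signature: tuple[int, ...]
    f1: frozenset[str]
    f2: frozenset[str]

    def __post_init__(self) -> None:
        if not self.f1 or not self.f2:
            raise EventValidationError(
                f"{self.event_type} event in {self.gene_id}: both forms need "
                f"at least one transcript"
            )
        if self.f1 & self.f2:
            raise EventValidationError(
                f"{self.event_type} event in {self.gene_id}: transcript sets "
                f"overlap: {sorted(self.f1 & self.f2)}"
            )

    @property
    def event_id(self) -> str:
        return format_event_id(self)

    @property
    def span(self) -> tuple[int, int]:
        return min(self.signature), max(self.signature)

    @property
    def all_transcripts(self) -> frozenset[str]:
        return self.f1 | self.f2


# Coordinate-block shapes per (type, strand): "j" renders two coordinates as
# "end-start" (a junction), "s" renders one (an outer exon boundary). AF/AL
# shapes swap with strand because the terminal exon swaps genomic side.
_SHAPES: dict[tuple[EventType, str], tuple[str, ...]] = {
    (EventType.SE, "+"): ("j", "j"),
    (EventType.SE, "-"): ("j", "j"),
    (EventType.A5, "+"): ("j", "j"),
    (EventType.A5, "-"): ("j", "j"),
    (EventType.A3, "+"): ("j", "j"),
    (EventType.A3, "-"): ("j", "j"),
    (EventType.MX, "+"): ("j", "j", "j", "j"),
    (EventType.MX, "-"): ("j", "j", "j", "j"),
    (EventType.RI, "+"): ("s", "j", "s"),
    (EventType.RI, "-"): ("s", "j", "s"),
    (EventType.AF, "+"): ("s", "j", "s", "j"),
    (EventType.AF, "-"): ("j", "s", "j", "s"),
    (EventType.AL, "+"): ("j", "s", "j", "s"),
    (EventType.AL, "-"): ("s", "j", "s", "j"),
}


def format_event_id(ev: Event) -> str:
    """Render the event identifier
    ``<gene_id>;<type>:<seqname>:<coordinates>:<strand>``."""
    shape = _SHAPES[(ev.event_type, ev.strand)]
    coords = list(ev.signature)
    parts: list[str] = []
    i = 0
    for token in shape:
        if token == "j":
            parts.append(f"{coords[i]}-{coords[i + 1]}")
            i += 2
        else:
            parts.append(str(coords[i]))
            i += 1
    if i != len(coords):
        raise EventValidationError(
            f"{ev.event_type} signature has {len(coords)} coordinates, "
            f"expected {i}"
        )
    return f"{ev.gene_id};{ev.event_type.value}:{ev.seqname}:{':'.join(parts)}:{ev.strand}"


def parse_event_id(event_id: str) -> tuple[str, EventType, str, tuple[int, ...], str]:
    """Invert :func:`format_event_id`.

    Returns ``(gene_id, event_type, seqname, signature, strand)``.
    """
    try:
        gene_id, rest = event_id.split(";", 1)
        fields = rest.split(":")
        etype = EventType(fields[0])
        seqname = fields[1]
        strand = fields[-1]
        coord_parts = fields[2:-1]
        if strand not in ("+", "-") or not coord_parts:
            raise ValueError
        signature: list[int] = []
        for part in coord_parts:
            signature.extend(int(x) for x in part.split("-"))
    except (ValueError, IndexError) as exc:
        raise IoeParseError(f"malformed event id {event_id!r}") from exc
    return gene_id, etype, seqname, tuple(signature), strand


def events_overlap(a: Event, b: Event) -> bool:
    """True iff the genomic spans of the two events intersect on the same
    chromosome."""
    if a.seqname != b.seqname:
        return False
    (a_lo, a_hi), (b_lo, b_hi) = a.span, b.span
    return a_lo <= b_hi and b_lo <= a_hi


# ---------------------------------------------------------------------------
# per-transcript lookup tables shared by the detectors


class _TxIndex:
    """Junction/exon lookups for the transcripts of one gene."""

    def __init__(self, gene: Gene):
        self.gene = gene
        self.junctions: dict[str, list[tuple[int, int]]] = {}
        self.junction_sets: dict[str, set[tuple[int, int]]] = {}
        self.exon_sets: dict[str, set[tuple[int, int]]] = {}
        self.tx: dict[str, Transcript] = {}
        for t in gene.transcripts:
            js = t.junctions()
            self.tx[t.transcript_id] = t
            self.junctions[t.transcript_id] = js
            self.junction_sets[t.transcript_id] = set(js)
            self.exon_sets[t.transcript_id] = {(e.start, e.end) for e in t.exons}

    def with_junction(self, j: tuple[int, int]) -> set[str]:
        return {tid for tid, js in self.junction_sets.items() if j in js}

    def left_terminal(self, tid: str) -> tuple[int, int]:
        e = self.tx[tid].exons[0]
        return e.start, e.end

    def right_terminal(self, tid: str) -> tuple[int, int]:
        e = self.tx[tid].exons[-1]
        return e.start, e.end


def _mk_event(
    gene: Gene,
    etype: EventType,
    signature: Sequence[int],
    f1: set[str],
    f2: set[str],
) -> Event:
    return Event(
        event_type=etype,
        gene_id=gene.gene_id,
        seqname=gene.seqname,
        strand=gene.strand,
        signature=tuple(signature),
        f1=frozenset(f1),
        f2=frozenset(f2),
    )


def detect_SE(gene: Gene) -> list[Event]:
    """Skipping-exon events: an internal exon flanked by junctions
    ``(e1, s2)`` and ``(e2, s3)`` in the inclusion form, with junction
    ``(e1, s3)`` in the skipping form. F1 includes the exon."""
    idx = _TxIndex(gene)
    events: dict[tuple[int, ...], tuple[set[str], set[str]]] = {}
    for tid, js in idx.junctions.items():
        for (e1, s2), (e2, s3) in zip(js, js[1:]):
            skip = idx.with_junction((e1, s3))
            if not skip:
                continue
            key = (e1, s2, e2, s3)
            if key in events:
                continue
            incl = {
                t
                for t in idx.junction_sets
                if (e1, s2) in idx.junction_sets[t]
                and (e2, s3) in idx.junction_sets[t]
                and (s2, e2) in idx.exon_sets[t]
            }
            if incl:
                events[key] = (incl, skip)
    return [
        _mk_event(gene, EventType.SE, key, f1, f2)
        for key, (f1, f2) in events.items()
    ]


def detect_RI(gene: Gene) -> list[Event]:
    """Retained-intron events: junction ``(e1, s2)`` in the spliced form
    versus a single exon spanning the whole region in the retaining form.
    F1 retains the intron.

    The outer boundaries ``s1``/``e2`` of the signature are the widest exon
    boundaries among the spliced supporters; the retaining exon must span
    them.
    """
    idx = _TxIndex(gene)
    events: list[Event] = []
    seen: set[tuple[int, int]] = set()
    for tid, js in idx.junctions.items():
        for (e1, s2) in js:
            if (e1, s2) in seen:
                continue
            seen.add((e1, s2))
            spliced = idx.with_junction((e1, s2))
            s1 = min(
                s for t in spliced for (s, e) in idx.exon_sets[t] if e == e1
            )
            e2 = max(
                e for t in spliced for (s, e) in idx.exon_sets[t] if s == s2
            )
            retaining = {
                t
                for t in idx.exon_sets
                if any(s <= s1 and e >= e2 for (s, e) in idx.exon_sets[t])
            }
            if retaining:
                events.append(
                    _mk_event(
                        gene, EventType.RI, (s1, e1, s2, e2), retaining, spliced
                    )
                )
    return events


def _alt_site_events(gene: Gene, idx: _TxIndex) -> list[Event]:
    """Alternative donor/acceptor events: two junctions sharing one anchor,
    with the variable boundaries lying on overlapping exons. F1 minimizes
    the intron length."""
    events: list[Event] = []

    # shared genomic-right anchor (acceptor on '+'): junctions (e, s) with
    # common s and distinct e; variation at the donor on '+', acceptor on '-'
    by_right: dict[int, set[int]] = defaultdict(set)
    for js in idx.junction_sets.values():
        for (e, s) in js:
            by_right[s].add(e)
    for s, ends in sorted(by_right.items()):
        for e_small in sorted(ends):
            for e_big in sorted(ends):
                if e_big <= e_small:
                    continue
                f_short = idx.with_junction((e_big, s))  # shorter intron
                f_long = idx.with_junction((e_small, s))
                # the extended exon must overlap the shorter exon: some
                # supporter's exon ending at e_big starts at or before e_small
                overlap = any(
                    es <= e_small
                    for t in f_short
                    for (es, ee) in idx.exon_sets[t]
                    if ee == e_big
                )
                if not overlap:
                    continue
                etype = EventType.A5 if gene.strand == "+" else EventType.A3
                events.append(
                    _mk_event(
                        gene, etype, (e_big, s, e_small, s), f_short, f_long
                    )
                )

    # shared genomic-left anchor (donor on '+'): junctions (e, s) with common
    # e and distinct s
    by_left: dict[int, set[int]] = defaultdict(set)
    for js in idx.junction_sets.values():
        for (e, s) in js:
            by_left[e].add(s)
    for e, starts in sorted(by_left.items()):
        for s_small in sorted(starts):
            for s_big in sorted(starts):
                if s_big <= s_small:
                    continue
                f_short = idx.with_junction((e, s_small))
                f_long = idx.with_junction((e, s_big))
                overlap = any(
                    ee >= s_big
                    for t in f_short
                    for (es, ee) in idx.exon_sets[t]
                    if es == s_small
                )
                if not overlap:
                    continue
                etype = EventType.A3 if gene.strand == "+" else EventType.A5
                events.append(
                    _mk_event(
                        gene, etype, (e, s_small, e, s_big), f_short, f_long
                    )
                )
    return events


def detect_A5(gene: Gene) -> list[Event]:
    idx = _TxIndex(gene)
    return [e for e in _alt_site_events(gene, idx) if e.event_type == EventType.A5]


def detect_A3(gene: Gene) -> list[Event]:
    idx = _TxIndex(gene)
    return [e for e in _alt_site_events(gene, idx) if e.event_type == EventType.A3]


def detect_MX(gene: Gene) -> list[Event]:
    """Mutually exclusive exons: two non-overlapping internal exons sharing
    both flanking junction anchors, never co-included. F1 contains the
    genomically left-most alternative exon, regardless of strand."""
    idx = _TxIndex(gene)
    # collect internal exons with their flanking junction pairs
    internal: dict[tuple[int, int, int, int], set[str]] = defaultdict(set)
    for tid, js in idx.junctions.items():
        for (e1, s2), (e2, s4) in zip(js, js[1:]):
            # middle exon is (s2, e2)
            internal[(e1, s2, e2, s4)].add(tid)
    events: list[Event] = []
    keys = sorted(internal)
    for i, (e1, s2, e2, s4) in enumerate(keys):
        for (f1_, s3, e3, f4_) in keys[i + 1 :]:
            if (f1_, f4_) != (e1, s4):
                continue
            if e2 >= s3:  # exons overlap: not mutually exclusive
                continue
            left = internal[(e1, s2, e2, s4)]
            right = internal[(e1, s3, e3, s4)]
            if left & right:
                continue
            events.append(
                _mk_event(
                    gene,
                    EventType.MX,
                    (e1, s2, e2, s4, e1, s3, e3, s4),
                    left,
                    right,
                )
            )
    return events


def _alt_terminal_events(gene: Gene, idx: _TxIndex) -> list[Event]:
    """Alternative first/last exon events: distinct, non-overlapping terminal
    exons splicing to a shared anchor junction. F1 maximizes the intron
    length."""
    events: list[Event] = []

    # genomic-left terminal exons: first exon on '+' (AF), last exon on '-'
    # (AL); junctions (e_term, s_anchor) grouped by the shared anchor start
    by_anchor_l: dict[int, dict[int, set[str]]] = defaultdict(lambda: defaultdict(set))
    term_start_l: dict[tuple[int, int], int] = {}
    for tid, js in idx.junctions.items():
        if not js:
            continue
        s_term, e_term = idx.left_terminal(tid)
        e, s = js[0]
        if e != e_term:
            continue
        by_anchor_l[s][e_term].add(tid)
        key = (s, e_term)
        term_start_l[key] = min(term_start_l.get(key, s_term), s_term)
    for s_anchor, forms in sorted(by_anchor_l.items()):
        ends = sorted(forms)
        for i, eA in enumerate(ends):
            for eB in ends[i + 1 :]:
                # eA < eB: form A has the longer intron (F1). Terminal exons
                # must not overlap, else this is an alternative splice site.
                if eA >= term_start_l[(s_anchor, eB)]:
                    continue
                etype = EventType.AF if gene.strand == "+" else EventType.AL
                sig = (
                    term_start_l[(s_anchor, eA)], eA, s_anchor,
                    term_start_l[(s_anchor, eB)], eB, s_anchor,
                )
                events.append(
                    _mk_event(gene, etype, sig, forms[eA], forms[eB])
                )

    # genomic-right terminal exons: last exon on '+' (AL), first on '-' (AF)
    by_anchor_r: dict[int, dict[int, set[str]]] = defaultdict(lambda: defaultdict(set))
    term_end_r: dict[tuple[int, int], int] = {}
    for tid, js in idx.junctions.items():
        if not js:
            continue
        s_term, e_term = idx.right_terminal(tid)
        e, s = js[-1]
        if s != s_term:
            continue
        by_anchor_r[e][s_term].add(tid)
        key = (e, s_term)
        term_end_r[key] = max(term_end_r.get(key, e_term), e_term)
    for e_anchor, forms in sorted(by_anchor_r.items()):
        starts = sorted(forms)
        for i, sA in enumerate(starts):
            for sB in starts[i + 1 :]:
                # sA < sB: form B has the longer intron (F1)
                if term_end_r[(e_anchor, sA)] >= sB:
                    continue
                etype = EventType.AL if gene.strand == "+" else EventType.AF
                sig = (
                    e_anchor, sB, term_end_r[(e_anchor, sB)],
                    e_anchor, sA, term_end_r[(e_anchor, sA)],
                )
                events.append(
                    _mk_event(gene, etype, sig, forms[sB], forms[sA])
                )
    return events


def detect_AF(gene: Gene) -> list[Event]:
    idx = _TxIndex(gene)
    return [e for e in _alt_terminal_events(gene, idx) if e.event_type == EventType.AF]


def detect_AL(gene: Gene) -> list[Event]:
    idx = _TxIndex(gene)
    return [e for e in _alt_terminal_events(gene, idx) if e.event_type == EventType.AL]


_DETECTORS = {
    EventType.SE: detect_SE,
    EventType.A5: detect_A5,
    EventType.A3: detect_A3,
    EventType.MX: detect_MX,
    EventType.RI: detect_RI,
    EventType.AF: detect_AF,
    EventType.AL: detect_AL,
}


def detect_events(
    gene: Gene, types: Iterable[EventType | str] | None = None
) -> list[Event]:
    """All events of the requested types in one gene.

    Events are keyed by ``(type, signature)``; the transcript sets pool
    every supporting isoform of the gene, so re-running on the same gene, or
    on a gene with duplicated transcript entries, returns the identical
    catalog. Genes with fewer than two transcripts yield no events.
    """
    wanted = (
        tuple(EventType(t) for t in types) if types is not None else ALL_EVENT_TYPES
    )
    if len(gene.transcripts) < 2:
        return []
    out: list[Event] = []
    for etype in ALL_EVENT_TYPES:  # fixed order for determinism
        if etype in wanted:
            out.extend(_DETECTORS[etype](gene))
    out.sort(key=lambda ev: (ev.event_type.value, ev.signature))
    return out


# ---------------------------------------------------------------------------
# catalog + ioe serialization


@dataclass
class EventCatalog:
    """All events detected in an annotation, serializable to an ioe file."""

    events: list[Event] = field(default_factory=list)
    source: str = ""

    def __post_init__(self) -> None:
        ids = [ev.event_id for ev in self.events]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise EventValidationError(f"duplicate event ids: {dupes[:5]}")

    def __len__(self) -> int:
        return len(self.events)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, EventCatalog):
            return NotImplemented
        return sorted(self.events, key=lambda e: e.event_id) == sorted(
            other.events, key=lambda e: e.event_id
        )

    def sorted_events(self) -> list[Event]:
        """Events in byte-stable output order: (seqname, first signature
        coordinate, event id)."""
        return sorted(
            self.events, key=lambda ev: (ev.seqname, ev.signature[0], ev.event_id)
        )

    def counts_by_type(self) -> dict[str, int]:
        counts: dict[str, int] = defaultdict(int)
        for ev in self.events:
            counts[ev.event_type.value] += 1
        return dict(counts)


def detect_all_events(
    annotation, types: Iterable[EventType | str] | None = None
) -> EventCatalog:
    """Run :func:`detect_events` over every gene of an annotation."""
    events: list[Event] = []
    for gene in annotation.genes.values():
        events.extend(detect_events(gene, types))
    return EventCatalog(events=events, source=annotation.source_path)


IOE_COLUMNS = (
    "seqname",
    "gene_id",
    "event_id",
    "alternative_transcripts",
    "total_transcripts",
)


def write_ioe(catalog: EventCatalog, path: str | Path) -> None:
    """Write the event-to-transcript mapping as a 5-column tab-separated
    file: ``alternative_transcripts`` lists the F1 transcripts and
    ``total_transcripts`` all transcripts of the event, comma-joined and
    sorted."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("\t".join(IOE_COLUMNS) + "\n")
        for ev in catalog.sorted_events():
            fh.write(
                "\t".join(
                    [
                        ev.seqname,
                        ev.gene_id,
                        ev.event_id,
                        ",".join(sorted(ev.f1)),
                        ",".join(sorted(ev.all_transcripts)),
                    ]
                )
                + "\n"
            )


def read_ioe(path: str | Path) -> EventCatalog:
    """Read an ioe file back into an :class:`EventCatalog`."""
    path = Path(path)
    events: list[Event] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header) != IOE_COLUMNS:
            raise IoeParseError(
                f"{path}: expected header {list(IOE_COLUMNS)}, got {header}"
            )
        for lineno, raw in enumerate(fh, start=2):
            line = raw.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 5:
                raise IoeParseError(
                    f"{path}:{lineno}: expected 5 fields, got {len(fields)}"
                )
            seqname, gene_id, event_id, alt_s, total_s = fields
            gid, etype, seq_id, signature, strand = parse_event_id(event_id)
            if gid != gene_id or seq_id != seqname:
                raise IoeParseError(
                    f"{path}:{lineno}: event id {event_id!r} disagrees with "
                    f"gene_id/seqname columns"
                )
            f1 = set(alt_s.split(",")) if alt_s else set()
            total = set(total_s.split(",")) if total_s else set()
            if not f1 <= total:
                raise IoeParseError(
                    f"{path}:{lineno}: alternative transcripts "
                    f"{sorted(f1 - total)} missing from total_transcripts"
                )
            events.append(
                Event(
                    event_type=etype,
                    gene_id=gene_id,
                    seqname=seqname,
                    strand=strand,
                    signature=signature,
                    f1=frozenset(f1),
                    f2=frozenset(total - f1),
                )
            )
    return EventCatalog(events=events, source=str(path))
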