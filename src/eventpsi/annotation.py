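"""GTF parsing into validated gene/transcript/exon models.

Coordinates are kept exactly as in GTF: 1-based, fully inclusive. No
conversion to half-open intervals happens anywhere in the package, so every
coordinate appearing in an event identifier can be matched against the
annotation by eye.

Only ``exon`` feature lines are used to build transcript models; ``gene``,
``transcript``, ``CDS`` and other feature lines are ignored. Both Ensembl
(``1``) and UCSC (``chr1``) chromosome naming conventions are accepted by
the default chromosome filter.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

logger = logging.getLogger(__name__)


class GtfParseError(ValueError):
    """A GTF line could not be parsed; the message names the line number."""


class AnnotationValidationError(ValueError):
    """A transcript or gene model violates a structural invariant."""


@dataclass(frozen=True, order=True)
class Exon:
    """A genomic interval (1-based, inclusive on both ends)."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < 1:
            raise AnnotationValidationError(
                f"exon coordinates must be positive: ({self.start}, {self.end})"
            )
        if self.start > self.end:
            raise AnnotationValidationError(
                f"exon start {self.start} exceeds end {self.end}"
            )

    def __len__(self) -> int:
        return self.end - self.start + 1


@dataclass
class Transcript:
    """An ordered exon chain on one strand of one chromosome.

    Exons are stored in ascending genomic order regardless of strand;
    transcription order on the minus strand is the reverse of storage order.
    """

    transcript_id: str
    gene_id: str
    seqname: str
    strand: str
    exons: list[Exon]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise AnnotationValidationError(
                f"transcript {self.transcript_id}: strand must be '+' or '-', "
                f"got {self.strand!r}"
            )
        if not self.exons:
            raise AnnotationValidationError(
                f"transcript {self.transcript_id} has no exons"
            )
        self.exons = sorted(self.exons, key=lambda e: (e.start, e.end))
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start <= a.end:
                raise AnnotationValidationError(
                    f"transcript {self.transcript_id}: exons ({a.start},{a.end}) "
                    f"and ({b.start},{b.end}) overlap"
                )

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0].start, self.exons[-1].end

    def junctions(self) -> list[tuple[int, int]]:
        """Splice junctions as (donor-side exon end, acceptor-side exon start)
        pairs in ascending genomic order."""
        return [
            (a.end, b.start) for a, b in zip(self.exons, self.exons[1:])
        ]


@dataclass
class Gene:
    """A gene: the set of transcripts sharing one ``gene_id``."""

    gene_id: str
    seqname: str
    strand: str
    transcripts: list[Transcript] = field(default_factory=list)

    def __post_init__(self) -> None:
        for t in self.transcripts:
            if t.gene_id != self.gene_id:
                raise AnnotationValidationError(
                    f"transcript {t.transcript_id} (gene {t.gene_id}) placed "
                    f"in gene {self.gene_id}"
                )
            if t.seqname != self.seqname:
                raise AnnotationValidationError(
                    f"transcript {t.transcript_id} on {t.seqname} placed in "
                    f"gene {self.gene_id} on {self.seqname}"
                )


@dataclass
class Annotation:
    """A collection of genes parsed from one annotation source."""

    genes: dict[str, Gene] = field(default_factory=dict)
    source_path: str = ""

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for g in self.genes.values():
            for t in g.transcripts:
                if t.transcript_id in seen:
                    raise AnnotationValidationError(
                        f"duplicate transcript id {t.transcript_id}"
                    )
                seen.add(t.transcript_id)

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_transcripts(self) -> int:
        return sum(len(g.transcripts) for g in self.genes.values())

    def transcripts(self) -> Iterator[Transcript]:
        for g in self.genes.values():
            yield from g.transcripts

    def transcript_to_gene(self) -> dict[str, str]:
        return {
            t.transcript_id: g.gene_id
            for g in self.genes.values()
            for t in g.transcripts
        }


# Default chromosome filter: autosomes and sex chromosomes, with and without
# the UCSC "chr" prefix. Scaffolds, patches and the mitochondrial genome are
# excluded, mirroring common practice for event enumeration.
STANDARD_CHROMOSOMES: frozenset[str] = frozenset(
    {str(i) for i in range(1, 23)}
    | {f"chr{i}" for i in range(1, 23)}
    | {"X", "Y", "chrX", "chrY"}
)

# key "value"; key=value and unquoted dialects also accepted
_ATTR_RE = re.compile(r'(\w+)\s*[= ]\s*"?([^";]+)"?')


def _parse_attributes(attr_field: str) -> dict[str, str]:
    return {m.group(1): m.group(2).strip() for m in _ATTR_RE.finditer(attr_field)}


def _merge_adjacent(exons: list[Exon], transcript_id: str) -> list[Exon]:
    """Merge book-ended exons (zero-length intron) into one exon."""
    exons = sorted(set(exons), key=lambda e: (e.start, e.end))
    merged: list[Exon] = []
    for e in exons:
        if merged and e.start == merged[-1].end + 1:
            logger.warning(
                "transcript %s: merging book-ended exons (%d,%d) and (%d,%d)",
                transcript_id, merged[-1].start, merged[-1].end, e.start, e.end,
            )
            merged[-1] = Exon(merged[-1].start, e.end)
        else:
            merged.append(e)
    return merged


def parse_gtf(path: str | Path, attribute_dialect: str = "auto") -> Annotation:
    """Parse a GTF file into an :class:`Annotation`.

    Parameters
    ----------
    path:
        GTF file; 9 tab-separated fields per line, ``#`` comments allowed.
    attribute_dialect:
        Accepted for interface completeness; attributes in Ensembl
        (``key "value";``) and plain ``key=value`` styles are both
        recognized automatically.

    Only ``exon`` features are used. Duplicate exon lines for one transcript
    are dropped silently; book-ended exons are merged with a warning;
    transcripts whose strand disagrees with the first-seen strand of their
    gene are dropped with a warning.
    """
    path = Path(path)
    # transcript_id -> (gene_id, seqname, strand, [Exon, ...])
    pending: dict[str, tuple[str, str, str, list[Exon]]] = {}
    order: list[str] = []

    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise GtfParseError(
                    f"{path}:{lineno}: expected 9 tab-separated fields, "
                    f"got {len(fields)}"
                )
            seqname, _source, feature, start_s, end_s, _score, strand, _frame, attrs = fields
            if feature != "exon":
                continue
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise GtfParseError(
                    f"{path}:{lineno}: non-integer coordinates "
                    f"{start_s!r}, {end_s!r}"
                ) from exc
            attributes = _parse_attributes(attrs)
            gene_id = attributes.get("gene_id")
            transcript_id = attributes.get("transcript_id")
            if not gene_id or not transcript_id:
                raise GtfParseError(
                    f"{path}:{lineno}: exon line lacks gene_id or transcript_id"
                )
            try:
                exon = Exon(start, end)
            except AnnotationValidationError as exc:
                raise GtfParseError(f"{path}:{lineno}: {exc}") from exc
            if transcript_id not in pending:
                pending[transcript_id] = (gene_id, seqname, strand, [])
                order.append(transcript_id)
            else:
                g0, s0, st0, _ = pending[transcript_id]
                if (g0, s0, st0) != (gene_id, seqname, strand):
                    raise GtfParseError(
                        f"{path}:{lineno}: transcript {transcript_id} has "
                        f"inconsistent gene/seqname/strand across exon lines"
                    )
            pending[transcript_id][3].append(exon)

    genes: dict[str, Gene] = {}
    for transcript_id in order:
        gene_id, seqname, strand, exons = pending[transcript_id]
        exons = _merge_adjacent(exons, transcript_id)
        t = Transcript(transcript_id, gene_id, seqname, strand, exons)
        if gene_id not in genes:
            genes[gene_id] = Gene(gene_id, seqname, strand)
        gene = genes[gene_id]
        if t.strand != gene.strand:
            logger.warning(
                "transcript %s on strand %s dropped: gene %s was first seen "
                "on strand %s", transcript_id, t.strand, gene_id, gene.strand,
            )
            continue
        if t.seqname != gene.seqname:
            logger.warning(
                "transcript %s on %s dropped: gene %s was first seen on %s",
                transcript_id, t.seqname, gene_id, gene.seqname,
            )
            continue
        gene.transcripts.append(t)

    genes = {gid: g for gid, g in genes.items() if g.transcripts}
    return Annotation(genes=genes, source_path=str(path))


def write_gtf(ann: Annotation, path: str | Path, source: str = "eventpsi") -> None:
    """Write an annotation back to GTF (exon features only)."""
    path = Path(path)
    with open(path, "w") as fh:
        for gene in ann.genes.values():
            for t in gene.transcripts:
                for e in t.exons:
                    attrs = (
                        f'gene_id "{t.gene_id}"; '
                        f'transcript_id "{t.transcript_id}";'
                    )
                    fh.write(
                        "\t".join(
                            [
                                t.seqname, source, "exon",
                                str(e.start), str(e.end),
                                ".", t.strand, ".", attrs,
                            ]
                        )
                        + "\n"
                    )


def filter_chromosomes(
    ann: Annotation, keep: Iterable[str] | None = None
) -> Annotation:
    """Restrict an annotation to genes on the given chromosomes.

    ``keep`` defaults to :data:`STANDARD_CHROMOSOMES` (autosomes + X/Y in
    both naming conventions). Counts of removed genes and transcripts are
    logged.
    """
    keep_set = frozenset(keep) if keep is not None else STANDARD_CHROMOSOMES
    if not keep_set:
        raise ValueError("keep must be non-empty")
    kept = {gid: g for gid, g in ann.genes.items() if g.seqname in keep_set}
    removed_genes = ann.n_genes - len(kept)
    removed_tx = ann.n_transcripts - sum(len(g.transcripts) for g in kept.values())
    if removed_genes:
        logger.info(
            "chromosome filter removed %d genes (%d transcripts)",
            removed_genes, removed_tx,
        )
    return Annotation(genes=kept, source_path=ann.source_path)


def introns_of(t: Transcript) -> list[tuple[int, int]]:
    """Intron intervals of a transcript, 1-based inclusive.

    For ascending exons ``(s_i, e_i)`` the introns are
    ``(e_i + 1, s_{i+1} - 1)``; a single-exon transcript has none.
    """
    return [(a.end + 1, b.start - 1) for a, b in zip(t.exons, t.exons[1:])]
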