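"""Synthetic annotations and quantifications with known ground-truth PSI.

The central construction mirrors how a reference set for accuracy analysis
is built from real annotations: a gene with exactly two transcript isoforms
that differ by a single binary splicing event. For such a gene the PSI of
the event is *identical* to the relative abundance of the inclusion
isoform, so a quantification built from chosen relative abundances gives
exact ground truth for the whole pipeline.

Coordinates are drawn on a toy chromosome of ~10^4 bp; no sequence content
is generated, since event detection depends only on exon-intron structure.
The multiplicative noise model (log-normal, unit mean) stands in for the
combined read-sampling and quantification error of a real RNA-seq
experiment; it preserves positivity and leaves the expected TPM unchanged,
which is all the recovery tests require.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from eventpsi.annotation import Exon, Gene, Transcript
from eventpsi.events import Event, EventType

DEFAULT_SCALE = 10_000


@dataclass(frozen=True)
class PlantedEvent:
    """A two-isoform gene realizing exactly one splicing event.

    ``expected_event`` is the event the detectors must find: its ``f1``
    holds the inclusion isoform and ``f2`` the alternative isoform.
    """

    event_type: EventType
    gene: Gene
    inclusion_transcript: str
    alternative_transcript: str
    expected_event: Event

    @property
    def expected_signature(self) -> tuple[int, ...]:
        return self.expected_event.signature

    @property
    def expected_event_id(self) -> str:
        return self.expected_event.event_id


def _coords(rng: np.random.Generator, n: int, scale: int) -> list[int]:
    """n strictly increasing coordinates with gaps >= 2 (positive exon and
    intron lengths) fitting comfortably inside [1, scale]."""
    max_step = max(3, scale // (n + 1))
    steps = rng.integers(2, max_step, size=n)
    start = int(rng.integers(1, max(2, scale // 20)))
    return list(np.cumsum(steps) + start)


# '+'-strand exon layouts: (inclusion exons, alternative exons, signature)
# as functions of an ascending coordinate vector c.
def _layout_plus(
    event_type: EventType, c: list[int]
) -> tuple[list[Exon], list[Exon], tuple[int, ...]]:
    E = Exon
    if event_type == EventType.SE:
        inc = [E(c[0], c[1]), E(c[2], c[3]), E(c[4], c[5])]
        alt = [E(c[0], c[1]), E(c[4], c[5])]
        sig = (c[1], c[2], c[3], c[4])
    elif event_type == EventType.RI:
        inc = [E(c[0], c[3])]  # retains the intron
        alt = [E(c[0], c[1]), E(c[2], c[3])]
        sig = (c[0], c[1], c[2], c[3])
    elif event_type == EventType.A5:
        # competing donors c[1] < c[2] with shared acceptor c[3]
        inc = [E(c[0], c[2]), E(c[3], c[4])]  # shorter intron
        alt = [E(c[0], c[1]), E(c[3], c[4])]
        sig = (c[2], c[3], c[1], c[3])
    elif event_type == EventType.A3:
        # shared donor c[1], competing acceptors c[2] < c[3]
        inc = [E(c[0], c[1]), E(c[2], c[4])]  # shorter intron
        alt = [E(c[0], c[1]), E(c[3], c[4])]
        sig = (c[1], c[2], c[1], c[3])
    elif event_type == EventType.MX:
        inc = [E(c[0], c[1]), E(c[2], c[3]), E(c[6], c[7])]  # left-most exon
        alt = [E(c[0], c[1]), E(c[4], c[5]), E(c[6], c[7])]
        sig = (c[1], c[2], c[3], c[6], c[1], c[4], c[5], c[6])
    elif event_type == EventType.AF:
        inc = [E(c[0], c[1]), E(c[4], c[5])]  # longer intron
        alt = [E(c[2], c[3]), E(c[4], c[5])]
        sig = (c[0], c[1], c[4], c[2], c[3], c[4])
    elif event_type == EventType.AL:
        inc = [E(c[0], c[1]), E(c[4], c[5])]  # longer intron
        alt = [E(c[0], c[1]), E(c[2], c[3])]
        sig = (c[1], c[4], c[5], c[1], c[2], c[3])
    else:  # pragma: no cover
        raise ValueError(f"unknown event type {event_type}")
    return inc, alt, sig


_N_COORDS = {
    EventType.SE: 6, EventType.RI: 4, EventType.A5: 5, EventType.A3: 5,
    EventType.MX: 8, EventType.AF: 6, EventType.AL: 6,
}


def mirror_signature(
    event_type: EventType, sig: tuple[int, ...], m: int
) -> tuple[int, ...]:
    """Signature of the event after reflecting every coordinate x -> m - x.

    SE/MX/RI signatures simply reverse; A5/A3 mirror each junction in place
    (the shorter-intron junction stays first); AF/AL mirror each 3-coordinate
    terminal-exon block in place (the longer-intron form stays first).
    """
    if event_type in (EventType.SE, EventType.MX, EventType.RI):
        return tuple(m - x for x in reversed(sig))
    if event_type in (EventType.A5, EventType.A3):
        (a, b), (cc, d) = (sig[0], sig[1]), (sig[2], sig[3])
        return (m - b, m - a, m - d, m - cc)
    # AF/AL: two blocks of three, each reversed and reflected
    g1, g2 = sig[:3], sig[3:]
    return tuple(m - x for x in reversed(g1)) + tuple(m - x for x in reversed(g2))


_REFLECT_SWAP = {
    EventType.A5: EventType.A3,
    EventType.A3: EventType.A5,
    EventType.AF: EventType.AL,
    EventType.AL: EventType.AF,
}


def mirror_gene(gene: Gene, m: int, flip_strand: bool = True) -> Gene:
    """Reflect every coordinate of a gene through ``m`` (x -> m - x),
    optionally flipping the strand (reflection + flip is the
    reverse-complement of the locus)."""
    strand = gene.strand
    if flip_strand:
        strand = "-" if strand == "+" else "+"
    transcripts = [
        Transcript(
            t.transcript_id,
            t.gene_id,
            t.seqname,
            strand,
            [Exon(m - e.end, m - e.start) for e in t.exons],
        )
        for t in gene.transcripts
    ]
    return Gene(gene.gene_id, gene.seqname, strand, transcripts)


def mirror_event(ev: Event, m: int, flip_strand: bool = True) -> Event:
    """The image of an event under :func:`mirror_gene`.

    With the strand flipped (reverse complement) every event keeps its
    type: donor/acceptor and first/last labels follow the strand. Without
    the flip A5<->A3 and AF<->AL exchange. In both cases the mutually
    exclusive exon that was left-most becomes right-most, so the reported
    MX form swaps (the left-most rule is strand-agnostic).
    """
    strand = ev.strand
    etype = ev.event_type
    if flip_strand:
        strand = "-" if strand == "+" else "+"
    else:
        etype = _REFLECT_SWAP.get(etype, etype)
    f1, f2 = ev.f1, ev.f2
    if etype == EventType.MX:
        f1, f2 = f2, f1
    return Event(
        event_type=etype,
        gene_id=ev.gene_id,
        seqname=ev.seqname,
        strand=strand,
        signature=mirror_signature(ev.event_type, ev.signature, m),
        f1=f1,
        f2=f2,
    )


def make_two_isoform_gene(
    event_type: EventType | str,
    seed: int,
    coordinate_scale: int = DEFAULT_SCALE,
    gene_id: str | None = None,
    seqname: str = "chrS",
    strand: str | None = None,
) -> PlantedEvent:
    """A gene with two isoforms differing by exactly one event of the given
    type, with randomized but valid coordinates. Deterministic per seed.

    ``strand`` defaults to a seed-determined random choice; minus-strand
    genes are built as the reverse complement of a plus-strand layout, so
    the planted event keeps its biological type.
    """
    event_type = EventType(event_type)
    rng = np.random.default_rng(seed)
    c = _coords(rng, _N_COORDS[event_type], coordinate_scale)
    if strand is None:
        strand = "+" if rng.integers(0, 2) == 0 else "-"
    gene_id = gene_id if gene_id is not None else f"G{event_type.value}{seed}"
    t_inc_id, t_alt_id = f"{gene_id}.t1", f"{gene_id}.t2"

    inc_exons, alt_exons, sig = _layout_plus(event_type, c)
    f1_tid, f2_tid = t_inc_id, t_alt_id
    if strand == "-":
        m = coordinate_scale + max(sig) + 1
        inc_exons = [Exon(m - e.end, m - e.start) for e in reversed(inc_exons)]
        alt_exons = [Exon(m - e.end, m - e.start) for e in reversed(alt_exons)]
        sig = mirror_signature(event_type, sig, m)
        if event_type == EventType.MX:
            # the formerly left-most exon is now right-most
            f1_tid, f2_tid = t_alt_id, t_inc_id

    t_inc = Transcript(t_inc_id, gene_id, seqname, strand, inc_exons)
    t_alt = Transcript(t_alt_id, gene_id, seqname, strand, alt_exons)
    gene = Gene(gene_id, seqname, strand, [t_inc, t_alt])
    expected = Event(
        event_type=event_type,
        gene_id=gene_id,
        seqname=seqname,
        strand=strand,
        signature=sig,
        f1=frozenset({f1_tid}),
        f2=frozenset({f2_tid}),
    )
    inclusion = f1_tid
    alternative = f2_tid
    return PlantedEvent(event_type, gene, inclusion, alternative, expected)


def make_quantification(
    planted: list[PlantedEvent],
    psi: np.ndarray,
    gene_tpm: np.ndarray,
    sample_ids: list[str] | None = None,
) -> pd.DataFrame:
    """Transcript x sample TPM table realizing the given ground truth.

    ``psi`` and ``gene_tpm`` are (n_events, n_samples) arrays (1-D input is
    treated as a single sample): the inclusion isoform receives
    ``psi * gene_tpm`` and the alternative isoform ``(1 - psi) * gene_tpm``,
    so the pipeline recovers ``psi`` exactly wherever the gene passes the
    expression filter.
    """
    psi = np.atleast_2d(np.asarray(psi, dtype=float))
    gene_tpm = np.atleast_2d(np.asarray(gene_tpm, dtype=float))
    if psi.shape != gene_tpm.shape or psi.shape[0] != len(planted):
        raise ValueError(
            f"shape mismatch: {len(planted)} events, psi {psi.shape}, "
            f"gene_tpm {gene_tpm.shape}"
        )
    if ((psi < 0) | (psi > 1)).any():
        raise ValueError("psi values must lie in [0, 1]")
    if (gene_tpm < 0).any():
        raise ValueError("gene TPM totals must be non-negative")
    n_samples = psi.shape[1]
    if sample_ids is None:
        sample_ids = [f"sample{j + 1}" for j in range(n_samples)]
    rows: dict[str, np.ndarray] = {}
    for i, pl in enumerate(planted):
        rows[pl.inclusion_transcript] = psi[i] * gene_tpm[i]
        rows[pl.alternative_transcript] = (1.0 - psi[i]) * gene_tpm[i]
    return pd.DataFrame.from_dict(rows, orient="index", columns=sample_ids)


def make_noisy_quantification(
    q: pd.DataFrame, dispersion: float, seed: int
) -> pd.DataFrame:
    """Multiply each TPM by an independent log-normal factor with unit mean
    and coefficient of variation ``dispersion``. Deterministic per seed;
    ``dispersion=0`` returns the input unchanged."""
    if dispersion < 0:
        raise ValueError("dispersion must be >= 0")
    if dispersion == 0:
        return q.copy()
    rng = np.random.default_rng(seed)
    sigma2 = np.log1p(dispersion**2)
    factors = rng.lognormal(
        mean=-sigma2 / 2.0, sigma=np.sqrt(sigma2), size=q.shape
    )
    return q * factors


def make_random_gene(
    seed: int,
    max_transcripts: int = 5,
    max_exons: int = 6,
    coordinate_scale: int = DEFAULT_SCALE,
    gene_id: str = "G1",
    seqname: str = "chrS",
) -> Gene:
    """A random toy gene for stress-testing the detectors.

    Transcripts are random walks over a shared grid of exon slots, each
    slot offering an optional alternative start or end, so shared and
    variant junctions arise naturally. Useful for comparing detectors
    against independent oracles.
    """
    rng = np.random.default_rng(seed)
    n_slots = int(rng.integers(2, max_exons + 1))
    bounds = _coords(rng, 2 * n_slots, coordinate_scale)
    slots = []
    for i in range(n_slots):
        s, e = bounds[2 * i], bounds[2 * i + 1]
        starts = [s]
        ends = [e]
        third = (e - s) // 3
        if third >= 1:  # alternative boundaries never cross each other
            if rng.random() < 0.5:
                starts.append(s + int(rng.integers(1, third + 1)))
            if rng.random() < 0.5:
                ends.append(e - int(rng.integers(1, third + 1)))
        slots.append((starts, ends))
    strand = "+" if rng.integers(0, 2) == 0 else "-"
    n_tx = int(rng.integers(2, max_transcripts + 1))
    transcripts = []
    for k in range(n_tx):
        chosen = [i for i in range(n_slots) if rng.random() < 0.75]
        if not chosen:
            chosen = [int(rng.integers(0, n_slots))]
        exons = []
        for i in chosen:
            starts, ends = slots[i]
            s = starts[int(rng.integers(0, len(starts)))]
            e = ends[int(rng.integers(0, len(ends)))]
            exons.append(Exon(s, e))
        transcripts.append(
            Transcript(f"{gene_id}.t{k + 1}", gene_id, seqname, strand, exons)
        )
    return Gene(gene_id, seqname, strand, transcripts)
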