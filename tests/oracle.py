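"""Independent brute-force reference detector.

Enumerates every ordered transcript pair of a gene and matches each event
template by direct case analysis over exon index positions, then assigns
form membership by scanning every transcript against the discovered
coordinates. Deliberately written in a different style from the package
detectors (pairwise exon-index loops rather than junction-set lookups) so
it can serve as an independent oracle.

Shared definitions (part of the event model, not of either implementation):
events are keyed by junction coordinates; RI/AF/AL outer boundaries are the
widest among supporting transcripts; form membership requires the defining
junctions (and exon, where the form has one); alternative splice sites need
overlapping flank exons, while alternative terminal exons and mutually
exclusive exons must not overlap.
"""

from __future__ import annotations

from eventpsi.annotation import Gene, Transcript
from eventpsi.events import Event, EventType


def _chain(t: Transcript) -> list[tuple[int, int]]:
    return [(e.start, e.end) for e in t.exons]


def _mk(gene: Gene, etype: EventType, sig, f1, f2) -> Event:
    return Event(
        event_type=etype,
        gene_id=gene.gene_id,
        seqname=gene.seqname,
        strand=gene.strand,
        signature=tuple(sig),
        f1=frozenset(f1),
        f2=frozenset(f2),
    )


def _has_junction(chain, e, s) -> bool:
    return any(
        chain[k][1] == e and chain[k + 1][0] == s for k in range(len(chain) - 1)
    )


def _has_triple(chain, e1, s2, e2, s3) -> bool:
    """Consecutive exons ...,e1) (s2,e2) (s3,..."""
    return any(
        chain[k][1] == e1
        and chain[k + 1] == (s2, e2)
        and chain[k + 2][0] == s3
        for k in range(len(chain) - 2)
    )


def brute_force_events(gene: Gene) -> list[Event]:
    chains = {t.transcript_id: _chain(t) for t in gene.transcripts}
    tids = sorted(chains)
    plus = gene.strand == "+"
    found: dict[tuple, Event] = {}

    def emit(etype, sig, f1, f2):
        key = (etype, tuple(sig))
        if key not in found:
            found[key] = _mk(gene, etype, sig, f1, f2)

    for ta in tids:
        A = chains[ta]
        for tb in tids:
            if tb == ta:
                continue
            B = chains[tb]

            # --- SE: middle exon of A skipped by a junction of B
            for i in range(1, len(A) - 1):
                e1, (s2, e2), s3 = A[i - 1][1], A[i], A[i + 1][0]
                for j in range(len(B) - 1):
                    if B[j][1] == e1 and B[j + 1][0] == s3:
                        incl = {
                            t for t in tids
                            if _has_triple(chains[t], e1, s2, e2, s3)
                        }
                        skip = {
                            t for t in tids if _has_junction(chains[t], e1, s3)
                        }
                        emit(EventType.SE, (e1, s2, e2, s3), incl, skip)

            # --- RI: junction of A contained in a single exon of B
            for i in range(len(A) - 1):
                e1, s2 = A[i][1], A[i + 1][0]
                spliced = {
                    t for t in tids if _has_junction(chains[t], e1, s2)
                }
                s1 = min(
                    chains[t][k][0]
                    for t in spliced
                    for k in range(len(chains[t]))
                    if chains[t][k][1] == e1
                )
                e2 = max(
                    chains[t][k][1]
                    for t in spliced
                    for k in range(len(chains[t]))
                    if chains[t][k][0] == s2
                )
                retaining = {
                    t for t in tids
                    if any(s <= s1 and e >= e2 for (s, e) in chains[t])
                }
                if retaining:
                    emit(EventType.RI, (s1, e1, s2, e2), retaining, spliced)

            # --- A5/A3: junctions sharing one anchor, flank exons overlap
            for i in range(len(A) - 1):
                for j in range(len(B) - 1):
                    dA, aA = A[i][1], A[i + 1][0]
                    dB, aB = B[j][1], B[j + 1][0]
                    if aA == aB and dA != dB:
                        # variation at the genomic-left (donor-on-plus) side
                        ex_a, ex_b = A[i], B[j]
                        if max(ex_a[0], ex_b[0]) <= min(ex_a[1], ex_b[1]):
                            e_small, e_big = min(dA, dB), max(dA, dB)
                            f_short = {
                                t for t in tids
                                if _has_junction(chains[t], e_big, aA)
                            }
                            f_long = {
                                t for t in tids
                                if _has_junction(chains[t], e_small, aA)
                            }
                            emit(
                                EventType.A5 if plus else EventType.A3,
                                (e_big, aA, e_small, aA),
                                f_short,
                                f_long,
                            )
                    if dA == dB and aA != aB:
                        ex_a, ex_b = A[i + 1], B[j + 1]
                        if max(ex_a[0], ex_b[0]) <= min(ex_a[1], ex_b[1]):
                            s_small, s_big = min(aA, aB), max(aA, aB)
                            f_short = {
                                t for t in tids
                                if _has_junction(chains[t], dA, s_small)
                            }
                            f_long = {
                                t for t in tids
                                if _has_junction(chains[t], dA, s_big)
                            }
                            emit(
                                EventType.A3 if plus else EventType.A5,
                                (dA, s_small, dA, s_big),
                                f_short,
                                f_long,
                            )

            # --- MX: disjoint middle exons sharing both flank anchors
            for i in range(1, len(A) - 1):
                for j in range(1, len(B) - 1):
                    f_l, mid_a, f_r = A[i - 1][1], A[i], A[i + 1][0]
                    g_l, mid_b, g_r = B[j - 1][1], B[j], B[j + 1][0]
                    if (f_l, f_r) != (g_l, g_r) or mid_a == mid_b:
                        continue
                    lo, hi = sorted([mid_a, mid_b])
                    if lo[1] >= hi[0]:  # overlap
                        continue
                    left_set = {
                        t for t in tids
                        if _has_triple(chains[t], f_l, lo[0], lo[1], f_r)
                    }
                    right_set = {
                        t for t in tids
                        if _has_triple(chains[t], f_l, hi[0], hi[1], f_r)
                    }
                    emit(
                        EventType.MX,
                        (f_l, lo[0], lo[1], f_r, f_l, hi[0], hi[1], f_r),
                        left_set,
                        right_set,
                    )

            # --- AF/AL, genomic-left terminal exons
            if len(A) >= 2 and len(B) >= 2:
                if A[1][0] == B[1][0] and A[0][1] != B[0][1]:
                    anchor = A[1][0]
                    eA_, eB_ = sorted([A[0][1], B[0][1]])

                    def left_form(e_end):
                        return {
                            t for t in tids
                            if len(chains[t]) >= 2
                            and chains[t][0][1] == e_end
                            and chains[t][1][0] == anchor
                        }

                    formA, formB = left_form(eA_), left_form(eB_)
                    minB = min(chains[t][0][0] for t in formB)
                    if eA_ < minB:  # all terminal exons disjoint
                        minA = min(chains[t][0][0] for t in formA)
                        emit(
                            EventType.AF if plus else EventType.AL,
                            (minA, eA_, anchor, minB, eB_, anchor),
                            formA,  # longer intron
                            formB,
                        )
                # genomic-right terminal exons
                if A[-2][1] == B[-2][1] and A[-1][0] != B[-1][0]:
                    anchor = A[-2][1]
                    sA_, sB_ = sorted([A[-1][0], B[-1][0]])

                    def right_form(s_start):
                        return {
                            t for t in tids
                            if len(chains[t]) >= 2
                            and chains[t][-1][0] == s_start
                            and chains[t][-2][1] == anchor
                        }

                    formA, formB = right_form(sA_), right_form(sB_)
                    maxA = max(chains[t][-1][1] for t in formA)
                    if maxA < sB_:
                        maxB = max(chains[t][-1][1] for t in formB)
                        emit(
                            EventType.AL if plus else EventType.AF,
                            (anchor, sB_, maxB, anchor, sA_, maxA),
                            formB,  # longer intron
                            formA,
                        )

    return sorted(
        found.values(), key=lambda ev: (ev.event_type.value, ev.signature)
    )
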