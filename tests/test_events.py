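import pytest

from oracle import brute_force_events

from eventpsi.events import (
    Event,
    EventCatalog,
    EventType,
    EventValidationError,
    IoeParseError,
    detect_all_events,
    detect_events,
    events_overlap,
    format_event_id,
    parse_event_id,
    read_ioe,
    write_ioe,
)
from eventpsi.fixtures import (
    make_random_gene,
    make_two_isoform_gene,
    mirror_event,
    mirror_gene,
)


class TestWorkedExamples:
    """Hand-checked detections pinning the coordinate dialect and the
    reported-form conventions."""

    def test_se_inclusion_form(self, se_gene):
        (ev,) = detect_events(se_gene, {EventType.SE})
        assert ev.signature == (200, 300, 400, 500)
        assert ev.f1 == {"t1"} and ev.f2 == {"t2"}
        assert format_event_id(ev) == "G1;SE:chr1:200-300:400-500:+"

    def test_ri_reports_retaining_form(self):
        from conftest import build_gene

        g = build_gene([[(100, 200), (300, 400)], [(100, 400)]])
        (ev,) = detect_events(g, {EventType.RI})
        assert ev.f1 == {"t2"} and ev.f2 == {"t1"}
        assert format_event_id(ev) == "G1;RI:chr1:100:200-300:400:+"

    def test_a5_minimizes_intron_length(self):
        from conftest import build_gene

        g = build_gene([[(100, 200), (500, 600)], [(100, 250), (500, 600)]])
        (ev,) = detect_events(g, {EventType.A5})
        # t2's intron 251-499 (249 nt) < t1's 201-499 (299 nt)
        assert ev.f1 == {"t2"} and ev.f2 == {"t1"}
        assert format_event_id(ev) == "G1;A5:chr1:250-500:200-500:+"

    def test_mx_leftmost_exon(self):
        from conftest import build_gene

        g = build_gene(
            [
                [(100, 200), (300, 400), (700, 800)],
                [(100, 200), (500, 600), (700, 800)],
            ]
        )
        (ev,) = detect_events(g, {EventType.MX})
        assert ev.f1 == {"t1"} and ev.f2 == {"t2"}
        assert ev.signature == (200, 300, 400, 700, 200, 500, 600, 700)

    def test_af_maximizes_intron_length(self):
        from conftest import build_gene

        g = build_gene([[(100, 200), (500, 600)], [(300, 400), (500, 600)]])
        (ev,) = detect_events(g, {EventType.AF})
        assert ev.f1 == {"t1"} and ev.f2 == {"t2"}
        assert format_event_id(ev) == "G1;AF:chr1:100:200-500:300:400-500:+"

    def test_single_transcript_gene_yields_nothing(self):
        from conftest import build_gene

        g = build_gene([[(100, 200), (300, 400)]])
        assert detect_events(g) == []

    def test_duplicate_intron_chain_pools_into_f1(self):
        from conftest import build_gene

        g = build_gene(
            [
                [(100, 200), (300, 400), (500, 600)],
                [(100, 200), (500, 600)],
                [(90, 200), (300, 400), (500, 650)],  # same junctions, new flanks
            ]
        )
        (ev,) = detect_events(g, {EventType.SE})
        assert ev.f1 == {"t1", "t3"} and ev.f2 == {"t2"}


class TestOracleEquivalence:
    @pytest.mark.parametrize("block", range(10))
    def test_random_genes_match_brute_force(self, block):
        for seed in range(block * 60, (block + 1) * 60):
            g = make_random_gene(seed)
            assert detect_events(g) == brute_force_events(g), f"seed {seed}"


class TestStructuralInvariants:
    def test_forms_disjoint_and_nonempty(self):
        for seed in range(150):
            for ev in detect_events(make_random_gene(seed)):
                assert ev.f1 and ev.f2 and not (ev.f1 & ev.f2)

    def test_pooling_idempotence(self):
        for seed in range(40):
            g = make_random_gene(seed)
            first = detect_events(g)
            assert detect_events(g) == first
            # duplicating transcript entries must not change the catalog
            from eventpsi.annotation import Gene

            doubled = Gene(
                g.gene_id, g.seqname, g.strand, g.transcripts + g.transcripts
            )
            assert detect_events(doubled) == first

    def test_planted_events_recovered_exactly(self):
        for etype in EventType:
            for strand in "+-":
                for seed in range(10):
                    pl = make_two_isoform_gene(etype, seed=seed, strand=strand)
                    dets = detect_events(pl.gene)
                    assert dets == [pl.expected_event], (etype, strand, seed)

    def test_fixed_seed_reproducible(self):
        a = make_two_isoform_gene(EventType.SE, seed=1)
        b = make_two_isoform_gene(EventType.SE, seed=1)
        assert a == b


class TestMirrorSymmetry:
    """Coordinate reflection swaps A5<->A3 and AF<->AL (splice-site side
    changes); adding a strand flip makes it a reverse complement, which
    preserves every type. Signatures map per the pinned dialect."""

    @pytest.mark.parametrize("flip_strand", [False, True])
    def test_reflection(self, flip_strand):
        m = 10**6
        for seed in range(120):
            g = make_random_gene(seed)
            expected = {
                mirror_event(ev, m, flip_strand=flip_strand)
                for ev in detect_events(g)
            }
            got = set(detect_events(mirror_gene(g, m, flip_strand=flip_strand)))
            assert got == expected, f"seed {seed}"

    def test_reflection_only_swaps_site_and_terminal_types(self):
        swaps = {
            EventType.A5: EventType.A3,
            EventType.A3: EventType.A5,
            EventType.AF: EventType.AL,
            EventType.AL: EventType.AF,
        }
        for etype in EventType:
            pl = make_two_isoform_gene(etype, seed=3, strand="+")
            (ev,) = detect_events(mirror_gene(pl.gene, 10**6, flip_strand=False))
            assert ev.event_type == swaps.get(etype, etype)


class TestEventId:
    def test_round_trip(self):
        for seed in range(80):
            for ev in detect_events(make_random_gene(seed)):
                gid, etype, seq, sig, strand = parse_event_id(format_event_id(ev))
                assert (gid, etype, seq, sig, strand) == (
                    ev.gene_id, ev.event_type, ev.seqname, ev.signature, ev.strand
                )

    def test_malformed_id_rejected(self):
        with pytest.raises(IoeParseError):
            parse_event_id("G1_no_semicolon:SE:chr1:1-2:+")


class TestEventsOverlap:
    def ev(self, etype, sig, seqname="chr1"):
        return Event(
            event_type=etype, gene_id="G", seqname=seqname, strand="+",
            signature=sig, f1=frozenset({"a"}), f2=frozenset({"b"}),
        )

    def test_intersecting_spans(self):
        a = self.ev(EventType.SE, (200, 300, 400, 500))
        b = self.ev(EventType.RI, (100, 200, 300, 400))
        assert events_overlap(a, b) and events_overlap(b, a)

    def test_different_chromosomes(self):
        a = self.ev(EventType.SE, (200, 300, 400, 500))
        b = self.ev(EventType.SE, (200, 300, 400, 500), seqname="chr2")
        assert not events_overlap(a, b)

    def test_reflexive(self):
        a = self.ev(EventType.SE, (200, 300, 400, 500))
        assert events_overlap(a, a)

    def test_disjoint_spans(self):
        a = self.ev(EventType.SE, (200, 300, 400, 500))
        b = self.ev(EventType.SE, (600, 700, 800, 900))
        assert not events_overlap(a, b)


class TestIoe:
    def catalog(self):
        events = []
        for i, etype in enumerate(EventType):
            pl = make_two_isoform_gene(etype, seed=100 + i, gene_id=f"G{i}")
            events.extend(detect_events(pl.gene))
        return EventCatalog(events=events, source="<synthetic>")

    def test_worked_se_row(self, se_gene, tmp_path):
        cat = EventCatalog(events=detect_events(se_gene, {EventType.SE}))
        path = tmp_path / "se.ioe"
        write_ioe(cat, path)
        lines = path.read_text().splitlines()
        assert lines[0] == (
            "seqname\tgene_id\tevent_id\talternative_transcripts\ttotal_transcripts"
        )
        assert lines[1] == "chr1\tG1\tG1;SE:chr1:200-300:400-500:+\tt1\tt1,t2"

    def test_round_trip(self, tmp_path):
        cat = self.catalog()
        path = tmp_path / "all.ioe"
        write_ioe(cat, path)
        assert read_ioe(path) == cat

    def test_byte_stable(self, tmp_path):
        cat = self.catalog()
        p1, p2 = tmp_path / "a.ioe", tmp_path / "b.ioe"
        write_ioe(cat, p1)
        write_ioe(EventCatalog(events=list(reversed(cat.events))), p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_alternative_outside_total_rejected(self, tmp_path):
        path = tmp_path / "bad.ioe"
        path.write_text(
            "seqname\tgene_id\tevent_id\talternative_transcripts\ttotal_transcripts\n"
            "chr1\tG1\tG1;SE:chr1:200-300:400-500:+\ttX\tt1,t2\n"
        )
        with pytest.raises(IoeParseError, match="tX"):
            read_ioe(path)

    def test_missing_header_rejected(self, tmp_path):
        path = tmp_path / "bad.ioe"
        path.write_text("chr1\tG1\tG1;SE:chr1:200-300:400-500:+\tt1\tt1,t2\n")
        with pytest.raises(IoeParseError, match="header"):
            read_ioe(path)

    def test_duplicate_event_ids_rejected(self):
        ev = detect_events(make_two_isoform_gene(EventType.SE, 1).gene)[0]
        with pytest.raises(EventValidationError, match="duplicate"):
            EventCatalog(events=[ev, ev])

    def test_detect_all_events_covers_each_gene(self):
        from eventpsi.annotation import Annotation

        genes = {}
        for i, etype in enumerate(EventType):
            pl = make_two_isoform_gene(etype, seed=40 + i, gene_id=f"G{i}")
            genes[pl.gene.gene_id] = pl.gene
        cat = detect_all_events(Annotation(genes=genes))
        assert len(cat) == len(EventType)
        assert sorted(cat.counts_by_type()) == sorted(t.value for t in EventType)
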