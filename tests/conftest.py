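import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # makes oracle.py importable

from eventpsi.annotation import Exon, Gene, Transcript


def build_gene(exon_lists, strand="+", gene_id="G1", seqname="chr1"):
    """Gene from bare exon tuples: [[(s, e), ...] per transcript]."""
    transcripts = [
        Transcript(
            f"t{i + 1}", gene_id, seqname, strand,
            [Exon(s, e) for s, e in exons],
        )
        for i, exons in enumerate(exon_lists)
    ]
    return Gene(gene_id, seqname, strand, transcripts)


@pytest.fixture
def se_gene():
    """The canonical skipping-exon gene: t1 includes the middle exon."""
    return build_gene(
        [[(100, 200), (300, 400), (500, 600)], [(100, 200), (500, 600)]]
    )
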