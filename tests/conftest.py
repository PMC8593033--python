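import pytest

from splicenrich import TranscriptModel


@pytest.fixture
def toy_model():
    """Three 100 bp exons at 101-200, 301-400, 501-600."""
    return TranscriptModel("TOY", "chr1", "+", [(101, 200), (301, 400), (501, 600)])


@pytest.fixture
def model8():
    """Eight 150 bp exons separated by 300 bp introns; panel-like locus."""
    exons = [(1000 + i * 450, 1000 + i * 450 + 149) for i in range(8)]
    return TranscriptModel("NM_SIM8", "panel", "+", exons)


@pytest.fixture
def model57():
    """A 57-exon transcript mimicking the scale of a large panel gene."""
    exons = [(1000 + i * 500, 1000 + i * 500 + 199) for i in range(57)]
    return TranscriptModel("NM_BIG", "chr17", "+", exons)


def write_toy_gtf(path, transcript_id="TOY", with_cds=False):
    lines = []
    for start, end in [(101, 200), (301, 400), (501, 600)]:
        attrs = f'gene_id "G1"; transcript_id "{transcript_id}";'
        lines.append(
            f"chr1\ttest\texon\t{start}\t{end}\t.\t+\t.\t{attrs}"
        )
        if with_cds:
            lines.append(f"chr1\ttest\tCDS\t{start}\t{end}\t.\t+\t0\t{attrs}")
    path.write_text("\n".join(lines) + "\n")
    return path


def write_toy_bed12(path, name="TOY"):
    # same toy structure in BED12: chromStart 100, blocks at offsets 0/200/400
    path.write_text(
        "chr1\t100\t600\t" + name + "\t0\t+\t100\t600\t0\t3\t100,100,100\t0,200,400\n"
    )
    return path
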