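import pytest

import missplice as mp
from missplice.simfix import default_config, generate_fixture


@pytest.fixture(scope="session")
def fixture100(tmp_path_factory):
    """Standard 100-sample, 3-gene fixture used across the suite."""
    out = tmp_path_factory.mktemp("fx100")
    return generate_fixture(default_config(n_samples=100, n_genes=3), out, seed=11)


@pytest.fixture(scope="session")
def transcripts100(fixture100):
    return mp.load_transcripts(fixture100.paths["annotation"])


@pytest.fixture(scope="session")
def vault100(fixture100, transcripts100):
    tables = [mp.read_junction_table(fixture100.paths["junctions"], "snaptron_tsv")]
    return mp.build_vault(tables, transcripts100)


@pytest.fixture()
def toy_gtf(tmp_path):
    """Two-exon plus-strand transcript: exon1 101-200, exon2 301-400."""
    path = tmp_path / "toy.gtf"
    attrs = 'gene_id "G1"; transcript_id "T1";'
    path.write_text(
        f"chr1\ttest\texon\t101\t200\t.\t+\t.\t{attrs}\n"
        f"chr1\ttest\texon\t301\t400\t.\t+\t.\t{attrs}\n"
    )
    return path


def make_transcript(n_exons=5, strand="+", exon_len=90, intron_len=200,
                    chrom="chr1", tx_id="TXT", origin=1001):
    """Regularly spaced synthetic transcript for geometry tests."""
    exons = []
    pos = origin
    for _ in range(n_exons):
        exons.append((pos, pos + exon_len - 1))
        pos += exon_len + intron_len
    return mp.TranscriptModel(
        transcript_id=tx_id, gene_id="G", chrom=chrom, strand=strand, exons=exons
    )
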