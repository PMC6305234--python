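import textwrap

import pytest

from demotif.core_model import Dataset, ProteinRecord


@pytest.fixture
def toy_files(tmp_path):
    """Minimal on-disk dataset: 3 proteins, one without any DE."""
    table = tmp_path / "table.tsv"
    table.write_text(textwrap.dedent("""\
        id\tlabel\tgroup
        P1\tsecretory\tg2
        P2\tnon_secretory\tg2
        P3\tsecretory\tg1
        """))
    fasta = tmp_path / "seqs.fasta"
    fasta.write_text(textwrap.dedent("""\
        >P1
        MADEK
        >P2
        MAKER
        >P3
        AAADEAAADEK
        """))
    ss = tmp_path / "ss.fasta"
    ss.write_text(textwrap.dedent("""\
        >P1
        CCHHC
        >P3
        HHHHHCCCCCC
        """))
    return table, fasta, ss


@pytest.fixture
def toy_dataset():
    """In-memory labelled dataset with multi-DE proteins and structure."""
    records = [
        ProteinRecord("A1", "AAADEAAA", "HHHHHHHH", "secretory", "g1"),
        ProteinRecord("A2", "KKKDEDDD", "CCCCCCCC", "non_secretory", "g1"),
        ProteinRecord("A3", "GGGDEGGGDEGGG", "HHHHHCCCCCCCC",
                      "secretory", "g2"),
        ProteinRecord("A4", "IIIDEIIIWTALDE", "CCCCCHHHHHHHHH",
                      "non_secretory", "g2"),
    ]
    return Dataset(records=records)


@pytest.fixture
def msa_files(tmp_path):
    afa = tmp_path / "toy.afa"
    afa.write_text(textwrap.dedent("""\
        >s1
        ACDEFGHK
        >s2
        ACDEFGHK
        >s3
        ACDWFGH-
        """))
    return afa
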