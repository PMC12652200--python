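import pytest

from pathprio import AnnotationSet, ProteinAnnotation


EMAPPER_FIXTURE = """\
## synthetic annotation fixture
#query\tseed_ortholog\tevalue\tGOs\tKEGG_ko\tKEGG_Pathway
p1\to1\t1e-10\tGO:0006915,GO:0003824\tko:K00001\tko04010,map04010
p2\to2\t1e-12\tGO:0016192\tko:K00002\tko04010
p3\to3\t1e-09\t-\t-\tko04010
p4\to4\t1e-20\t-\t-\t-
p5\to5\t1e-30\tGO:0005737\t-\tko04144
"""


@pytest.fixture
def emapper_path(tmp_path):
    path = tmp_path / "fixture.emapper.annotations"
    path.write_text(EMAPPER_FIXTURE)
    return path


@pytest.fixture
def six_protein_set():
    """Six proteins over two pathways (4 vs 2 members)."""
    proteins = [
        ProteinAnnotation(f"q{i}", pathway_ids=frozenset({"ko04010"}))
        for i in range(4)
    ] + [
        ProteinAnnotation(f"r{i}", pathway_ids=frozenset({"ko04144"}))
        for i in range(2)
    ]
    return AnnotationSet(proteins=proteins)
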