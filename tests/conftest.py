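import pytest

from piare.corpus_io import Corpus, LabeledDocument
from piare.synthetic import ActConfig, generate_act_corpus


def make_doc(doc_id: str, text: str, label: str) -> LabeledDocument:
    return LabeledDocument(doc_id=doc_id, title="", abstract=text, label=label)


@pytest.fixture
def toy_corpus() -> Corpus:
    """2 positive / 2 negative documents with a hand-countable vocabulary."""
    return Corpus(
        [
            make_doc("p1", "alpha beta gamma", "positive"),
            make_doc("p2", "alpha delta", "positive"),
            make_doc("n1", "alpha epsilon", "negative"),
            make_doc("n2", "zeta eta", "negative"),
        ]
    )


@pytest.fixture(scope="session")
def act_500():
    """One medium synthetic classification corpus shared across tests."""
    return generate_act_corpus(ActConfig(n_pos=500, n_neg=500, seed=42))


OBO_FIXTURE = """format-version: 1.2
ontology: mi

[Term]
id: MI:0001
name: interaction detection method

[Term]
id: MI:0018
name: two hybrid
synonym: "yeast two-hybrid" EXACT []
synonym: "classical two hybrid" EXACT []
is_a: MI:0001 ! interaction detection method

[Term]
id: MI:0019
name: coimmunoprecipitation
synonym: "immunoprecipitation" EXACT []
is_a: MI:0001 ! interaction detection method

[Term]
id: MI:0006
name: anti bait coimmunoprecipitation
is_a: MI:0019 ! coimmunoprecipitation

[Term]
id: MI:0007
name: anti tag coimmunoprecipitation
is_a: MI:0019 ! coimmunoprecipitation

[Term]
id: MI:0416
name: fluorescence microscopy
is_a: MI:0001 ! interaction detection method

[Term]
id: MI:0096
name: pull down
synonym: "pull-down" EXACT []
is_a: MI:0001 ! interaction detection method

[Term]
id: MI:0407
name: direct interaction
is_a: MI:0914 ! association

[Term]
id: MI:0914
name: association

[Term]
id: MI:0021
name: colocalization by fluorescent probes cloning
is_obsolete: true
is_a: MI:0001 ! interaction detection method
"""


@pytest.fixture
def obo_path(tmp_path):
    path = tmp_path / "psi-mi-fixture.obo"
    path.write_text(OBO_FIXTURE, encoding="utf-8")
    return path
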