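import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=40,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

from rarephen.encoder import EncodingStrategy  # noqa: E402
from rarephen.links import CandidateLink  # noqa: E402
from rarephen.ontology import build_umls_to_ordo_map  # noqa: E402
from rarephen.synthetic import StubEncoderBackend, make_end_to_end_fixture  # noqa: E402


def make_link(
    mention="tracheobronchomalacia",
    umls_id="C0040211",
    doc_id="doc0",
    left="history of ",
    right=" noted today",
    section="Past Medical History",
    flag=False,
):
    """A valid candidate link embedded in a small context window."""
    context = left + mention + right
    return CandidateLink(
        doc_id=doc_id,
        m_start=len(left),
        m_end=len(left) + len(mention),
        mention_text=mention,
        umls_id=umls_id,
        context=context,
        context_offset=0,
        section=section,
        hypo_neg_flag=flag,
    )


@pytest.fixture(scope="session")
def stub_backend():
    return StubEncoderBackend()


@pytest.fixture(scope="session")
def strategy():
    return EncodingStrategy()


@pytest.fixture(scope="session")
def tiny_fixture():
    corpus, lexicon, tables, configs = make_end_to_end_fixture("tiny", seed=42)
    return corpus, lexicon, tables, configs


@pytest.fixture(scope="session")
def standard_fixture():
    corpus, lexicon, tables, configs = make_end_to_end_fixture("standard", seed=42)
    return corpus, lexicon, tables, configs


@pytest.fixture(scope="session")
def standard_maps(standard_fixture):
    corpus, _, _, _ = standard_fixture
    xrefs, meta, icd9_icd10, icd9_umls = corpus.load_ontology()
    umls_map = build_umls_to_ordo_map(xrefs, meta)
    return umls_map, xrefs, meta, icd9_icd10, icd9_umls


@pytest.fixture(scope="session")
def ws_pipeline_run(standard_fixture, standard_maps, stub_backend, strategy):
    """The weak-supervision pipeline executed once on the standard corpus.

    Returns the rare-restricted candidate list, the closed-world gold labels
    over it, the trained model and the confirmed key set.
    """
    from rarephen.links import restrict_to_rare
    from rarephen.encoder import encode_links
    from rarephen.model import confirm_links, fit_confirmation_model, subsample_training
    from rarephen.weak import weak_label_dataset

    corpus, _, _, configs = standard_fixture
    umls_map = standard_maps[0]
    links = restrict_to_rare(corpus.candidate_links(), umls_map.rare_umls_set)
    keys = {link.key for link in links}
    gold = {link.key: bool(label) for link, label in corpus.gold_links if link.key in keys}

    dataset = weak_label_dataset(links, configs["rules"])
    train_links, train_labels = subsample_training(dataset, n=configs["train_n"], seed=42)
    vectors = encode_links(train_links, stub_backend, strategy)
    model = fit_confirmation_model(vectors, train_labels, seed=42, provenance="weak")

    all_vectors = encode_links(links, stub_backend, strategy)
    confirmed = confirm_links(links, all_vectors, model)
    confirmed_keys = {link.key for link, _ in confirmed}
    return {
        "links": links,
        "gold": gold,
        "dataset": dataset,
        "model": model,
        "confirmed_keys": confirmed_keys,
        "vectors": all_vectors,
    }
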