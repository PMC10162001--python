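"""Synthetic corpus generator and stub encoder."""

import numpy as np
import pytest

from rarephen.encoder import EncodingStrategy, encode_links
from rarephen.links import gazetteer_candidates
from rarephen.model import fit_confirmation_model, predict_confirmation
from rarephen.ontology import build_umls_to_ordo_map
from rarephen.synthetic import (
    ConceptSpec,
    CorpusConfig,
    generate_corpus,
    make_end_to_end_fixture,
    stub_encoder,
)


def small_config(seed=1, **overrides):
    concepts = [
        ConceptSpec(
            umls_id="C0000001", ordo_id="Orphanet_1", long_term="bravol syndrome",
            frequency=0.5, disease_cues=["cuea", "cueb"], icd9="700.1", icd10="Q70.1",
        ),
        ConceptSpec(
            umls_id="C0000002", ordo_id="Orphanet_2", long_term="hemodial disease",
            abbreviation="HD", frequency=0.5, positive_prob=0.3,
            disease_cues=["cuec", "cued"], nondisease_cues=["cuee", "cuef"],
            icd9="701.2", icd10="Q71.2",
        ),
    ]
    defaults = dict(n_docs=12, concepts=concepts, seed=seed)
    defaults.update(overrides)
    return CorpusConfig(**defaults)


class TestGenerateCorpus:
    def test_same_seed_byte_identical(self):
        first = generate_corpus(small_config(seed=3))
        second = generate_corpus(small_config(seed=3))
        assert first.documents == second.documents
        assert first.gold_links == second.gold_links
        assert first.icd_codes == second.icd_codes

    def test_different_seed_differs(self):
        assert generate_corpus(small_config(seed=3)).documents != generate_corpus(
            small_config(seed=4)
        ).documents

    def test_zero_docs_empty_corpus(self):
        corpus = generate_corpus(small_config(n_docs=0))
        assert corpus.documents == [] and corpus.gold_links == []

    def test_infeasible_config_errors(self):
        with pytest.raises(ValueError, match="concept"):
            generate_corpus(CorpusConfig(n_docs=3, concepts=[]))
        with pytest.raises(ValueError, match="disjoint"):
            bad = small_config()
            bad.concepts[0].disease_cues = ["cuee"]  # collides with HD non-disease
            generate_corpus(bad)

    def test_span_invariants_hold_for_every_gold_link(self):
        corpus = generate_corpus(small_config(negation_rate=0.3))
        texts = dict(corpus.documents)
        for link, label in corpus.gold_links:
            link.validate()
            assert texts[link.doc_id][link.m_start : link.m_end] == link.mention_text
            if link.hypo_neg_flag:
                assert label == 0

    def test_realised_frequencies_near_targets(self):
        corpus, _, _, _ = make_end_to_end_fixture("standard", seed=42)
        total = len(corpus.gold_links)
        tallies: dict[str, int] = {}
        for link, _ in corpus.gold_links:
            tallies[link.umls_id] = tallies.get(link.umls_id, 0) + 1
        for spec in corpus.concepts:
            realised = tallies.get(spec.umls_id, 0) / total
            assert realised == pytest.approx(spec.frequency, rel=0.2)

    def test_gazetteer_recovers_gold_mentions(self):
        corpus = generate_corpus(small_config(negation_rate=0.2))
        lexicon = corpus.lexicon()
        gold_spans = {
            (link.doc_id, link.m_start, link.m_end) for link, _ in corpus.gold_links
        }
        found = set()
        for doc_id, text in corpus.documents:
            for link in gazetteer_candidates(doc_id, text, lexicon):
                found.add((link.doc_id, link.m_start, link.m_end))
        assert gold_spans <= found

    def test_icd_lists_undercode_true_phenotypes(self):
        corpus = generate_corpus(small_config(n_docs=60, icd_undercoding_rate=0.5))
        truth = corpus.true_admission_phenotypes()
        by_umls = {spec.icd9: spec.ordo_id for spec in corpus.concepts}
        coded_pairs = set()
        for admission, codes in corpus.icd_codes.items():
            for code in codes:
                if code in by_umls:
                    coded_pairs.add((admission, by_umls[code]))
        true_pairs = {(a, o) for a, os in truth.items() for o in os}
        assert coded_pairs < true_pairs  # strict subset: under-coding happened

    def test_admission_sizes_within_range(self):
        corpus = generate_corpus(small_config(n_docs=40))
        sizes: dict[str, int] = {}
        for doc, admission in corpus.admissions.items():
            sizes[admission] = sizes.get(admission, 0) + 1
        # the final admission may be truncated below the configured minimum
        assert all(1 <= size <= 3 for size in sizes.values())


class TestStubEncoder:
    def test_deterministic(self):
        first = stub_encoder("patient with bravol syndrome today")
        second = stub_encoder("patient with bravol syndrome today")
        np.testing.assert_array_equal(first.layers, second.layers)

    def test_token_offsets_exact(self):
        text = "aa  bb\ncc"
        enc = stub_encoder(text)
        for token, start, end in enc.tokens:
            assert text[start:end] == token

    def test_empty_text(self):
        enc = stub_encoder("")
        assert enc.tokens == []
        assert enc.layers.shape == (3, 0, 64)

    def test_context_sensitivity_of_second_last_layer(self):
        left = stub_encoder("cuea cueb HD cuea cueb")
        right = stub_encoder("cuee cuef HD cuee cuef")
        index = [t for t, _, _ in left.tokens].index("HD")
        jndex = [t for t, _, _ in right.tokens].index("HD")
        assert np.allclose(left.layers[0][index], right.layers[0][jndex])  # H0 static
        assert not np.allclose(left.layers[1][index], right.layers[1][jndex])  # H1 contextual

    def test_layers_differ_by_rotation(self):
        enc = stub_encoder("one two three")
        assert not np.allclose(enc.layers[1], enc.layers[2])
        # rotation preserves norms
        np.testing.assert_allclose(
            np.linalg.norm(enc.layers[1], axis=1),
            np.linalg.norm(enc.layers[2], axis=1),
        )


class TestFixtures:
    def test_tiny_scale_bounds(self, tiny_fixture):
        corpus, lexicon, tables, configs = tiny_fixture
        assert len(corpus.documents) <= 20
        assert set(tables) == {"crossref", "ordo_meta", "icd9_to_icd10", "icd9_to_umls"}
        assert lexicon.entries

    def test_standard_has_prevalence_violator_and_traps(self, standard_fixture, standard_maps):
        corpus, _, tables, configs = standard_fixture
        umls_map = standard_maps[0]
        tallies: dict[str, int] = {}
        for link, _ in corpus.gold_links:
            tallies[link.umls_id] = tallies.get(link.umls_id, 0) + 1
        total = len(corpus.gold_links)
        shares = {u: c / total for u, c in tallies.items()}
        assert any(share >= 0.005 for share in shares.values())
        assert any(share < 0.005 for share in shares.values())
        # group-of-disorders trap excluded from the rare map
        group = [s for s in corpus.concepts if s.is_group_of_disorders]
        assert group and all(s.umls_id not in umls_map for s in group)
        # NTBT trap row present in the crossref table but not in the map
        assert "NTBT" in tables["crossref"]
        assert "C0888001" not in umls_map

    def test_fixture_ontology_round_trips_through_loaders(self, tiny_fixture):
        corpus, _, _, _ = tiny_fixture
        xrefs, meta, icd9_icd10, icd9_umls = corpus.load_ontology()
        assert xrefs and meta and icd9_icd10 and icd9_umls
        mapping = build_umls_to_ordo_map(xrefs, meta)
        assert len(mapping) > 0

    def test_learnability_of_senses_from_stub_vectors(self, stub_backend):
        """With fully reliable cues a logistic model separates the senses of
        one ambiguous abbreviation at >= 95% held-out accuracy (balanced
        senses, so accuracy measures the cue signal rather than the prior)."""
        config = small_config(n_docs=150, seed=11, cue_strength=1.0)
        config.concepts[1].positive_prob = 0.5
        corpus = generate_corpus(config)
        pairs = [(l, y) for l, y in corpus.gold_links if l.umls_id == "C0000002"]
        links = [l for l, _ in pairs]
        labels = [y for _, y in pairs]
        vectors = encode_links(links, stub_backend, EncodingStrategy())
        rng = np.random.default_rng(0)
        order = rng.permutation(len(links))
        half = len(links) // 2
        train, test = order[:half], order[half:]
        model = fit_confirmation_model(
            [vectors[i] for i in train], [labels[i] for i in train], seed=0
        )
        correct = sum(
            predict_confirmation(model, vectors[i])[1] == labels[i] for i in test
        )
        assert correct / len(test) >= 0.95
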