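"""Weak labelling rules, XNOR/AND aggregation, grid search."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from conftest import make_link
from rarephen.weak import (
    WeakRuleParams,
    concept_frequencies,
    rule_mention_length,
    rule_prevalence,
    rules_or_predict,
    tune_rule_params,
    weak_label_dataset,
)


def links_with_ids(ids):
    return [
        make_link(mention="x" * (3 + len(i)), umls_id=i, doc_id=f"d{n}")
        for n, i in enumerate(ids)
    ]


class TestRules:
    def test_mention_length_strict_threshold(self):
        assert not rule_mention_length(make_link(mention="HD"), 3)
        assert not rule_mention_length(make_link(mention="abc"), 3)
        assert rule_mention_length(make_link(mention="tracheobronchomalacia"), 3)

    def test_prevalence_strict_threshold(self):
        assert not rule_prevalence("c", {"c": 5}, 1000, 0.005)
        assert rule_prevalence("c", {"c": 1}, 1000, 0.005)
        # 636/127,150 = 0.005002 fails the strict < 0.005 test
        assert not rule_prevalence("c", {"c": 636}, 127150, 0.005)

    def test_prevalence_undefined_for_empty_corpus(self):
        with pytest.raises(ValueError):
            rule_prevalence("c", {}, 0, 0.005)

    def test_param_validation(self):
        with pytest.raises(ValueError):
            WeakRuleParams(l=-1)
        with pytest.raises(ValueError):
            WeakRuleParams(p=0.0)

    def test_concept_frequencies_tally(self):
        assert concept_frequencies([]) == {}
        links = links_with_ids(["C1", "C1", "C1"])
        assert concept_frequencies(links) == {"C1": 3}
        rng = np.random.default_rng(0)
        ids = [f"C{i}" for i in rng.integers(0, 5, size=50)]
        freqs = concept_frequencies(links_with_ids(ids))
        assert sum(freqs.values()) == 50
        for concept, count in freqs.items():
            assert count == ids.count(concept)


def brute_force_partition(links, params):
    """Independent per-link evaluation of lambda1, lambda2, XNOR, AND."""
    from collections import Counter

    freqs = Counter(l.umls_id for l in links)
    total = len(links)
    positive, negative, unlabelled = [], [], []
    for link in links:
        lam1 = (link.m_end - link.m_start) > params.l
        lam2 = freqs[link.umls_id] / total < params.p
        if lam1 == lam2:
            (positive if (lam1 and lam2) else negative).append(link)
        else:
            unlabelled.append(link)
    return positive, negative, unlabelled


class TestWeakLabelDataset:
    def test_empty_input(self):
        dataset = weak_label_dataset([])
        assert dataset.total == 0
        assert not dataset.positive and not dataset.negative and not dataset.unlabelled

    def test_four_quadrants(self):
        # 6 links, 2 concepts: Crare appears once (low prevalence),
        # Ccommon five times (high prevalence) at p=0.3
        links = [make_link(mention="longmention", umls_id="Crare", doc_id="d0")]
        links += [
            make_link(mention="HD" if i < 3 else "alsolong", umls_id="Ccommon", doc_id=f"d{i+1}")
            for i in range(5)
        ]
        dataset = weak_label_dataset(links, WeakRuleParams(l=3, p=0.3))
        expected_pos, expected_neg, expected_unl = brute_force_partition(
            links, WeakRuleParams(l=3, p=0.3)
        )
        assert [l for l, _ in dataset.positive] == expected_pos
        assert [l for l, _ in dataset.negative] == expected_neg
        assert dataset.unlabelled == expected_unl
        assert dataset.positive and dataset.negative and dataset.unlabelled

    @given(st.data())
    def test_oracle_equivalence_and_conservation(self, data):
        n = data.draw(st.integers(1, 40))
        rng = np.random.default_rng(data.draw(st.integers(0, 10_000)))
        links = [
            make_link(
                mention="m" * int(rng.integers(1, 9)),
                umls_id=f"C{int(rng.integers(0, 4))}",
                doc_id=f"d{i}",
            )
            for i in range(n)
        ]
        params = WeakRuleParams(l=int(rng.integers(0, 6)), p=float(rng.uniform(0.01, 1.0)))
        dataset = weak_label_dataset(links, params)
        pos, neg, unl = brute_force_partition(links, params)
        assert [l for l, _ in dataset.positive] == pos
        assert [l for l, _ in dataset.negative] == neg
        assert dataset.unlabelled == unl
        assert len(dataset.positive) + len(dataset.negative) + len(dataset.unlabelled) == len(links)

    def test_label_consistency_and_monotonicity(self):
        rng = np.random.default_rng(7)
        links = [
            make_link(
                mention="m" * int(rng.integers(1, 10)),
                umls_id=f"C{int(rng.integers(0, 3))}",
                doc_id=f"d{i}",
            )
            for i in range(60)
        ]
        freqs = concept_frequencies(links)
        for l_lo, l_hi in [(2, 5)]:
            sat_lo = {x.key for x in links if rule_mention_length(x, l_lo)}
            sat_hi = {x.key for x in links if rule_mention_length(x, l_hi)}
            assert sat_hi <= sat_lo  # raising l never grows lambda1
        for p_lo, p_hi in [(0.05, 0.5)]:
            sat_lo = {x.key for x in links if rule_prevalence(x.umls_id, freqs, 60, p_lo)}
            sat_hi = {x.key for x in links if rule_prevalence(x.umls_id, freqs, 60, p_hi)}
            assert sat_lo <= sat_hi  # raising p never shrinks lambda2
        dataset = weak_label_dataset(links, WeakRuleParams(l=3, p=0.4))
        for link, label in dataset.positive:
            assert label == 1 and rule_mention_length(link, 3)
            assert rule_prevalence(link.umls_id, freqs, 60, 0.4)
        for link, label in dataset.negative:
            assert label == 0 and not rule_mention_length(link, 3)
            assert not rule_prevalence(link.umls_id, freqs, 60, 0.4)


class TestTuneRuleParams:
    def make_corpus(self):
        # short rare mentions that are true positives: l=4 cannot beat l=2 on
        # recall unless prevalence covers them
        links = [
            make_link(mention="abcde", umls_id="C1", doc_id="d0"),
            make_link(mention="abc", umls_id="C2", doc_id="d1"),
            make_link(mention="xy", umls_id="C3", doc_id="d2"),
            make_link(mention="wxyz", umls_id="C3", doc_id="d3"),
        ]
        gold = {links[0].key: True, links[1].key: True, links[2].key: False, links[3].key: False}
        return links, gold

    def test_singleton_grid_returned(self):
        links, gold = self.make_corpus()
        best, table = tune_rule_params(links, gold, [3], [0.005], "f1")
        assert (best.l, best.p) == (3, 0.005)
        assert len(table) == 1

    def test_dominating_cell_wins(self):
        # gold positive iff mention length > 4: l=4 dominates l=3
        links = [
            make_link(mention="abcdef", umls_id="C1", doc_id="d0"),
            make_link(mention="abcd", umls_id="C2", doc_id="d1"),
        ]
        gold = {links[0].key: True, links[1].key: False}
        best, table = tune_rule_params(links, gold, [3, 4], [0.0001], "f1")
        assert best.l == 4

    def test_tie_breaks_deterministically_toward_larger_p(self):
        links, gold = self.make_corpus()
        best1, _ = tune_rule_params(links, gold, [3], [0.0001, 0.0002], "f1")
        best2, _ = tune_rule_params(links, gold, [3], [0.0002, 0.0001], "f1")
        assert best1 == best2
        assert best1.p == 0.0002

    def test_empty_grid_errors(self):
        links, gold = self.make_corpus()
        with pytest.raises(ValueError):
            tune_rule_params(links, gold, [], [0.005], "f1")

    def test_or_classifier_is_the_rules_baseline(self):
        links, _ = self.make_corpus()
        predicted = rules_or_predict(links, WeakRuleParams(l=3, p=0.3))
        freqs = concept_frequencies(links)
        expected = {
            l.key
            for l in links
            if (l.m_end - l.m_start) > 3 or freqs[l.umls_id] / len(links) < 0.3
        }
        assert predicted == expected
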