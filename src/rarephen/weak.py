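"""Rule-based weak labelling of candidate links.

Two heuristics label a candidate mention-UMLS link without any annotation:

* mention-length rule (lambda1): the mention has more than ``l`` characters,
  i.e. ``m_end - m_start > l``. Screens out short ambiguous abbreviations,
  the dominant source of false links.
* prevalence rule (lambda2): the linked concept accounts for less than a
  fraction ``p`` of all candidate links, ``Freq(c)/|L| < p``. A concept too
  frequent in a consecutive sample of notes is unlikely to be a rare disease.

Both inequalities are strict. Selection is an XNOR of the two rules: a link
enters the weak training set only when the rules agree, and its label is
their AND (positive when both hold, negative when neither does). Links where
exactly one rule fires stay unlabelled; at evaluation time they form the
"unseen" strata. The rules-only baseline classifier, by contrast, predicts
positive when either rule fires (OR) — both aggregations are exposed under
distinct names.

Frequencies are computed once over the full (rare-restricted) candidate list
of the corpus, not per document.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from itertools import product

import pandas as pd

from .links import CandidateLink, LinkKey
from .metrics import EvalReport, prf

DEFAULT_LENGTH_THRESHOLD = 3
DEFAULT_PREVALENCE_THRESHOLD = 0.005


@dataclass(frozen=True)
class WeakRuleParams:
    """Thresholds of the two labelling rules.

    l: mention character-length threshold (strict ``>``), default 3.
    p: prevalence threshold as a fraction of all candidate links
       (strict ``<``), default 0.005 (0.5%).
    """

    l: int = DEFAULT_LENGTH_THRESHOLD
    p: float = DEFAULT_PREVALENCE_THRESHOLD

    def __post_init__(self) -> None:
        if self.l < 0:
            raise ValueError("length threshold l must be >= 0")
        if not (0 < self.p <= 1):
            raise ValueError("prevalence threshold p must be in (0, 1]")


@dataclass
class WeakDataset:
    """Rule-partitioned candidates: positive / negative / unlabelled."""

    positive: list[tuple[CandidateLink, int]] = field(default_factory=list)
    negative: list[tuple[CandidateLink, int]] = field(default_factory=list)
    unlabelled: list[CandidateLink] = field(default_factory=list)
    params: WeakRuleParams = field(default_factory=WeakRuleParams)
    total: int = 0

    @property
    def labelled(self) -> list[tuple[CandidateLink, int]]:
        return self.positive + self.negative


def rule_mention_length(link: CandidateLink, l: int = DEFAULT_LENGTH_THRESHOLD) -> bool:
    """lambda1: mention longer than ``l`` characters (strict)."""
    return (link.m_end - link.m_start) > l


def concept_frequencies(links: list[CandidateLink]) -> dict[str, int]:
    """Candidate-link count per UMLS concept; counts sum to ``len(links)``."""
    return dict(Counter(link.umls_id for link in links))


def rule_prevalence(
    umls_id: str,
    freqs: dict[str, int],
    total: int,
    p: float = DEFAULT_PREVALENCE_THRESHOLD,
) -> bool:
    """lambda2: concept share of all candidate links strictly below ``p``."""
    if total <= 0:
        raise ValueError("prevalence undefined for an empty candidate list")
    return freqs.get(umls_id, 0) / total < p


def weak_label_dataset(
    links: list[CandidateLink], params: WeakRuleParams | None = None
) -> WeakDataset:
    """Partition links by XNOR selection and AND labelling."""
    params = params or WeakRuleParams()
    dataset = WeakDataset(params=params, total=len(links))
    if not links:
        return dataset
    freqs = concept_frequencies(links)
    total = len(links)
    for link in links:
        lam1 = rule_mention_length(link, params.l)
        lam2 = rule_prevalence(link.umls_id, freqs, total, params.p)
        if lam1 and lam2:
            dataset.positive.append((link, 1))
        elif not lam1 and not lam2:
            dataset.negative.append((link, 0))
        else:
            dataset.unlabelled.append(link)
    return dataset


def rules_or_predict(
    links: list[CandidateLink], params: WeakRuleParams | None = None
) -> set[LinkKey]:
    """Rules-only baseline: predict positive when either rule fires (OR)."""
    params = params or WeakRuleParams()
    if not links:
        return set()
    freqs = concept_frequencies(links)
    total = len(links)
    return {
        link.key
        for link in links
        if rule_mention_length(link, params.l)
        or rule_prevalence(link.umls_id, freqs, total, params.p)
    }


def tune_rule_params(
    links: list[CandidateLink],
    gold: dict[LinkKey, bool],
    grid_l: list[int],
    grid_p: list[float],
    objective: str = "f1",
) -> tuple[WeakRuleParams, pd.DataFrame]:
    """Grid search over (l, p) scoring the rules-only OR classifier on gold.

    Ties break toward higher recall, then larger p, then smaller l, then
    grid order — deterministic and recall-biased.
    """
    if objective not in {"f1", "recall"}:
        raise ValueError(f"unknown objective {objective!r}")
    if not grid_l or not grid_p:
        raise ValueError("empty parameter grid")
    key_set = {link.key for link in links}
    missing = [key for key in gold if key not in key_set]
    if missing:
        raise ValueError(f"{len(missing)} gold keys not found among links, e.g. {missing[0]}")

    rows = []
    best: tuple | None = None
    best_params: WeakRuleParams | None = None
    for index, (l, p) in enumerate(product(grid_l, grid_p)):
        params = WeakRuleParams(l=l, p=p)
        predicted = rules_or_predict(links, params)
        gold_links = [link for link in links if link.key in gold]
        report = prf(gold, predicted & {link.key for link in gold_links})
        rows.append(
            {"l": l, "p": p, "precision": report.precision,
             "recall": report.recall, "f1": report.f1}
        )
        score = report.f1 if objective == "f1" else report.recall
        rank = (score, report.recall, p, -l, -index)
        if best is None or rank > best:
            best, best_params = rank, params
    table = pd.DataFrame(rows)
    assert best_params is not None
    return best_params, table
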