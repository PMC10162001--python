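"""Evaluation: P/R/F1 at mention and admission level, strata, agreement.

Conventions
-----------
* Percent scale throughout; full precision internally, rounding (half-up,
  one decimal) only at the reporting boundary.
* Zero-denominator convention: precision/recall are 0 when their
  denominator is 0; F1 is 0 when P + R = 0.
* Closed-world by default: the gold set labels every candidate pair, so a
  predicted key absent from gold is ignored. The open-world mode counts
  such extra predictions as false positives, for the case where annotators
  found true mentions outside the candidate set (those appear in gold as
  positives with keys the system can never predict, depressing recall).
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from typing import Hashable, Iterable, Mapping, Sequence

import numpy as np
from sklearn.metrics import cohen_kappa_score
from statsmodels.stats.inter_rater import aggregate_raters
from statsmodels.stats.inter_rater import fleiss_kappa as _sm_fleiss_kappa


def round1(value: float) -> float:
    """Half-up rounding to one decimal, as printed in results tables."""
    return float(Decimal(repr(value)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


@dataclass
class EvalReport:
    tp: int
    fp: int
    fn: int
    stratum: str = "all"

    @property
    def precision(self) -> float:
        denominator = self.tp + self.fp
        return 100.0 * self.tp / denominator if denominator else 0.0

    @property
    def recall(self) -> float:
        denominator = self.tp + self.fn
        return 100.0 * self.tp / denominator if denominator else 0.0

    @property
    def f1(self) -> float:
        p, r = self.precision, self.recall
        return 2 * p * r / (p + r) if (p + r) else 0.0

    def rounded(self) -> tuple[float, float, float]:
        return round1(self.precision), round1(self.recall), round1(self.f1)

    def to_dict(self) -> dict:
        p, r, f = self.rounded()
        return {
            "stratum": self.stratum,
            "tp": self.tp,
            "fp": self.fp,
            "fn": self.fn,
            "precision": p,
            "recall": r,
            "f1": f,
        }


def prf(
    gold: Mapping[Hashable, bool],
    predicted: Iterable[Hashable],
    closed_world: bool = True,
    stratum: str = "all",
) -> EvalReport:
    """Precision/recall/F1 of a predicted key set against labelled gold keys."""
    predicted = set(predicted)
    tp = sum(1 for key, label in gold.items() if label and key in predicted)
    fp = sum(1 for key, label in gold.items() if not label and key in predicted)
    if not closed_world:
        fp += sum(1 for key in predicted if key not in gold)
    fn = sum(1 for key, label in gold.items() if label and key not in predicted)
    return EvalReport(tp=tp, fp=fp, fn=fn, stratum=stratum)


def f1_from_pr(p: float, r: float) -> float:
    """Harmonic mean of printed P and R percentages, to one decimal."""
    if p + r == 0:
        return 0.0
    return round1(2 * p * r / (p + r))


def seen_unseen_split(gold_links, params, corpus_links) -> dict[str, list]:
    """Partition gold pairs by rule agreement.

    "Seen" pairs are those the two weak rules agree on (they could have been
    weakly labelled); "unseen-lambda1" satisfy only the mention-length rule,
    "unseen-lambda2" only the prevalence rule. Frequencies come from the full
    corpus candidate list, as during weak labelling.

    ``gold_links`` is a sequence of ``(CandidateLink, label)`` pairs.
    """
    from .weak import concept_frequencies, rule_mention_length, rule_prevalence

    freqs = concept_frequencies(corpus_links)
    total = len(corpus_links)
    strata: dict[str, list] = {"seen": [], "unseen-lambda1": [], "unseen-lambda2": []}
    for link, label in gold_links:
        lam1 = rule_mention_length(link, params.l)
        lam2 = rule_prevalence(link.umls_id, freqs, total, params.p)
        if lam1 == lam2:
            strata["seen"].append((link, label))
        elif lam1:
            strata["unseen-lambda1"].append((link, label))
        else:
            strata["unseen-lambda2"].append((link, label))
    return strata


def micro_admission_metrics(
    gold: Mapping[str, set], predicted: Mapping[str, set], stratum: str = "admission"
) -> EvalReport:
    """Micro label-based multi-label metrics over (admission, concept) instances."""
    gold_pairs = {(admission, concept) for admission, concepts in gold.items() for concept in concepts}
    predicted_pairs = {
        (admission, concept) for admission, concepts in predicted.items() for concept in concepts
    }
    tp = len(gold_pairs & predicted_pairs)
    return EvalReport(
        tp=tp,
        fp=len(predicted_pairs - gold_pairs),
        fn=len(gold_pairs - predicted_pairs),
        stratum=stratum,
    )


def matching_accuracy(
    judgements: Sequence[tuple[Hashable, bool, int]],
) -> tuple[float, float]:
    """Accuracy of concept mappings, unique and mention-weighted.

    ``judgements`` holds one ``(mapping, correct, multiplicity)`` triple per
    distinct mapping; multiplicity is how many mentions used it. Returns
    percentages rounded to one decimal.
    """
    if not judgements:
        raise ValueError("no judgements given")
    total = len(judgements)
    correct = sum(1 for _, ok, _ in judgements if ok)
    weight_total = sum(mult for _, _, mult in judgements)
    weight_correct = sum(mult for _, ok, mult in judgements if ok)
    unique = 100.0 * correct / total
    weighted = 100.0 * weight_correct / weight_total if weight_total else 0.0
    return round1(unique), round1(weighted)


def cohen_kappa(ratings: Sequence[Sequence[Hashable]]) -> float:
    """Cohen's kappa for two raters; ``ratings`` is n x 2."""
    array = np.asarray(ratings)
    if array.ndim != 2 or array.shape[1] != 2:
        raise ValueError("cohen_kappa expects an n x 2 table")
    return float(cohen_kappa_score(array[:, 0], array[:, 1]))


def fleiss_kappa(ratings: Sequence[Sequence[Hashable]]) -> float:
    """Fleiss' kappa for k raters; ``ratings`` is n subjects x k raters."""
    array = np.asarray(ratings)
    if array.ndim != 2 or array.shape[1] < 2:
        raise ValueError("fleiss_kappa expects an n x k table with k >= 2")
    table, _ = aggregate_raters(array)
    return float(_sm_fleiss_kappa(table))
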