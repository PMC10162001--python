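"""End-to-end inference and cohort comparison.

The text route composes the stages: candidate links (restricted to UMLS
concepts with a rare-disease ORDO mapping) are encoded, filtered by the
confirmation model, and each confirmed link's concept is mapped through the
UMLS -> ORDO map; a document's rare-disease set is the union over its
confirmed links. Documents aggregate to admissions, and the text-derived
cohort is compared per concept with the cohort derived from the admission's
ICD-9 codes (via the ICD-9 -> ORDO map).

Links flagged upstream as hypothetical/negated/other-experiencer are dropped
before inference by default; one confirmed mention suffices to assign an
admission-level phenotype.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .encoder import EncodingStrategy, encode_links
from .links import CandidateLink
from .model import ConfirmationModel, confirm_links
from .ontology import Icd9ToOrdoMap, UmlsToOrdoMap, map_umls_to_ordo


@dataclass
class DocOrdoResult:
    """Rare-disease concepts identified in one document, with evidence."""

    doc_id: str
    ordo_ids: set[str] = field(default_factory=set)
    support: list[dict] = field(default_factory=list)


@dataclass
class AdmissionCohorts:
    nlp: dict[str, set[str]] = field(default_factory=dict)
    icd: dict[str, set[str]] = field(default_factory=dict)


@dataclass(frozen=True)
class CohortCounts:
    icd_only: int
    nlp_only: int
    both: int

    @property
    def total(self) -> int:
        return self.icd_only + self.nlp_only + self.both


def run_text_to_ordo(
    links: list[CandidateLink],
    backend,
    strategy: EncodingStrategy | None,
    model: ConfirmationModel,
    umls_to_ordo: UmlsToOrdoMap,
    drop_flagged: bool = True,
) -> list[DocOrdoResult]:
    """Candidates -> confirmation -> ORDO, unioned per document."""
    stage = "restrict"
    try:
        kept = [
            link
            for link in links
            if link.umls_id in umls_to_ordo and not (drop_flagged and link.hypo_neg_flag)
        ]
        stage = "encode"
        vectors = encode_links(kept, backend, strategy)
        stage = "confirm"
        confirmed = confirm_links(kept, vectors, model)
        stage = "map"
        results: dict[str, DocOrdoResult] = {}
        for link, probability in confirmed:
            ordo_ids = map_umls_to_ordo(link.umls_id, umls_to_ordo)
            result = results.setdefault(link.doc_id, DocOrdoResult(doc_id=link.doc_id))
            result.ordo_ids |= ordo_ids
            result.support.append(
                {
                    "link_key": link.key,
                    "umls_id": link.umls_id,
                    "probability": probability,
                    "ordo_ids": sorted(ordo_ids),
                }
            )
        return list(results.values())
    except Exception as exc:
        raise RuntimeError(f"text-to-ordo pipeline failed at stage {stage!r}: {exc}") from exc


def aggregate_admissions(
    doc_results: list[DocOrdoResult], doc_to_admission: dict[str, str]
) -> dict[str, set[str]]:
    """Union document ORDO sets per admission.

    A document absent from the admission table forms a singleton admission
    keyed by its own doc_id.
    """
    cohort: dict[str, set[str]] = {}
    for result in doc_results:
        admission = doc_to_admission.get(result.doc_id) or result.doc_id
        cohort.setdefault(admission, set()).update(result.ordo_ids)
    return cohort


def icd_cohort(
    admission_codes: dict[str, list[str]], icd9_map: Icd9ToOrdoMap
) -> dict[str, set[str]]:
    """Per-admission union of ORDO sets mapped from its ICD-9 codes."""
    cohort: dict[str, set[str]] = {}
    for admission, codes in admission_codes.items():
        ordo_ids: set[str] = set()
        for code in codes:
            ordo_ids |= icd9_map.entries.get(code, set())
        cohort[admission] = ordo_ids
    return cohort


def compare_cohorts(cohorts: AdmissionCohorts) -> dict[str, CohortCounts]:
    """Per-ORDO-concept admission counts: ICD-only, NLP-only, both."""
    concepts: set[str] = set()
    for mapping in (cohorts.icd, cohorts.nlp):
        for ordo_ids in mapping.values():
            concepts |= ordo_ids
    counts = {}
    for concept in concepts:
        icd_admissions = {a for a, ids in cohorts.icd.items() if concept in ids}
        nlp_admissions = {a for a, ids in cohorts.nlp.items() if concept in ids}
        counts[concept] = CohortCounts(
            icd_only=len(icd_admissions - nlp_admissions),
            nlp_only=len(nlp_admissions - icd_admissions),
            both=len(icd_admissions & nlp_admissions),
        )
    return counts
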