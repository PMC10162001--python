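"""Cross-reference tables and concept maps between UMLS, ORDO and ICD.

Orphanet's rare-disease ontology (ORDO) publishes cross-references to UMLS
and ICD-10. Each correspondence is a triple (source concept, target concept,
relation); the relation says whether the match is exact (``E``), maps a
broader ORDO term to a narrower external term (``BTNT``), or the reverse
(``NTBT``). Restricting to E/BTNT keeps targets that are themselves rare
diseases; NTBT targets are broader, usually common, disorders. A second
filter removes ORDO concepts sitting under the "group of disorders" phenome
class, whose UMLS cross-references are typically common-disease umbrella
concepts (e.g. plain hyperlipidemia linked to "rare hyperlipidemia").

Ingestion here is preprocessed TSV, not OWL/RRF: converting the ontology
distributions to these tables is an upstream concern, which keeps the core
testable from small text fixtures.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

logger = logging.getLogger(__name__)

KNOWN_RELATIONS = frozenset({"E", "BTNT", "NTBT"})
#: Relations that guarantee the external target is itself a rare disease.
DEFAULT_ALLOWED_RELATIONS = frozenset({"E", "BTNT"})

CROSSREF_COLUMNS = ["source_id", "target_id", "target_system", "relation"]
ORDO_META_COLUMNS = ["ordo_id", "label", "is_group_of_disorders"]


@dataclass(frozen=True)
class CrossRef:
    """One ontology correspondence triple with its target system."""

    source_id: str
    target_id: str
    target_system: str  # "UMLS" or "ICD10"
    relation: str  # "E", "BTNT", "NTBT" or "other"


@dataclass(frozen=True)
class OrdoMeta:
    ordo_id: str
    label: str
    is_group_of_disorders: bool


@dataclass
class UmlsToOrdoMap:
    """The filtered UMLS -> ORDO correspondence used at inference time.

    ``rare_umls_set`` (the key set) is the set of UMLS concepts accepted as
    candidate rare-disease links; everything outside it is ignored by the
    pipeline.
    """

    entries: dict[str, set[str]] = field(default_factory=dict)

    @property
    def rare_umls_set(self) -> set[str]:
        return set(self.entries)

    def __contains__(self, umls_id: str) -> bool:
        return umls_id in self.entries

    def __len__(self) -> int:
        return len(self.entries)


@dataclass
class Icd9ToOrdoMap:
    """ICD-9 -> ORDO map for the code-based baseline cohort.

    ``provenance[code]`` records which composition path(s) produced the
    entry: via ICD-10 cross-references, via UMLS cross-references, or both.
    """

    entries: dict[str, set[str]] = field(default_factory=dict)
    provenance: dict[str, set[str]] = field(default_factory=dict)


def _norm_relation(token: str) -> str:
    token = token.strip().upper()
    return token if token in KNOWN_RELATIONS else "other"


def _norm_id(value: str, system: str | None = None) -> str:
    value = str(value).strip()
    if system == "UMLS":
        value = value.upper()
    return value


def _read_tsv(path: str | Path, required: list[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for column in required:
        if column not in frame.columns:
            raise ValueError(f"malformed header in {path}: missing column {column!r}")
    return frame


def load_crossref_table(path: str | Path) -> list[CrossRef]:
    """Read a cross-reference TSV (source_id, target_id, target_system, relation)."""
    frame = _read_tsv(path, CROSSREF_COLUMNS)
    records: list[CrossRef] = []
    skipped = 0
    for row in frame.itertuples(index=False):
        source = _norm_id(row.source_id)
        system = str(row.target_system).strip().upper()
        target = _norm_id(row.target_id, system)
        if not source or not target:
            skipped += 1
            continue
        records.append(CrossRef(source, target, system, _norm_relation(row.relation)))
    if skipped:
        logger.info("load_crossref_table(%s): skipped %d rows with empty ids", path, skipped)
    return records


def load_ordo_meta(path: str | Path) -> dict[str, OrdoMeta]:
    """Read the ORDO metadata TSV (ordo_id, label, is_group_of_disorders)."""
    frame = _read_tsv(path, ORDO_META_COLUMNS)
    meta: dict[str, OrdoMeta] = {}
    for row in frame.itertuples(index=False):
        ordo_id = _norm_id(row.ordo_id)
        if not ordo_id:
            continue
        flag = str(row.is_group_of_disorders).strip().lower() in {"true", "1", "yes"}
        if ordo_id in meta:
            raise ValueError(f"duplicate ordo_id in {path}: {ordo_id}")
        meta[ordo_id] = OrdoMeta(ordo_id, str(row.label), flag)
    return meta


def load_pair_table(path: str | Path) -> list[tuple[str, str]]:
    """Read a two-column (source, target) TSV with a header row."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if frame.shape[1] < 2:
        raise ValueError(f"malformed header in {path}: expected two columns")
    pairs = []
    for row in frame.itertuples(index=False):
        source, target = str(row[0]).strip(), str(row[1]).strip()
        if source and target:
            pairs.append((source, target))
    return pairs


def build_umls_to_ordo_map(
    xrefs: list[CrossRef],
    meta: dict[str, OrdoMeta],
    allowed_relations: frozenset[str] | set[str] = DEFAULT_ALLOWED_RELATIONS,
    drop_groups: bool = True,
) -> UmlsToOrdoMap:
    """Build the relation- and phenome-filtered UMLS -> ORDO map.

    Only UMLS-system cross-references whose relation is in
    ``allowed_relations`` contribute; with ``drop_groups`` the
    "group of disorders" concepts are excluded. Cross-references whose ORDO
    id has no metadata row are dropped (fail-safe toward precision) and
    counted in the log.
    """
    entries: dict[str, set[str]] = {}
    no_meta = 0
    for xref in xrefs:
        if xref.target_system != "UMLS" or xref.relation not in allowed_relations:
            continue
        info = meta.get(xref.source_id)
        if info is None:
            no_meta += 1
            continue
        if drop_groups and info.is_group_of_disorders:
            continue
        entries.setdefault(xref.target_id, set()).add(xref.source_id)
    if no_meta:
        logger.info("build_umls_to_ordo_map: dropped %d xrefs lacking ORDO metadata", no_meta)
    return UmlsToOrdoMap(entries)


def map_umls_to_ordo(umls_id: str, mapping: UmlsToOrdoMap) -> set[str]:
    """Mapped ORDO ids for one UMLS concept; empty set when unmapped."""
    return set(mapping.entries.get(umls_id, set()))


def _ordo_targets_by_external(
    xrefs: list[CrossRef],
    meta: dict[str, OrdoMeta],
    system: str,
    allowed_relations: frozenset[str] | set[str],
    drop_groups: bool,
) -> dict[str, set[str]]:
    targets: dict[str, set[str]] = {}
    for xref in xrefs:
        if xref.target_system != system or xref.relation not in allowed_relations:
            continue
        info = meta.get(xref.source_id)
        if info is None or (drop_groups and info.is_group_of_disorders):
            continue
        targets.setdefault(xref.target_id, set()).add(xref.source_id)
    return targets


def build_icd9_to_ordo_map(
    icd9_to_icd10: list[tuple[str, str]],
    icd9_to_umls: list[tuple[str, str]],
    ordo_xrefs: list[CrossRef],
    meta: dict[str, OrdoMeta],
    allowed_relations: frozenset[str] | set[str] = DEFAULT_ALLOWED_RELATIONS,
    drop_groups: bool = True,
) -> Icd9ToOrdoMap:
    """Compose ICD-9 codes to ORDO via ICD-10 and via UMLS, union of both paths."""
    icd10_map = _ordo_targets_by_external(ordo_xrefs, meta, "ICD10", allowed_relations, drop_groups)
    umls_map = build_umls_to_ordo_map(ordo_xrefs, meta, allowed_relations, drop_groups)

    result = Icd9ToOrdoMap()

    def _add(code: str, ordo_ids: set[str], path: str) -> None:
        if not ordo_ids:
            return
        result.entries.setdefault(code, set()).update(ordo_ids)
        result.provenance.setdefault(code, set()).add(path)

    for icd9, icd10 in icd9_to_icd10:
        _add(icd9, icd10_map.get(icd10, set()), "via_icd10")
    for icd9, umls in icd9_to_umls:
        _add(icd9, map_umls_to_ordo(_norm_id(umls, "UMLS"), umls_map), "via_umls")
    return result
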