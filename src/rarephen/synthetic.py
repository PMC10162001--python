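"""Seeded synthetic corpora with the statistical structure the method assumes.

The generator emulates the features of clinical notes that the weak rules
and the confirmation model exploit, without any clinical data:

* sectioned notes (section names carried on every candidate link);
* long, unambiguous rare-disease terms at individually low corpus
  frequency (below any sensible prevalence threshold);
* short ambiguous abbreviations at high corpus frequency whose true sense
  per occurrence — rare disease vs something mundane (a procedure, a drug)
  — is cued by pseudo-words injected into the surrounding token window,
  with sense-disjoint cue vocabularies;
* shared phrasing frames: true-phenotype mentions sit in diagnosis-style
  frames, non-phenotype mentions in procedure/medication-style frames, as
  clinical notes phrase them;
* admission groupings and deliberately under-coded ICD-9 code lists;
* ontology cross-reference tables consistent with the concepts, including
  a "group of disorders" trap and an NTBT-only trap relation.

Everything flows from one seeded generator; two calls with the same config
yield byte-identical corpora. Mention counts are allocated to concepts by
largest remainder on the target frequencies, so realised per-concept
frequencies track the targets up to rounding.

The stub encoder stands behind the encoder-backend contract for tests: a
whitespace tokenizer with exact offsets and three deterministic layers —
H^0 per-token hash-derived unit vectors, H^1 context-mixed (each row blends
its own H^0 row with half the mean of neighbours within five tokens), H^2 a
fixed orthogonal rotation of H^1 so layer selection is observable.
"""

from __future__ import annotations

import hashlib
import io
import re
from dataclasses import dataclass, field

import numpy as np

from .encoder import EncoderOutput
from .links import CandidateLink, Lexicon, extract_context_window

# ---------------------------------------------------------------------------
# Stub encoder


STUB_DIM = 64
_NEIGHBOUR_WINDOW = 5
_token_cache: dict[str, np.ndarray] = {}


def _token_unit_vector(token: str) -> np.ndarray:
    cached = _token_cache.get(token)
    if cached is not None:
        return cached
    digest = hashlib.blake2b(token.encode("utf-8"), digest_size=8).digest()
    rng = np.random.default_rng(int.from_bytes(digest, "big") % (2**31))
    vector = rng.standard_normal(STUB_DIM)
    vector /= np.linalg.norm(vector)
    _token_cache[token] = vector
    return vector


def _fixed_rotation() -> np.ndarray:
    rng = np.random.default_rng(177013)
    q, _ = np.linalg.qr(rng.standard_normal((STUB_DIM, STUB_DIM)))
    return q


_ROTATION = _fixed_rotation()
_WS_RE = re.compile(r"\S+")


def stub_encoder(text: str) -> EncoderOutput:
    """Deterministic three-layer encoder over whitespace tokens."""
    matches = list(_WS_RE.finditer(text))
    tokens = [(m.group(), m.start(), m.end()) for m in matches]
    n = len(tokens)
    h0 = np.zeros((n, STUB_DIM))
    for i, (token, _, _) in enumerate(tokens):
        h0[i] = _token_unit_vector(token)
    h1 = np.zeros_like(h0)
    for i in range(n):
        low, high = max(0, i - _NEIGHBOUR_WINDOW), min(n, i + _NEIGHBOUR_WINDOW + 1)
        neighbours = [j for j in range(low, high) if j != i]
        row = h0[i] + (0.5 * h0[neighbours].mean(axis=0) if neighbours else 0.0)
        h1[i] = row / np.linalg.norm(row)
    h2 = h1 @ _ROTATION
    return EncoderOutput(tokens=tokens, layers=np.stack([h0, h1, h2]))


class StubEncoderBackend:
    """Backend-contract wrapper around :func:`stub_encoder`."""

    mask_token = "[MASK]"
    max_tokens: int | None = None

    def encode(self, text: str) -> EncoderOutput:
        return stub_encoder(text)


# ---------------------------------------------------------------------------
# Corpus configuration


@dataclass
class ConceptSpec:
    """One synthetic concept with its ontology identities and text behaviour.

    ``positive_prob`` is the probability that an occurrence of the surface
    form truly asserts the rare-disease phenotype (1.0 for unambiguous rare
    terms; low for abbreviations that usually mean something else; 0.0 for a
    common disorder falsely cross-referenced to a rare concept).
    """

    umls_id: str
    ordo_id: str
    long_term: str
    frequency: float
    abbreviation: str | None = None
    positive_prob: float = 1.0
    is_group_of_disorders: bool = False
    disease_cues: list[str] = field(default_factory=list)
    nondisease_cues: list[str] = field(default_factory=list)
    icd9: str = ""
    icd10: str = ""
    relation: str = "E"

    @property
    def surface(self) -> str:
        return self.abbreviation if self.abbreviation else self.long_term


DEFAULT_SECTIONS = [
    "Chief Complaint",
    "History of Present Illness",
    "Past Medical History",
    "Hospital Course",
    "Medications",
    "Discharge Diagnosis",
]

_FILLER_VOCAB = (
    "the patient was stable overnight vitals remained within normal limits plan "
    "to continue current care reviewed by team tolerating oral intake well "
    "monitor status daily labs pending follow up arranged with primary provider "
    "family updated at bedside rest encouraged ambulating without assistance"
).split()

_DISEASE_FRAMES = [
    ("patient diagnosed with", "confirmed on further workup"),
    ("known history of", "documented in prior records"),
    ("findings consistent with", "per specialist assessment"),
    ("longstanding", "managed chronically in clinic"),
]
_NONDISEASE_FRAMES = [
    ("patient received", "session completed this morning"),
    ("continued on", "schedule otherwise unchanged"),
    ("tolerated", "without any complication noted"),
    ("routine", "performed again at bedside"),
]
_NEGATION_FRAMES = [
    ("no evidence of", "on current assessment"),
    ("patient denies", "at this time"),
    ("family history notable for", "in a first-degree relative"),
]

_DISTRACTOR_ICD9 = ["401.9", "414.01", "250.00", "530.81", "311"]


@dataclass
class CorpusConfig:
    n_docs: int
    concepts: list[ConceptSpec]
    docs_per_admission: tuple[int, int] = (1, 3)
    mentions_per_doc: tuple[int, int] = (3, 9)
    sections: list[str] = field(default_factory=lambda: list(DEFAULT_SECTIONS))
    cue_strength: float = 1.0
    negation_rate: float = 0.0
    icd_undercoding_rate: float = 0.5
    context_window: int = 5
    seed: int = 42

    def validate(self) -> None:
        if self.n_docs < 0:
            raise ValueError("n_docs must be non-negative")
        if self.n_docs and not self.concepts:
            raise ValueError("infeasible config: no concepts to mention")
        for spec in self.concepts:
            if not (0 < spec.frequency <= 1):
                raise ValueError(f"frequency out of (0, 1] for {spec.umls_id}")
        cue_sets = [frozenset(spec.disease_cues) for spec in self.concepts] + [
            frozenset(spec.nondisease_cues) for spec in self.concepts if spec.nondisease_cues
        ]
        for i, left in enumerate(cue_sets):
            for right in cue_sets[i + 1 :]:
                if left & right:
                    raise ValueError("cue vocabularies must be disjoint across senses")


@dataclass
class SyntheticCorpus:
    documents: list[tuple[str, str]]
    gold_links: list[tuple[CandidateLink, int]]
    admissions: dict[str, str]  # doc_id -> admission_id
    icd_codes: dict[str, list[str]]  # admission_id -> ICD-9 codes
    ontology_tables: dict[str, str]  # table name -> TSV text
    concepts: list[ConceptSpec]
    config: CorpusConfig

    def candidate_links(self) -> list[CandidateLink]:
        return [link for link, _ in self.gold_links]

    def gold_labels(self) -> dict[tuple, bool]:
        return {link.key: bool(label) for link, label in self.gold_links}

    def lexicon(self) -> Lexicon:
        return Lexicon({spec.surface: spec.umls_id for spec in self.concepts})

    def true_admission_phenotypes(self) -> dict[str, set[str]]:
        """Admission -> ORDO ids truly present (from gold-positive links)."""
        by_umls = {spec.umls_id: spec.ordo_id for spec in self.concepts}
        cohort: dict[str, set[str]] = {adm: set() for adm in self.icd_codes}
        for link, label in self.gold_links:
            if label:
                admission = self.admissions.get(link.doc_id, link.doc_id)
                cohort.setdefault(admission, set()).add(by_umls[link.umls_id])
        return cohort

    def load_ontology(self):
        """Parse the TSV tables through the real loaders (round-trip)."""
        import tempfile
        from pathlib import Path

        from . import ontology

        with tempfile.TemporaryDirectory() as tmp:
            base = Path(tmp)
            for name, text in self.ontology_tables.items():
                (base / f"{name}.tsv").write_text(text, encoding="utf-8")
            xrefs = ontology.load_crossref_table(base / "crossref.tsv")
            meta = ontology.load_ordo_meta(base / "ordo_meta.tsv")
            icd9_icd10 = ontology.load_pair_table(base / "icd9_to_icd10.tsv")
            icd9_umls = ontology.load_pair_table(base / "icd9_to_umls.tsv")
        return xrefs, meta, icd9_icd10, icd9_umls


# ---------------------------------------------------------------------------
# Generation


def _largest_remainder(weights: np.ndarray, total: int) -> np.ndarray:
    """Integer allocation of ``total`` proportional to ``weights``."""
    ideal = weights / weights.sum() * total
    counts = np.floor(ideal).astype(int)
    remainder = total - counts.sum()
    order = np.argsort(-(ideal - counts), kind="stable")
    counts[order[:remainder]] += 1
    return counts


class _DocBuilder:
    def __init__(self) -> None:
        self.parts: list[str] = []
        self.length = 0

    def emit(self, text: str) -> int:
        start = self.length
        self.parts.append(text)
        self.length += len(text)
        return start

    def text(self) -> str:
        return "".join(self.parts)


def _filler_sentence(rng: np.random.Generator) -> str:
    count = int(rng.integers(4, 9))
    indices = rng.integers(0, len(_FILLER_VOCAB), size=count)
    return " ".join(_FILLER_VOCAB[int(i)] for i in indices) + " ."


def _build_ontology_tables(concepts: list[ConceptSpec]) -> dict[str, str]:
    crossref = io.StringIO()
    crossref.write("source_id\ttarget_id\ttarget_system\trelation\n")
    meta = io.StringIO()
    meta.write("ordo_id\tlabel\tis_group_of_disorders\n")
    icd9_icd10 = io.StringIO()
    icd9_icd10.write("icd9\ticd10\n")
    icd9_umls = io.StringIO()
    icd9_umls.write("icd9\tumls_id\n")
    for spec in concepts:
        crossref.write(f"{spec.ordo_id}\t{spec.umls_id}\tUMLS\t{spec.relation}\n")
        if spec.icd10:
            crossref.write(f"{spec.ordo_id}\t{spec.icd10}\tICD10\tE\n")
        meta.write(
            f"{spec.ordo_id}\t{spec.long_term}\t{'true' if spec.is_group_of_disorders else 'false'}\n"
        )
        if spec.icd9 and spec.icd10:
            icd9_icd10.write(f"{spec.icd9}\t{spec.icd10}\n")
        if spec.icd9:
            icd9_umls.write(f"{spec.icd9}\t{spec.umls_id}\n")
    # NTBT-only trap: a broader external concept that must never enter the map
    crossref.write("Orphanet_888001\tC0888001\tUMLS\tNTBT\n")
    meta.write("Orphanet_888001\tbroad trap disorder\tfalse\n")
    return {
        "crossref": crossref.getvalue(),
        "ordo_meta": meta.getvalue(),
        "icd9_to_icd10": icd9_icd10.getvalue(),
        "icd9_to_umls": icd9_umls.getvalue(),
    }


def generate_corpus(config: CorpusConfig) -> SyntheticCorpus:
    """Generate a seeded corpus; fully deterministic per config."""
    config.validate()
    rng = np.random.default_rng(config.seed)

    if config.n_docs == 0:
        return SyntheticCorpus(
            documents=[], gold_links=[], admissions={}, icd_codes={},
            ontology_tables=_build_ontology_tables(config.concepts),
            concepts=config.concepts, config=config,
        )

    # admission grouping
    admissions: dict[str, str] = {}
    doc_ids = [f"doc{i:05d}" for i in range(config.n_docs)]
    adm_index = 0
    cursor = 0
    low, high = config.docs_per_admission
    while cursor < config.n_docs:
        size = int(rng.integers(low, high + 1))
        admission = f"adm{adm_index:05d}"
        for doc_id in doc_ids[cursor : cursor + size]:
            admissions[doc_id] = admission
        adm_index += 1
        cursor += size

    # mention slots and concept allocation (largest remainder on targets)
    per_doc = rng.integers(
        config.mentions_per_doc[0], config.mentions_per_doc[1] + 1, size=config.n_docs
    )
    total_mentions = int(per_doc.sum())
    weights = np.array([spec.frequency for spec in config.concepts], dtype=float)
    counts = _largest_remainder(weights, total_mentions)
    assignment = np.repeat(np.arange(len(config.concepts)), counts)
    rng.shuffle(assignment)

    documents: list[tuple[str, str]] = []
    gold_links: list[tuple[CandidateLink, int]] = []
    slot = 0
    for doc_index, doc_id in enumerate(doc_ids):
        n_mentions = int(per_doc[doc_index])
        n_sections = int(rng.integers(2, len(config.sections) + 1))
        section_ids = sorted(
            rng.choice(len(config.sections), size=n_sections, replace=False).tolist()
        )
        chosen = [config.sections[i] for i in section_ids]
        mention_sections = rng.integers(0, n_sections, size=n_mentions)

        builder = _DocBuilder()
        # (start, end, surface, section, concept index, negated, label)
        mention_records: list[tuple[int, int, str, str, int, bool, int]] = []
        for section_index, section in enumerate(chosen):
            builder.emit(f"{section}:\n")
            n_here = int((mention_sections == section_index).sum())
            sentences = int(rng.integers(1, 4))
            for _ in range(sentences):
                builder.emit(_filler_sentence(rng) + " ")
            for _ in range(n_here):
                concept_index = int(assignment[slot])
                slot += 1
                spec = config.concepts[concept_index]
                is_disease_sense = rng.random() < spec.positive_prob
                negated = bool(is_disease_sense and rng.random() < config.negation_rate)
                label = int(is_disease_sense and not negated)

                if negated:
                    frame = _NEGATION_FRAMES[int(rng.integers(len(_NEGATION_FRAMES)))]
                elif is_disease_sense:
                    frame = _DISEASE_FRAMES[int(rng.integers(len(_DISEASE_FRAMES)))]
                else:
                    frame = _NONDISEASE_FRAMES[int(rng.integers(len(_NONDISEASE_FRAMES)))]
                cues: list[str] = []
                vocabulary = spec.disease_cues if is_disease_sense else spec.nondisease_cues
                if vocabulary and rng.random() < config.cue_strength:
                    picks = rng.choice(len(vocabulary), size=3, replace=True)
                    cues = [vocabulary[int(i)] for i in picks]
                before = frame[0] + (f" {cues[0]}" if cues else "")
                after = (f"{' '.join(cues[1:])} " if cues else "") + frame[1]
                builder.emit(before + " ")
                start = builder.emit(spec.surface)
                end = start + len(spec.surface)
                builder.emit(" " + after + " . ")
                mention_records.append(
                    (start, end, spec.surface, section, concept_index, negated, label)
                )
            builder.emit(_filler_sentence(rng) + "\n")
        doc_text = builder.text()
        documents.append((doc_id, doc_text))
        for start, end, surface, section, concept_index, negated, label in mention_records:
            spec = config.concepts[concept_index]
            assert doc_text[start:end] == surface
            context, offset = extract_context_window(
                doc_text, start, end, config.context_window
            )
            link = CandidateLink(
                doc_id=doc_id,
                admission_id=admissions[doc_id],
                m_start=start,
                m_end=end,
                mention_text=surface,
                umls_id=spec.umls_id,
                context=context,
                context_offset=offset,
                section=section,
                hypo_neg_flag=negated,
            )
            gold_links.append((link, label))

    # ICD lists: per admission, true phenotype codes minus under-coding, plus noise
    icd_codes: dict[str, list[str]] = {}
    by_umls = {spec.umls_id: spec for spec in config.concepts}
    admission_ids = sorted(set(admissions.values()))
    positive_concepts: dict[str, set[str]] = {adm: set() for adm in admission_ids}
    for link, label in gold_links:
        if label:
            positive_concepts[admissions[link.doc_id]].add(link.umls_id)
    for admission in admission_ids:
        codes: list[str] = []
        for umls_id in sorted(positive_concepts[admission]):
            spec = by_umls[umls_id]
            if spec.icd9 and rng.random() >= config.icd_undercoding_rate:
                codes.append(spec.icd9)
        n_noise = int(rng.integers(1, 4))
        codes.extend(
            str(rng.choice(_DISTRACTOR_ICD9)) for _ in range(n_noise)
        )
        icd_codes[admission] = codes

    return SyntheticCorpus(
        documents=documents,
        gold_links=gold_links,
        admissions=admissions,
        icd_codes=icd_codes,
        ontology_tables=_build_ontology_tables(config.concepts),
        concepts=config.concepts,
        config=config,
    )


# ---------------------------------------------------------------------------
# End-to-end fixtures

_SYLLABLES = [
    "bra", "cor", "den", "fel", "gor", "hul", "jin", "kel", "lom", "mer",
    "nol", "pra", "quen", "ros", "sil", "tor", "vul", "wex", "yor", "zim",
]


def _pseudo_word(rng: np.random.Generator, used: set[str], n_syllables: int = 3) -> str:
    while True:
        word = "".join(
            _SYLLABLES[int(i)] for i in rng.integers(0, len(_SYLLABLES), size=n_syllables)
        )
        if word not in used:
            used.add(word)
            return word


def _make_rare_concepts(
    rng: np.random.Generator, used: set[str], count: int, total_frequency: float, start_id: int
) -> list[ConceptSpec]:
    specs = []
    for i in range(count):
        stem = _pseudo_word(rng, used)
        term = stem + (" syndrome" if i % 3 == 0 else " disease" if i % 3 == 1 else "")
        specs.append(
            ConceptSpec(
                umls_id=f"C{3000000 + start_id + i}",
                ordo_id=f"Orphanet_{400000 + start_id + i}",
                long_term=term,
                frequency=total_frequency / count,
                disease_cues=[_pseudo_word(rng, used, 3) for _ in range(4)],
                icd9=f"{700 + (start_id + i) // 10}.{(start_id + i) % 10}",
                icd10=f"Q{(start_id + i) // 10:02d}.{(start_id + i) % 10}",
                relation="BTNT" if i % 7 == 6 else "E",
            )
        )
    return specs


def make_end_to_end_fixture(scale: str = "tiny", seed: int = 42):
    """Build (corpus, lexicon, ontology tables, default configs) at a scale.

    ``tiny`` is a 20-document corpus for unit tests; ``standard`` is a
    1,000-document corpus with the full frequency structure (150 rare
    concepts each below the 0.5% prevalence threshold, two high-frequency
    ambiguous abbreviations, a common false-link concept, a group-of-
    disorders trap and an NTBT trap).
    """
    from .encoder import EncodingStrategy
    from .weak import WeakRuleParams

    rng = np.random.default_rng(seed + 104729)
    used: set[str] = set(_FILLER_VOCAB)

    def _ambiguous(abbr, freq, pos, idx):
        return ConceptSpec(
            umls_id=f"C{3100000 + idx}",
            ordo_id=f"Orphanet_{410000 + idx}",
            long_term=_pseudo_word(rng, used) + " disease",
            abbreviation=abbr,
            frequency=freq,
            positive_prob=pos,
            disease_cues=[_pseudo_word(rng, used, 3) for _ in range(4)],
            nondisease_cues=[_pseudo_word(rng, used, 3) for _ in range(4)],
            icd9=f"33{idx}.0",
            icd10=f"G{idx + 10}.0",
        )

    def _group_trap(freq, idx):
        return ConceptSpec(
            umls_id=f"C{3200000 + idx}",
            ordo_id=f"Orphanet_{420000 + idx}",
            long_term=_pseudo_word(rng, used) + "emia",
            frequency=freq,
            positive_prob=1.0,
            is_group_of_disorders=True,
            disease_cues=[_pseudo_word(rng, used, 3) for _ in range(4)],
            icd9=f"27{idx}.4",
            icd10=f"E7{idx}.5",
        )

    def _common_false(freq, idx):
        return ConceptSpec(
            umls_id=f"C{3300000 + idx}",
            ordo_id=f"Orphanet_{430000 + idx}",
            long_term=_pseudo_word(rng, used) + "osis",
            frequency=freq,
            positive_prob=0.0,
            disease_cues=[_pseudo_word(rng, used, 3) for _ in range(4)],
            nondisease_cues=[_pseudo_word(rng, used, 3) for _ in range(4)],
            icd9=f"40{idx}.1",
            icd10=f"I1{idx}.0",
        )

    if scale == "tiny":
        concepts = (
            _make_rare_concepts(rng, used, 4, 0.48, 0)
            + [
                _ambiguous("HD", 0.30, 0.25, 1),
                _group_trap(0.12, 1),
                _common_false(0.08, 1),
                _ambiguous("WM", 0.02, 0.5, 3),
            ]
        )
        config = CorpusConfig(
            n_docs=20, concepts=concepts, negation_rate=0.2, seed=seed
        )
    elif scale == "standard":
        concepts = (
            _make_rare_concepts(rng, used, 150, 0.487, 0)
            + [
                _ambiguous("HD", 0.24, 0.08, 1),
                _ambiguous("MG", 0.15, 0.08, 2),
                _common_false(0.08, 1),
                _group_trap(0.04, 1),
                _ambiguous("WM", 0.003, 0.5, 3),
            ]
        )
        config = CorpusConfig(
            n_docs=1000, concepts=concepts, negation_rate=0.0, seed=seed
        )
    else:
        raise ValueError(f"unknown scale {scale!r}")

    corpus = generate_corpus(config)
    configs = {
        "rules": WeakRuleParams(),
        "strategy": EncodingStrategy(),
        "train_n": 9000,
        "context_window": config.context_window,
    }
    return corpus, corpus.lexicon(), corpus.ontology_tables, configs


def write_corpus(corpus: SyntheticCorpus, out_dir) -> None:
    """Write documents/, links.jsonl, gold.jsonl, admissions.tsv, icd.tsv, ontology/."""
    import json
    from pathlib import Path

    from .links import write_links

    base = Path(out_dir)
    (base / "documents").mkdir(parents=True, exist_ok=True)
    (base / "ontology").mkdir(exist_ok=True)
    for doc_id, text in corpus.documents:
        (base / "documents" / f"{doc_id}.txt").write_text(text, encoding="utf-8")
    write_links(corpus.candidate_links(), base / "links.jsonl")
    with open(base / "gold.jsonl", "w", encoding="utf-8") as handle:
        for link, label in corpus.gold_links:
            record = link.to_dict()
            record["label"] = int(label)
            handle.write(json.dumps(record) + "\n")
    with open(base / "admissions.tsv", "w", encoding="utf-8") as handle:
        handle.write("doc_id\tadmission_id\n")
        for doc_id, admission in corpus.admissions.items():
            handle.write(f"{doc_id}\t{admission}\n")
    with open(base / "icd.tsv", "w", encoding="utf-8") as handle:
        handle.write("admission_id\ticd9_code\n")
        for admission, codes in corpus.icd_codes.items():
            for code in codes:
                handle.write(f"{admission}\t{code}\n")
    for name, text in corpus.ontology_tables.items():
        (base / "ontology" / f"{name}.tsv").write_text(text, encoding="utf-8")
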