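"""Candidate mention-UMLS links: the record every pipeline stage consumes.

A candidate link is one mention (a character span in a document) tentatively
linked to a UMLS concept by an upstream NER+L tool, carried with its context
window and the name of the note section it sits in. Offsets are 0-based,
end-exclusive, in Unicode code points. The records travel as JSONL.

A small gazetteer tagger is included as a stand-in for the upstream tool:
longest-match-first dictionary matching at word boundaries, deliberately
*not* disambiguating ambiguous surface forms (most-frequent-sense priors in
fast NER+L tools link every "HD" to the same concept regardless of context;
rejecting the false ones is the confirmation model's job, not the tagger's).
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field, asdict
from pathlib import Path

_JSON_FIELDS = (
    "doc_id",
    "admission_id",
    "m_start",
    "m_end",
    "mention_text",
    "umls_id",
    "context",
    "context_offset",
    "section",
    "hypo_neg_flag",
)

LinkKey = tuple[str, int, int, str]


class LinkFormatError(ValueError):
    """Raised on malformed or invariant-violating candidate-link records."""


@dataclass
class CandidateLink:
    doc_id: str
    m_start: int
    m_end: int
    mention_text: str
    umls_id: str
    context: str
    context_offset: int
    section: str = ""
    admission_id: str = ""
    hypo_neg_flag: bool = False

    @property
    def key(self) -> LinkKey:
        return (self.doc_id, self.m_start, self.m_end, self.umls_id)

    @property
    def mention_length(self) -> int:
        return self.m_end - self.m_start

    def validate(self) -> None:
        if not (0 <= self.m_start < self.m_end):
            raise LinkFormatError(
                f"doc {self.doc_id!r}: invalid span [{self.m_start}, {self.m_end})"
            )
        start, end = self.m_start - self.context_offset, self.m_end - self.context_offset
        if start < 0 or end > len(self.context):
            raise LinkFormatError(
                f"doc {self.doc_id!r}: mention span outside its context window"
            )
        if self.context[start:end] != self.mention_text:
            raise LinkFormatError(
                f"doc {self.doc_id!r}: mention_text does not match context substring"
            )

    def to_dict(self) -> dict:
        record = asdict(self)
        return {name: record[name] for name in _JSON_FIELDS}

    @classmethod
    def from_dict(cls, record: dict) -> "CandidateLink":
        return cls(**{name: record[name] for name in _JSON_FIELDS})


@dataclass
class Lexicon:
    """Surface-term gazetteer; each term maps to exactly one UMLS id,
    mimicking a most-frequent-sense prior."""

    entries: dict[str, str] = field(default_factory=dict)
    case_sensitive: bool = False

    def lookup(self, term: str) -> str | None:
        if self.case_sensitive:
            return self.entries.get(term)
        lowered = {t.lower(): u for t, u in self.entries.items()}
        return lowered.get(term.lower())


def read_lexicon(path: str | Path, case_sensitive: bool = False) -> Lexicon:
    """Read a (term, umls_id) TSV with a header row."""
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    entries: dict[str, str] = {}
    for line in lines[1:]:
        if not line.strip():
            continue
        term, umls_id = line.split("\t")[:2]
        entries[term] = umls_id.strip().upper()
    return Lexicon(entries, case_sensitive)


def read_links(path: str | Path) -> list[CandidateLink]:
    """Read candidate links from JSONL, verifying span invariants per record."""
    links: list[CandidateLink] = []
    with open(path, encoding="utf-8") as handle:
        for number, line in enumerate(handle, start=1):
            if not line.strip():
                continue
            try:
                record = json.loads(line)
            except json.JSONDecodeError as exc:
                raise LinkFormatError(f"line {number}: malformed JSON ({exc.msg})") from exc
            try:
                link = CandidateLink.from_dict(record)
            except (KeyError, TypeError) as exc:
                raise LinkFormatError(f"line {number}: missing or bad field ({exc})") from exc
            try:
                link.validate()
            except LinkFormatError as exc:
                raise LinkFormatError(f"line {number}: {exc}") from exc
            links.append(link)
    return links


def write_links(links: list[CandidateLink], path: str | Path) -> int:
    """Write links as JSONL; round-trips with :func:`read_links`."""
    with open(path, "w", encoding="utf-8") as handle:
        for link in links:
            handle.write(json.dumps(link.to_dict(), ensure_ascii=False) + "\n")
    return len(links)


_TOKEN_RE = re.compile(r"\S+")


def extract_context_window(
    doc_text: str, m_start: int, m_end: int, w: int = 5
) -> tuple[str, int]:
    """Context of ``w`` whitespace tokens either side of the mention.

    Fewer tokens are taken at document edges; ``w=0`` returns the mention
    itself. Returns ``(context, context_offset)``.
    """
    if not (0 <= m_start < m_end <= len(doc_text)):
        raise ValueError(f"span [{m_start}, {m_end}) outside document of length {len(doc_text)}")
    start = m_start
    if w > 0:
        left = [m.start() for m in _TOKEN_RE.finditer(doc_text, 0, m_start)]
        if left:
            start = left[-w] if len(left) >= w else left[0]
    end = m_end
    if w > 0:
        right = [m.end() for m in _TOKEN_RE.finditer(doc_text, m_end)]
        if right:
            end = right[w - 1] if len(right) >= w else right[-1]
    return doc_text[start:end], start


def _is_word_char(char: str) -> bool:
    return char.isalnum()


def gazetteer_candidates(
    doc_id: str,
    doc_text: str,
    lexicon: Lexicon,
    rare_set: set[str] | None = None,
    w: int = 5,
    admission_id: str = "",
    section: str = "",
) -> list[CandidateLink]:
    """Dictionary-match candidate links in one document.

    Longest-match-first, left-to-right, non-overlapping, at word boundaries
    (an alphanumeric/non-alphanumeric transition, so "HD" never fires inside
    "CHD"). Only terms whose UMLS id is in ``rare_set`` are emitted (all
    terms when ``rare_set`` is None). Ambiguity is *not* resolved here.
    """
    if not lexicon.entries:
        return []
    terms = sorted(lexicon.entries, key=len, reverse=True)
    flags = 0 if lexicon.case_sensitive else re.IGNORECASE
    pattern = re.compile("|".join(re.escape(term) for term in terms), flags)
    term_to_id = (
        dict(lexicon.entries)
        if lexicon.case_sensitive
        else {term.lower(): umls for term, umls in lexicon.entries.items()}
    )

    links: list[CandidateLink] = []
    position = 0
    while position < len(doc_text):
        match = pattern.search(doc_text, position)
        if match is None:
            break
        start, end = match.span()
        boundary_ok = (start == 0 or not _is_word_char(doc_text[start - 1])) and (
            end == len(doc_text) or not _is_word_char(doc_text[end])
        )
        if not boundary_ok:
            position = start + 1
            continue
        surface = match.group()
        umls_id = term_to_id[surface if lexicon.case_sensitive else surface.lower()]
        if rare_set is None or umls_id in rare_set:
            context, offset = extract_context_window(doc_text, start, end, w)
            links.append(
                CandidateLink(
                    doc_id=doc_id,
                    m_start=start,
                    m_end=end,
                    mention_text=surface,
                    umls_id=umls_id,
                    context=context,
                    context_offset=offset,
                    section=section,
                    admission_id=admission_id,
                )
            )
        position = end
    return links


def restrict_to_rare(links: list[CandidateLink], rare_set: set[str]) -> list[CandidateLink]:
    """Keep links whose UMLS concept is in the rare set; order preserved."""
    return [link for link in links if link.umls_id in rare_set]
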