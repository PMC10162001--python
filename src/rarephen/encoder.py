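"""Contextual mention vectors: input preparation, alignment, pooling.

A pluggable encoder backend turns text into a stack of hidden layers with
per-token character offsets. The mention's character span is aligned to the
minimal token range overlapping it, and the selected layer's rows over that
range are mean-pooled into one vector. The second-to-last layer is the
default feature layer: the top layer of a pretrained masked-language model
is biased toward its training objective, while the layer below it carries
the more general contextual signal.

Two optional encoding strategies: prepend the note-section name to the
context (document structure carries strong priors — "Past Medical History"
vs "Medications"), and mask the mention surface so the classifier must rely
on context alone. Non-masked encoding with section names is the default.

Backends: any object with ``encode(text) -> EncoderOutput``, a ``mask_token``
string and an optional ``max_tokens`` limit. The deterministic stub in
:mod:`rarephen.synthetic` serves tests; :class:`HuggingFaceBackend` adapts a
pretrained transformer when the ``transformers`` library is available.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

from .links import CandidateLink, LinkKey

#: Delimiter between a section name and the context window.
SECTION_DELIMITER = ": "

DEFAULT_MASK_SYMBOL = "[MASK]"


@dataclass
class EncoderOutput:
    """Tokenised text plus the stack of hidden layers H^0..H^n."""

    tokens: list[tuple[str, int, int]]
    layers: np.ndarray  # shape (n_layers, n_tokens, dim)

    def __post_init__(self) -> None:
        self.layers = np.asarray(self.layers, dtype=float)
        if self.layers.ndim != 3:
            raise ValueError("layers must be a (n_layers, n_tokens, dim) stack")
        if self.layers.shape[0] < 2:
            raise ValueError("encoder must expose at least 2 layers")
        if self.layers.shape[1] != len(self.tokens):
            raise ValueError("layer rows must match token count")

    @property
    def dim(self) -> int:
        return int(self.layers.shape[2])

    @property
    def n_layers(self) -> int:
        return int(self.layers.shape[0])


@dataclass(frozen=True)
class EncodingStrategy:
    """How a candidate link is turned into encoder input and pooled.

    ``layer_index`` indexes the layer stack Python-style; the default -2 is
    the second-to-last layer.
    """

    mask_mention: bool = False
    include_section: bool = True
    layer_index: int = -2
    pooling: str = "mean"


@dataclass
class MentionVector:
    v: np.ndarray
    link_key: LinkKey

    def __post_init__(self) -> None:
        self.v = np.asarray(self.v, dtype=float)
        if not np.all(np.isfinite(self.v)):
            raise ValueError(f"non-finite mention vector for {self.link_key}")


class EncoderError(RuntimeError):
    def __init__(self, link_key: LinkKey, message: str):
        super().__init__(f"encoding failed for link {link_key}: {message}")
        self.link_key = link_key


def prepare_encoder_input(
    link: CandidateLink,
    strategy: EncodingStrategy,
    mask_symbol: str = DEFAULT_MASK_SYMBOL,
) -> tuple[str, tuple[int, int]]:
    """Build encoder input text and the mention's char span within it."""
    start = link.m_start - link.context_offset
    end = link.m_end - link.context_offset
    text = link.context
    if strategy.mask_mention:
        text = text[:start] + mask_symbol + text[end:]
        end = start + len(mask_symbol)
    if strategy.include_section and link.section:
        prefix = link.section + SECTION_DELIMITER
        text = prefix + text
        start += len(prefix)
        end += len(prefix)
    return text, (start, end)


def align_mention_to_tokens(
    span: tuple[int, int], tokens: list[tuple[str, int, int]]
) -> tuple[int, int]:
    """Minimal inclusive token range overlapping the char span.

    Overlap (not containment): a subword tokenizer may merge the mention
    boundary with a neighbour, and containment would yield empty ranges.
    """
    char_start, char_end = span
    indices = [
        i
        for i, (_, token_start, token_end) in enumerate(tokens)
        if token_start < char_end and token_end > char_start
    ]
    if not indices:
        raise ValueError(f"no token overlaps mention span {span}: tokenizer/offset mismatch")
    return indices[0], indices[-1]


def pool_mention_vector(
    enc: EncoderOutput, token_span: tuple[int, int], strategy: EncodingStrategy
) -> np.ndarray:
    """Aggregate the selected layer's rows over the inclusive token span."""
    if strategy.pooling != "mean":
        raise ValueError(f"unsupported pooling rule {strategy.pooling!r}")
    first, last = token_span
    if not (0 <= first <= last < len(enc.tokens)):
        raise ValueError(f"token span {token_span} invalid for {len(enc.tokens)} tokens")
    layer = enc.layers[strategy.layer_index]
    return layer[first : last + 1].mean(axis=0)


_WS_TOKEN_RE = re.compile(r"\S+")


def truncate_around_mention(
    text: str, span: tuple[int, int], max_tokens: int
) -> tuple[str, tuple[int, int]]:
    """Symmetric whitespace-token truncation around the mention span."""
    tokens = list(_WS_TOKEN_RE.finditer(text))
    if len(tokens) <= max_tokens:
        return text, span
    char_start, char_end = span
    mention_idx = [
        i for i, m in enumerate(tokens) if m.start() < char_end and m.end() > char_start
    ]
    low = mention_idx[0] if mention_idx else 0
    high = mention_idx[-1] if mention_idx else 0
    while (high - low + 1) < max_tokens and (low > 0 or high < len(tokens) - 1):
        if low > 0:
            low -= 1
        if (high - low + 1) < max_tokens and high < len(tokens) - 1:
            high += 1
    new_start = tokens[low].start()
    new_end = tokens[high].end()
    clipped = text[new_start:new_end]
    return clipped, (char_start - new_start, char_end - new_start)


def encode_links(
    links: list[CandidateLink],
    backend,
    strategy: EncodingStrategy | None = None,
) -> list[MentionVector]:
    """prepare -> encode -> align -> pool, one vector per link, order kept."""
    strategy = strategy or EncodingStrategy()
    mask_symbol = getattr(backend, "mask_token", None) or DEFAULT_MASK_SYMBOL
    max_tokens = getattr(backend, "max_tokens", None)
    vectors: list[MentionVector] = []
    for link in links:
        try:
            text, span = prepare_encoder_input(link, strategy, mask_symbol)
            if max_tokens is not None:
                text, span = truncate_around_mention(text, span, max_tokens)
            enc = backend.encode(text)
            token_span = align_mention_to_tokens(span, enc.tokens)
            vector = pool_mention_vector(enc, token_span, strategy)
            vectors.append(MentionVector(v=vector, link_key=link.key))
        except Exception as exc:  # annotate with the offending link
            raise EncoderError(link.key, str(exc)) from exc
    return vectors


class HuggingFaceBackend:
    """Adapter over a pretrained transformer encoder (production use).

    Requires the optional ``transformers`` dependency; construction raises
    ImportError with guidance when it is absent.
    """

    def __init__(self, model_name: str, device: str = "cpu"):
        try:
            from transformers import AutoModel, AutoTokenizer  # noqa: PLC0415
        except ImportError as exc:  # pragma: no cover - optional dependency
            raise ImportError(
                "HuggingFaceBackend requires the 'transformers' package; "
                "install it or use the deterministic stub backend"
            ) from exc
        import torch  # pragma: no cover

        self._torch = torch
        self.tokenizer = AutoTokenizer.from_pretrained(model_name)
        self.model = AutoModel.from_pretrained(model_name, output_hidden_states=True)
        self.model.eval().to(device)
        self.device = device
        self.mask_token = self.tokenizer.mask_token or DEFAULT_MASK_SYMBOL
        self.max_tokens = getattr(self.tokenizer, "model_max_length", None)

    def encode(self, text: str) -> EncoderOutput:  # pragma: no cover
        encoding = self.tokenizer(
            text, return_offsets_mapping=True, return_tensors="pt", truncation=True
        )
        offsets = encoding.pop("offset_mapping")[0].tolist()
        with self._torch.no_grad():
            output = self.model(**{k: v.to(self.device) for k, v in encoding.items()})
        layers = np.stack([h[0].cpu().numpy() for h in output.hidden_states])
        tokens = [
            (text[s:e], s, e) for s, e in offsets
        ]
        keep = [i for i, (tok, s, e) in enumerate(tokens) if e > s]
        return EncoderOutput(
            tokens=[tokens[i] for i in keep], layers=layers[:, keep, :]
        )
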