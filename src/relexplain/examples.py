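"""Turn candidate mention pairs into model-ready token windows.

For each unordered pair of protein mentions in a document the text is
transformed — *marking* wraps the two mentions in reserved begin/end tokens,
*masking* replaces each surface with a reserved placeholder — then tokenized,
and if both entities fit inside a window of at most MSL sub-tokens
(including the snippet start/end boundary tokens) an example is emitted
with maximal symmetric context.  No sentence splitting happens anywhere, so
cross-sentence pairs are handled exactly like intra-sentence ones.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Literal, Sequence

from .brat import AnnotatedDocument, EntityMention
from .tokenization import WordPieceTokenizer

Label = Literal["positive", "negative", "unlabeled"]

# reserved-vocabulary roles
MARK_B1, MARK_E1, MARK_B2, MARK_E2 = "[unused1]", "[unused2]", "[unused3]", "[unused4]"
MASK_1, MASK_2 = "[unused5]", "[unused6]"


@dataclass(frozen=True)
class CandidatePair:
    doc_id: str
    e1: str  # mention id occurring first in the document
    e2: str
    label: Label = "unlabeled"

    def key(self) -> tuple[str, frozenset[str]]:
        return (self.doc_id, frozenset((self.e1, self.e2)))


@dataclass
class ModelConfig:
    """Hyper-parameters shared by the example builder and the classifier."""

    encoder: str = "tiny-2l-32d"
    msl: int = 128
    learning_rate: float = 3e-6
    batch_size: int = 5
    epochs: int = 11
    seed: int = 0
    scheme: Literal["mark", "mask"] = "mark"
    weight_decay: float = 0.01
    warmup_frac: float = 0.1

    def __post_init__(self) -> None:
        if self.msl < 16:
            raise ValueError("MSL must be >= 16")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")


#: reference hyper-parameters of the best published configuration
REFERENCE_CONFIG = dict(msl=128, learning_rate=3e-6, epochs=11, batch_size=5)
#: reference hyper-parameters of the published baseline encoder run
BASELINE_CONFIG = dict(msl=128, learning_rate=5e-6, epochs=12, batch_size=5)


class OffsetCorrespondence:
    """Piecewise map from transformed-text offsets back to the original.

    Segments are ``(new_start, new_end, orig_start, orig_end)``; inserted
    marker text maps to an empty original interval, mask placeholders map to
    the replaced mention span.
    """

    def __init__(self, segments: list[tuple[int, int, int, int, str]]):
        self.segments = segments  # (ns, ne, os, oe, kind) kind: text|insert|mask

    def to_original(self, new_start: int, new_end: int) -> tuple[int, int] | None:
        """Original character span covered by [new_start, new_end), or None
        if the range covers only inserted marker text."""
        lo, hi = None, None
        for ns, ne, os_, oe, kind in self.segments:
            if ne <= new_start or ns >= new_end:
                continue
            if kind == "insert":
                continue
            if kind == "mask":
                s, e = os_, oe
            else:  # verbatim text: clip proportionally (1:1 mapping)
                s = os_ + max(0, new_start - ns)
                e = oe - max(0, ne - new_end)
            lo = s if lo is None else min(lo, s)
            hi = e if hi is None else max(hi, e)
        if lo is None or hi is None or lo >= hi:
            return None
        return (lo, hi)


@dataclass
class TransformResult:
    text: str
    correspondence: OffsetCorrespondence
    #: transformed-text char interval enclosing each focus entity
    #: (markers included under the mark scheme)
    e1_region: tuple[int, int]
    e2_region: tuple[int, int]


@dataclass
class EncodedExample:
    doc_id: str
    e1: str
    e2: str
    label: Label
    scheme: str
    token_ids: list[int]
    tokens: list[str]
    #: original-document char span per token; None for boundary/marker tokens
    token_spans: list[tuple[int, int] | None]
    #: pre-token (word) index per token; None for boundary tokens
    word_ids: list[int | None]
    window_span: tuple[int, int]
    e1_span: tuple[int, int]
    e2_span: tuple[int, int]
    #: half-open token-index ranges of the two (marked/masked) entities
    #: inside the final token list, boundary tokens included in indexing
    e1_token_range: tuple[int, int] = (0, 1)
    e2_token_range: tuple[int, int] = (0, 1)
    other_entity_spans: list[tuple[int, int]] = field(default_factory=list)

    @property
    def pair(self) -> CandidatePair:
        return CandidatePair(self.doc_id, self.e1, self.e2, self.label)

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @classmethod
    def from_json(cls, line: str) -> "EncodedExample":
        d = json.loads(line)
        d["token_spans"] = [tuple(s) if s is not None else None for s in d["token_spans"]]
        d["window_span"] = tuple(d["window_span"])
        d["e1_span"] = tuple(d["e1_span"])
        d["e2_span"] = tuple(d["e2_span"])
        d["e1_token_range"] = tuple(d["e1_token_range"])
        d["e2_token_range"] = tuple(d["e2_token_range"])
        d["other_entity_spans"] = [tuple(s) for s in d["other_entity_spans"]]
        return cls(**d)


def enumerate_pairs(doc: AnnotatedDocument, labeled: bool = True) -> list[CandidatePair]:
    """All unordered mention pairs of a (filtered) document.

    A pair is positive iff a Complex_formation relation joins the mentions
    directly or through any Equiv-expansion of either side.  Pairs whose two
    mentions belong to one Equiv group are self-pairs and are skipped.
    With ``labeled=False`` (prediction regime) every pair is ``unlabeled``.
    """
    mentions = sorted(doc.entities.values(), key=lambda e: (e.start, e.end, e.id))
    related = doc.related_pairs()
    pairs: list[CandidatePair] = []
    for i in range(len(mentions)):
        for j in range(i + 1, len(mentions)):
            a, b = mentions[i], mentions[j]
            ca, cb = doc.equiv_class(a.id), doc.equiv_class(b.id)
            if ca is cb or a.id in cb:
                continue  # aliases of the same entity
            if not labeled:
                label: Label = "unlabeled"
            else:
                hit = any(frozenset((x, y)) in related for x in ca for y in cb)
                label = "positive" if hit else "negative"
            pairs.append(CandidatePair(doc.doc_id, a.id, b.id, label))
    return pairs


def transform_text(
    doc: AnnotatedDocument,
    pair: CandidatePair,
    scheme: str,
) -> TransformResult:
    """Apply the mark or mask transform for one candidate pair.

    Markers are inserted at exact offsets even for interleaved mentions;
    masking replaces exactly each focus mention's span.  All non-focus text
    is left untouched.
    """
    if scheme not in ("mark", "mask"):
        raise ValueError(f"unknown scheme {scheme!r}")
    m1, m2 = doc.entities[pair.e1], doc.entities[pair.e2]
    if (m1.start, m1.end) > (m2.start, m2.end):
        m1, m2 = m2, m1
    text = doc.text

    if scheme == "mark":
        # (position, tie_rank, inserted_string, role)
        inserts = [
            (m1.start, (1, -m1.end), f"{MARK_B1} ", "b1"),
            (m1.end, (0, -m1.start), f" {MARK_E1}", "e1"),
            (m2.start, (1, -m2.end), f"{MARK_B2} ", "b2"),
            (m2.end, (0, -m2.start), f" {MARK_E2}", "e2"),
        ]
        inserts.sort(key=lambda t: (t[0], t[1]))
        segments: list[tuple[int, int, int, int, str]] = []
        out: list[str] = []
        cursor = 0  # original coords
        new_pos = 0
        roles: dict[str, tuple[int, int]] = {}
        for pos, _, s, role in inserts:
            if pos > cursor:
                out.append(text[cursor:pos])
                segments.append((new_pos, new_pos + pos - cursor, cursor, pos, "text"))
                new_pos += pos - cursor
                cursor = pos
            out.append(s)
            segments.append((new_pos, new_pos + len(s), pos, pos, "insert"))
            roles[role] = (new_pos, new_pos + len(s))
            new_pos += len(s)
        if cursor < len(text):
            out.append(text[cursor:])
            segments.append((new_pos, new_pos + len(text) - cursor, cursor, len(text), "text"))
        e1_region = (roles["b1"][0], roles["e1"][1])
        e2_region = (roles["b2"][0], roles["e2"][1])
        return TransformResult("".join(out), OffsetCorrespondence(segments), e1_region, e2_region)

    # mask scheme: replace each focus span; clip the second if they overlap
    spans = [(m1.start, m1.end, MASK_1, "m1"), (max(m2.start, m1.end), m2.end, MASK_2, "m2")]
    segments = []
    out = []
    cursor = 0
    new_pos = 0
    regions: dict[str, tuple[int, int]] = {}
    for s, e, placeholder, role in spans:
        s = max(s, cursor)
        e = max(e, s)
        if s > cursor:
            out.append(text[cursor:s])
            segments.append((new_pos, new_pos + s - cursor, cursor, s, "text"))
            new_pos += s - cursor
        out.append(placeholder)
        orig = (m1.start, m1.end) if role == "m1" else (m2.start, m2.end)
        segments.append((new_pos, new_pos + len(placeholder), orig[0], orig[1], "mask"))
        regions[role] = (new_pos, new_pos + len(placeholder))
        new_pos += len(placeholder)
        cursor = e
    if cursor < len(text):
        out.append(text[cursor:])
        segments.append((new_pos, new_pos + len(text) - cursor, cursor, len(text), "text"))
    return TransformResult("".join(out), OffsetCorrespondence(segments), regions["m1"], regions["m2"])


def build_example(
    doc: AnnotatedDocument,
    pair: CandidatePair,
    config: ModelConfig,
    tokenizer: WordPieceTokenizer,
) -> EncodedExample | None:
    """Encode one pair, or return None when it cannot fit any MSL window.

    The window is placed around the minimal token span enclosing both
    (transformed) entities and grown symmetrically until the sub-token
    budget ``MSL - 2`` (snippet start/end tokens reserved) is exhausted or
    the document ends; leftover budget flows to the open side.
    """
    tr = transform_text(doc, pair, config.scheme)
    toks = tokenizer.tokenize(tr.text)
    if not toks:
        return None

    def covering(region: tuple[int, int]) -> tuple[int, int]:
        idx = [i for i, t in enumerate(toks) if t.start < region[1] and t.end > region[0]]
        if not idx:
            raise ValueError(f"no tokens cover focus region {region}")
        return (min(idx), max(idx))

    r1, r2 = covering(tr.e1_region), covering(tr.e2_region)
    lo = min(r1[0], r2[0])
    hi = max(r1[1], r2[1])
    budget = config.msl - 2
    if hi - lo + 1 > budget:
        return None
    left, right = lo, hi
    size = hi - lo + 1
    while size < budget and (left > 0 or right < len(toks) - 1):
        if left > 0:
            left -= 1
            size += 1
        if size < budget and right < len(toks) - 1:
            right += 1
            size += 1

    window = toks[left : right + 1]
    omap = tr.correspondence
    token_ids = [tokenizer.cls_id]
    tokens = ["[CLS]"]
    token_spans: list[tuple[int, int] | None] = [None]
    word_ids: list[int | None] = [None]
    for t in window:
        token_ids.append(t.id)
        tokens.append(t.text)
        token_spans.append(omap.to_original(t.start, t.end))
        word_ids.append(t.word_index)
    token_ids.append(tokenizer.sep_id)
    tokens.append("[SEP]")
    token_spans.append(None)
    word_ids.append(None)

    covered = [s for s in token_spans if s is not None]
    window_span = (min(s for s, _ in covered), max(e for _, e in covered))
    m1, m2 = doc.entities[pair.e1], doc.entities[pair.e2]
    others = [
        e.span
        for e in doc.entities.values()
        if e.id not in (pair.e1, pair.e2)
        and e.start < window_span[1]
        and e.end > window_span[0]
    ]
    return EncodedExample(
        doc_id=doc.doc_id,
        e1=pair.e1,
        e2=pair.e2,
        label=pair.label,
        scheme=config.scheme,
        token_ids=token_ids,
        tokens=tokens,
        token_spans=token_spans,
        word_ids=word_ids,
        window_span=window_span,
        e1_span=m1.span,
        e2_span=m2.span,
        e1_token_range=(r1[0] - left + 1, r1[1] - left + 2),
        e2_token_range=(r2[0] - left + 1, r2[1] - left + 2),
        other_entity_spans=sorted(others),
    )


def build_examples(
    docs: Iterable[AnnotatedDocument],
    config: ModelConfig,
    tokenizer: WordPieceTokenizer,
    labeled: bool = True,
) -> list[EncodedExample]:
    out: list[EncodedExample] = []
    for doc in docs:
        for pair in enumerate_pairs(doc, labeled=labeled):
            ex = build_example(doc, pair, config, tokenizer)
            if ex is not None:
                out.append(ex)
    return out


def write_examples_jsonl(examples: Sequence[EncodedExample], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for ex in examples:
            fh.write(ex.to_json() + "\n")


def read_examples_jsonl(path: str | Path) -> list[EncodedExample]:
    with open(path, encoding="utf-8") as fh:
        return [EncodedExample.from_json(line) for line in fh if line.strip()]
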