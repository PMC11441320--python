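"""Reading, writing and summarising BRAT standoff (.txt/.ann) documents.

The standoff grammar handled here covers entity (``T``), relation (``R``),
attribute (``A``/``M``), equivalence (``*\tEquiv``), note (``#``) and
normalization (``N``) lines.  Character offsets are 0-based half-open
throughout; discontinuous entity spans are kept as their fragment list with
the enclosing ``(min start, max end)`` interval used as the working span.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "EntityMention",
    "RelationAnnotation",
    "EquivGroup",
    "AnnotatedDocument",
    "StandoffParseError",
    "StandoffIntegrityError",
    "StatsReport",
    "read_standoff",
    "write_standoff",
    "read_document_pair",
    "read_corpus_dir",
    "write_corpus_dir",
    "corpus_statistics",
]

ENTITY_TYPES = ("Gene_or_gene_product", "Chemical", "Complex", "Protein_Family")

#: attribute names used by the corpus annotation scheme
KNOWN_ATTRIBUTES = (
    "Blocklisted",
    "Mutant",
    "Fusion",
    "Non-coding",
    "Small_protein_post-translation_modification",
)

RELATION_TYPE = "Complex_formation"


class StandoffParseError(ValueError):
    """A line of an .ann file does not follow the standoff grammar."""


class StandoffIntegrityError(ValueError):
    """Annotations reference missing ids or offsets outside the text."""


@dataclass
class EntityMention:
    id: str
    type: str
    start: int
    end: int
    text: str
    fragments: tuple[tuple[int, int], ...] = ()
    attributes: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if not self.fragments:
            self.fragments = ((self.start, self.end),)

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)

    @property
    def discontinuous(self) -> bool:
        return len(self.fragments) > 1


@dataclass(frozen=True)
class RelationAnnotation:
    id: str
    type: str
    arg1: str
    arg2: str

    def key(self) -> tuple[str, str, str]:
        """Unordered pair key — relations are undirected."""
        a, b = sorted((self.arg1, self.arg2))
        return (self.type, a, b)


@dataclass(frozen=True)
class EquivGroup:
    members: frozenset[str]

    def __post_init__(self) -> None:
        if len(self.members) < 2:
            raise StandoffIntegrityError("Equiv group needs >= 2 members")


@dataclass
class AnnotatedDocument:
    doc_id: str
    text: str
    entities: dict[str, EntityMention] = field(default_factory=dict)
    relations: list[RelationAnnotation] = field(default_factory=list)
    equiv_groups: list[EquivGroup] = field(default_factory=list)
    #: verbatim lines preserved for lossless round-trip (notes, normalizations)
    opaque_lines: list[str] = field(default_factory=list)

    def equiv_class(self, entity_id: str) -> frozenset[str]:
        """All ids equivalent to *entity_id* (including itself)."""
        for g in self.equiv_groups:
            if entity_id in g.members:
                return g.members
        return frozenset((entity_id,))

    def related_pairs(self) -> set[frozenset[str]]:
        """Unordered id pairs directly joined by a relation annotation."""
        return {frozenset((r.arg1, r.arg2)) for r in self.relations}

    def validate(self) -> None:
        n = len(self.text)
        for e in self.entities.values():
            if not (0 <= e.start < e.end <= n):
                raise StandoffIntegrityError(
                    f"{self.doc_id}: entity {e.id} span ({e.start},{e.end}) "
                    f"outside text of length {n}"
                )
        for r in self.relations:
            for arg in (r.arg1, r.arg2):
                if arg not in self.entities:
                    raise StandoffIntegrityError(
                        f"{self.doc_id}: relation {r.id} references unknown {arg}"
                    )
            if r.arg1 == r.arg2:
                raise StandoffIntegrityError(
                    f"{self.doc_id}: relation {r.id} is a self-relation"
                )
        seen: set[str] = set()
        for g in self.equiv_groups:
            for m in g.members:
                if m not in self.entities:
                    raise StandoffIntegrityError(
                        f"{self.doc_id}: Equiv references unknown {m}"
                    )
                if m in seen:
                    raise StandoffIntegrityError(
                        f"{self.doc_id}: entity {m} in two Equiv groups"
                    )
                seen.add(m)


_T_RE = re.compile(r"^(T\w+)\t(\S+) (\d+(?: \d+)?(?:;\d+ \d+)*)\t(.*)$", re.S)
_R_RE = re.compile(r"^(R\w+)\t(\S+) Arg1:(\w+) Arg2:(\w+)\s*$")
_A_RE = re.compile(r"^([AM]\w+)\t(\S+) (\w+)(?: (\S+))?\s*$")
_EQ_RE = re.compile(r"^\*\tEquiv((?: T\w+)+)\s*$")


def _merge_equivs(groups: Iterable[set[str]]) -> list[EquivGroup]:
    """Transitively merge overlapping groups into disjoint ones."""
    merged: list[set[str]] = []
    for g in groups:
        g = set(g)
        overlapping = [m for m in merged if m & g]
        for m in overlapping:
            g |= m
            merged.remove(m)
        merged.append(g)
    return [EquivGroup(frozenset(g)) for g in merged]


def read_standoff(txt_content: str, ann_content: str, doc_id: str = "doc") -> AnnotatedDocument:
    """Parse a .txt/.ann content pair into an :class:`AnnotatedDocument`.

    Raises :class:`StandoffParseError` naming the offending line number for
    malformed lines, :class:`StandoffIntegrityError` for dangling references
    or out-of-range offsets.  Duplicate relations on the same unordered
    entity pair are collapsed with a warning.
    """
    doc = AnnotatedDocument(doc_id=doc_id, text=txt_content)
    raw_equivs: list[set[str]] = []
    seen_rel_keys: set[tuple[str, str, str]] = set()
    attr_lines: list[tuple[int, str, str]] = []

    for lineno, line in enumerate(ann_content.splitlines(), start=1):
        if not line.strip():
            continue
        head = line[0]
        if head == "T":
            m = _T_RE.match(line)
            if m is None:
                raise StandoffParseError(f"line {lineno}: malformed entity line: {line!r}")
            tid, etype, offsets, surface = m.groups()
            frags = []
            for frag in offsets.split(";"):
                parts = frag.split()
                if len(parts) != 2:
                    raise StandoffParseError(f"line {lineno}: malformed offsets {offsets!r}")
                frags.append((int(parts[0]), int(parts[1])))
            start = min(s for s, _ in frags)
            end = max(e for _, e in frags)
            if not (0 <= start < end <= len(txt_content)):
                raise StandoffIntegrityError(
                    f"line {lineno}: span ({start},{end}) outside text"
                )
            if tid in doc.entities:
                raise StandoffParseError(f"line {lineno}: duplicate entity id {tid}")
            doc.entities[tid] = EntityMention(
                id=tid, type=etype, start=start, end=end,
                text=txt_content[start:end], fragments=tuple(frags),
            )
        elif head == "R":
            m = _R_RE.match(line)
            if m is None:
                raise StandoffParseError(f"line {lineno}: malformed relation line: {line!r}")
            rid, rtype, a1, a2 = m.groups()
            rel = RelationAnnotation(id=rid, type=rtype, arg1=a1, arg2=a2)
            if rel.key() in seen_rel_keys:
                warnings.warn(
                    f"{doc_id} line {lineno}: duplicate relation on pair "
                    f"({a1},{a2}) collapsed",
                    stacklevel=2,
                )
                continue
            seen_rel_keys.add(rel.key())
            doc.relations.append(rel)
        elif head in ("A", "M"):
            m = _A_RE.match(line)
            if m is None:
                raise StandoffParseError(f"line {lineno}: malformed attribute line: {line!r}")
            _, name, target, _value = m.groups()
            attr_lines.append((lineno, name, target))
        elif head == "*":
            m = _EQ_RE.match(line)
            if m is None:
                raise StandoffParseError(f"line {lineno}: malformed Equiv line: {line!r}")
            raw_equivs.append(set(m.group(1).split()))
        elif head in ("#", "N"):
            doc.opaque_lines.append(line)
        else:
            raise StandoffParseError(f"line {lineno}: unrecognized line type: {line!r}")

    for lineno, name, target in attr_lines:
        if target not in doc.entities:
            raise StandoffIntegrityError(
                f"line {lineno}: attribute {name} on unknown entity {target}"
            )
        doc.entities[target].attributes.add(name)

    doc.equiv_groups = _merge_equivs(raw_equivs)
    doc.validate()
    return doc


def write_standoff(doc: AnnotatedDocument) -> tuple[str, str]:
    """Serialize back to (.txt content, .ann content).

    ``read_standoff(*write_standoff(doc))`` reproduces the document up to
    annotation line order and attribute/Equiv id renumbering.
    """
    lines: list[str] = []
    for e in doc.entities.values():
        offsets = ";".join(f"{s} {t}" for s, t in e.fragments)
        lines.append(f"{e.id}\t{e.type} {offsets}\t{e.text}")
    aid = 1
    for e in doc.entities.values():
        for attr in sorted(e.attributes):
            lines.append(f"A{aid}\t{attr} {e.id}")
            aid += 1
    for r in doc.relations:
        lines.append(f"{r.id}\t{r.type} Arg1:{r.arg1} Arg2:{r.arg2}")
    for g in doc.equiv_groups:
        members = " ".join(sorted(g.members, key=_tid_sort_key))
        lines.append(f"*\tEquiv {members}")
    lines.extend(doc.opaque_lines)
    ann = "\n".join(lines)
    if ann:
        ann += "\n"
    return doc.text, ann


def _tid_sort_key(tid: str):
    m = re.match(r"^T(\d+)$", tid)
    return (0, int(m.group(1))) if m else (1, tid)


def read_document_pair(txt_path: str | Path, ann_path: str | Path | None = None) -> AnnotatedDocument:
    txt_path = Path(txt_path)
    if ann_path is None:
        ann_path = txt_path.with_suffix(".ann")
    txt = txt_path.read_text(encoding="utf-8")
    ann = Path(ann_path).read_text(encoding="utf-8") if Path(ann_path).exists() else ""
    return read_standoff(txt, ann, doc_id=txt_path.stem)


def read_corpus_dir(directory: str | Path) -> list[AnnotatedDocument]:
    """Read every .txt/.ann pair under *directory* (recursive), sorted by id."""
    directory = Path(directory)
    docs = [read_document_pair(p) for p in sorted(directory.rglob("*.txt"))]
    return docs


def write_corpus_dir(docs: Iterable[AnnotatedDocument], directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for doc in docs:
        txt, ann = write_standoff(doc)
        (directory / f"{doc.doc_id}.txt").write_text(txt, encoding="utf-8")
        (directory / f"{doc.doc_id}.ann").write_text(ann, encoding="utf-8")


@dataclass
class StatsReport:
    documents: int = 0
    words: int = 0
    entities_by_type: dict[str, int] = field(default_factory=dict)
    relations_by_type: dict[str, int] = field(default_factory=dict)
    entities_by_attribute: dict[str, int] = field(default_factory=dict)
    equiv_groups: int = 0

    @property
    def entities(self) -> int:
        return sum(self.entities_by_type.values())

    @property
    def relations(self) -> int:
        return sum(self.relations_by_type.values())

    def __add__(self, other: "StatsReport") -> "StatsReport":
        def merge(a: dict[str, int], b: dict[str, int]) -> dict[str, int]:
            out = dict(a)
            for k, v in b.items():
                out[k] = out.get(k, 0) + v
            return out

        return StatsReport(
            documents=self.documents + other.documents,
            words=self.words + other.words,
            entities_by_type=merge(self.entities_by_type, other.entities_by_type),
            relations_by_type=merge(self.relations_by_type, other.relations_by_type),
            entities_by_attribute=merge(self.entities_by_attribute, other.entities_by_attribute),
            equiv_groups=self.equiv_groups + other.equiv_groups,
        )

    def to_tsv(self) -> str:
        rows = [("documents", self.documents), ("words", self.words)]
        rows += [(f"entities:{k}", v) for k, v in sorted(self.entities_by_type.items())]
        rows += [(f"relations:{k}", v) for k, v in sorted(self.relations_by_type.items())]
        rows += [(f"attribute:{k}", v) for k, v in sorted(self.entities_by_attribute.items())]
        rows.append(("equiv_groups", self.equiv_groups))
        return "\n".join(f"{k}\t{v}" for k, v in rows) + "\n"

    def pretty(self) -> str:
        lines = [
            f"documents        {self.documents}",
            f"words            {self.words}",
            f"entities         {self.entities}",
        ]
        for k, v in sorted(self.entities_by_type.items()):
            lines.append(f"  {k:<30s} {v}")
        lines.append(f"relations        {self.relations}")
        for k, v in sorted(self.relations_by_type.items()):
            lines.append(f"  {k:<30s} {v}")
        lines.append("entity attributes")
        for k, v in sorted(self.entities_by_attribute.items()):
            lines.append(f"  {k:<30s} {v}")
        lines.append(f"equiv groups     {self.equiv_groups}")
        return "\n".join(lines) + "\n"


def corpus_statistics(corpus: Sequence[AnnotatedDocument]) -> StatsReport:
    """Count documents, whitespace tokens, entities, relations and attributes."""
    report = StatsReport()
    for doc in corpus:
        r = StatsReport(documents=1, words=len(doc.text.split()))
        for e in doc.entities.values():
            r.entities_by_type[e.type] = r.entities_by_type.get(e.type, 0) + 1
            for a in e.attributes:
                r.entities_by_attribute[a] = r.entities_by_attribute.get(a, 0) + 1
        for rel in doc.relations:
            r.relations_by_type[rel.type] = r.relations_by_type.get(rel.type, 0) + 1
        r.equiv_groups = len(doc.equiv_groups)
        report = report + r
    return report
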