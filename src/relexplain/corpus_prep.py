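"""Entity filtering for the prediction regime, document splits, and
construction of the two trigger-annotation pair sets."""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .brat import AnnotatedDocument, EquivGroup
from .examples import CandidatePair, ModelConfig, build_example, enumerate_pairs
from .tokenization import WordPieceTokenizer

PROTEIN_TYPE = "Gene_or_gene_product"
BLOCKLISTED = "Blocklisted"


def filter_for_prediction(doc: AnnotatedDocument) -> AnnotatedDocument:
    """Keep only non-Blocklisted protein mentions (idempotent, non-mutating).

    Relations losing an argument are dropped and Equiv groups are pruned to
    surviving members (groups shrinking below two members disappear).
    """
    keep = {
        eid
        for eid, e in doc.entities.items()
        if e.type == PROTEIN_TYPE and BLOCKLISTED not in e.attributes
    }
    out = AnnotatedDocument(doc_id=doc.doc_id, text=doc.text)
    out.entities = {eid: copy.deepcopy(doc.entities[eid]) for eid in doc.entities if eid in keep}
    out.relations = [r for r in doc.relations if r.arg1 in keep and r.arg2 in keep]
    out.equiv_groups = [
        EquivGroup(frozenset(m))
        for g in doc.equiv_groups
        if len(m := g.members & keep) >= 2
    ]
    out.opaque_lines = list(doc.opaque_lines)
    out.validate()
    return out


def split_documents(
    corpus: Sequence[AnnotatedDocument],
    fractions: tuple[float, float, float] = (0.6, 0.2, 0.2),
    seed: int = 0,
) -> tuple[list[AnnotatedDocument], list[AnnotatedDocument], list[AnnotatedDocument]]:
    """Partition whole documents into (train, dev, test) deterministically."""
    if not corpus:
        raise ValueError("cannot split an empty corpus")
    if not math.isclose(sum(fractions), 1.0, abs_tol=1e-9):
        raise ValueError(f"fractions must sum to 1, got {fractions}")
    order = np.random.default_rng(seed).permutation(len(corpus))
    n = len(corpus)
    counts = [int(n * f) for f in fractions]
    for i in range(n - sum(counts)):  # distribute the remainder in order
        counts[i % 3] += 1
    parts: list[list[AnnotatedDocument]] = []
    pos = 0
    for c in counts:
        parts.append([corpus[i] for i in sorted(order[pos : pos + c])])
        pos += c
    return parts[0], parts[1], parts[2]


def load_split_manifest(path: str | Path) -> list[str]:
    """Plain-text doc-id list, one id per line (blank lines ignored)."""
    return [ln.strip() for ln in Path(path).read_text(encoding="utf-8").splitlines() if ln.strip()]


def apply_split_manifests(
    corpus: Sequence[AnnotatedDocument],
    manifests: Sequence[Sequence[str]],
) -> list[list[AnnotatedDocument]]:
    """Partition the corpus by released doc-id lists (takes precedence over
    re-sampling)."""
    by_id = {d.doc_id: d for d in corpus}
    seen: set[str] = set()
    parts = []
    for ids in manifests:
        part = []
        for i in ids:
            if i in seen:
                raise ValueError(f"document {i} listed in two partitions")
            if i not in by_id:
                raise ValueError(f"manifest references unknown document {i}")
            seen.add(i)
            part.append(by_id[i])
        parts.append(part)
    return parts


@dataclass
class TriggerSets:
    """Positive protein-pair halves used to annotate and evaluate triggers."""

    dev_doc_ids: list[str]
    test_doc_ids: list[str]
    dev_pairs: list[CandidatePair]
    test_pairs: list[CandidatePair]
    #: positive pairs dropped because they fit no MSL window
    excluded_pairs: list[CandidatePair] = field(default_factory=list)


def build_trigger_sets(
    dev_docs: Sequence[AnnotatedDocument],
    msl: int,
    tokenizer: WordPieceTokenizer,
    seed: int = 0,
    scheme: str = "mark",
) -> TriggerSets:
    """Split dev documents into two halves balanced by document count and
    collect their gold positive protein pairs, excluding pairs whose encoded
    example would exceed *msl* sub-tokens.

    The exclusion test depends only on (tokenizer, msl, scheme), never on
    the seed; an odd document count puts the extra document in the first
    (trigger-development) half.
    """
    filtered = [filter_for_prediction(d) for d in dev_docs]
    order = np.random.default_rng(seed).permutation(len(filtered))
    n_dev = (len(filtered) + 1) // 2
    dev_half = [filtered[i] for i in sorted(order[:n_dev])]
    test_half = [filtered[i] for i in sorted(order[n_dev:])]

    config = ModelConfig(msl=msl, scheme=scheme)  # only msl/scheme matter here
    excluded: list[CandidatePair] = []

    def positives(docs: Sequence[AnnotatedDocument]) -> list[CandidatePair]:
        out = []
        for doc in docs:
            for pair in enumerate_pairs(doc):
                if pair.label != "positive":
                    continue
                if build_example(doc, pair, config, tokenizer) is None:
                    excluded.append(pair)
                else:
                    out.append(pair)
        return out

    return TriggerSets(
        dev_doc_ids=[d.doc_id for d in dev_half],
        test_doc_ids=[d.doc_id for d in test_half],
        dev_pairs=positives(dev_half),
        test_pairs=positives(test_half),
        excluded_pairs=excluded,
    )
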