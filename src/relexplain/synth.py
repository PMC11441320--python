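"""Synthetic standoff corpora with planted relations and trigger cues.

Documents are templated pseudo-English: each sentence mentions protein
names (synthetic alphanumeric identifiers, never real gene symbols) and
positive pairs always co-occur with a cue from the trigger lexicon, while
negatives carry distractor verbs or no cue at all.  A small fraction of
relations crosses sentence boundaries, some mentions are Blocklisted, some
get Equiv alias groups, and hyphenated fusion sentences plant two equally
valid alternative trigger spans.  Every generated corpus passes the
standoff integrity checks, and the exact trigger span(s) of each planted
relation are recorded as the test oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .brat import AnnotatedDocument, EntityMention, EquivGroup, RelationAnnotation
from .corpus_prep import split_documents
from .examples import ModelConfig, build_examples
from .relation_clf import evaluate_pairs, predict, train
from .tokenization import WordPieceTokenizer
from .trigger_eval import TriggerGold, evaluate_triggers
from .attrib import AttributionConfig, detect_triggers

DEFAULT_TRIGGERS = ("binds", "interacts with", "associates with", "forms a complex with")
DEFAULT_DISTRACTORS = ("regulates", "phosphorylates", "activates", "represses")

_FILLERS_PRE = (
    "",
    "Recent assays showed that ",
    "We found that ",
    "In these cells , ",
    "Notably , ",
    "Earlier work suggested that ",
)
_FILLERS_POST = ("", " in vitro", " directly", " under stress", " in most samples")


@dataclass
class SynthConfig:
    n_docs: int = 100
    sentences_per_doc: tuple[int, int] = (1, 3)
    vocab_size: int = 60
    mentions_per_doc: tuple[int, int] = (2, 40)
    positive_rate: float = 0.5
    cross_sentence_fraction: float = 0.04
    trigger_lexicon: tuple[str, ...] = DEFAULT_TRIGGERS
    distractor_lexicon: tuple[str, ...] = DEFAULT_DISTRACTORS
    fusion_rate: float = 0.15  # share of positives written as "A-B complex"
    blocklisted_rate: float = 0.1  # chance of an extra Blocklisted mention
    equiv_rate: float = 0.1  # share of positives with an alias for one side
    nonprotein_rate: float = 0.1  # chance of an extra Chemical mention
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("positive_rate", "cross_sentence_fraction", "fusion_rate",
                     "blocklisted_rate", "equiv_rate", "nonprotein_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        lo, hi = self.mentions_per_doc
        if not (2 <= lo <= hi <= 40):
            raise ValueError("mentions_per_doc must lie within [2, 40]")
        if self.cross_sentence_fraction > 0 and self.sentences_per_doc[1] < 2:
            raise ValueError(
                "cross-sentence relations are infeasible with single-sentence documents"
            )


@dataclass
class SynthGold:
    """Planted trigger spans per positive pair (Equiv-expanded)."""

    triggers: dict[tuple[str, frozenset[str]], tuple[tuple[int, int], ...]] = field(
        default_factory=dict
    )

    def gold_for(self, doc_id: str, e1: str, e2: str) -> tuple[tuple[int, int], ...] | None:
        return self.triggers.get((doc_id, frozenset((e1, e2))))

    def as_trigger_golds(self) -> list[TriggerGold]:
        out = []
        for (doc_id, ids), spans in sorted(
            self.triggers.items(), key=lambda kv: (kv[0][0], sorted(kv[0][1]))
        ):
            e1, e2 = sorted(ids)
            out.append(TriggerGold(doc_id=doc_id, e1=e1, e2=e2, spans=spans))
        return out


def _make_names(rng: np.random.Generator, count: int) -> list[str]:
    letters = np.array(list("ABCDEFGHIJKLMNOPQRSTUVWXYZ"))
    names: list[str] = []
    seen: set[str] = set()
    while len(names) < count:
        name = "".join(rng.choice(letters, size=3)) + str(rng.integers(1, 10))
        if name not in seen:
            seen.add(name)
            names.append(name)
    return names


class _DocBuilder:
    def __init__(self, doc_id: str):
        self.doc_id = doc_id
        self.parts: list[str] = []
        self.pos = 0
        self.entities: list[EntityMention] = []
        self.relations: list[tuple[str, str]] = []
        self.equivs: list[set[str]] = []
        self.gold: dict[frozenset[str], tuple[tuple[int, int], ...]] = {}

    def add_text(self, s: str) -> tuple[int, int]:
        start = self.pos
        self.parts.append(s)
        self.pos += len(s)
        return (start, self.pos)

    def add_entity(self, name: str, etype: str = "Gene_or_gene_product",
                   attributes: set[str] | None = None) -> str:
        span = self.add_text(name)
        tid = f"T{len(self.entities) + 1}"
        self.entities.append(
            EntityMention(id=tid, type=etype, start=span[0], end=span[1],
                          text=name, attributes=attributes or set())
        )
        return tid

    def add_relation(self, a: str, b: str, trigger_spans: Sequence[tuple[int, int]]) -> None:
        self.relations.append((a, b))
        self.gold[frozenset((a, b))] = tuple(trigger_spans)

    def finish(self) -> AnnotatedDocument:
        doc = AnnotatedDocument(doc_id=self.doc_id, text="".join(self.parts))
        doc.entities = {e.id: e for e in self.entities}
        doc.relations = [
            RelationAnnotation(id=f"R{i+1}", type="Complex_formation", arg1=a, arg2=b)
            for i, (a, b) in enumerate(self.relations)
        ]
        doc.equiv_groups = [EquivGroup(frozenset(g)) for g in self.equivs]
        doc.validate()
        return doc


def generate_corpus(config: SynthConfig) -> tuple[list[AnnotatedDocument], SynthGold]:
    """Deterministically generate standoff documents plus the trigger oracle."""
    rng = np.random.default_rng(config.seed)
    names = _make_names(rng, config.vocab_size)
    chem_names = [f"cpd{c}{d}" for c in "QWXZ" for d in range(1, 4)]
    docs: list[AnnotatedDocument] = []
    gold = SynthGold()

    # plan sentence-unit counts up front, then distribute exactly the number
    # of two-sentence (cross-boundary) emissions that realizes the requested
    # fraction of relations: C / (S - C) = f  =>  C = f * S / (1 + f)
    lo, hi = config.sentences_per_doc
    n_units_per_doc = rng.integers(lo, hi + 1, size=config.n_docs)
    f = config.cross_sentence_fraction
    total_units = int(n_units_per_doc.sum())
    n_cross = int(round(f * total_units / (1.0 + f)))
    capacity = [n // 2 for n in n_units_per_doc]
    slots = [d for d, c in enumerate(capacity) for _ in range(c)]
    if n_cross > len(slots):
        raise ValueError("cross-sentence fraction infeasible for the sentence range")
    cross_per_doc = np.zeros(config.n_docs, dtype=int)
    if n_cross:
        for s in rng.choice(len(slots), size=n_cross, replace=False):
            cross_per_doc[slots[s]] += 1

    for d in range(config.n_docs):
        b = _DocBuilder(f"synth{d:04d}")
        n_units = int(n_units_per_doc[d])
        max_mentions = config.mentions_per_doc[1]
        # every mention in a document gets a distinct name, so surface
        # strings never accidentally corefer across sentences
        doc_names = iter(names[i] for i in rng.permutation(len(names)))
        # emission plan: k two-sentence emissions + single-sentence fillers
        k = int(cross_per_doc[d])
        plan = ["cross"] * k + ["single"] * (n_units - 2 * k)
        plan = [plan[i] for i in rng.permutation(len(plan))]
        mentions = 0
        for kind in plan:
            if mentions + 2 > max_mentions:
                break
            a_name, b_name = next(doc_names), next(doc_names)
            positive = bool(rng.random() < config.positive_rate) or (not b.parts and d % 7 == 0)
            if b.parts:
                b.add_text(" ")
            # template family is drawn independently of the label so that
            # only the cue token(s) discriminate positives from negatives
            if kind == "cross":
                _emit_cross_sentence(b, rng, config, a_name, b_name, positive)
            elif rng.random() < config.fusion_rate:
                _emit_fusion(b, a_name, b_name, positive)
            else:
                alias = None
                if positive and rng.random() < config.equiv_rate:
                    alias = next(doc_names)
                _emit_intra(b, rng, config, a_name, b_name, positive, alias=alias)
            mentions = len(b.entities)
            if rng.random() < config.blocklisted_rate and mentions + 1 <= max_mentions:
                extra = next(doc_names)
                b.add_text(" Levels of ")
                b.add_entity(extra, attributes={"Blocklisted"})
                b.add_text(" were elevated .")
                mentions += 1
            if rng.random() < config.nonprotein_rate and mentions + 1 <= max_mentions:
                chem = chem_names[int(rng.choice(len(chem_names)))]
                b.add_text(" Treatment with ")
                b.add_entity(chem, etype="Chemical")
                b.add_text(" had no effect .")
                mentions += 1
        doc = b.finish()
        if len(doc.entities) < config.mentions_per_doc[0]:
            continue  # infeasibly small document; skip (rare)
        docs.append(doc)
        for key, spans in b.gold.items():
            gold.triggers[(doc.doc_id, key)] = spans
        # Equiv expansion: the planted trigger also explains alias pairs
        for g in doc.equiv_groups:
            for (doc_key, pair), spans in list(gold.triggers.items()):
                if doc_key != doc.doc_id:
                    continue
                for member in pair & g.members:
                    other = next(iter(pair - {member}))
                    for alias in g.members - {member}:
                        gold.triggers.setdefault(
                            (doc.doc_id, frozenset((alias, other))), spans
                        )
    return docs, gold


def _pick(rng: np.random.Generator, items: Sequence[str]) -> str:
    return items[int(rng.choice(len(items)))]


def _emit_intra(b: _DocBuilder, rng: np.random.Generator, config: SynthConfig,
                a_name: str, b_name: str, positive: bool, alias: str | None = None) -> None:
    b.add_text(_pick(rng, _FILLERS_PRE))
    a = b.add_entity(a_name)
    if alias is not None:
        b.add_text(" ( also known as ")
        a2 = b.add_entity(alias)
        b.add_text(" )")
        b.equivs.append({a, a2})
    b.add_text(" ")
    if positive:
        cue = _pick(rng, config.trigger_lexicon)
        cue_span = b.add_text(cue)
    else:
        cue = _pick(rng, config.distractor_lexicon) if rng.random() < 0.7 else "and"
        b.add_text(cue)
    b.add_text(" ")
    other = b.add_entity(b_name)
    b.add_text(_pick(rng, _FILLERS_POST))
    b.add_text(" .")
    if positive:
        b.add_relation(a, other, [cue_span])


def _emit_fusion(b: _DocBuilder, a_name: str, b_name: str, positive: bool) -> None:
    # positive: "The A-B complex was purified ." — the hyphen and the word
    # "complex" are alternative, equally valid trigger spans.  The negative
    # variant shares the whole template except the linking cue tokens.
    b.add_text("The ")
    a = b.add_entity(a_name)
    if positive:
        hyphen = b.add_text("-")
    else:
        b.add_text(" and ")
    other = b.add_entity(b_name)
    b.add_text(" ")
    if positive:
        complex_span = b.add_text("complex")
    else:
        b.add_text("samples")
    b.add_text(" was purified .")
    if positive:
        b.add_relation(a, other, [hyphen, complex_span])


def _emit_cross_sentence(b: _DocBuilder, rng: np.random.Generator, config: SynthConfig,
                         a_name: str, b_name: str, positive: bool) -> None:
    b.add_text(_pick(rng, _FILLERS_PRE))
    a = b.add_entity(a_name)
    b.add_text(" was purified . This protein ")
    if positive:
        cue = _pick(rng, config.trigger_lexicon)
        cue_span = b.add_text(cue)
    else:
        b.add_text(_pick(rng, config.distractor_lexicon))
    b.add_text(" ")
    other = b.add_entity(b_name)
    b.add_text(" .")
    if positive:
        b.add_relation(a, other, [cue_span])


def _trigger_golds_for(gold: SynthGold, examples) -> list[TriggerGold]:
    golds = []
    for ex in examples:
        spans = gold.gold_for(ex.doc_id, ex.e1, ex.e2)
        if spans:
            golds.append(TriggerGold(doc_id=ex.doc_id, e1=ex.e1, e2=ex.e2, spans=spans))
    return golds


def _trigger_eval(model, examples, golds, attrib_config):
    gold_keys = {g.key() for g in golds}
    triggers = detect_triggers(model, examples, attrib_config)
    triggers = [t for t in triggers if (t.doc_id, frozenset((t.e1, t.e2))) in gold_keys]
    return triggers, evaluate_triggers(triggers, golds, penalize_alternatives=False)


def end_to_end_recovery(
    config: SynthConfig,
    model_config: ModelConfig,
    attrib_config: AttributionConfig | None = None,
    shuffle_labels: bool = False,
    repeats: int = 1,
) -> dict:
    """Run generate → split → build-examples → train → predict → triggers →
    eval and return the headline metrics.

    Training is repeated ``repeats`` times with distinct seeds and the model
    with the highest best-epoch dev F1 is kept (the repeat-and-select
    protocol).  When no attribution config is given, the LIG layer is
    chosen by sweeping all layers on the dev-split positives — the
    trigger-development set — before scoring the test positives.
    ``shuffle_labels`` permutes training labels as a negative control.
    """
    from .corpus_prep import filter_for_prediction

    docs, gold = generate_corpus(config)
    train_docs, dev_docs, test_docs = split_documents(docs, seed=config.seed)
    tokenizer = WordPieceTokenizer.train([d.text for d in docs], min_word_freq=1)

    def prepared(subset):
        return build_examples(
            [filter_for_prediction(d) for d in subset], model_config, tokenizer
        )

    train_ex, dev_ex, test_ex = prepared(train_docs), prepared(dev_docs), prepared(test_docs)
    if shuffle_labels:
        rng = np.random.default_rng(model_config.seed)
        labels = [ex.label for ex in train_ex]
        rng.shuffle(labels)
        train_ex = [replace(ex, label=lab) for ex, lab in zip(train_ex, labels)]

    model, history = None, None
    best_dev = -1.0
    for r in range(max(1, repeats)):
        cfg_r = replace(model_config, seed=model_config.seed + r)
        model_r, history_r = train(train_ex, dev_ex, cfg_r, tokenizer)
        dev_f1 = max(h.f1 for h in history_r)
        if dev_f1 > best_dev:
            best_dev = dev_f1
            model, history = model_r, history_r
    test_preds = predict(model, test_ex)
    pair_report = evaluate_pairs(test_preds, [ex.pair for ex in test_ex])

    dev_pos = [ex for ex in dev_ex if ex.label == "positive"]
    dev_golds = _trigger_golds_for(gold, dev_pos)
    if attrib_config is None:
        # method sweep on the trigger-development half, best overlap F1 wins:
        # LIG per layer plus SHAP with/without the boundary tokens
        candidates = [
            AttributionConfig(method="lig", layer=layer, steps=32)
            for layer in range(model.classifier.n_layers + 1)
        ] + [
            AttributionConfig(method="shap", samples=16, seed=model_config.seed,
                              include_boundary=flag)
            for flag in (False, True)
        ]
        best = None
        for cand in candidates:
            _, rep = _trigger_eval(model, dev_pos, dev_golds, cand)
            score = rep.modes["overlap"].f1
            if best is None or score > best[0]:
                best = (score, cand)
        attrib_config = best[1]
    positive_gold_ex = [ex for ex in test_ex if ex.label == "positive"]
    golds = _trigger_golds_for(gold, positive_gold_ex)
    triggers, trig_report = _trigger_eval(model, positive_gold_ex, golds, attrib_config)

    base_rate = (
        sum(ex.label == "positive" for ex in test_ex) / len(test_ex) if test_ex else 0.0
    )
    return {
        "pair_report": pair_report,
        "pair_f1": pair_report.f1,
        "pair_precision": pair_report.precision,
        "pair_recall": pair_report.recall,
        "positive_base_rate": base_rate,
        "best_epoch_dev_f1": max(h.f1 for h in history),
        "trigger_report": trig_report,
        "trigger_overlap_precision": trig_report.modes["overlap"].precision,
        "trigger_overlap_recall": trig_report.modes["overlap"].recall,
        "trigger_overlap_f1": trig_report.modes["overlap"].f1,
        "n_train": len(train_ex),
        "n_test": len(test_ex),
        "n_triggers": len(triggers),
        "attrib_method": attrib_config.method,
        "attrib_layer": attrib_config.layer,
        "model": model,
    }
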