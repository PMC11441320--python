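"""Four-mode span matching of predicted trigger spans against gold spans.

Matching modes over half-open character intervals: *exact* (both boundaries
equal), *left-bound* (starts equal), *right-bound* (ends equal) and
*overlap* (non-empty intersection).  A gold entry may carry several
equally-valid alternative spans; two accounting modes are provided:

* penalizing — every alternative span is its own recall target: a pair
  with k alternatives contributes k recall opportunities, the single
  prediction can satisfy at most one of them, and the remaining k-1
  alternatives count as undetected (FN);
* non-penalizing — a pair scores one TP if its prediction matches any
  alternative, otherwise one FN.

Non-penalizing recall therefore never falls below penalizing recall.

In both modes a prediction matching nothing adds one FP, and a positive
pair for which the classifier emitted no trigger counts as missed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from .attrib import TriggerPrediction

MODES = ("left", "right", "overlap", "exact")

Span = tuple[int, int]


@dataclass(frozen=True)
class TriggerGold:
    doc_id: str
    e1: str
    e2: str
    spans: tuple[Span, ...]  # alternative, equally valid trigger spans
    multi_token_allowed: bool = True

    def __post_init__(self) -> None:
        if not self.spans:
            raise ValueError("gold entry needs at least one span")
        deduped = tuple(dict.fromkeys(self.spans))  # alternatives are distinct
        object.__setattr__(self, "spans", deduped)
        for s, e in self.spans:
            if s >= e:
                raise ValueError(f"empty gold span ({s},{e})")

    def key(self) -> tuple[str, frozenset[str]]:
        return (self.doc_id, frozenset((self.e1, self.e2)))


def match_span(pred: Span, gold: Span, mode: str) -> bool:
    ps, pe = pred
    gs, ge = gold
    if mode == "exact":
        return ps == gs and pe == ge
    if mode == "left":
        return ps == gs
    if mode == "right":
        return pe == ge
    if mode == "overlap":
        return ps < ge and pe > gs
    raise ValueError(f"unknown mode {mode!r}")


@dataclass
class ModeScores:
    tp: int = 0
    fp: int = 0
    fn: int = 0

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if self.tp + self.fp else 0.0

    @property
    def recall(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else 0.0

    @property
    def f1(self) -> float:
        p, r = self.precision, self.recall
        return 2 * p * r / (p + r) if p + r else 0.0


@dataclass
class TriggerEvalReport:
    penalize_alternatives: bool
    modes: dict[str, ModeScores] = field(default_factory=dict)

    @property
    def avg_precision(self) -> float:
        return sum(m.precision for m in self.modes.values()) / len(self.modes)

    @property
    def avg_recall(self) -> float:
        return sum(m.recall for m in self.modes.values()) / len(self.modes)

    @property
    def avg_f1(self) -> float:
        return sum(m.f1 for m in self.modes.values()) / len(self.modes)

    def to_tsv(self) -> str:
        lines = ["mode\ttp\tfp\tfn\tprecision\trecall\tf1"]
        for mode in MODES:
            m = self.modes[mode]
            lines.append(
                f"{mode}\t{m.tp}\t{m.fp}\t{m.fn}"
                f"\t{m.precision:.4f}\t{m.recall:.4f}\t{m.f1:.4f}"
            )
        lines.append(
            f"average\t\t\t\t{self.avg_precision:.4f}\t{self.avg_recall:.4f}\t{self.avg_f1:.4f}"
        )
        return "\n".join(lines) + "\n"

    def pretty(self) -> str:
        mode_word = "penalizing" if self.penalize_alternatives else "non-penalizing"
        out = [f"trigger evaluation ({mode_word} alternative spans)"]
        for mode in MODES:
            m = self.modes[mode]
            out.append(
                f"  {mode:<8s} P={m.precision:6.2%} R={m.recall:6.2%} F1={m.f1:6.2%}"
                f"  (TP={m.tp} FP={m.fp} FN={m.fn})"
            )
        out.append(
            f"  {'average':<8s} P={self.avg_precision:6.2%} "
            f"R={self.avg_recall:6.2%} F1={self.avg_f1:6.2%}"
        )
        return "\n".join(out) + "\n"


def evaluate_triggers(
    predictions: Sequence[TriggerPrediction],
    golds: Sequence[TriggerGold],
    penalize_alternatives: bool = True,
) -> TriggerEvalReport:
    """Score ≤1 prediction per positive pair against alternative gold spans."""
    gold_by_key = {g.key(): g for g in golds}
    if len(gold_by_key) != len(golds):
        raise ValueError("duplicate gold entries for one pair")
    pred_by_key: dict[tuple, TriggerPrediction] = {}
    for p in predictions:
        key = (p.doc_id, frozenset((p.e1, p.e2)))
        if key in pred_by_key:
            raise ValueError(f"more than one prediction for pair {key}")
        if key not in gold_by_key:
            raise ValueError(f"prediction for pair {key} absent from gold set")
        pred_by_key[key] = p

    report = TriggerEvalReport(penalize_alternatives=penalize_alternatives)
    for mode in MODES:
        scores = ModeScores()
        for key, gold in gold_by_key.items():
            pred = pred_by_key.get(key)
            if pred is None:  # classifier said negative: trigger missed
                scores.fn += len(gold.spans) if penalize_alternatives else 1
                continue
            matched = any(match_span(pred.span, s, mode) for s in gold.spans)
            if matched:
                scores.tp += 1
                if penalize_alternatives:
                    scores.fn += len(gold.spans) - 1
            else:
                scores.fn += len(gold.spans) if penalize_alternatives else 1
                scores.fp += 1
        report.modes[mode] = scores
    return report


def write_gold_tsv(golds: Sequence[TriggerGold], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("doc_id\tentity1\tentity2\tspans\n")
        for g in golds:
            spans = ";".join(f"{s},{e}" for s, e in g.spans)
            fh.write(f"{g.doc_id}\t{g.e1}\t{g.e2}\t{spans}\n")


def read_gold_tsv(path: str | Path) -> list[TriggerGold]:
    golds = []
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    for line in lines[1:]:
        if not line.strip():
            continue
        doc_id, e1, e2, spans = line.split("\t")
        parsed = tuple(
            (int(s.split(",")[0]), int(s.split(",")[1])) for s in spans.split(";")
        )
        golds.append(TriggerGold(doc_id=doc_id, e1=e1, e2=e2, spans=parsed))
    return golds
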