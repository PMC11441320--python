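"""Binary relation classifier: encoder + two-way softmax decision layer.

Training follows the fixed-epoch protocol: no early stopping, metrics on
the development pairs after every epoch, and the returned weights are those
of the epoch with the highest dev F1 (ties broken toward the earliest
epoch).  ``grid_search`` repeats each configuration with distinct seeds and
reports mean/std of the best-epoch F1.
"""

from __future__ import annotations

import json
import statistics
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .encoder import EncoderConfig, TransformerClassifier
from .examples import CandidatePair, EncodedExample, ModelConfig
from .nn import no_grad
from .tokenization import WordPieceTokenizer

LABEL_TO_INT = {"negative": 0, "positive": 1}


@dataclass(frozen=True)
class PairPrediction:
    pair: CandidatePair
    label: str  # "positive" | "negative"
    score: float  # positive-class softmax probability

    def __post_init__(self) -> None:
        if not (0.0 <= self.score <= 1.0):
            raise ValueError(f"score {self.score} outside [0,1]")


@dataclass
class PairEvalReport:
    tp: int
    fp: int
    fn: int

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

    def as_dict(self) -> dict:
        return {
            "tp": self.tp, "fp": self.fp, "fn": self.fn,
            "precision": self.precision, "recall": self.recall, "f1": self.f1,
        }


@dataclass
class TrainedModel:
    classifier: TransformerClassifier
    tokenizer: WordPieceTokenizer
    config: ModelConfig
    best_epoch: int = 0

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.classifier.save(directory)
        self.tokenizer.save(directory / "vocab.json")
        (directory / "model_config.json").write_text(
            json.dumps({**self.config.__dict__, "best_epoch": self.best_epoch})
        )

    @classmethod
    def load(cls, directory: str | Path) -> "TrainedModel":
        directory = Path(directory)
        meta = json.loads((directory / "model_config.json").read_text())
        best_epoch = meta.pop("best_epoch", 0)
        return cls(
            classifier=TransformerClassifier.load(directory),
            tokenizer=WordPieceTokenizer.load(directory / "vocab.json"),
            config=ModelConfig(**meta),
            best_epoch=best_epoch,
        )


def _batchify(examples: Sequence[EncodedExample], indices: np.ndarray,
              pad_id: int) -> tuple[np.ndarray, np.ndarray]:
    width = max(len(examples[i].token_ids) for i in indices)
    ids = np.full((len(indices), width), pad_id, dtype=np.int64)
    anchors = np.zeros((len(indices), 2), dtype=np.int64)
    for row, i in enumerate(indices):
        ex = examples[i]
        ids[row, : len(ex.token_ids)] = ex.token_ids
        anchors[row] = (ex.e1_token_range[0], ex.e2_token_range[0])
    return ids, anchors


def train(
    train_examples: Sequence[EncodedExample],
    dev_examples: Sequence[EncodedExample],
    config: ModelConfig,
    tokenizer: WordPieceTokenizer,
) -> tuple[TrainedModel, list[PairEvalReport]]:
    """Fine-tune the encoder + decision layer; return best-epoch weights."""
    if not train_examples or not dev_examples:
        raise ValueError("train and dev sets must be non-empty")
    labels = {ex.label for ex in train_examples}
    if labels - {"positive", "negative"}:
        raise ValueError("training examples must be labeled positive/negative")
    if len(labels) < 2:
        raise ValueError(
            f"training set contains a single label ({labels.pop()}); "
            "a binary classifier needs both classes"
        )

    enc_config = EncoderConfig.from_identifier(
        config.encoder, vocab_size=len(tokenizer),
        max_len=config.msl, pad_id=tokenizer.pad_id,
    )
    model = TransformerClassifier(enc_config, seed=config.seed)
    y = np.array([LABEL_TO_INT[ex.label] for ex in train_examples])
    n = len(train_examples)
    n_batches = (n + config.batch_size - 1) // config.batch_size
    optimizer = model.make_optimizer(
        lr=config.learning_rate,
        total_steps=config.epochs * n_batches,
        weight_decay=config.weight_decay,
        warmup_frac=config.warmup_frac,
    )
    rng = np.random.default_rng(config.seed)

    history: list[PairEvalReport] = []
    best_f1 = -1.0
    best_state = model.state_dict()
    best_epoch = 0
    for epoch in range(1, config.epochs + 1):
        order = rng.permutation(n)
        for b in range(n_batches):
            idx = order[b * config.batch_size : (b + 1) * config.batch_size]
            ids, anchors = _batchify(train_examples, idx, tokenizer.pad_id)
            loss = model.loss(ids, y[idx], anchors)
            optimizer.zero_grad()
            loss.backward()
            optimizer.step()
        preds = _predict_classifier(model, dev_examples, tokenizer.pad_id, config.batch_size)
        report = evaluate_pairs(preds, [ex.pair for ex in dev_examples])
        history.append(report)
        if report.f1 > best_f1:  # strict: earliest epoch wins ties
            best_f1 = report.f1
            best_state = model.state_dict()
            best_epoch = epoch
    model.load_state_dict(best_state)
    return TrainedModel(model, tokenizer, config, best_epoch=best_epoch), history


def _predict_classifier(
    classifier: TransformerClassifier,
    examples: Sequence[EncodedExample],
    pad_id: int,
    batch_size: int,
) -> list[PairPrediction]:
    preds: list[PairPrediction] = []
    with no_grad():
        for b in range(0, len(examples), batch_size):
            chunk = list(range(b, min(b + batch_size, len(examples))))
            ids, anchors = _batchify(examples, np.array(chunk), pad_id)
            probs = classifier.predict_proba(ids, anchors)
            for row, i in enumerate(chunk):
                score = float(probs[row, 1])
                preds.append(
                    PairPrediction(
                        pair=examples[i].pair,
                        label="positive" if score >= 0.5 else "negative",
                        score=score,
                    )
                )
    return preds


def predict(model: TrainedModel, examples: Sequence[EncodedExample]) -> list[PairPrediction]:
    """One deterministic prediction per example."""
    for ex in examples:
        if len(ex.token_ids) > model.config.msl:
            raise ValueError(
                f"example for ({ex.doc_id},{ex.e1},{ex.e2}) has "
                f"{len(ex.token_ids)} tokens > model MSL {model.config.msl}"
            )
    return _predict_classifier(
        model.classifier, examples, model.tokenizer.pad_id,
        batch_size=max(8, model.config.batch_size),
    )


def evaluate_pairs(
    predictions: Sequence[PairPrediction],
    gold_pairs: Sequence[CandidatePair],
) -> PairEvalReport:
    """Micro TP/FP/FN on the positive class over unordered pairs.

    Gold labels are expected to be Equiv-expanded already (the pair
    enumerator does this).  The prediction and gold universes must match.
    """
    pred_by_key = {p.pair.key(): p for p in predictions}
    gold_by_key = {g.key(): g for g in gold_pairs}
    if set(pred_by_key) != set(gold_by_key):
        raise ValueError(
            f"pair universe mismatch: {len(pred_by_key)} predictions vs "
            f"{len(gold_by_key)} gold pairs"
        )
    tp = fp = fn = 0
    for key, gold in gold_by_key.items():
        predicted_positive = pred_by_key[key].label == "positive"
        is_positive = gold.label == "positive"
        if predicted_positive and is_positive:
            tp += 1
        elif predicted_positive:
            fp += 1
        elif is_positive:
            fn += 1
    return PairEvalReport(tp=tp, fp=fp, fn=fn)


@dataclass
class ExperimentReport:
    config: ModelConfig
    per_repeat: list[PairEvalReport] = field(default_factory=list)
    errors: list[str] = field(default_factory=list)

    @property
    def mean_f1(self) -> float:
        return statistics.fmean(r.f1 for r in self.per_repeat) if self.per_repeat else 0.0

    @property
    def std_f1(self) -> float:
        vals = [r.f1 for r in self.per_repeat]
        return statistics.pstdev(vals) if len(vals) > 1 else 0.0

    @property
    def mean_precision(self) -> float:
        return statistics.fmean(r.precision for r in self.per_repeat) if self.per_repeat else 0.0

    @property
    def mean_recall(self) -> float:
        return statistics.fmean(r.recall for r in self.per_repeat) if self.per_repeat else 0.0


def grid_search(
    train_examples: Sequence[EncodedExample],
    dev_examples: Sequence[EncodedExample],
    config_grid: Sequence[ModelConfig],
    repeats: int,
    tokenizer: WordPieceTokenizer,
) -> list[ExperimentReport]:
    """Train every configuration *repeats* times with distinct seeds.

    Per-cell training errors are recorded and the grid continues.  Reports
    come back sorted with the highest mean best-epoch dev F1 first.
    """
    if repeats < 1:
        raise ValueError("repeats must be >= 1")
    if not config_grid:
        raise ValueError("empty configuration grid")
    reports = []
    for config in config_grid:
        report = ExperimentReport(config=config)
        for r in range(repeats):
            cell = ModelConfig(**{**config.__dict__, "seed": config.seed + r})
            try:
                _, history = train(train_examples, dev_examples, cell, tokenizer)
                report.per_repeat.append(max(history, key=lambda h: h.f1))
            except Exception as exc:  # noqa: BLE001 — grid must continue
                report.errors.append(f"seed {cell.seed}: {exc}")
        reports.append(report)
    reports.sort(key=lambda r: r.mean_f1, reverse=True)
    return reports


def write_predictions_tsv(predictions: Sequence[PairPrediction], path: str | Path) -> None:
    """Tab-delimited export: doc id, entity1, entity2, score, label."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("doc_id\tentity1\tentity2\tscore\tlabel\n")
        for p in predictions:
            fh.write(f"{p.pair.doc_id}\t{p.pair.e1}\t{p.pair.e2}\t{p.score:.6f}\t{p.label}\n")
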