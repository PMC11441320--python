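"""Unsupervised trigger detection for positive-predicted pairs.

Two per-token attribution methods explain the positive-class probability of
the trained classifier: layer integrated gradients (LIG — a Riemann
path-integral of gradients taken at a chosen layer's activations) and
permutation-sampled Shapley values under a pad-masking value function.
Post-processing heuristics strike irrelevant tokens, and the surviving
argmax token — widened to its full word-piece group — becomes the predicted
trigger span.  Triggers are only ever produced for pairs the classifier
scored positive.  A regex/lexicon window matcher serves as the baseline.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .examples import EncodedExample
from .nn import Tensor, no_grad
from .relation_clf import TrainedModel, predict
from .tokenization import SPECIAL_TOKENS

DEFAULT_HEURISTICS = ("specials", "focus_entities", "other_entities", "numeric")


class NoTriggerAssignable(ValueError):
    """Every token of an example was struck by the heuristic rules."""


@dataclass
class AttributionConfig:
    method: str = "lig"  # "lig" | "shap"
    layer: int = 0  # 0 = embedding output, 1..L = hidden layers (LIG only)
    steps: int = 64  # Riemann points (LIG)
    baseline: str = "pad"  # baseline construction rule
    include_boundary: bool = False  # SHAP: treat [CLS]/[SEP] as players
    samples: int = 200  # SHAP permutation draws
    seed: int = 0
    heuristics: tuple[str, ...] = DEFAULT_HEURISTICS

    def __post_init__(self) -> None:
        if self.method not in ("lig", "shap"):
            raise ValueError(f"unknown attribution method {self.method!r}")
        if self.steps < 8:
            raise ValueError("steps must be >= 8")
        if self.samples < 1:
            raise ValueError("samples must be >= 1")


@dataclass
class AttributionVector:
    example: EncodedExample
    scores: np.ndarray  # one finite score per token (pre-heuristics)
    method: str
    layer: int = 0

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=np.float64)
        if len(self.scores) != len(self.example.token_ids):
            raise ValueError("one score per token required")


@dataclass(frozen=True)
class TriggerPrediction:
    doc_id: str
    e1: str
    e2: str
    span: tuple[int, int]  # original-document character offsets
    score: float
    method: str
    layer: int = 0


def _baseline_ids(example: EncodedExample, pad_id: int, special_ids: frozenset[int]) -> np.ndarray:
    """Content-free reference: non-special tokens replaced by padding."""
    ids = np.array(example.token_ids)
    keep = np.isin(ids, list(special_ids))
    return np.where(keep, ids, pad_id)


def integrated_gradients(
    f: Callable[[Tensor], Tensor],
    x: np.ndarray,
    baseline: np.ndarray,
    steps: int,
) -> np.ndarray:
    """Path integral of grad f from *baseline* to *x* (midpoint Riemann rule).

    Satisfies completeness: ``sum(result) ≈ f(x) - f(baseline)`` as steps
    grow.  *f* must map a Tensor shaped like *x* to a scalar Tensor.
    """
    x = np.asarray(x, dtype=np.float64)
    baseline = np.asarray(baseline, dtype=np.float64)
    total = np.zeros_like(x)
    for k in range(steps):
        alpha = (k + 0.5) / steps
        point = Tensor(baseline + alpha * (x - baseline), requires_grad=True)
        out = f(point)
        out.backward()
        total += point.grad
    return (x - baseline) * total / steps


def layer_integrated_gradients(
    model: TrainedModel,
    example: EncodedExample,
    config: AttributionConfig,
) -> AttributionVector:
    """Per-token LIG scores for the positive-class logit margin.

    Scores integrate gradients with respect to the chosen layer's output
    activations along the straight line between the baseline-input
    activations and the actual ones, then sum over the hidden dimension.
    All Riemann points are evaluated as one batch.
    """
    clf = model.classifier
    if not (0 <= config.layer <= clf.n_layers):
        raise ValueError(f"layer {config.layer} outside [0, {clf.n_layers}]")
    tok = model.tokenizer
    ids = np.array([example.token_ids])
    anchors = np.array([[example.e1_token_range[0], example.e2_token_range[0]]])
    base_ids = _baseline_ids(example, tok.pad_id, tok.special_ids)[None, :]
    with no_grad():
        _, acts = clf.forward(ids, anchors, collect_layers=True)
        # baseline activations keep the original attention mask so the
        # integration endpoints agree with the resumed forward pass
        _, acts_base = clf.forward(base_ids, anchors, collect_layers=True, mask_ids=ids)
    a1 = acts[config.layer].data[0]
    a0 = acts_base[config.layer].data[0]

    steps = config.steps
    alphas = (np.arange(steps) + 0.5) / steps
    interp = Tensor(a0[None] + alphas[:, None, None] * (a1 - a0)[None], requires_grad=True)
    logits = clf.forward_from_layer(
        config.layer, interp, np.repeat(ids, steps, axis=0),
        np.repeat(anchors, steps, axis=0),
    )
    # attribute the positive-class logit margin (log-odds): unlike the
    # softmax probability it does not saturate, so confident predictions
    # still produce usable gradients
    margin = logits.take(np.array([1]), axis=1) - logits.take(np.array([0]), axis=1)
    margin.sum().backward()
    avg_grad = interp.grad.mean(axis=0)
    scores = ((a1 - a0) * avg_grad).sum(axis=-1)
    return AttributionVector(example, scores, method="lig", layer=config.layer)


def shapley_values(
    model: TrainedModel,
    example: EncodedExample,
    config: AttributionConfig,
) -> AttributionVector:
    """Permutation-sampled Shapley values of the positive-class logit margin.

    The value function keeps coalition tokens and replaces absent ones with
    the padding token.  Boundary tokens join the player set only when
    ``include_boundary`` is on; non-players keep a zero score.
    """
    tok = model.tokenizer
    ids = np.array(example.token_ids)
    boundary = {tok.cls_id, tok.sep_id}
    players = [
        i for i, t in enumerate(ids)
        if int(t) not in tok.special_ids or (config.include_boundary and int(t) in boundary)
    ]
    scores = np.zeros(len(ids))
    if not players:
        return AttributionVector(example, scores, method="shap")

    clf = model.classifier

    anchors = np.array([example.e1_token_range[0], example.e2_token_range[0]])

    def coalition_values(masks: np.ndarray) -> np.ndarray:
        # masks: (n_rows, n_players) booleans — True keeps the token;
        # the payoff is the positive-class logit margin (see LIG note)
        batch = np.repeat(ids[None, :], masks.shape[0], axis=0)
        for col, pos in enumerate(players):
            batch[~masks[:, col], pos] = tok.pad_id
        tiled = np.repeat(anchors[None, :], masks.shape[0], axis=0)
        with no_grad():
            logits = clf.forward(batch, tiled).data
        return logits[:, 1] - logits[:, 0]

    rng = np.random.default_rng(config.seed)
    n = len(players)
    totals = np.zeros(n)
    for _ in range(config.samples):
        perm = rng.permutation(n)
        # prefix masks: row k keeps the first k players of the permutation
        masks = np.zeros((n + 1, n), dtype=bool)
        for k, p in enumerate(perm):
            masks[k + 1] = masks[k]
            masks[k + 1, p] = True
        vals = coalition_values(masks)
        totals[perm] += np.diff(vals)
    for p, v in zip(players, totals / config.samples):
        scores[p] = v
    return AttributionVector(example, scores, method="shap")


# -- post-processing heuristics ----------------------------------------------

def _rule_specials(vec: AttributionVector) -> list[int]:
    ex = vec.example
    return [
        i for i, t in enumerate(ex.tokens)
        if t in SPECIAL_TOKENS or ex.token_spans[i] is None
    ]


def _overlaps(span: tuple[int, int] | None, other: tuple[int, int]) -> bool:
    return span is not None and span[0] < other[1] and span[1] > other[0]


def _rule_focus_entities(vec: AttributionVector) -> list[int]:
    ex = vec.example
    return [
        i for i, s in enumerate(ex.token_spans)
        if _overlaps(s, ex.e1_span) or _overlaps(s, ex.e2_span)
    ]


def _rule_other_entities(vec: AttributionVector) -> list[int]:
    ex = vec.example
    return [
        i for i, s in enumerate(ex.token_spans)
        if any(_overlaps(s, o) for o in ex.other_entity_spans)
    ]


_NUMERIC_RE = re.compile(r"^\d+$")


def _rule_numeric(vec: AttributionVector) -> list[int]:
    # purely numeric tokens only; punctuation is deliberately retained
    return [
        i for i, t in enumerate(vec.example.tokens)
        if _NUMERIC_RE.match(t.removeprefix("##"))
    ]


HEURISTIC_RULES: dict[str, Callable[[AttributionVector], list[int]]] = {
    "specials": _rule_specials,
    "focus_entities": _rule_focus_entities,
    "other_entities": _rule_other_entities,
    "numeric": _rule_numeric,
}


def apply_heuristics(
    vector: AttributionVector,
    rules: Sequence[str] = DEFAULT_HEURISTICS,
) -> AttributionVector:
    """Strike tokens matched by each named rule, in order, with -inf scores."""
    scores = vector.scores.copy()
    for name in rules:
        try:
            rule = HEURISTIC_RULES[name]
        except KeyError:
            raise ValueError(f"unknown heuristic rule {name!r}") from None
        for i in rule(vector):
            scores[i] = -math.inf
    if not np.isfinite(scores).any():
        raise NoTriggerAssignable(
            f"all tokens removed for ({vector.example.doc_id},"
            f"{vector.example.e1},{vector.example.e2})"
        )
    return AttributionVector(vector.example, scores, vector.method, vector.layer)


def select_trigger(vector: AttributionVector) -> TriggerPrediction:
    """Argmax surviving token (ties leftmost), widened to its whole word.

    Boundary/placeholder tokens and tokens without a character span never
    win, even when no heuristics were applied.
    """
    ex = vector.example
    candidates = [
        i for i, s in enumerate(vector.scores)
        if np.isfinite(s) and ex.token_spans[i] is not None
        and ex.tokens[i] not in SPECIAL_TOKENS
    ]
    if not candidates:
        raise NoTriggerAssignable("no surviving token to select")
    best = max(candidates, key=lambda i: (vector.scores[i], -i))
    word = ex.word_ids[best]
    group = [
        i for i in range(len(ex.tokens))
        if ex.word_ids[i] == word and ex.token_spans[i] is not None
    ]
    start = min(ex.token_spans[i][0] for i in group)
    end = max(ex.token_spans[i][1] for i in group)
    return TriggerPrediction(
        doc_id=ex.doc_id, e1=ex.e1, e2=ex.e2, span=(start, end),
        score=float(vector.scores[best]), method=vector.method, layer=vector.layer,
    )


def attribute(model: TrainedModel, example: EncodedExample,
              config: AttributionConfig) -> AttributionVector:
    if config.method == "lig":
        return layer_integrated_gradients(model, example, config)
    return shapley_values(model, example, config)


def detect_triggers(
    model: TrainedModel,
    examples: Sequence[EncodedExample],
    config: AttributionConfig,
) -> list[TriggerPrediction]:
    """Full pipeline: predict → keep positives → attribute → heuristics →
    select.  Negative-predicted pairs yield no trigger (gating)."""
    out: list[TriggerPrediction] = []
    predictions = predict(model, examples)
    for example, pred in zip(examples, predictions):
        if pred.label != "positive":
            continue
        vector = attribute(model, example, config)
        if config.heuristics:
            vector = apply_heuristics(vector, config.heuristics)
        out.append(select_trigger(vector))
    return out


# -- lexicon/window baseline --------------------------------------------------

def _entity_token_range(example: EncodedExample, span: tuple[int, int]) -> tuple[int, int]:
    idx = [i for i, s in enumerate(example.token_spans) if _overlaps(s, span)]
    if not idx:
        raise ValueError("entity tokens not found in example window")
    return min(idx), max(idx)


def baseline_trigger_match(
    example: EncodedExample,
    text: str,
    lexicon: Sequence[str],
    window_size: int,
) -> list[tuple[int, int]]:
    """Regex-match lexicon items inside sub-token windows around each entity.

    Items are tried longest-first, case-insensitively, on whole-token
    boundaries; each matched character span is reported once.
    """
    if window_size < 1:
        raise ValueError("window_size must be >= 1")
    if not lexicon:
        return []
    regions: list[tuple[int, int]] = []
    for span in (example.e1_span, example.e2_span):
        lo, hi = _entity_token_range(example, span)
        lo = max(0, lo - window_size)
        hi = min(len(example.token_spans) - 1, hi + window_size)
        covered = [s for s in example.token_spans[lo : hi + 1] if s is not None]
        if covered:
            regions.append((min(s for s, _ in covered), max(e for _, e in covered)))

    matches: list[tuple[int, int]] = []
    for item in sorted(set(lexicon), key=lambda s: (-len(s), s)):
        pattern = re.escape(item)
        if item and item[0].isalnum():
            pattern = r"\b" + pattern
        if item and item[-1].isalnum():
            pattern = pattern + r"\b"
        for lo, hi in regions:
            for m in re.finditer(pattern, text[lo:hi], flags=re.IGNORECASE):
                span = (lo + m.start(), lo + m.end())
                if not any(span[0] < e and span[1] > s for s, e in matches):
                    matches.append(span)
    return sorted(matches)
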