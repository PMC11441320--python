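"""Attribution methods checked against closed forms and brute-force oracles."""

import dataclasses
import itertools
import math

import numpy as np
import pytest

from relexplain.attrib import (AttributionConfig, AttributionVector,
                               NoTriggerAssignable, apply_heuristics,
                               baseline_trigger_match, detect_triggers,
                               integrated_gradients, layer_integrated_gradients,
                               select_trigger, shapley_values)
from relexplain.corpus_prep import filter_for_prediction
from relexplain.examples import ModelConfig, build_examples
from relexplain.nn import Tensor, no_grad
from relexplain.relation_clf import predict, train
from relexplain.synth import SynthConfig, generate_corpus
from relexplain.tokenization import WordPieceTokenizer


@pytest.fixture(scope="module")
def trained_setup():
    config = SynthConfig(
        n_docs=60, sentences_per_doc=(1, 2), positive_rate=0.5,
        cross_sentence_fraction=0.0, fusion_rate=0.2, equiv_rate=0.0,
        blocklisted_rate=0.05, nonprotein_rate=0.0, seed=17,
    )
    docs, gold = generate_corpus(config)
    tokenizer = WordPieceTokenizer.train([d.text for d in docs], min_word_freq=1)
    mc = ModelConfig(encoder="tiny-2l-32d", msl=48, learning_rate=5e-3,
                     batch_size=8, epochs=12, seed=1)
    examples = build_examples([filter_for_prediction(d) for d in docs], mc, tokenizer)
    model, history = train(examples, examples, mc, tokenizer)
    assert max(h.f1 for h in history) >= 0.9  # prerequisite for the rest
    by_id = {d.doc_id: d for d in docs}
    return model, examples, gold, by_id


def margin(model, example):
    ids = np.array([example.token_ids])
    anchors = np.array([[example.e1_token_range[0], example.e2_token_range[0]]])
    with no_grad():
        logits = model.classifier.forward(ids, anchors).data[0]
    return logits[1] - logits[0]


class TestIntegratedGradientsCore:
    def test_linear_model_closed_form(self):
        w = np.array([0.5, -2.0, 3.0, 1.5])
        x = np.array([1.0, 2.0, -1.0, 0.5])

        def f(t: Tensor) -> Tensor:
            return (t * Tensor(w)).sum()

        attr = integrated_gradients(f, x, np.zeros_like(x), steps=16)
        assert np.allclose(attr, w * x, atol=1e-12)

    def test_baseline_equals_input_all_zero(self):
        def f(t: Tensor) -> Tensor:
            return (t * t).sum()

        x = np.array([1.0, -2.0])
        attr = integrated_gradients(f, x, x.copy(), steps=16)
        assert np.allclose(attr, 0.0)

    def test_completeness_on_nonlinear_function(self):
        rng = np.random.default_rng(0)
        W = rng.normal(size=(4, 3))

        def f(t: Tensor) -> Tensor:
            return (t @ Tensor(W)).tanh().sum()

        x = rng.normal(size=(2, 4))
        base = np.zeros_like(x)
        attr = integrated_gradients(f, x, base, steps=256)
        def val(a):
            return float(np.tanh(a @ W).sum())
        assert math.isclose(attr.sum(), val(x) - val(base), rel_tol=0.01)


class TestLayerIntegratedGradients:
    def test_completeness_within_one_percent(self, trained_setup):
        # sum of attributions == margin at the input activations minus
        # margin at the baseline activations (both resumed from the layer)
        model, examples, _, _ = trained_setup
        ex = next(e for e in examples if e.label == "positive")
        tok = model.tokenizer
        clf = model.classifier
        from relexplain.attrib import _baseline_ids

        ids = np.array([ex.token_ids])
        anchors = np.array([[ex.e1_token_range[0], ex.e2_token_range[0]]])
        base_ids = _baseline_ids(ex, tok.pad_id, tok.special_ids)[None, :]
        for layer in range(clf.n_layers + 1):
            cfg = AttributionConfig(method="lig", layer=layer, steps=256)
            vec = layer_integrated_gradients(model, ex, cfg)
            with no_grad():
                _, acts = clf.forward(ids, anchors, collect_layers=True)
                _, acts_base = clf.forward(base_ids, anchors, collect_layers=True,
                                           mask_ids=ids)

                def resumed_margin(a):
                    logits = clf.forward_from_layer(layer, Tensor(a.data), ids, anchors)
                    return float(logits.data[0, 1] - logits.data[0, 0])

                delta = resumed_margin(acts[layer]) - resumed_margin(acts_base[layer])
            assert math.isclose(vec.scores.sum(), delta, rel_tol=0.01, abs_tol=1e-9)

    def test_one_score_per_token(self, trained_setup):
        model, examples, _, _ = trained_setup
        vec = layer_integrated_gradients(model, examples[0],
                                         AttributionConfig(method="lig", layer=1, steps=16))
        assert len(vec.scores) == len(examples[0].token_ids)
        assert np.isfinite(vec.scores).all()

    def test_invalid_layer_rejected(self, trained_setup):
        model, examples, _, _ = trained_setup
        cfg = AttributionConfig(method="lig", layer=9, steps=16)
        with pytest.raises(ValueError, match="layer"):
            layer_integrated_gradients(model, examples[0], cfg)

    def test_deterministic(self, trained_setup):
        model, examples, _, _ = trained_setup
        cfg = AttributionConfig(method="lig", layer=1, steps=32)
        a = layer_integrated_gradients(model, examples[0], cfg)
        b = layer_integrated_gradients(model, examples[0], cfg)
        assert np.array_equal(a.scores, b.scores)


def exact_shapley(model, example, players):
    """Brute-force Shapley over all 2^n coalitions (independent oracle)."""
    tok = model.tokenizer
    ids = np.array(example.token_ids)
    anchors = np.array([[example.e1_token_range[0], example.e2_token_range[0]]])

    def value(subset):
        v = ids.copy()
        for p in players:
            if p not in subset:
                v[p] = tok.pad_id
        with no_grad():
            logits = model.classifier.forward(v[None, :], anchors).data[0]
        return logits[1] - logits[0]

    n = len(players)
    values = {}
    cache = {}
    def v_of(frozen):
        if frozen not in cache:
            cache[frozen] = value(frozen)
        return cache[frozen]

    for i, p in enumerate(players):
        total = 0.0
        rest = [q for q in players if q != p]
        for r in range(len(rest) + 1):
            for combo in itertools.combinations(rest, r):
                s = frozenset(combo)
                weight = (math.factorial(r) * math.factorial(n - r - 1)) / math.factorial(n)
                total += weight * (v_of(s | {p}) - v_of(s))
        values[p] = total
    return values


@pytest.fixture(scope="module")
def short_example(trained_setup):
    model, examples, _, _ = trained_setup
    tok = model.tokenizer
    candidates = [
        e for e in examples
        if sum(t not in tok.special_ids for t in e.token_ids) <= 8
        and e.label == "positive"
    ]
    return min(candidates, key=lambda e: len(e.token_ids))


class TestShapley:
    def test_sampled_matches_exact_enumeration(self, trained_setup, short_example):
        model, _, _, _ = trained_setup
        tok = model.tokenizer
        cfg = AttributionConfig(method="shap", samples=400, seed=5)
        vec = shapley_values(model, short_example, cfg)
        players = [i for i, t in enumerate(short_example.token_ids)
                   if t not in tok.special_ids]
        assert len(players) <= 8
        exact = exact_shapley(model, short_example, players)
        scale = max(1e-9, max(abs(v) for v in exact.values()))
        for p in players:
            assert abs(vec.scores[p] - exact[p]) <= 0.12 * scale + 0.02

    def test_constant_value_function_all_zero(self, trained_setup, short_example):
        model, _, _, _ = trained_setup
        import copy

        frozen = copy.deepcopy(model)
        frozen.classifier.params["cls_w"].data[:] = 0.0
        frozen.classifier.params["cls_b"].data[:] = 0.0
        vec = shapley_values(frozen, short_example,
                             AttributionConfig(method="shap", samples=20, seed=0))
        assert np.allclose(vec.scores, 0.0)

    def test_efficiency_axiom(self, trained_setup, short_example):
        model, _, _, _ = trained_setup
        tok = model.tokenizer
        cfg = AttributionConfig(method="shap", samples=50, seed=3)
        vec = shapley_values(model, short_example, cfg)
        full = margin(model, short_example)
        empty_ids = [
            tok.pad_id if t not in tok.special_ids else t
            for t in short_example.token_ids
        ]
        empty = margin(model, dataclasses.replace(short_example, token_ids=empty_ids))
        assert math.isclose(vec.scores.sum(), full - empty, rel_tol=1e-6, abs_tol=1e-9)

    def test_seeded_sampling_deterministic(self, trained_setup, short_example):
        model, _, _, _ = trained_setup
        cfg = AttributionConfig(method="shap", samples=10, seed=11)
        a = shapley_values(model, short_example, cfg)
        b = shapley_values(model, short_example, cfg)
        assert np.array_equal(a.scores, b.scores)

    def test_boundary_flag_adds_players(self, trained_setup, short_example):
        model, _, _, _ = trained_setup
        without = shapley_values(model, short_example,
                                 AttributionConfig(method="shap", samples=10, seed=0))
        with_b = shapley_values(
            model, short_example,
            AttributionConfig(method="shap", samples=10, seed=0, include_boundary=True),
        )
        assert without.scores[0] == 0.0  # [CLS] not a player
        assert with_b.scores[0] != 0.0


class TestHeuristics:
    def make_vector(self, example, scores):
        return AttributionVector(example, np.array(scores, float), method="lig", layer=1)

    def test_entity_token_removed_second_best_wins(self, trained_setup):
        model, examples, _, _ = trained_setup
        ex = examples[0]
        scores = np.zeros(len(ex.token_ids))
        inside = ex.e1_token_range[0] + 1  # first token of entity 1 surface
        scores[inside] = 5.0
        outside = next(
            i for i, s in enumerate(ex.token_spans)
            if s is not None
            and not (s[0] < ex.e1_span[1] and s[1] > ex.e1_span[0])
            and not (s[0] < ex.e2_span[1] and s[1] > ex.e2_span[0])
            and not any(s[0] < o[1] and s[1] > o[0] for o in ex.other_entity_spans)
        )
        scores[outside] = 3.0
        vec = apply_heuristics(self.make_vector(ex, scores))
        assert select_trigger(vec).span == (
            min(t[0] for i, t in enumerate(ex.token_spans)
                if t and ex.word_ids[i] == ex.word_ids[outside]),
            max(t[1] for i, t in enumerate(ex.token_spans)
                if t and ex.word_ids[i] == ex.word_ids[outside]),
        )

    def test_empty_rule_list_is_identity(self, trained_setup):
        _, examples, _, _ = trained_setup
        ex = examples[0]
        vec = self.make_vector(ex, np.arange(len(ex.token_ids), dtype=float))
        out = apply_heuristics(vec, rules=())
        assert np.array_equal(out.scores, vec.scores)

    def test_hyphen_in_fusion_survives(self, trained_setup):
        _, examples, _, by_id = trained_setup
        fusion = next(
            e for e in examples
            if e.label == "positive" and "-" in e.tokens
        )
        vec = self.make_vector(fusion, np.zeros(len(fusion.token_ids)))
        out = apply_heuristics(vec)
        hyphens = [i for i, t in enumerate(fusion.tokens) if t == "-"]
        assert any(np.isfinite(out.scores[i]) for i in hyphens)

    def test_numeric_tokens_removed(self, trained_setup):
        model, examples, _, _ = trained_setup
        ex = examples[0]
        vec = self.make_vector(ex, np.zeros(len(ex.token_ids)))
        out = apply_heuristics(vec, rules=("numeric",))
        for i, t in enumerate(ex.tokens):
            if t.removeprefix("##").isdigit():
                assert out.scores[i] == -np.inf

    def test_all_tokens_removed_raises(self, trained_setup):
        _, examples, _, _ = trained_setup
        ex = examples[0]
        vec = self.make_vector(ex, np.zeros(len(ex.token_ids)))
        vec.scores[:] = 0.0
        with pytest.raises(NoTriggerAssignable):
            # strike everything by applying the specials rule to a vector
            # whose only finite scores are on special tokens
            stripped = AttributionVector(
                ex, np.where([t == "[CLS]" for t in ex.tokens], 0.0, -np.inf),
                method="lig",
            )
            apply_heuristics(stripped, rules=("specials",))

    def test_unknown_rule_rejected(self, trained_setup):
        _, examples, _, _ = trained_setup
        vec = self.make_vector(examples[0], np.zeros(len(examples[0].token_ids)))
        with pytest.raises(ValueError, match="unknown heuristic"):
            apply_heuristics(vec, rules=("bogus",))


class TestSelectTrigger:
    def test_argmax_token_selected(self, trained_setup):
        _, examples, _, by_id = trained_setup
        ex = examples[0]
        scores = np.full(len(ex.token_ids), -np.inf)
        target = next(i for i, s in enumerate(ex.token_spans) if s is not None)
        scores[target] = 0.9
        vec = AttributionVector(ex, scores, method="lig")
        pred = select_trigger(vec)
        text = by_id[ex.doc_id].text
        span_text = text[pred.span[0] : pred.span[1]]
        assert ex.tokens[target].removeprefix("##") in span_text

    def test_tie_broken_leftmost(self, trained_setup):
        _, examples, _, _ = trained_setup
        ex = examples[0]
        idx = [i for i, s in enumerate(ex.token_spans) if s is not None]
        scores = np.full(len(ex.token_ids), -np.inf)
        scores[idx[2]] = 1.0
        scores[idx[4]] = 1.0
        vec = AttributionVector(ex, scores, method="lig")
        assert select_trigger(vec).span[0] == ex.token_spans[idx[2]][0]

    def test_subtoken_widened_to_word(self):
        # vocabulary without "interact": the word splits into pieces and the
        # winning continuation piece must widen to the whole word's span
        from relexplain.brat import AnnotatedDocument, EntityMention, RelationAnnotation
        from relexplain.examples import build_example, enumerate_pairs

        text = "AAA1 interact BBB2"
        doc = AnnotatedDocument(doc_id="w", text=text)
        for tid, (s, e) in (("T1", (0, 4)), ("T2", (14, 18))):
            doc.entities[tid] = EntityMention(
                id=tid, type="Gene_or_gene_product", start=s, end=e, text=text[s:e]
            )
        doc.relations = [RelationAnnotation("R1", "Complex_formation", "T1", "T2")]
        tok = WordPieceTokenizer.train(["AAA1 in ter act BBB2"], min_word_freq=1)
        ex = build_example(doc, enumerate_pairs(doc)[0], ModelConfig(msl=32), tok)
        subs = [i for i, t in enumerate(ex.tokens) if t.startswith("##")]
        assert subs, ex.tokens
        scores = np.full(len(ex.token_ids), -np.inf)
        scores[subs[-1]] = 1.0
        pred = select_trigger(AttributionVector(ex, scores, method="lig"))
        assert text[pred.span[0] : pred.span[1]] == "interact"

    def test_no_surviving_token_raises(self, trained_setup):
        _, examples, _, _ = trained_setup
        ex = examples[0]
        vec = AttributionVector(ex, np.full(len(ex.token_ids), -np.inf), method="lig")
        with pytest.raises(NoTriggerAssignable):
            select_trigger(vec)


class TestDetectTriggers:
    def test_gating_no_triggers_for_negatives(self, trained_setup):
        model, examples, _, _ = trained_setup
        cfg = AttributionConfig(method="lig", layer=1, steps=16)
        preds = predict(model, examples)
        negatives = [e for e, p in zip(examples, preds) if p.label == "negative"]
        assert detect_triggers(model, negatives, cfg) == []

    def test_planted_cue_recovery(self, trained_setup):
        model, examples, gold, _ = trained_setup
        positives = [e for e in examples if e.label == "positive"]
        cfg = AttributionConfig(method="shap", samples=15, seed=0)
        triggers = detect_triggers(model, positives, cfg)
        assert triggers
        hits = total = 0
        for t in triggers:
            spans = gold.gold_for(t.doc_id, t.e1, t.e2)
            if spans is None:
                continue
            total += 1
            hits += any(t.span[0] < e and t.span[1] > s for s, e in spans)
        assert total > 10
        assert hits / total >= 0.8

    def test_prediction_set_sweep_counts(self, trained_setup):
        # 2-layer encoder: LIG over embedding + 2 hidden layers, SHAP with
        # and without boundary tokens -> 3 + 2 = 5 prediction sets
        model, examples, _, _ = trained_setup
        positives = [e for e in examples if e.label == "positive"][:5]
        configs = [
            AttributionConfig(method="lig", layer=l, steps=16)
            for l in range(model.classifier.n_layers + 1)
        ] + [
            AttributionConfig(method="shap", samples=8, seed=0, include_boundary=False),
            AttributionConfig(method="shap", samples=8, seed=0, include_boundary=True),
        ]
        assert len(configs) == 5
        sets = [tuple(t.span for t in detect_triggers(model, positives, c)) for c in configs]
        assert all(len(s) == len(sets[0]) for s in sets)

    def test_determinism_across_runs(self, trained_setup):
        model, examples, _, _ = trained_setup
        positives = [e for e in examples if e.label == "positive"][:8]
        for cfg in (
            AttributionConfig(method="lig", layer=1, steps=16),
            AttributionConfig(method="shap", samples=10, seed=7),
        ):
            a = detect_triggers(model, positives, cfg)
            b = detect_triggers(model, positives, cfg)
            assert [t.span for t in a] == [t.span for t in b]


class TestBaselineTriggerMatch:
    def test_lexicon_hit_in_window(self, trained_setup):
        _, examples, gold, by_id = trained_setup
        ex = next(
            e for e in examples
            if e.label == "positive" and gold.gold_for(e.doc_id, e.e1, e.e2)
            and "binds" in e.tokens
        )
        text = by_id[ex.doc_id].text
        spans = baseline_trigger_match(ex, text, ["binds"], window_size=6)
        assert any(text[s:e] == "binds" for s, e in spans)

    def test_window_too_small_no_hit(self, trained_setup):
        _, examples, _, by_id = trained_setup
        ex = examples[0]
        text = by_id[ex.doc_id].text
        spans = baseline_trigger_match(ex, text, ["notpresentword"], window_size=1)
        assert spans == []

    def test_longest_match_reported_once(self, trained_setup):
        _, examples, gold, by_id = trained_setup
        ex = next(
            e for e in examples
            if e.label == "positive"
            and any(
                by_id[e.doc_id].text[s:t] == "interacts with"
                for s, t in (gold.gold_for(e.doc_id, e.e1, e.e2) or ())
            )
        )
        text = by_id[ex.doc_id].text
        spans = baseline_trigger_match(
            ex, text, ["interacts", "interacts with"], window_size=8
        )
        covered = [text[s:e] for s, e in spans]
        assert "interacts with" in covered
        assert "interacts" not in covered

    def test_empty_lexicon(self, trained_setup):
        _, examples, _, by_id = trained_setup
        ex = examples[0]
        assert baseline_trigger_match(ex, by_id[ex.doc_id].text, [], 4) == []

    def test_bad_window_size(self, trained_setup):
        _, examples, _, by_id = trained_setup
        with pytest.raises(ValueError):
            baseline_trigger_match(examples[0], by_id[examples[0].doc_id].text, ["x"], 0)


def test_attribution_config_validation():
    with pytest.raises(ValueError):
        AttributionConfig(method="saliency")
    with pytest.raises(ValueError):
        AttributionConfig(steps=4)
    with pytest.raises(ValueError):
        AttributionConfig(samples=0)
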