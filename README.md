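# relexplain

Relation extraction over BRAT standoff corpora with attribution-based
trigger-word detection.

The package implements a complete desk-scale pipeline:

1. **`relexplain.brat`** — read/write BRAT standoff (`.txt`/`.ann`) documents
   (entities, undirected binary relations, attributes, Equiv alias groups,
   discontinuous spans) and compute corpus statistics.
2. **`relexplain.corpus_prep`** — entity filtering for the prediction regime
   (keep non-Blocklisted protein mentions only), document-level splits, and
   construction of the trigger development/test pair sets.
3. **`relexplain.examples`** — turn every candidate mention pair into a
   model-ready token window by *marking* (reserved begin/end tokens around
   both mentions) or *masking* (reserved placeholder per mention), with a
   full offset correspondence back to document characters.  No sentence
   splitting: cross-sentence pairs are windowed like any other.
4. **`relexplain.relation_clf`** — binary softmax classifier on top of a
   small trainable transformer encoder (pure numpy, custom reverse-mode
   autodiff in `relexplain.nn`), with best-epoch selection, seeded repeats
   and grid search.
5. **`relexplain.attrib`** — unsupervised trigger detection for
   positive-predicted pairs: layer integrated gradients (LIG) and
   permutation-sampled Shapley values over the positive-class logit margin,
   post-processing heuristics, argmax span selection widened to whole
   words, and a regex/lexicon window baseline.
6. **`relexplain.trigger_eval`** — four-mode span matching (left-bound,
   right-bound, overlap, exact) with alternative-span groups and both
   penalizing / non-penalizing accounting.
7. **`relexplain.synth`** — deterministic synthetic standoff corpora with
   planted relations, trigger cues, distractors, Blocklisted mentions,
   Equiv aliases and cross-sentence relations, plus an end-to-end recovery
   harness.

Everything runs on a single CPU; no pretrained weights or network access
are required (the encoder is tiny and trained from scratch on the synthetic
corpora).

## CLI

```bash
relexplain synth --n-docs 100 --seed 1 --out runs/synth      # corpus + gold triggers
relexplain stats runs/synth/corpus                           # corpus statistics
relexplain filter runs/synth/corpus --out runs/filtered      # prediction regime
relexplain split runs/synth/corpus --out runs/splits --seed 1
relexplain build-vocab runs/synth/corpus --out runs/vocab.json
relexplain build-examples runs/synth/corpus --vocab runs/vocab.json \
    --scheme mark --msl 64 --out runs/examples.jsonl
relexplain train --train-examples runs/examples.jsonl \
    --dev-examples runs/examples.jsonl --vocab runs/vocab.json \
    --msl 64 --learning-rate 3e-3 --epochs 8 --out runs/model
relexplain predict  --model runs/model --examples runs/examples.jsonl --out runs/preds.tsv
relexplain evaluate --model runs/model --examples runs/examples.jsonl
relexplain triggers --model runs/model --examples runs/examples.jsonl \
    --method lig --layer 1 --out runs/triggers.tsv
relexplain eval-triggers --triggers runs/triggers.tsv \
    --gold runs/synth/gold_triggers.tsv --penalize off
relexplain trigger-sets runs/splits/dev --vocab runs/vocab.json --msl 128 --out runs/trigsets
relexplain e2e --n-docs 120 --epochs 8 --seed 1                # full synthetic round trip
relexplain run pipeline.yaml                                   # multi-stage YAML driver
```

## Design notes

* The encoder (`tiny-<L>l-<D>d[-<H>h]` identifiers) is a post-LN
  transformer with learned absolute position embeddings plus a clipped
  relative-position attention bias; the decision layer pools the
  snippet-start token together with the encoder outputs at the two entity
  anchor positions.
* Attribution explains the positive-class logit margin (log-odds) rather
  than the softmax probability, which saturates on confident predictions.
* LIG uses a midpoint Riemann rule over a pad-token baseline whose
  attention mask is kept from the original input; Shapley values use
  permutation sampling with a pad-masking value function.
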