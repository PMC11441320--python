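"""Sub-word tokenizer with character offsets and reserved placeholder tokens.

A greedy longest-match WordPiece-style tokenizer whose vocabulary is built
from a corpus.  In-vocabulary words become single tokens; out-of-vocabulary
words are split into pieces (continuations carry the ``##`` prefix), with
single characters always present so no word ever falls back to ``[UNK]``
unless it contains a character unseen at vocabulary-build time.

Reserved entries ``[unused1]`` .. ``[unused8]`` are atomic at
pre-tokenization and are used by the example builder as entity
markers/masks.
"""

from __future__ import annotations

import json
import re
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

PAD, UNK, CLS, SEP = "[PAD]", "[UNK]", "[CLS]", "[SEP]"
N_UNUSED = 8
UNUSED = tuple(f"[unused{i}]" for i in range(1, N_UNUSED + 1))
SPECIAL_TOKENS = (PAD, UNK, CLS, SEP) + UNUSED

_PRETOKEN_RE = re.compile(r"\[unused\d+\]|\w+|[^\w\s]")


@dataclass(frozen=True)
class Token:
    text: str
    id: int
    start: int  # character offsets into the tokenized string, half-open
    end: int
    word_index: int  # pieces of one pre-token share this index

    @property
    def is_special(self) -> bool:
        return self.text in SPECIAL_TOKENS

    @property
    def is_continuation(self) -> bool:
        return self.text.startswith("##") and self.text not in SPECIAL_TOKENS


def pretokenize(text: str) -> list[tuple[str, int, int]]:
    """Split into words / punctuation marks / reserved tokens with offsets."""
    return [(m.group(0), m.start(), m.end()) for m in _PRETOKEN_RE.finditer(text)]


class WordPieceTokenizer:
    def __init__(self, vocab: Sequence[str]):
        for i, tok in enumerate(SPECIAL_TOKENS):
            if vocab[i] != tok:
                raise ValueError(f"vocab slot {i} must be {tok!r}, got {vocab[i]!r}")
        self.vocab = list(vocab)
        self.token_to_id = {t: i for i, t in enumerate(self.vocab)}
        if len(self.token_to_id) != len(self.vocab):
            raise ValueError("duplicate vocabulary entries")
        self._max_piece_len = max((len(t) for t in self.vocab), default=1)

    # -- construction ------------------------------------------------------

    @classmethod
    def train(
        cls,
        texts: Iterable[str],
        min_word_freq: int = 2,
        max_vocab: int = 20000,
    ) -> "WordPieceTokenizer":
        """Build a vocabulary: frequent whole words + all seen characters."""
        counts: Counter[str] = Counter()
        chars: set[str] = set()
        for text in texts:
            for w, _, _ in pretokenize(text):
                if w in SPECIAL_TOKENS:
                    continue
                counts[w] += 1
                chars.update(w)
        vocab = list(SPECIAL_TOKENS)
        for c in sorted(chars):
            vocab.append(c)
            vocab.append(f"##{c}")
        present = set(vocab)
        # deterministic order: frequency desc, then lexicographic
        for w, n in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0])):
            if n < min_word_freq or len(vocab) >= max_vocab:
                break
            if w not in present:
                vocab.append(w)
                present.add(w)
        return cls(vocab)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps({"vocab": self.vocab}, ensure_ascii=False), encoding="utf-8"
        )

    @classmethod
    def load(cls, path: str | Path) -> "WordPieceTokenizer":
        data = json.loads(Path(path).read_text(encoding="utf-8"))
        return cls(data["vocab"])

    # -- properties --------------------------------------------------------

    def __len__(self) -> int:
        return len(self.vocab)

    @property
    def pad_id(self) -> int:
        return self.token_to_id[PAD]

    @property
    def unk_id(self) -> int:
        return self.token_to_id[UNK]

    @property
    def cls_id(self) -> int:
        return self.token_to_id[CLS]

    @property
    def sep_id(self) -> int:
        return self.token_to_id[SEP]

    def unused_id(self, i: int) -> int:
        """1-based reserved-token id lookup."""
        return self.token_to_id[f"[unused{i}]"]

    @property
    def special_ids(self) -> frozenset[int]:
        return frozenset(self.token_to_id[t] for t in SPECIAL_TOKENS)

    # -- tokenization ------------------------------------------------------

    def _split_word(self, word: str, start: int, word_index: int) -> list[Token]:
        wid = self.token_to_id.get(word)
        if wid is not None:
            return [Token(word, wid, start, start + len(word), word_index)]
        pieces: list[Token] = []
        pos = 0
        while pos < len(word):
            prefix = "##" if pos > 0 else ""
            end = min(len(word), pos + self._max_piece_len)
            piece_id = None
            while end > pos:
                cand = prefix + word[pos:end]
                piece_id = self.token_to_id.get(cand)
                if piece_id is not None:
                    break
                end -= 1
            if piece_id is None:  # character unseen at build time
                return [Token(UNK, self.unk_id, start, start + len(word), word_index)]
            pieces.append(
                Token(prefix + word[pos:end], piece_id, start + pos, start + end, word_index)
            )
            pos = end
        return pieces

    def tokenize(self, text: str) -> list[Token]:
        tokens: list[Token] = []
        for word_index, (w, s, _) in enumerate(pretokenize(text)):
            if w in SPECIAL_TOKENS:
                tokens.append(Token(w, self.token_to_id[w], s, s + len(w), word_index))
            else:
                tokens.extend(self._split_word(w, s, word_index))
        return tokens

    def encode(self, text: str) -> list[int]:
        return [t.id for t in self.tokenize(text)]
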