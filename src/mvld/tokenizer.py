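"""Whitespace tokenizer over a fixed plain-text vocabulary.

The vocabulary file lists one token per line with the special tokens first.
Captions are lower-cased, split on whitespace, wrapped in [CLS] ... [SEP]
and padded with [PAD] to a fixed length; unknown words map to [UNK].
"""

from __future__ import annotations

from pathlib import Path
from typing import List, Sequence

import numpy as np

SPECIAL_TOKENS = ("[PAD]", "[CLS]", "[SEP]", "[MASK]", "[UNK]")


class Vocabulary:
    def __init__(self, tokens: Sequence[str]):
        tokens = list(tokens)
        for i, s in enumerate(SPECIAL_TOKENS):
            if i >= len(tokens) or tokens[i] != s:
                raise ValueError(
                    f"vocabulary must begin with the special tokens {SPECIAL_TOKENS}")
        if len(set(tokens)) != len(tokens):
            raise ValueError("vocabulary contains duplicate tokens")
        self.tokens = tokens
        self.token_to_id = {t: i for i, t in enumerate(tokens)}

    @classmethod
    def load(cls, path) -> "Vocabulary":
        lines = Path(path).read_text().splitlines()
        return cls([ln for ln in lines if ln])

    def save(self, path):
        Path(path).write_text("\n".join(self.tokens) + "\n")

    def __len__(self):
        return len(self.tokens)

    @property
    def pad_id(self) -> int:
        return self.token_to_id["[PAD]"]

    @property
    def cls_id(self) -> int:
        return self.token_to_id["[CLS]"]

    @property
    def sep_id(self) -> int:
        return self.token_to_id["[SEP]"]

    @property
    def mask_id(self) -> int:
        return self.token_to_id["[MASK]"]

    @property
    def unk_id(self) -> int:
        return self.token_to_id["[UNK]"]

    @property
    def special_ids(self) -> set:
        return {self.token_to_id[t] for t in SPECIAL_TOKENS}

    def encode(self, text: str, max_len: int) -> np.ndarray:
        words = text.lower().split()
        ids = [self.cls_id]
        for w in words[: max_len - 2]:
            ids.append(self.token_to_id.get(w, self.unk_id))
        ids.append(self.sep_id)
        ids.extend([self.pad_id] * (max_len - len(ids)))
        return np.asarray(ids, dtype=np.int64)

    def encode_batch(self, texts: Sequence[str], max_len: int) -> np.ndarray:
        return np.stack([self.encode(t, max_len) for t in texts])

    def decode(self, ids) -> List[str]:
        return [self.tokens[int(i)] for i in ids]
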