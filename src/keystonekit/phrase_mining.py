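"""N-gram phrase frequency tables and word-cloud weights.

Consumes noun/noun-phrase lists (one phrase per line, tokenised with the
shared tokenizer) and counts overlapping sliding-window n-grams within each
phrase — n-grams never span across separate input phrases.  Word-cloud
weights are raw frequencies (the rendering size is directly proportional to
frequency; proportionality constant 1, rendering left to consumers).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

from .io_formats import tokenize

N_MIN, N_MAX = 2, 7


@dataclass
class PhraseFrequencyTable:
    n: int
    counts: dict[str, int]  # phrase (space-joined tokens) -> count
    total_tokens: int

    def total_ngrams(self) -> int:
        return sum(self.counts.values())

    def sorted_items(self) -> list[tuple[str, int]]:
        return sorted(self.counts.items(), key=lambda kv: (-kv[1], kv[0]))


def _as_token_lists(phrases: Iterable[str | Sequence[str]]) -> list[list[str]]:
    out = []
    for p in phrases:
        out.append(tokenize(p) if isinstance(p, str) else [str(t).lower() for t in p])
    return out


def ngram_frequencies(
    phrases: Iterable[str | Sequence[str]], n: int, n_max: int = N_MAX
) -> PhraseFrequencyTable:
    """Overlapping n-gram counts within each phrase, 2 <= n <= n_max."""
    if not N_MIN <= n <= n_max:
        raise ValueError(f"n must lie in [{N_MIN}, {n_max}], got {n}")
    counts: Counter = Counter()
    total_tokens = 0
    for tokens in _as_token_lists(phrases):
        total_tokens += len(tokens)
        for i in range(len(tokens) - n + 1):
            counts[" ".join(tokens[i : i + n])] += 1
    return PhraseFrequencyTable(n=n, counts=dict(counts), total_tokens=total_tokens)


def wordcloud_weights(words: Iterable[str | Sequence[str]]) -> dict[str, int]:
    """Word -> raw frequency over the flattened token stream."""
    counts: Counter = Counter()
    for tokens in _as_token_lists(words):
        counts.update(tokens)
    if not counts:
        raise ValueError("empty input")
    return dict(sorted(counts.items(), key=lambda kv: (-kv[1], kv[0])))
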