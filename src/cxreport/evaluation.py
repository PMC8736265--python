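"""BLEU-n scoring and the normality keyword rule.

BLEU-n is the brevity-penalised geometric mean of clipped (modified)
n-gram precisions:

    BLEU = BP * exp(sum_n w_n * ln p_n),   BP = min(1, e^(1 - r/c))

where ``c`` is the candidate length, ``r`` the closest reference length,
and ``p_n`` the ratio of candidate n-grams that also occur in a reference,
with each n-gram's count clipped at its maximum reference count.  The four
cumulative weightings used here are (1,0,0,0), (0.5,0.5,0,0),
(0.33,0.33,0.33,0) and (0.25,0.25,0.25,0.25).  No smoothing is applied by
default, so a zero precision at any weighted order gives a score of 0; an
optional epsilon floor exists because short clinical sentences frequently
zero out the higher orders.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

BLEU_WEIGHTS = {
    1: (1.0, 0.0, 0.0, 0.0),
    2: (0.5, 0.5, 0.0, 0.0),
    3: (0.33, 0.33, 0.33, 0.0),
    4: (0.25, 0.25, 0.25, 0.25),
}
THIRDS_WEIGHTS = (1 / 3, 1 / 3, 1 / 3, 0.0)

NORMALITY_KEYWORDS = frozenset({"no", "normal", "clear", "stable"})


@dataclass
class BleuResult:
    bleu1: float
    bleu2: float
    bleu3: float
    bleu4: float
    brevity_penalty: float
    precisions: tuple[float, float, float, float]

    def __getitem__(self, n: int) -> float:
        return (self.bleu1, self.bleu2, self.bleu3, self.bleu4)[n - 1]


def _ngrams(tokens: Sequence[str], n: int) -> Counter:
    return Counter(tuple(tokens[i : i + n]) for i in range(len(tokens) - n + 1))


def _clipped_counts(
    candidate: Sequence[str], references: Sequence[Sequence[str]], n: int
) -> tuple[int, int]:
    """(clipped matching n-grams, total candidate n-grams)."""
    cand = _ngrams(candidate, n)
    if not cand:
        return 0, 0
    max_ref: Counter = Counter()
    for ref in references:
        for gram, cnt in _ngrams(ref, n).items():
            max_ref[gram] = max(max_ref[gram], cnt)
    clipped = sum(min(cnt, max_ref[gram]) for gram, cnt in cand.items())
    return clipped, sum(cand.values())


def _closest_ref_length(c: int, references: Sequence[Sequence[str]]) -> int:
    """Reference length closest to the candidate's; ties prefer the shorter."""
    return min((abs(len(r) - c), len(r)) for r in references)[1]


def _combine(
    counts: list[tuple[int, int]], c: int, r: int, smooth_eps: float
) -> BleuResult:
    precisions = []
    for clipped, total in counts:
        if total == 0:
            precisions.append(0.0)
        else:
            p = clipped / total
            if p == 0.0 and smooth_eps > 0:
                p = smooth_eps
            precisions.append(p)
    bp = min(1.0, np.exp(1.0 - r / c)) if c > 0 else 0.0
    scores = []
    for order in (1, 2, 3, 4):
        w = BLEU_WEIGHTS[order]
        if any(precisions[i] == 0.0 for i in range(4) if w[i] > 0):
            scores.append(0.0)
            continue
        log_mean = sum(w[i] * np.log(precisions[i]) for i in range(4) if w[i] > 0)
        scores.append(float(bp * np.exp(log_mean)))
    return BleuResult(*scores, brevity_penalty=float(bp),
                      precisions=tuple(precisions))


def bleu(
    candidate: Sequence[str],
    references: Sequence[Sequence[str]],
    smooth_eps: float = 0.0,
    exact_thirds: bool = False,
) -> BleuResult:
    """Sentence-level BLEU-1..4 with the cumulative weight vectors.

    ``exact_thirds`` swaps the printed (0.33, 0.33, 0.33) third-order
    weights for exact 1/3 values.
    """
    if not references or not any(len(r) for r in references):
        raise ValueError("at least one non-empty reference is required")
    if not candidate:
        warnings.warn("empty candidate: all BLEU scores are 0", stacklevel=2)
        return BleuResult(0.0, 0.0, 0.0, 0.0, 0.0, (0.0,) * 4)
    counts = [_clipped_counts(candidate, references, n) for n in (1, 2, 3, 4)]
    c = len(candidate)
    r = _closest_ref_length(c, references)
    result = _combine(counts, c, r, smooth_eps)
    if exact_thirds:
        result = _reweigh_thirds(result)
    return result


def _reweigh_thirds(res: BleuResult) -> BleuResult:
    p = res.precisions
    if all(p[i] > 0 for i in range(3)):
        b3 = res.brevity_penalty * float(
            np.exp(sum(THIRDS_WEIGHTS[i] * np.log(p[i]) for i in range(3)))
        )
    else:
        b3 = 0.0
    return BleuResult(res.bleu1, res.bleu2, b3, res.bleu4,
                      res.brevity_penalty, p)


def corpus_bleu(
    pairs: Sequence[tuple[Sequence[str], Sequence[Sequence[str]]]],
    smooth_eps: float = 0.0,
) -> BleuResult:
    """Corpus-level BLEU: counts and lengths pooled over all pairs.

    Each pair is ``(candidate_tokens, [reference_tokens, ...])``.  Clipped
    and total n-gram counts are summed over pairs before the precisions are
    formed, and the brevity penalty uses summed candidate and closest-
    reference lengths — so one bad sentence dilutes rather than zeroes the
    corpus score.
    """
    if not pairs:
        raise ValueError("at least one candidate/reference pair is required")
    totals = {n: [0, 0] for n in (1, 2, 3, 4)}
    c_len = r_len = 0
    for candidate, references in pairs:
        if not references:
            raise ValueError("every pair needs at least one reference")
        if not candidate:
            r_len += min(len(r) for r in references)
            continue
        for n in (1, 2, 3, 4):
            clipped, total = _clipped_counts(candidate, references, n)
            totals[n][0] += clipped
            totals[n][1] += total
        c_len += len(candidate)
        r_len += _closest_ref_length(len(candidate), references)
    counts = [tuple(totals[n]) for n in (1, 2, 3, 4)]
    return _combine(counts, c_len, r_len, smooth_eps)


def label_normality(
    sentence: Sequence[str], keywords: frozenset[str] = NORMALITY_KEYWORDS
) -> str:
    """'normal' iff any keyword appears in the (preprocessed) sentence."""
    return "normal" if any(tok in keywords for tok in sentence) else "abnormal"
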