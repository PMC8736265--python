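"""Report generation: greedy (argmax) sampling and beam search.

Generation starts from the image injection at t = -1 followed by the
``startseq`` sentinel; tokens are emitted one at a time until ``endseq``
appears or the length cap is reached.  Greedy decoding takes the argmax at
every step (ties broken toward the lowest token id); beam search keeps the
``k`` best partial hypotheses by summed log-probability, retiring completed
hypotheses into the candidate pool.  ``k = 1`` reproduces greedy decoding
exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .attention import AttentionResult
from .corpus import END_ID, START_ID, Vocabulary, decode_ids
from .decoder import DecoderParams, DecoderState, decode_step, init_state
from .encoder import FeatureGrid

LOGP_EPS = 1e-300   # floor before log; far below any reachable softmax value


@dataclass
class GenerationResult:
    token_ids: list[int]                       # emitted word ids, no sentinels
    words: list[str]
    log_prob: float                            # summed log p of emitted ids + end
    attention: list[AttentionResult | None]
    truncated: bool = False

    @property
    def report(self) -> str:
        return " ".join(self.words)


def _argmax_lowest(p: np.ndarray) -> int:
    """Argmax with ties broken toward the lowest token id (determinism)."""
    return int(np.argmax(p))  # np.argmax already returns the first maximum


def greedy_sample(
    features: FeatureGrid,
    params: DecoderParams,
    vocab: Vocabulary,
    max_len: int,
) -> GenerationResult:
    """Iterative argmax decoding with per-step attention weights."""
    if max_len < 2:
        raise ValueError("max_len must be >= 2")
    state = init_state(features, params)
    prev = START_ID
    ids: list[int] = []
    att: list[AttentionResult | None] = []
    logp = 0.0
    truncated = False
    for _ in range(max_len - 1):
        out = decode_step(prev, state, features, params)
        tok = _argmax_lowest(out.p_next) + 1
        logp += float(np.log(max(out.p_next[tok - 1], LOGP_EPS)))
        att.append(out.attention)
        state = out.state
        prev = tok
        if tok == END_ID:
            break
        ids.append(tok)
    else:
        truncated = True
    words = [vocab.token(i) for i in ids]
    return GenerationResult(ids, words, logp, att, truncated)


@dataclass
class _Hypothesis:
    ids: tuple[int, ...]
    logp: float
    state: DecoderState
    attention: list[AttentionResult | None]
    done: bool = False


def beam_search(
    features: FeatureGrid,
    params: DecoderParams,
    vocab: Vocabulary,
    k: int,
    max_len: int,
    length_normalise: bool = False,
) -> GenerationResult:
    """Breadth-limited search over summed log-probabilities.

    At each length, every live hypothesis is extended by all vocabulary
    words; the best ``k`` survive (score ties broken by token-id order).
    Hypotheses that emit ``endseq`` retire into the completed pool.  The
    returned sequence maximises summed log-probability (optionally divided
    by length when ``length_normalise``).
    """
    if k < 1:
        raise ValueError("beam width k must be >= 1")
    if max_len < 2:
        raise ValueError("max_len must be >= 2")
    state0 = init_state(features, params)
    live = [_Hypothesis(ids=(), logp=0.0, state=state0, attention=[])]
    completed: list[_Hypothesis] = []

    for step_no in range(max_len - 1):
        candidates: list[_Hypothesis] = []
        for hyp in live:
            prev = hyp.ids[-1] if hyp.ids else START_ID
            out = decode_step(prev, hyp.state, features, params)
            logs = np.log(np.maximum(out.p_next, LOGP_EPS))
            for tok_idx in range(len(logs)):
                tok = tok_idx + 1
                candidates.append(
                    _Hypothesis(
                        ids=hyp.ids + (tok,),
                        logp=hyp.logp + float(logs[tok_idx]),
                        state=out.state,
                        attention=hyp.attention + [out.attention],
                    )
                )
        # ties: higher logp first, then lexicographically smaller id tuple
        candidates.sort(key=lambda h: (-h.logp, h.ids))
        live = []
        for cand in candidates:
            if len(live) >= k:
                break
            if cand.ids[-1] == END_ID:
                cand.done = True
                completed.append(cand)
                # a completed hypothesis still occupies a beam slot this step
                live.append(cand)
            else:
                live.append(cand)
        live = [h for h in live if not h.done]
        if not live:
            break

    pool = completed + live  # unfinished hypotheses compete if nothing ended
    if not pool:
        raise RuntimeError("beam search produced no hypotheses")

    def score(h: _Hypothesis) -> float:
        n = max(len(h.ids), 1)
        return h.logp / n if length_normalise else h.logp

    pool.sort(key=lambda h: (-score(h), h.ids))
    best = pool[0]
    ids = [i for i in best.ids if i != END_ID]
    words = [vocab.token(i) for i in ids]
    return GenerationResult(
        token_ids=ids,
        words=words,
        log_prob=best.logp,
        attention=best.attention,
        truncated=not best.done,
    )


def rescore_sequence(
    features: FeatureGrid,
    params: DecoderParams,
    token_ids: list[int],
    include_end: bool = True,
) -> float:
    """Summed log-probability of an emitted id sequence under the model.

    Used as a self-consistency check: the probability reported by the
    search must equal re-driving ``decode_step`` over the same ids.
    """
    state = init_state(features, params)
    prev = START_ID
    total = 0.0
    seq = list(token_ids) + ([END_ID] if include_end else [])
    for tok in seq:
        out = decode_step(prev, state, features, params)
        total += float(np.log(max(out.p_next[tok - 1], LOGP_EPS)))
        state = out.state
        prev = tok
    return total
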