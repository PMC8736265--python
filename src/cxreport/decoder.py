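"""LSTM sentence decoder: gate equations, per-step vocabulary distribution.

The cell follows the plain gated form

    i_t = sigmoid(W_ix x_t + W_im m_{t-1})
    f_t = sigmoid(W_fx x_t + W_fm m_{t-1})
    o_t = sigmoid(W_ox x_t + W_om m_{t-1})
    c_t = f_t * c_{t-1} + i_t * tanh(W_cx x_t + W_cm m_{t-1})
    m_t = o_t * c_t                     (optionally o_t * tanh(c_t))

with no bias terms inside the gates.  The per-step input x_t is the
concatenation of the previous word's embedding and the attention context;
the image is injected once, at step t = -1, through the embedding slot with
the context slot zero-filled.  m_t feeds an affine vocabulary head followed
by a softmax.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .attention import AttentionParams, AttentionResult, attend
from .corpus import END_ID, PAD_ID
from .encoder import FeatureGrid


def sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def softmax(logits: np.ndarray) -> np.ndarray:
    z = np.exp(logits - logits.max(axis=-1, keepdims=True))
    return z / z.sum(axis=-1, keepdims=True)


@dataclass
class LSTMParams:
    """Gate weight matrices; ``*_x`` are input-side (x_dim x H), ``*_m``
    recurrent (H x H)."""

    w_ix: np.ndarray
    w_im: np.ndarray
    w_fx: np.ndarray
    w_fm: np.ndarray
    w_ox: np.ndarray
    w_om: np.ndarray
    w_cx: np.ndarray
    w_cm: np.ndarray

    def __post_init__(self) -> None:
        h = self.w_im.shape[0]
        x = self.w_ix.shape[0]
        for name in ("w_ix", "w_fx", "w_ox", "w_cx"):
            if getattr(self, name).shape != (x, h):
                raise ValueError(f"{name} must be {x} x {h}")
        for name in ("w_im", "w_fm", "w_om", "w_cm"):
            if getattr(self, name).shape != (h, h):
                raise ValueError(f"{name} must be {h} x {h}")

    @property
    def hidden_dim(self) -> int:
        return self.w_im.shape[0]

    @property
    def input_dim(self) -> int:
        return self.w_ix.shape[0]


@dataclass
class DecoderState:
    """Cell memory ``c`` and emitted output ``m`` at one timestep."""

    c: np.ndarray
    m: np.ndarray

    def __post_init__(self) -> None:
        if self.c.shape != self.m.shape:
            raise ValueError("c and m must have the same width")
        if not (np.isfinite(self.c).all() and np.isfinite(self.m).all()):
            raise ValueError("non-finite decoder state")


@dataclass
class StepOutput:
    p_next: np.ndarray          # length-V distribution over word ids 1..V
    state: DecoderState
    attention: AttentionResult | None


def lstm_step(
    x_t: np.ndarray,
    state: DecoderState,
    params: LSTMParams,
    output_tanh: bool = False,
) -> DecoderState:
    """One application of the gate equations."""
    if x_t.shape[-1] != params.input_dim:
        raise ValueError(
            f"input width {x_t.shape[-1]} != expected {params.input_dim}"
        )
    i = sigmoid(x_t @ params.w_ix + state.m @ params.w_im)
    f = sigmoid(x_t @ params.w_fx + state.m @ params.w_fm)
    o = sigmoid(x_t @ params.w_ox + state.m @ params.w_om)
    g = np.tanh(x_t @ params.w_cx + state.m @ params.w_cm)
    c = f * state.c + i * g
    m = o * (np.tanh(c) if output_tanh else c)
    return DecoderState(c=c, m=m)


@dataclass
class DecoderParams:
    """Everything the decoder needs beyond the image features."""

    embedding: np.ndarray        # (V+1) x E, row 0 (pad) unused
    lstm: LSTMParams
    attn: AttentionParams
    w_out: np.ndarray            # H x V
    b_out: np.ndarray            # V
    use_attention: bool = True
    output_tanh: bool = False

    @property
    def vocab_size(self) -> int:
        return self.w_out.shape[1]

    @property
    def embed_dim(self) -> int:
        return self.embedding.shape[1]

    @property
    def context_dim(self) -> int:
        return self.lstm.input_dim - self.embed_dim


def init_state(features: FeatureGrid, params: DecoderParams) -> DecoderState:
    """Image injection at t = -1.

    The pooled image vector enters through the embedding slot of x, the
    context slot is zero-filled (there is no query state yet), and one
    lstm_step runs from the zero state.  No token is emitted.
    """
    h = params.lstm.hidden_dim
    x = np.concatenate([features.pooled.reshape(-1), np.zeros(params.context_dim)])
    zero = DecoderState(c=np.zeros(h), m=np.zeros(h))
    return lstm_step(x, zero, params.lstm, params.output_tanh)


def vocab_distribution(m: np.ndarray, params: DecoderParams) -> np.ndarray:
    """Affine head + softmax over word ids 1..V (index v-1 is word id v)."""
    return softmax(m @ params.w_out + params.b_out)


def decode_step(
    prev_token_id: int,
    state: DecoderState,
    features: FeatureGrid,
    params: DecoderParams,
) -> StepOutput:
    """One generation step: embed, attend with query m_{t-1}, recur, predict."""
    if not 1 <= prev_token_id <= params.embedding.shape[0] - 1 or prev_token_id == PAD_ID:
        raise ValueError(f"invalid token id {prev_token_id}")
    e = params.embedding[prev_token_id]
    if params.use_attention:
        att = attend(features.locations, state.m, params.attn)
        ctx = att.context
    else:
        att = None
        ctx = np.zeros(params.context_dim)
    x = np.concatenate([e, ctx])
    new_state = lstm_step(x, state, params.lstm, params.output_tanh)
    return StepOutput(
        p_next=vocab_distribution(new_state.m, params),
        state=new_state,
        attention=att,
    )
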