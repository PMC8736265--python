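import math

import numpy as np
import pytest

from cxreport.attention import attend
from cxreport.corpus import START_ID
from cxreport.decoder import (
    DecoderState,
    LSTMParams,
    decode_step,
    init_state,
    lstm_step,
    softmax,
    vocab_distribution,
)
from conftest import make_decoder


def scalar_lstm_oracle(x, c_prev, m_prev, W, output_tanh=False):
    """Independent scalar-loop evaluation of the gate equations."""
    H = len(c_prev)

    def matvec(mat, vec):
        return [sum(mat[i][j] * vec[i] for i in range(len(vec))) for j in range(H)]

    def sig(z):
        return 1.0 / (1.0 + math.exp(-z))

    ai = matvec(W["w_ix"], x)
    am = matvec(W["w_im"], m_prev)
    af = matvec(W["w_fx"], x)
    afm = matvec(W["w_fm"], m_prev)
    ao = matvec(W["w_ox"], x)
    aom = matvec(W["w_om"], m_prev)
    ac = matvec(W["w_cx"], x)
    acm = matvec(W["w_cm"], m_prev)
    c, m = [], []
    for j in range(H):
        i_g = sig(ai[j] + am[j])
        f_g = sig(af[j] + afm[j])
        o_g = sig(ao[j] + aom[j])
        g = math.tanh(ac[j] + acm[j])
        cj = f_g * c_prev[j] + i_g * g
        mj = o_g * (math.tanh(cj) if output_tanh else cj)
        c.append(cj)
        m.append(mj)
    return c, m


def random_lstm(rng, x_dim, h):
    mats = {}
    for g in "ifoc":
        mats[f"w_{g}x"] = rng.normal(size=(x_dim, h))
        mats[f"w_{g}m"] = rng.normal(size=(h, h))
    return LSTMParams(**{k: mats[k] for k in
                         ("w_ix", "w_im", "w_fx", "w_fm", "w_ox", "w_om",
                          "w_cx", "w_cm")})


class TestLstmStep:
    def test_zero_weights_half_gates(self):
        """All-zero weights: every gate is sigmoid(0)=0.5 and tanh write is 0,
        so c' = 0.5*c and m' = 0.25*c."""
        p = LSTMParams(*(np.zeros((1, 1)) for _ in range(8)))
        out = lstm_step(np.zeros(1), DecoderState(c=np.ones(1), m=np.zeros(1)), p)
        assert np.allclose(out.c, 0.5) and np.allclose(out.m, 0.25)

    def test_zero_everything_stays_zero(self, rng):
        p = random_lstm(rng, 3, 2)
        out = lstm_step(np.zeros(3), DecoderState(c=np.zeros(2), m=np.zeros(2)), p)
        assert np.allclose(out.c, 0) and np.allclose(out.m, 0)

    @pytest.mark.parametrize("output_tanh", [False, True])
    @pytest.mark.parametrize("seed", range(5))
    def test_matches_scalar_oracle(self, seed, output_tanh):
        rng = np.random.default_rng(seed)
        h = int(rng.integers(1, 5))
        x_dim = int(rng.integers(1, 6))
        p = random_lstm(rng, x_dim, h)
        x = rng.normal(size=x_dim)
        st = DecoderState(c=rng.normal(size=h), m=rng.normal(size=h))
        out = lstm_step(x, st, p, output_tanh=output_tanh)
        W = {k: getattr(p, k).tolist() for k in
             ("w_ix", "w_im", "w_fx", "w_fm", "w_ox", "w_om", "w_cx", "w_cm")}
        c_o, m_o = scalar_lstm_oracle(x.tolist(), st.c.tolist(), st.m.tolist(),
                                      W, output_tanh)
        assert np.allclose(out.c, c_o, atol=1e-10)
        assert np.allclose(out.m, m_o, atol=1e-10)

    def test_shape_mismatch(self, rng):
        p = random_lstm(rng, 3, 2)
        with pytest.raises(ValueError):
            lstm_step(np.zeros(4), DecoderState(c=np.zeros(2), m=np.zeros(2)), p)

    def test_cell_growth_bound(self, rng):
        """|c_t| <= |c_{t-1}| + 1 elementwise: gates are in (0,1) and the
        candidate write is bounded by 1."""
        for seed in range(20):
            r = np.random.default_rng(seed)
            p = random_lstm(r, 4, 3)
            st = DecoderState(c=r.normal(size=3) * 5, m=r.normal(size=3))
            out = lstm_step(r.normal(size=4), st, p)
            assert (np.abs(out.c) <= np.abs(st.c) + 1 + 1e-12).all()


class TestDecodeStep:
    def test_p_next_is_distribution(self, tiny_decoder):
        features, params = tiny_decoder
        st = init_state(features, params)
        out = decode_step(START_ID, st, features, params)
        assert out.p_next.min() >= 0
        assert abs(out.p_next.sum() - 1) < 1e-6

    def test_zero_head_uniform(self, rng):
        features, params = make_decoder(rng)
        params.w_out[:] = 0
        params.b_out[:] = 0
        st = init_state(features, params)
        out = decode_step(START_ID, st, features, params)
        assert np.allclose(out.p_next, 1.0 / params.vocab_size)

    def test_invalid_token_id(self, tiny_decoder):
        features, params = tiny_decoder
        st = init_state(features, params)
        with pytest.raises(ValueError):
            decode_step(0, st, features, params)
        with pytest.raises(ValueError):
            decode_step(99, st, features, params)

    def test_composition_oracle_single_location(self, rng):
        """decode_step equals attention oracle -> lstm oracle -> softmax."""
        features, params = make_decoder(rng, n_vocab=3, n_loc=1)
        st = init_state(features, params)
        out = decode_step(START_ID, st, features, params)

        att = attend(features.locations, st.m, params.attn)
        x = np.concatenate([params.embedding[START_ID], att.context])
        expected_state = lstm_step(x, st, params.lstm)
        expected_p = softmax(expected_state.m @ params.w_out + params.b_out)
        assert np.allclose(out.p_next, expected_p, atol=1e-10)
        assert np.allclose(out.state.c, expected_state.c, atol=1e-10)


class TestInitState:
    def test_zero_pooled_zero_weights(self, rng):
        features, params = make_decoder(rng)
        features.pooled[:] = 0
        for k in ("w_ix", "w_im", "w_fx", "w_fm", "w_ox", "w_om", "w_cx", "w_cm"):
            getattr(params.lstm, k)[:] = 0
        st = init_state(features, params)
        assert np.allclose(st.c, 0) and np.allclose(st.m, 0)

    def test_different_images_different_states(self, rng):
        features, params = make_decoder(rng)
        st1 = init_state(features, params)
        features2, _ = make_decoder(np.random.default_rng(99))
        st2 = init_state(features2, params)
        assert not np.allclose(st1.m, st2.m)

    def test_deterministic(self, tiny_decoder):
        features, params = tiny_decoder
        a, b = init_state(features, params), init_state(features, params)
        assert np.array_equal(a.c, b.c) and np.array_equal(a.m, b.m)


def test_gate_boundedness_property(rng):
    """Gate activations stay strictly inside (0,1) for finite inputs."""
    from cxreport.decoder import sigmoid

    for seed in range(50):
        r = np.random.default_rng(seed)
        z = r.normal(scale=10, size=8)
        s = sigmoid(z)
        assert ((s > 0) & (s < 1)).all()
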