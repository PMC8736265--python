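import numpy as np
import pytest

from cxreport.attention import AttentionParams
from cxreport.corpus import Vocabulary
from cxreport.decoder import DecoderParams, LSTMParams
from cxreport.encoder import FeatureGrid


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_vocab():
    return Vocabulary.from_reports(
        ["the lungs are clear", "opacity in the left upper zone",
         "effusion at the right base"]
    )


def make_decoder(rng, n_vocab=3, embed=4, feat=3, hidden=4, attn=3, n_loc=2,
                 use_attention=True, output_tanh=False, scale=0.5):
    """Random tiny decoder + feature grid for oracle tests.

    ``n_vocab`` counts all ids including the two sentinels, so the smallest
    usable value is 3 (start, end, one word).
    """
    x_dim = embed + feat

    def m(*shape):
        return rng.normal(scale=scale, size=shape)

    params = DecoderParams(
        embedding=m(n_vocab + 1, embed),
        lstm=LSTMParams(
            w_ix=m(x_dim, hidden), w_im=m(hidden, hidden),
            w_fx=m(x_dim, hidden), w_fm=m(hidden, hidden),
            w_ox=m(x_dim, hidden), w_om=m(hidden, hidden),
            w_cx=m(x_dim, hidden), w_cm=m(hidden, hidden),
        ),
        attn=AttentionParams(u=m(feat, attn), w=m(hidden, attn), v=m(attn)),
        w_out=m(hidden, n_vocab),
        b_out=m(n_vocab),
        use_attention=use_attention,
        output_tanh=output_tanh,
    )
    features = FeatureGrid(locations=m(n_loc, feat), pooled=m(1, embed))
    return features, params


@pytest.fixture
def tiny_decoder(rng):
    return make_decoder(rng)
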