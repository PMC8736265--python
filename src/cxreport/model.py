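"""The assembled caption model and its gradients.

``CaptionModel`` wires the frozen convolutional backbone to the trainable
parts — feature projections, word embedding, additive attention, LSTM cell
and vocabulary head — and implements the teacher-forced batched forward
pass plus reverse-mode gradients (backpropagation through time) in plain
numpy.  The single-step functions in :mod:`cxreport.decoder` and
:mod:`cxreport.attention` define the per-step semantics; the batched pass
here is an optimisation of the same computation and is tested against a
composition of those per-step functions.

Parameter layout (shapes; V = vocabulary size, E = embedding width,
D = location-feature width, H = hidden width, A = attention width):

==========  =============  ====================================
key         shape          role
==========  =============  ====================================
w_loc       Cf x D         spatial-map -> location features h_j
w_pool      P x E          penultimate -> pooled image vector
b_pool      E              pooled bias
embed       (V+1) x E      word embedding (row 0 = pad, unused)
attn_u      D x A          attention, location side
attn_w      H x A          attention, query side
attn_v      A              attention energy vector
w_{i,f,o,c}x  (E+D) x H    LSTM input-side gate weights
w_{i,f,o,c}m  H x H        LSTM recurrent gate weights
w_out       H x V          vocabulary head
b_out       V              vocabulary head bias
==========  =============  ====================================
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import corpus as _corpus
from .attention import AttentionParams
from .corpus import PAD_ID, Vocabulary
from .decoder import DecoderParams, LSTMParams
from .encoder import Backbone, EncoderConfig, FeatureGrid, build_backbone

LOSS_EPS = 1e-12  # clamp for -log p reporting when a probability underflows

_GATES = ("i", "f", "o", "c")


@dataclass
class ModelConfig:
    """Architecture + regularisation configuration.

    Defaults mirror the reference design (256-wide embedding/feature space,
    dropout 0.5); the synthetic end-to-end runs shrink ``width`` to keep
    desk-scale training fast.
    """

    backbone: str = "toy"
    embed_dim: int = 256
    hidden_dim: int = 256
    attn_dim: int = 256
    feat_dim: int = 256
    dropout_p: float = 0.5
    use_attention: bool = True
    output_tanh: bool = False
    toy_channels: tuple[int, ...] = (8, 16, 32)
    image_size: int = 64
    seed: int = 0


def _glorot(rng: np.random.Generator, shape: tuple[int, int]) -> np.ndarray:
    limit = np.sqrt(6.0 / (shape[0] + shape[1]))
    return rng.uniform(-limit, limit, size=shape)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


class CaptionModel:
    """Encoder + attention + LSTM caption generator over a fixed vocabulary."""

    def __init__(self, config: ModelConfig, vocab: Vocabulary):
        self.config = config
        self.vocab = vocab
        self.backbone: Backbone = build_backbone(
            EncoderConfig(
                backbone=config.backbone,
                d_out=config.embed_dim,
                dropout_p=config.dropout_p,
                toy_channels=config.toy_channels,
                input_size=config.image_size,
                seed=config.seed,
            )
        )
        self.params = self._init_params(np.random.default_rng(config.seed))

    # ------------------------------------------------------------------ #
    # parameters

    def _init_params(self, rng: np.random.Generator) -> dict[str, np.ndarray]:
        cfg = self.config
        v = len(self.vocab)
        e, d, h, a = cfg.embed_dim, cfg.feat_dim, cfg.hidden_dim, cfg.attn_dim
        cf = self.backbone.spatial_channels
        p = self.backbone.penultimate_width
        x = e + d
        params = {
            "w_loc": _glorot(rng, (cf, d)),
            "w_pool": _glorot(rng, (p, e)),
            "b_pool": np.zeros(e),
            "embed": _glorot(rng, (v + 1, e)),
            "attn_u": _glorot(rng, (d, a)),
            "attn_w": _glorot(rng, (h, a)),
            "attn_v": _glorot(rng, (a, 1))[:, 0],
            "w_out": _glorot(rng, (h, v)),
            "b_out": np.zeros(v),
        }
        for g in _GATES:
            params[f"w_{g}x"] = _glorot(rng, (x, h))
            params[f"w_{g}m"] = _glorot(rng, (h, h))
        return params

    @property
    def decoder_params(self) -> DecoderParams:
        """Single-instance view of the trainable parameters (shared arrays)."""
        p = self.params
        return DecoderParams(
            embedding=p["embed"],
            lstm=LSTMParams(*(p[f"w_{g}{s}"] for g in _GATES for s in "xm")),
            attn=AttentionParams(u=p["attn_u"], w=p["attn_w"], v=p["attn_v"]),
            w_out=p["w_out"],
            b_out=p["b_out"],
            use_attention=self.config.use_attention,
            output_tanh=self.config.output_tanh,
        )

    # ------------------------------------------------------------------ #
    # encoding

    def extract_features(self, images: list[np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
        """Run the frozen backbone over a list of same-sized images.

        Returns stacked ``(spatial, penultimate)`` arrays of shape
        (B, n, Cf) and (B, P).  The backbone is frozen, so callers may cache
        the result across epochs.
        """
        spatials, penults = [], []
        for img in images:
            if img.ndim == 2:
                img = img[:, :, None]
            sp, pen = self.backbone.forward(img)
            hf, wf, cf = sp.shape
            self._grid_shape = (hf, wf)
            spatials.append(sp.reshape(hf * wf, cf))
            penults.append(pen)
        return np.stack(spatials), np.stack(penults)

    def feature_grid(self, spatial: np.ndarray, penult: np.ndarray) -> FeatureGrid:
        """Evaluation-mode FeatureGrid for one image (no dropout)."""
        pooled = np.maximum(penult @ self.params["w_pool"] + self.params["b_pool"], 0.0)
        return FeatureGrid(
            locations=spatial @ self.params["w_loc"],
            pooled=pooled[None, :],
            grid_shape=getattr(self, "_grid_shape", (0, 0)),
        )

    # ------------------------------------------------------------------ #
    # teacher-forced batched forward / backward

    def forward_batch(
        self,
        spatial: np.ndarray,
        penult: np.ndarray,
        tokens: np.ndarray,
        training: bool = False,
        rng: np.random.Generator | None = None,
    ) -> dict:
        """Teacher-forced pass over a padded batch.

        ``tokens`` is (B, L); the token at position t is the input for
        predicting position t+1, so L-1 distributions are produced per
        sequence and positions whose target is padding contribute nothing.
        Returns a dict with ``loss`` (sum over timesteps, mean over batch),
        ``probs`` (B, L-1, V), ``mask``, token ``accuracy`` and the caches
        needed by :meth:`backward`.
        """
        p = self.params
        cfg = self.config
        b, l = tokens.shape
        e_dim, d_dim, h_dim = cfg.embed_dim, cfg.feat_dim, cfg.hidden_dim
        drop = cfg.dropout_p if training else 0.0
        if drop > 0 and rng is None:
            raise ValueError("training-mode dropout needs an rng")

        locs = spatial @ p["w_loc"]                      # (B, n, D)
        if drop > 0:
            pen_mask = (rng.random(penult.shape) >= drop) / (1.0 - drop)
        else:
            pen_mask = np.ones_like(penult)
        pen_d = penult * pen_mask
        pool_pre = pen_d @ p["w_pool"] + p["b_pool"]
        pooled = np.maximum(pool_pre, 0.0)

        lstm_w = {g: (p[f"w_{g}x"], p[f"w_{g}m"]) for g in _GATES}

        def step(x, m_prev, c_prev):
            i = _sigmoid(x @ lstm_w["i"][0] + m_prev @ lstm_w["i"][1])
            f = _sigmoid(x @ lstm_w["f"][0] + m_prev @ lstm_w["f"][1])
            o = _sigmoid(x @ lstm_w["o"][0] + m_prev @ lstm_w["o"][1])
            g = np.tanh(x @ lstm_w["c"][0] + m_prev @ lstm_w["c"][1])
            c = f * c_prev + i * g
            mc = np.tanh(c) if cfg.output_tanh else c
            m = o * mc
            return {"x": x, "i": i, "f": f, "o": o, "g": g, "c": c,
                    "c_prev": c_prev, "m_prev": m_prev, "m": m}

        # image injection at t = -1
        x_init = np.concatenate([pooled, np.zeros((b, d_dim))], axis=1)
        init_cache = step(x_init, np.zeros((b, h_dim)), np.zeros((b, h_dim)))
        m_t, c_t = init_cache["m"], init_cache["c"]

        steps = []
        probs = np.zeros((b, l - 1, len(self.vocab)))
        mask = (tokens[:, 1:] != PAD_ID)
        for t in range(l - 1):
            inp = tokens[:, t]
            emb = p["embed"][inp]
            if drop > 0:
                emb_mask = (rng.random(emb.shape) >= drop) / (1.0 - drop)
            else:
                emb_mask = np.ones_like(emb)
            emb_d = emb * emb_mask
            if cfg.use_attention:
                u_pre = locs @ p["attn_u"] + (m_t @ p["attn_w"])[:, None, :]
                u = np.tanh(u_pre)
                en = u @ p["attn_v"]                      # (B, n)
                en_s = en - en.max(axis=1, keepdims=True)
                alpha = np.exp(en_s)
                alpha /= alpha.sum(axis=1, keepdims=True)
                ctx = np.einsum("bn,bnd->bd", alpha, locs)
            else:
                u = alpha = None
                ctx = np.zeros((b, d_dim))
            x = np.concatenate([emb_d, ctx], axis=1)
            cache = step(x, m_t, c_t)
            m_t, c_t = cache["m"], cache["c"]
            logits = m_t @ p["w_out"] + p["b_out"]
            z = np.exp(logits - logits.max(axis=1, keepdims=True))
            pr = z / z.sum(axis=1, keepdims=True)
            probs[:, t, :] = pr
            cache.update(inp=inp, emb_mask=emb_mask, u=u, alpha=alpha, probs=pr)
            steps.append(cache)

        tgt = tokens[:, 1:]
        idx = np.clip(tgt - 1, 0, None)
        p_correct = np.take_along_axis(probs, idx[:, :, None], axis=2)[:, :, 0]
        nll = -np.log(np.maximum(p_correct, LOSS_EPS)) * mask
        loss = nll.sum(axis=1).mean()
        pred = probs.argmax(axis=2) + 1
        acc = float((pred == tgt)[mask].mean()) if mask.any() else float("nan")

        return {
            "loss": float(loss),
            "probs": probs,
            "mask": mask,
            "accuracy": acc,
            "tokens": tokens,
            "steps": steps,
            "init": init_cache,
            "locs": locs,
            "spatial": spatial,
            "pen_d": pen_d,
            "pool_pre": pool_pre,
        }

    def backward(self, fwd: dict) -> dict[str, np.ndarray]:
        """Gradients of the forward pass's loss w.r.t. every parameter."""
        p = self.params
        cfg = self.config
        tokens = fwd["tokens"]
        b, l = tokens.shape
        e_dim, d_dim = cfg.embed_dim, cfg.feat_dim
        grads = {k: np.zeros_like(v) for k, v in p.items()}
        dlocs = np.zeros_like(fwd["locs"])

        def lstm_back(cache, dm, dc_in, dgrads):
            """Returns (dx, dm_prev, dc_prev); accumulates weight grads."""
            c = cache["c"]
            if cfg.output_tanh:
                tc = np.tanh(c)
                dc = dm * cache["o"] * (1 - tc * tc) + dc_in
                do = dm * tc
            else:
                dc = dm * cache["o"] + dc_in
                do = dm * c
            df = dc * cache["c_prev"]
            di = dc * cache["g"]
            dg = dc * cache["i"]
            dc_prev = dc * cache["f"]
            pre = {
                "i": di * cache["i"] * (1 - cache["i"]),
                "f": df * cache["f"] * (1 - cache["f"]),
                "o": do * cache["o"] * (1 - cache["o"]),
                "c": dg * (1 - cache["g"] ** 2),
            }
            dx = np.zeros_like(cache["x"])
            dm_prev = np.zeros_like(dm)
            for g in _GATES:
                dgrads[f"w_{g}x"] += cache["x"].T @ pre[g]
                dgrads[f"w_{g}m"] += cache["m_prev"].T @ pre[g]
                dx += pre[g] @ p[f"w_{g}x"].T
                dm_prev += pre[g] @ p[f"w_{g}m"].T
            return dx, dm_prev, dc_prev

        dm_next = np.zeros((b, cfg.hidden_dim))
        dc_next = np.zeros((b, cfg.hidden_dim))
        mask = fwd["mask"]
        tgt = tokens[:, 1:]
        for t in range(l - 2, -1, -1):
            cache = fwd["steps"][t]
            # softmax cross-entropy head
            dlogits = cache["probs"].copy()
            rows = np.arange(b)
            valid = mask[:, t]
            dlogits[rows, np.clip(tgt[:, t] - 1, 0, None)] -= 1.0
            dlogits *= valid[:, None] / b
            grads["w_out"] += cache["m"].T @ dlogits
            grads["b_out"] += dlogits.sum(axis=0)
            dm = dlogits @ p["w_out"].T + dm_next

            dx, dm_prev, dc_prev = lstm_back(cache, dm, dc_next, grads)
            demb_d, dctx = dx[:, :e_dim], dx[:, e_dim:]

            demb = demb_d * cache["emb_mask"]
            np.add.at(grads["embed"], cache["inp"], demb)

            if cfg.use_attention:
                alpha, u, locs = cache["alpha"], cache["u"], fwd["locs"]
                dalpha = np.einsum("bd,bnd->bn", dctx, locs)
                dlocs += alpha[:, :, None] * dctx[:, None, :]
                den = alpha * (dalpha - (alpha * dalpha).sum(axis=1, keepdims=True))
                grads["attn_v"] += np.einsum("bn,bna->a", den, u)
                dpre = den[:, :, None] * p["attn_v"] * (1 - u * u)
                grads["attn_u"] += np.einsum("bnd,bna->da", locs, dpre)
                grads["attn_w"] += cache["m_prev"].T @ dpre.sum(axis=1)
                dm_prev += dpre.sum(axis=1) @ p["attn_w"].T
                dlocs += dpre @ p["attn_u"].T

            dm_next, dc_next = dm_prev, dc_prev

        # image-injection step
        dx_init, _, _ = lstm_back(fwd["init"], dm_next, dc_next, grads)
        dpool = dx_init[:, :e_dim] * (fwd["pool_pre"] > 0)
        grads["w_pool"] += fwd["pen_d"].T @ dpool
        grads["b_pool"] += dpool.sum(axis=0)

        grads["w_loc"] += np.einsum("bnc,bnd->cd", fwd["spatial"], dlocs)
        return grads

    # ------------------------------------------------------------------ #
    # checkpointing

    def save(self, path: str | Path) -> None:
        """Single-archive checkpoint: named arrays + JSON metadata."""
        meta = {
            "config": {**asdict(self.config),
                       "toy_channels": list(self.config.toy_channels)},
            "vocab": self.vocab.index_of,
        }
        np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
                 **self.params)

    @classmethod
    def load(cls, path: str | Path) -> "CaptionModel":
        arrs = np.load(path)
        meta = json.loads(bytes(arrs["__meta__"]).decode())
        cfg_d = meta["config"]
        cfg_d["toy_channels"] = tuple(cfg_d["toy_channels"])
        model = cls(ModelConfig(**cfg_d), Vocabulary(index_of=meta["vocab"]))
        for k in model.params:
            loaded = arrs[k]
            if loaded.shape != model.params[k].shape:
                raise ValueError(f"checkpoint shape mismatch for {k}")
            model.params[k] = loaded
        return model

    def copy_params(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.params.items()}

    def set_params_dict(self, params: dict[str, np.ndarray]) -> None:
        for k in self.params:
            self.params[k] = params[k].copy()
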