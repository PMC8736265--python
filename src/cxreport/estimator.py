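"""Scikit-learn style estimator wrapping the full captioning pipeline.

``ChestXrayReportGenerator`` is the package's top surface: ``fit`` takes
images and findings strings, builds the vocabulary, extracts (and caches)
frozen backbone features, and trains the attention/LSTM decoder with Adam;
``predict`` greedily decodes a report per image; ``score`` returns the
corpus BLEU-1 of the predictions.  It follows the sklearn estimator
contract (``get_params``/``set_params``, trailing-underscore fitted
attributes, ``check_is_fitted``-compatible), so it composes with sklearn
model-selection utilities.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from . import corpus as corpus_mod
from .corpus import Vocabulary, encode_report, preprocess_report
from .encoder import load_image
from .evaluation import BleuResult, corpus_bleu
from .inference import GenerationResult, beam_search, greedy_sample
from .model import CaptionModel, ModelConfig
from .trainer import EpochTrace, TrainConfig, train


class ChestXrayReportGenerator(BaseEstimator):
    """Image-to-findings generator (conv encoder + additive attention + LSTM).

    Parameters
    ----------
    backbone : {"toy", "vgg16"}
        Convolutional feature extractor; "toy" is sized for small synthetic
        images, "vgg16" has the classic 16-layer shape.
    width : int
        Shared width of the embedding, location-feature, attention and
        hidden spaces.  The reference design uses 256; small synthetic
        studies run comfortably at 64.
    dropout : float
        Dropout probability on the penultimate image vector and the word
        embeddings during training.
    learning_rate, batch_size, max_epochs : Adam training schedule.
    use_attention : bool
        If False the per-step context is zero-filled, leaving the single
        image injection at t = -1 as the only visual signal (the
        "without attention" ablation).
    max_words : int
        Word cap per report chunk; sequences are padded to max_words + 2
        (start/end sentinels).
    val_fraction : float
        Held-out fraction of the training data used for the epoch-selection
        rule when no explicit validation set is passed to ``fit``.
    random_state : int
        Seeds parameter initialisation, batch order and dropout masks.

    Attributes
    ----------
    vocab_ : Vocabulary
    model_ : CaptionModel with the best-validation-epoch parameters loaded
    traces_ : list of per-epoch loss/accuracy records
    best_epoch_ : int, argmin of validation loss
    """

    def __init__(
        self,
        backbone: str = "toy",
        width: int = 64,
        dropout: float = 0.5,
        learning_rate: float = 0.001,
        batch_size: int = 64,
        max_epochs: int = 30,
        use_attention: bool = True,
        max_words: int = 22,
        val_fraction: float = 0.2,
        random_state: int = 0,
        toy_channels: tuple[int, ...] = (8, 16, 32),
    ):
        self.backbone = backbone
        self.width = width
        self.dropout = dropout
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.use_attention = use_attention
        self.max_words = max_words
        self.val_fraction = val_fraction
        self.random_state = random_state
        self.toy_channels = toy_channels

    # ------------------------------------------------------------------ #

    def _as_image(self, x) -> np.ndarray:
        if isinstance(x, (str, Path)):
            return load_image(x)
        arr = np.asarray(x, dtype=np.float64)
        if arr.ndim == 2:
            arr = arr[:, :, None]
        return arr

    @property
    def l_max_(self) -> int:
        check_is_fitted(self, "vocab_")
        return self.max_words + 2

    def fit(self, X, y, validation_data=None):
        """Train on images ``X`` (arrays or paths) and findings strings ``y``.

        ``validation_data=(X_val, y_val)`` pins the epoch-selection set;
        otherwise ``val_fraction`` of the training pairs is held out.
        """
        if len(X) != len(y):
            raise ValueError("X and y must have the same length")
        if len(X) == 0:
            raise ValueError("cannot fit on an empty corpus")
        images = [self._as_image(x) for x in X]

        chunk_lists = [preprocess_report(t, self.max_words) for t in y]
        all_chunks = [c for chunks in chunk_lists for c in chunks]
        self.vocab_ = Vocabulary.from_reports(all_chunks)
        l_max = self.max_words + 2

        cfg = ModelConfig(
            backbone=self.backbone,
            embed_dim=self.width,
            hidden_dim=self.width,
            attn_dim=self.width,
            feat_dim=self.width,
            dropout_p=self.dropout,
            use_attention=self.use_attention,
            toy_channels=tuple(self.toy_channels),
            image_size=images[0].shape[0],
            seed=self.random_state,
        )
        model = CaptionModel(cfg, self.vocab_)

        # one record per chunk; images with several chunks appear repeatedly
        img_idx, tokens = [], []
        for i, chunks in enumerate(chunk_lists):
            for chunk in chunks:
                img_idx.append(i)
                tokens.append(encode_report(chunk, self.vocab_, l_max))
        tokens = np.stack(tokens)

        spatial, penult = model.extract_features(images)
        spatial, penult = spatial[img_idx], penult[img_idx]

        if validation_data is not None:
            xv, yv = validation_data
            v_images = [self._as_image(x) for x in xv]
            v_tokens = []
            v_idx = []
            for i, t in enumerate(yv):
                for chunk in preprocess_report(t, self.max_words):
                    v_idx.append(i)
                    v_tokens.append(encode_report(chunk, self.vocab_, l_max))
            v_sp, v_pen = model.extract_features(v_images)
            val = (v_sp[v_idx], v_pen[v_idx], np.stack(v_tokens))
            tr = (spatial, penult, tokens)
        else:
            n = len(tokens)
            n_val = max(1, round(self.val_fraction * n))
            perm = np.random.default_rng(self.random_state).permutation(n)
            val_sel, tr_sel = perm[:n_val], perm[n_val:]
            if len(tr_sel) == 0:
                raise ValueError("validation split leaves no training data")
            tr = (spatial[tr_sel], penult[tr_sel], tokens[tr_sel])
            val = (spatial[val_sel], penult[val_sel], tokens[val_sel])

        tcfg = TrainConfig(
            learning_rate=self.learning_rate,
            batch_size=self.batch_size,
            max_epochs=self.max_epochs,
            dropout_p=self.dropout,
            seed=self.random_state,
        )
        best_params, traces = train(model, tr, val, tcfg)
        model.set_params_dict(best_params)
        self.model_ = model
        self.traces_ = traces
        self.best_epoch_ = int(np.argmin([t.val_loss for t in traces]))
        return self

    # ------------------------------------------------------------------ #

    def _generate(self, image: np.ndarray, beam_width: int = 1) -> GenerationResult:
        model = self.model_
        sp, pen = model.extract_features([image])
        grid = model.feature_grid(sp[0], pen[0])
        if beam_width == 1:
            return greedy_sample(grid, model.decoder_params, self.vocab_, self.l_max_)
        return beam_search(grid, model.decoder_params, self.vocab_,
                           beam_width, self.l_max_)

    def predict(self, X, beam_width: int = 1) -> list[str]:
        """Generate one report string per image (greedy unless beam_width>1)."""
        check_is_fitted(self, "model_")
        return [self._generate(self._as_image(x), beam_width).report for x in X]

    def generate_with_attention(self, x, beam_width: int = 1) -> GenerationResult:
        """Full generation record including per-token attention weights."""
        check_is_fitted(self, "model_")
        return self._generate(self._as_image(x), beam_width)

    def score(self, X, y) -> float:
        """Corpus BLEU-1 of greedy predictions against the references."""
        check_is_fitted(self, "model_")
        preds = self.predict(X)
        pairs = []
        for pred, ref_text in zip(preds, y):
            refs = [c.split() for c in preprocess_report(ref_text, self.max_words)]
            pairs.append((pred.split(), refs))
        return corpus_bleu(pairs).bleu1

    def bleu_report(self, X, y) -> BleuResult:
        """Corpus BLEU-1..4 of greedy predictions against the references."""
        check_is_fitted(self, "model_")
        preds = self.predict(X)
        pairs = [
            (p.split(), [c.split() for c in preprocess_report(t, self.max_words)])
            for p, t in zip(preds, y)
        ]
        return corpus_bleu(pairs)
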