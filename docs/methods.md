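# Methods

## Pipeline

The package implements a classic visual captioning pipeline specialised to
radiology findings: a convolutional encoder, an additive-attention block,
an LSTM decoder trained by teacher forcing, greedy/beam inference, and
BLEU evaluation. All trainable computation — forward passes, gradients,
Adam — is plain numpy; gradients are hand-derived backpropagation through
time and are validated in the test suite by central finite differences and
by independent scalar-loop re-implementations of the gate and attention
equations.

### Text preprocessing

Findings text is split into sentences at `.?!`, lowercased, and reduced to
ASCII-alphabetic word runs (digits and punctuation vanish; non-ASCII
letters are dropped for reproducibility on an English corpus). Sentences
are packed greedily left-to-right into chunks of at most `max_words`
(default 22) tokens; a single oversized sentence is hard-cut into
`max_words`-sized closed chunks. Each chunk becomes one training record:
`[startseq, words…, endseq, pad…]` padded to `max_words + 2`. The word cap
excludes the two sentinels. Vocabulary ids are deterministic: `pad = 0`,
`startseq = 1`, `endseq = 2`, then words by descending corpus frequency
with lexicographic tie-break.

### Encoder

Two backbones share the 3×3-conv + ReLU + 2×-max-pool vocabulary. The
`vgg16` backbone has the canonical 16-layer shape (13 convolutions in five
pooled blocks, two 4096-wide dense layers; the classifier is removed so
the network ends at the 1×4096 penultimate vector). The `toy` backbone is
a short frozen stack (default channels 8, 16, 32) sized for 64×64
synthetic images; its penultimate vector is the flattened final map.
Pixels are scaled to [0, 1] with no mean subtraction; greyscale input is
replicated to three channels for `vgg16`.

Attention needs per-location features, which the penultimate vector alone
cannot provide, so the location matrix h (n × d) is a trainable linear
projection of the last convolutional map — the only reading under which
the attention equations are well-defined — while the pooled vector is
`ReLU(dense(dropout(penultimate)))` and is used solely for the one-off
image injection.

The convolutional stack itself is frozen at seeded random weights (a
`weights_path` hook exists for pretrained weights). Freezing lets features
be extracted once per image and cached across epochs, and random
convolutional features are sufficient for the synthetic corpus because the
blobs are high-contrast and spatially separated; everything from the
projections onward is trained. The dense projection, embedding, attention,
LSTM and vocabulary head therefore carry all learning.

### Attention

Energies e_jt = vᵀ tanh(U h_j + W m_{t−1}); weights by softmax (the
canonical map onto the simplex); context C_t = Σ α_jt h_j. The query is
always the previous decoder state. One head by default; the head count is
configurable with concatenated contexts. Weights are exportable per token
and as upsampled heat-map overlays.

### Decoder

Gates are biasless, exactly as the recurrence is written: i, f, o =
σ(W·x + W·m), cell c_t = f⊙c + i⊙tanh(·), and the emitted output is
m_t = o_t ⊙ c_t with no output tanh by default (`output_tanh` turns the
conventional form on). The step input x_t concatenates the previous
word's embedding (dropout-regularised) with the attention context; at
t = −1 the pooled image vector enters through the embedding slot with the
context slot zero-filled, bypassing attention because no query state
exists yet. The vocabulary head is affine (bias included) over word ids
1..V; padding is not a predictable class. In the attention-ablated
configuration the context slot is zero-filled at every step, leaving the
single image injection as the only visual signal.

### Training

Adam (β₁ = 0.9, β₂ = 0.999, ε = 1e−8) at learning rate 0.001, dropout 0.5
on the penultimate vector and the embeddings, global-norm gradient
clipping at 5.0 (protects small-batch runs), uniform Glorot initialisation
with zero biases, all seeded. Loss is summed −log p over non-pad targets
per sequence, averaged over the batch; probabilities are clamped at 1e−12
only when reporting. Every epoch ends with a full validation pass and the
returned checkpoint minimises validation loss (first epoch wins ties).
During the end-to-end study the held-out 20 % split doubles as the
validation set; `fit` can also carve an internal validation fraction for
three-way splits.

### Inference

Greedy decoding takes the argmax at each step, ties broken toward the
lowest token id; generation stops at `endseq` or at the length cap, in
which case the result is flagged truncated. Beam search ranks partial
hypotheses by raw summed log-probability (no length normalisation by
default; a flag enables it), retires completed hypotheses into the
candidate pool, and at k = 1 reproduces greedy decoding token for token.

### Evaluation

BLEU-n uses clipped (modified) n-gram precisions, the brevity penalty
min(1, e^{1−r/c}) with r the closest-length reference, and the cumulative
weight vectors (1,0,0,0), (0.5,0.5,0,0), (0.33,0.33,0.33,0),
(0.25,0.25,0.25,0.25). The third-order weights are used exactly as
printed; an `exact_thirds` switch substitutes 1/3. No smoothing by
default — any weighted order with zero precision zeroes the score — with
an optional epsilon floor because short clinical sentences frequently have
no matching 4-grams. Corpus BLEU pools counts and lengths over pairs
before forming precisions. A sentence is labelled "normal" iff it contains
any of the keywords {no, normal, clear, stable} (configurable).

## Synthetic corpus

The generator emulates the layout of paired image/findings corpora: 64×64
8-bit greyscale PNGs of a dark background with a brighter thorax ellipse,
one bright Gaussian blob per sampled finding at a fixed region, and
Gaussian pixel noise (σ = 0.05 against blob amplitude 0.5, SNR 10 — high
enough that the frozen toy encoder separates the classes). Four findings
(upper/lower × left/right), each independently present with probability
0.3; the report is the concatenation of the present findings' template
sentences in fixed inventory order, or "the lungs are clear". The mapping
from blob pattern to text is deterministic, so a correct pipeline can
drive held-out loss toward zero; 200 images is the default study size.

What this corpus does **not** emulate: anatomical appearance, label noise,
inter-report paraphrase variability, long multi-sentence findings, and
class imbalance beyond the Bernoulli rate. Passing the end-to-end study
therefore demonstrates that the machinery — encoding, attention, gate
equations, gradients, decoding, scoring — is correct and learnable, not
that the model reaches any particular accuracy on real radiology data.

## Study sizes and defaults

The end-to-end study trains width-64 models (embedding = hidden =
attention = feature width) on 160/40 train/test images with batch 16 for
up to 30 epochs — about 20–25 s per run on one CPU. The reference design
width is 256, kept as the library default for `ModelConfig`; the estimator
default is 64, matching the synthetic study. BLEU-1 on the held-out split
reaches ≈ 0.98 with attention and ≈ 0.85 without under seed 1; the
attention model's advantage comes from re-reading blob locations at every
step instead of compressing them into the single injection.

## Numerical choices and degenerate inputs

Softmaxes subtract the row maximum before exponentiation. Log-probabilities
floor at 1e−300 before `log` during decoding. Empty BLEU candidates warn
and score 0; an empty reference set is an error. Encoding rejects
out-of-vocabulary tokens by name and reports that do not fit the length
budget. Images smaller than the pooling budget of the configured backbone
are rejected. `argmax` tie-breaks (lowest index) make generation
deterministic at fixed weights.

## Known limitations

Single-layer LSTM only; no GRU/bidirectional variants. No pretrained
encoder weights are bundled, so absolute performance on real X-rays is out
of scope. Beam search is exact only in the exhaustive-width limit.
Training is single-threaded numpy and sized for small studies, not for
full radiology corpora.
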