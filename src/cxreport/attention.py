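"""Additive (Bahdanau-style) attention over image locations.

At each decoding step the previous decoder state queries the ``n`` location
features ``h_j``: a small feed-forward scorer produces one energy per
location, a softmax turns the energies into simplex weights, and the
context vector is the weights' convex combination of the ``h_j`` rows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class AttentionParams:
    """Scorer parameters: energy_j = v^T tanh(U h_j + W s)."""

    u: np.ndarray       # d x a
    w: np.ndarray       # s x a
    v: np.ndarray       # a

    def __post_init__(self) -> None:
        if self.u.shape[1] != self.w.shape[1] or self.u.shape[1] != self.v.shape[0]:
            raise ValueError("attention width mismatch between U, W and v")


@dataclass
class AttentionResult:
    energies: np.ndarray   # n
    weights: np.ndarray    # n, on the probability simplex
    context: np.ndarray    # d

    def __post_init__(self) -> None:
        if abs(self.weights.sum() - 1.0) > 1e-6 or (self.weights < -1e-12).any():
            raise ValueError("attention weights must lie on the simplex")


def score(h: np.ndarray, s_prev: np.ndarray, params: AttentionParams) -> np.ndarray:
    """Per-location energies e_j = v^T tanh(U h_j + W s_prev)."""
    if h.shape[1] != params.u.shape[0]:
        raise ValueError(f"location width {h.shape[1]} != U rows {params.u.shape[0]}")
    if s_prev.shape[-1] != params.w.shape[0]:
        raise ValueError(f"query width {s_prev.shape[-1]} != W rows {params.w.shape[0]}")
    return np.tanh(h @ params.u + s_prev @ params.w) @ params.v


def normalise(energies: np.ndarray) -> np.ndarray:
    """Softmax over locations; invariant to adding a constant energy."""
    e = np.asarray(energies, dtype=np.float64)
    if e.size == 0:
        raise ValueError("cannot normalise an empty energy vector")
    z = np.exp(e - e.max())
    return z / z.sum()


def context(weights: np.ndarray, h: np.ndarray) -> np.ndarray:
    """Context vector C = sum_j alpha_j h_j (convex combination of rows)."""
    if weights.shape[0] != h.shape[0]:
        raise ValueError("one weight per location is required")
    return weights @ h


def attend(h: np.ndarray, s_prev: np.ndarray, params: AttentionParams) -> AttentionResult:
    """Full attention step: energies -> weights -> context."""
    e = score(h, s_prev, params)
    a = normalise(e)
    return AttentionResult(energies=e, weights=a, context=context(a, h))


def weights_to_heatmap(
    weights: np.ndarray, grid_shape: tuple[int, int], image: np.ndarray
) -> np.ndarray:
    """Upsample per-location weights to the image plane for overlay plots."""
    from skimage.transform import resize

    grid = np.asarray(weights, dtype=np.float64).reshape(grid_shape)
    return resize(grid, image.shape[:2], order=1, anti_aliasing=False)


def save_heatmap_overlay(
    weights: np.ndarray,
    grid_shape: tuple[int, int],
    image: np.ndarray,
    path: str,
    token: str | None = None,
) -> None:
    """Write a PNG of the image with the attention map blended on top."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    heat = weights_to_heatmap(weights, grid_shape, image)
    fig, ax = plt.subplots(figsize=(3, 3))
    ax.imshow(image.squeeze(), cmap="gray", vmin=0, vmax=1)
    ax.imshow(heat, cmap="inferno", alpha=0.45)
    ax.set_axis_off()
    if token:
        ax.set_title(token, fontsize=9)
    fig.savefig(path, bbox_inches="tight", dpi=100)
    plt.close(fig)
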