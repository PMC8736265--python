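"""Synthetic chest-image/report corpus generator.

Real report-generation corpora pair an X-ray with a free-text findings
paragraph.  This generator emulates that layout with fully programmatic
data: each image is a dark background with a brighter "thorax" ellipse,
plus one bright Gaussian blob per sampled finding at a fixed region, plus
pixel noise; the report is the concatenation of the findings' sentence
templates in a fixed inventory order ("the lungs are clear" when no
finding was sampled).  The image -> report mapping is deterministic given
the sampled findings, so a correct pipeline can drive its held-out loss
near zero — which is what the end-to-end tests rely on.  The vocabulary is
closed and small (well under 40 words with the default inventory).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image

from .corpus import END_TOKEN, START_TOKEN

#: (name, blob centre as fractions of image size, sentence template)
DEFAULT_INVENTORY: tuple[tuple[str, tuple[float, float], str], ...] = (
    ("left_upper", (0.30, 0.32), "opacity in the left upper zone"),
    ("right_upper", (0.30, 0.68), "opacity in the right upper zone"),
    ("left_lower", (0.68, 0.32), "effusion at the left base"),
    ("right_lower", (0.68, 0.68), "effusion at the right base"),
)

NORMAL_TEMPLATE = "the lungs are clear"


@dataclass
class SynthSpec:
    """Study conditions for the synthetic corpus.

    ``finding_prob`` is the independent per-finding presence probability
    (so the findings-per-image count is Binomial(n_inventory,
    finding_prob)); ``noise_sd`` is the Gaussian pixel noise level against
    a blob amplitude of 0.5, i.e. SNR 10 at the default.
    """

    n_images: int = 200
    image_size: int = 64
    inventory: tuple[tuple[str, tuple[float, float], str], ...] = DEFAULT_INVENTORY
    finding_prob: float = 0.3
    noise_sd: float = 0.05
    blob_amplitude: float = 0.5
    blob_sigma: float = 0.09      # as a fraction of image size
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.inventory:
            raise ValueError("finding inventory must be non-empty")
        reserved = {START_TOKEN, END_TOKEN}
        for _, _, template in list(self.inventory) + [(None, None, NORMAL_TEMPLATE)]:
            for tok in template.split():
                if not (tok.isalpha() and tok == tok.lower()):
                    raise ValueError(f"template token {tok!r} must be lowercase alphabetic")
                if tok in reserved:
                    raise ValueError(f"template token {tok!r} collides with a sentinel")


def render_image(
    spec: SynthSpec, findings: list[int], rng: np.random.Generator
) -> np.ndarray:
    """One image: thorax ellipse + one blob per finding index + noise."""
    s = spec.image_size
    yy, xx = np.mgrid[0:s, 0:s] / (s - 1)
    img = np.full((s, s), 0.05)
    # thorax: centred ellipse of moderate brightness
    ell = ((yy - 0.5) / 0.46) ** 2 + ((xx - 0.5) / 0.38) ** 2 <= 1.0
    img[ell] = 0.30
    sig = spec.blob_sigma
    for idx in findings:
        _, (cy, cx), _ = spec.inventory[idx]
        img += spec.blob_amplitude * np.exp(
            -(((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * sig**2))
        )
    img += rng.normal(0.0, spec.noise_sd, size=img.shape)
    return np.clip(img, 0.0, 1.0)


def report_for(spec: SynthSpec, findings: list[int]) -> str:
    """Deterministic findings -> text mapping, fixed inventory order."""
    if not findings:
        return NORMAL_TEMPLATE
    return " ".join(spec.inventory[i][2] for i in sorted(findings))


def sample_corpus(spec: SynthSpec) -> tuple[list[np.ndarray], list[str], list[list[int]]]:
    """In-memory corpus: (images, report texts, per-image finding indices)."""
    rng = np.random.default_rng(spec.seed)
    images, texts, all_findings = [], [], []
    for _ in range(spec.n_images):
        present = [
            i for i in range(len(spec.inventory)) if rng.random() < spec.finding_prob
        ]
        images.append(render_image(spec, present, rng))
        texts.append(report_for(spec, present))
        all_findings.append(present)
    return images, texts, all_findings


def generate(spec: SynthSpec, out_dir: str | Path) -> Path:
    """Write PNG images + JSON-lines manifest; returns the manifest path.

    Deterministic at fixed seed: the same spec writes byte-identical
    manifests (and images).
    """
    out_dir = Path(out_dir)
    img_dir = out_dir / "images"
    img_dir.mkdir(parents=True, exist_ok=True)
    images, texts, _ = sample_corpus(spec)
    manifest_path = out_dir / "manifest.jsonl"
    with open(manifest_path, "w") as fh:
        for i, (img, text) in enumerate(zip(images, texts)):
            rel = f"images/img_{i:04d}.png"
            Image.fromarray((img * 255).round().astype(np.uint8)).save(out_dir / rel)
            fh.write(json.dumps({"image": rel, "findings": text}) + "\n")
    return manifest_path


def corpus_vocab_words(spec: SynthSpec) -> set[str]:
    words = set(NORMAL_TEMPLATE.split())
    for _, _, template in spec.inventory:
        words.update(template.split())
    return words
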