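"""Seeded synthetic image generators.

Everything downstream is exercised offline on generated data: MRI-like
grayscale "phantoms" (a bright elliptical brain on a dark background,
Gaussian noise, optionally a brighter circular tumour blob with a known
mask and binary label) and the four canonical cipher test images
(constant, gradient, checkerboard, uniform random).

The phantoms are geometric, not anatomically realistic: classifier tests
against them demonstrate parameter and label recovery, not clinical
validity.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "PhantomConfig",
    "generate_phantom",
    "generate_dataset",
    "generate_cipher_testset",
]


@dataclass(frozen=True)
class PhantomConfig:
    """Phantom geometry and intensity model.

    Intensities are 8-bit gray levels; ``noise_sigma`` is the standard
    deviation of the additive Gaussian noise; the tumour is a disk of
    uniform extra intensity ``tumour_contrast`` above the brain tissue.
    """

    size: tuple[int, int] = (64, 64)
    background: float = 20.0
    noise_sigma: float = 8.0
    brain_intensity: float = 120.0
    tumour_prob: float = 0.5
    tumour_radius: tuple[float, float] = (5.0, 10.0)
    tumour_contrast: float = 80.0
    seed: int = 0

    def __post_init__(self) -> None:
        p, q = self.size
        if p < 4 or q < 4:
            raise ValueError("phantom must be at least 4x4")
        for v in (self.background, self.brain_intensity,
                  self.brain_intensity + self.tumour_contrast):
            if not (0.0 <= v <= 255.0):
                raise ValueError("intensities must stay within [0, 255]")
        if self.tumour_radius[1] >= min(p, q) / 2:
            raise ValueError("tumour radius must be below half the image size")
        if not (0.0 <= self.tumour_prob <= 1.0):
            raise ValueError("tumour_prob must be a probability")


def generate_phantom(
    cfg: PhantomConfig,
    rng: np.random.Generator | None = None,
    force_tumour: bool | None = None,
):
    """One phantom; returns ``(image, label, tumour_mask)``.

    ``label`` is 1 iff a tumour was placed; ``tumour_mask`` marks its
    pixels.  With ``rng=None`` the config seed fixes all randomness.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    p, q = cfg.size
    ii, jj = np.mgrid[0:p, 0:q].astype(np.float64)
    ci, cj = (p - 1) / 2.0, (q - 1) / 2.0
    ai, aj = 0.42 * p, 0.42 * q
    brain = ((ii - ci) / ai) ** 2 + ((jj - cj) / aj) ** 2 <= 1.0
    img = np.full((p, q), cfg.background, dtype=np.float64)
    img[brain] = cfg.brain_intensity

    has_tumour = bool(rng.random() < cfg.tumour_prob) if force_tumour is None \
        else bool(force_tumour)
    mask = np.zeros((p, q), dtype=bool)
    if has_tumour:
        r = float(rng.uniform(*cfg.tumour_radius))
        # centre well inside the brain ellipse
        ti = ci + rng.uniform(-0.45, 0.45) * ai
        tj = cj + rng.uniform(-0.45, 0.45) * aj
        mask = ((ii - ti) ** 2 + (jj - tj) ** 2 <= r * r) & brain
        img[mask] += cfg.tumour_contrast

    img += rng.normal(0.0, cfg.noise_sigma, size=(p, q))
    img = np.clip(np.round(img), 0, 255).astype(np.uint8)
    return img, int(has_tumour), mask


def generate_dataset(
    n: int,
    tumour_fraction: float = 0.5,
    cfg: PhantomConfig | None = None,
    seed: int = 0,
):
    """Stratified phantom set; returns ``(images, labels, masks)``.

    Exactly ``round(n * tumour_fraction)`` phantoms carry a tumour; the
    order is a seeded shuffle.  Fully reproducible under ``seed``.
    """
    if n < 2:
        raise ValueError("need at least 2 images")
    cfg = cfg or PhantomConfig()
    rng = np.random.default_rng(seed)
    n_pos = int(round(n * tumour_fraction))
    wants = np.array([True] * n_pos + [False] * (n - n_pos))
    wants = wants[rng.permutation(n)]
    p, q = cfg.size
    images = np.empty((n, p, q), dtype=np.uint8)
    labels = np.empty(n, dtype=np.int64)
    masks = np.empty((n, p, q), dtype=bool)
    for i, want in enumerate(wants):
        images[i], labels[i], masks[i] = generate_phantom(
            cfg, rng=rng, force_tumour=bool(want)
        )
    return images, labels, masks


def generate_cipher_testset(size: int = 256, seed: int = 0) -> dict[str, np.ndarray]:
    """Canonical images for entropy/correlation/differential studies.

    constant (mid gray), gradient (horizontal 0..255 ramp), checkerboard
    (alternating 0/255) and uniform random bytes.
    """
    if size < 2:
        raise ValueError("size must be at least 2")
    rng = np.random.default_rng(seed)
    ramp = np.round(np.linspace(0, 255, size)).astype(np.uint8)
    ii, jj = np.mgrid[0:size, 0:size]
    return {
        "constant": np.full((size, size), 128, dtype=np.uint8),
        "gradient": np.tile(ramp, (size, 1)),
        "checkerboard": (((ii + jj) % 2) * 255).astype(np.uint8),
        "random": rng.integers(0, 256, size=(size, size), dtype=np.uint8),
    }


def config_fingerprint(cfg: PhantomConfig) -> str:
    """Stable hash of a phantom configuration (distinct configs differ)."""
    return hashlib.sha256(repr(cfg).encode()).hexdigest()[:16]
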