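"""Cryptanalysis metric suite.

Implements the four standard figures used to judge an image cipher:

* information entropy of the 256-bin pixel histogram (ideal 8 bits),
* adjacent-pixel correlation in the horizontal / vertical / diagonal
  directions over a random sample of neighbour pairs,
* NPCR — the percentage of positions at which two ciphertexts differ,
* UACI — the mean absolute intensity difference as a percentage of 255,

plus :func:`analyze`, which encrypts an image and a one-pixel-perturbed
copy and fills a complete :class:`SecurityReport`, and
:func:`differential_benchmark`, the seeded many-trial NPCR/UACI study.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .chaos import ChaosParams, random_key
from .cipher import CipherConfig, as_gray_image, encrypt

__all__ = [
    "SecurityReport",
    "DegenerateVarianceWarning",
    "information_entropy",
    "adjacent_correlation",
    "npcr",
    "uaci",
    "analyze",
    "differential_benchmark",
    "perturb_one_pixel",
]

_DIRECTION_OFFSETS = {"H": (0, 1), "V": (1, 0), "D": (1, 1)}


class DegenerateVarianceWarning(UserWarning):
    """Raised as a flag when a correlation marginal is constant."""


def information_entropy(img) -> float:
    """Shannon entropy of the pixel histogram in bits per pixel (0..8)."""
    a = as_gray_image(img)
    counts = np.bincount(a.ravel(), minlength=256)
    p = counts[counts > 0] / a.size
    return float(-(p * np.log2(p)).sum())


def adjacent_correlation(
    img,
    direction: str = "H",
    n_pairs: int = 2000,
    seed: int | None = None,
) -> float:
    """Pearson correlation of ``n_pairs`` sampled adjacent-pixel pairs.

    ``direction`` is one of H (offset (0,1)), V ((1,0)), D ((1,1)).
    Anchors are drawn uniformly without replacement among positions that
    have a valid neighbour.  A constant marginal makes the coefficient
    undefined; 0.0 is returned and a :class:`DegenerateVarianceWarning`
    is emitted as the flag.
    """
    a = as_gray_image(img).astype(np.float64)
    try:
        di, dj = _DIRECTION_OFFSETS[direction]
    except KeyError:
        raise ValueError(f"direction must be one of H, V, D; got {direction!r}")
    rows, cols = a.shape
    vr, vc = rows - di, cols - dj
    if vr < 1 or vc < 1 or vr * vc < n_pairs:
        raise ValueError(
            f"image too small to sample {n_pairs} {direction}-pairs "
            f"({vr * vc} available)"
        )
    rng = np.random.default_rng(seed)
    idx = rng.choice(vr * vc, size=n_pairs, replace=False)
    ii, jj = idx // vc, idx % vc
    x = a[ii, jj]
    y = a[ii + di, jj + dj]
    sx, sy = x.std(), y.std()
    if sx == 0.0 or sy == 0.0:
        warnings.warn("constant marginal in correlation sample",
                      DegenerateVarianceWarning, stacklevel=2)
        return 0.0
    return float(np.mean((x - x.mean()) * (y - y.mean())) / (sx * sy))


def npcr(e1, e2) -> float:
    """Number of pixels change rate, percent of differing positions."""
    a, b = as_gray_image(e1), as_gray_image(e2)
    if a.shape != b.shape:
        raise ValueError("images must share a shape")
    return float(100.0 * np.count_nonzero(a != b) / a.size)


def uaci(e1, e2) -> float:
    """Unified average changing intensity, percent of the 255 gray range."""
    a, b = as_gray_image(e1), as_gray_image(e2)
    if a.shape != b.shape:
        raise ValueError("images must share a shape")
    diff = np.abs(a.astype(np.int16) - b.astype(np.int16))
    return float(100.0 * diff.mean() / 255.0)


def perturb_one_pixel(img, rng: np.random.Generator) -> np.ndarray:
    """Copy with one uniformly chosen pixel set to a new uniform value."""
    a = as_gray_image(img).copy()
    flat = a.reshape(-1)
    pos = int(rng.integers(flat.size))
    old = flat[pos]
    new = int(rng.integers(256))
    while new == old:
        new = int(rng.integers(256))
    flat[pos] = new
    return a


@dataclass
class SecurityReport:
    """Combined cryptanalysis report for one plain/cipher pair."""

    entropy_plain: float
    entropy_cipher: float
    correlations: dict        # {"plain"|"cipher": {"H"|"V"|"D": r}}
    npcr: float
    uaci: float
    n_pairs: int
    seed: int

    def to_json(self, path: str | Path | None = None) -> str:
        doc = json.dumps(asdict(self), indent=2)
        if path is not None:
            Path(path).write_text(doc + "\n")
        return doc


def analyze(
    plain,
    key: ChaosParams,
    cfg: CipherConfig | None = None,
    n_pairs: int = 2000,
    seed: int = 0,
) -> SecurityReport:
    """Full security study of one image under one key.

    Encrypts the image and a one-random-pixel-perturbed copy, then computes
    entropy, directional correlations (plain and cipher) and the NPCR/UACI
    pair between the two ciphertexts.  Deterministic given ``seed``.
    """
    plain = as_gray_image(plain)
    rng = np.random.default_rng(seed)
    cipher1, _ = encrypt(plain, key, cfg)
    cipher2, _ = encrypt(perturb_one_pixel(plain, rng), key, cfg)
    corr = {"plain": {}, "cipher": {}}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", DegenerateVarianceWarning)
        for d in ("H", "V", "D"):
            corr["plain"][d] = adjacent_correlation(plain, d, n_pairs, seed)
            corr["cipher"][d] = adjacent_correlation(cipher1, d, n_pairs, seed)
    return SecurityReport(
        entropy_plain=information_entropy(plain),
        entropy_cipher=information_entropy(cipher1),
        correlations=corr,
        npcr=npcr(cipher1, cipher2),
        uaci=uaci(cipher1, cipher2),
        n_pairs=n_pairs,
        seed=seed,
    )


def differential_benchmark(
    n_trials: int = 50,
    size: int = 256,
    seed: int = 0,
    key: ChaosParams | None = None,
) -> dict:
    """Seeded NPCR/UACI study on uniform-random plaintext pairs.

    Each trial draws a fresh ``size`` x ``size`` plaintext of i.i.d. uniform
    bytes, flips one uniformly chosen pixel to a new uniform value, encrypts
    both with the same key and records NPCR and UACI between the two
    ciphertexts.  Returns per-trial values and their means.
    """
    rng = np.random.default_rng(seed)
    npcrs = np.empty(n_trials)
    uacis = np.empty(n_trials)
    for t in range(n_trials):
        k = key if key is not None else random_key(rng)
        plain = rng.integers(0, 256, size=(size, size), dtype=np.uint8)
        other = perturb_one_pixel(plain, rng)
        c1, _ = encrypt(plain, k)
        c2, _ = encrypt(other, k)
        npcrs[t] = npcr(c1, c2)
        uacis[t] = uaci(c1, c2)
    return {
        "npcr_mean": float(npcrs.mean()),
        "uaci_mean": float(uacis.mean()),
        "npcr": npcrs.tolist(),
        "uaci": uacis.tolist(),
        "n_trials": n_trials,
        "size": size,
        "seed": seed,
    }
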