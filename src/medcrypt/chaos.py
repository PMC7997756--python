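"""Chaotic keystream generation.

The cipher draws all of its pseudorandomness from a parameterised chaotic
system.  The default system is three independent logistic maps

    x <- r * x * (1 - x)

run in the fully chaotic regime (r close to 4).  The maps are iterated
``transient_m + length + 1`` times; the first ``transient_m`` values are
discarded to decouple the streams from the initial state, the next value of
the first series is reserved for scramble-corner selection, and the
remaining values are quantised to bytes and XOR-combined pairwise into the
two diffusion keystreams R1 and R2.

The :class:`ChaosParams` object *is* the secret key; it round-trips through
a small JSON file (see :func:`save_key` / :func:`load_key`).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "ChaosParams",
    "Keystream",
    "DEFAULT_SCALE",
    "DEFAULT_TRANSIENT",
    "iterate_system",
    "derive_keystreams",
    "generate_keystream",
    "derive_ivs",
    "select_corner",
    "quantize_byte",
    "save_key",
    "load_key",
    "random_key",
]

DEFAULT_SCALE = 10_000_000_000  # 10^10 quantiser
DEFAULT_TRANSIENT = 1000
_DEFAULT_R = (3.99, 3.98, 3.97)
_CORNER_SCALE = 10_000


@dataclass(frozen=True)
class ChaosParams:
    """Secret key: chaotic-system seed and parameters.

    ``initial_state`` must lie strictly inside (0, 1) for the logistic
    system (the fixed points 0 and 1 are excluded); ``transient_m`` values
    are burned before any keystream material is emitted.
    """

    initial_state: tuple[float, float, float]
    control_params: tuple[float, float, float] = _DEFAULT_R
    system_id: str = "logistic3"
    transient_m: int = DEFAULT_TRANSIENT
    quantizer_scale: int = DEFAULT_SCALE

    def __post_init__(self) -> None:
        if self.system_id != "logistic3":
            raise ValueError(f"unknown chaotic system {self.system_id!r}")
        if len(self.initial_state) != 3 or len(self.control_params) != 3:
            raise ValueError("initial_state and control_params need 3 components")
        for x in self.initial_state:
            if not (0.0 < x < 1.0):
                raise ValueError(f"initial state {x} outside the open unit interval")
        for r in self.control_params:
            if not (0.0 < r <= 4.0):
                raise ValueError(f"logistic parameter {r} outside (0, 4]")
        if self.transient_m < 0:
            raise ValueError("transient_m must be non-negative")
        if self.quantizer_scale <= 0:
            raise ValueError("quantizer_scale must be positive")


@dataclass(frozen=True)
class Keystream:
    """Derived byte streams plus the raw value reserved for corner choice."""

    r1: np.ndarray  # uint8
    r2: np.ndarray  # uint8
    corner_value: float

    def __len__(self) -> int:
        return len(self.r1)


def _iterate_raw(params: ChaosParams, total: int) -> np.ndarray:
    """Iterate the three logistic maps ``total`` times; shape (3, total)."""
    out = np.empty((3, total), dtype=np.float64)
    x1, x2, x3 = params.initial_state
    r1, r2, r3 = params.control_params
    c1, c2, c3 = out[0], out[1], out[2]
    for i in range(total):
        x1 = r1 * x1 * (1.0 - x1)
        x2 = r2 * x2 * (1.0 - x2)
        x3 = r3 * x3 * (1.0 - x3)
        c1[i] = x1
        c2[i] = x2
        c3[i] = x3
    return out


def iterate_system(params: ChaosParams, n: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Return the three post-transient chaotic series of length ``n``.

    The system is iterated ``transient_m + n`` times and the leading
    ``transient_m`` values of every series are discarded.
    """
    if n < 0:
        raise ValueError("n must be non-negative")
    raw = _iterate_raw(params, params.transient_m + n)
    kept = raw[:, params.transient_m :]
    return kept[0], kept[1], kept[2]


def quantize_byte(u: float | np.ndarray, scale: int = DEFAULT_SCALE):
    """Quantise a raw chaotic value to a byte: floor(u * scale) mod 256."""
    return np.floor(np.asarray(u, dtype=np.float64) * scale).astype(np.int64) % 256


def derive_keystreams(
    series: tuple[np.ndarray, np.ndarray, np.ndarray],
    length: int,
    scale: int = DEFAULT_SCALE,
) -> Keystream:
    """Combine three chaotic series into the byte keystreams R1 and R2.

    Element 0 of series 1 is reserved as the corner value; bytes come from
    elements 1..length of each series (each series therefore needs at least
    ``length + 1`` elements).  Each raw value u is quantised to
    ``floor(u * scale) mod 256`` and the quantised series are XOR-combined:
    R1 = b1 ^ b2, R2 = b2 ^ b3.
    """
    s1, s2, s3 = (np.asarray(s, dtype=np.float64) for s in series)
    if length < 0:
        raise ValueError("length must be non-negative")
    need = length + 1
    if min(len(s1), len(s2), len(s3)) < need:
        raise ValueError(
            f"series too short: need {need} elements, have "
            f"{min(len(s1), len(s2), len(s3))}"
        )
    corner_value = float(s1[0])
    b1 = quantize_byte(s1[1 : length + 1], scale)
    b2 = quantize_byte(s2[1 : length + 1], scale)
    b3 = quantize_byte(s3[1 : length + 1], scale)
    r1 = np.bitwise_xor(b1, b2).astype(np.uint8)
    r2 = np.bitwise_xor(b2, b3).astype(np.uint8)
    return Keystream(r1=r1, r2=r2, corner_value=corner_value)


def generate_keystream(params: ChaosParams, length: int) -> Keystream:
    """Iterate the system and derive ``length`` keystream bytes."""
    series = iterate_system(params, length + 1)
    return derive_keystreams(series, length, scale=params.quantizer_scale)


def derive_ivs(params: ChaosParams) -> tuple[int, int]:
    """Diffusion boundary bytes from the chaotic transient.

    The forward IV is the quantised last discarded value of series 1, the
    reverse IV that of series 3.  With ``transient_m == 0`` there is no
    transient and both IVs are 0.
    """
    m = params.transient_m
    if m == 0:
        return 0, 0
    raw = _iterate_raw(params, m)
    iv_f = int(quantize_byte(raw[0, m - 1], params.quantizer_scale))
    iv_r = int(quantize_byte(raw[2, m - 1], params.quantizer_scale))
    return iv_f, iv_r


def select_corner(keystream: Keystream) -> int:
    """Pick the zigzag start corner from the reserved chaotic value.

    corner = floor(v * 10^4) mod 4, encoded TL=0, TR=1, BL=2, BR=3.
    """
    return int(math.floor(keystream.corner_value * _CORNER_SCALE)) % 4


# --- key file I/O ---------------------------------------------------------

def save_key(params: ChaosParams, path: str | Path) -> None:
    """Write the key as JSON: {"system", "x0", "r", "m", "scale"}."""
    doc = {
        "system": params.system_id,
        "x0": list(params.initial_state),
        "r": list(params.control_params),
        "m": params.transient_m,
        "scale": params.quantizer_scale,
    }
    Path(path).write_text(json.dumps(doc, indent=2) + "\n")


def load_key(path: str | Path) -> ChaosParams:
    doc = json.loads(Path(path).read_text())
    return ChaosParams(
        initial_state=tuple(doc["x0"]),
        control_params=tuple(doc.get("r", _DEFAULT_R)),
        system_id=doc.get("system", "logistic3"),
        transient_m=int(doc.get("m", DEFAULT_TRANSIENT)),
        quantizer_scale=int(doc.get("scale", DEFAULT_SCALE)),
    )


def random_key(rng: np.random.Generator | None = None, seed: int | None = None) -> ChaosParams:
    """Draw a fresh key with initial state uniform in (0.05, 0.95)."""
    if rng is None:
        rng = np.random.default_rng(seed)
    x0 = tuple(rng.uniform(0.05, 0.95, size=3).tolist())
    return ChaosParams(initial_state=x0)
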