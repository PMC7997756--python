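"""Fuzzy convolutional neural network for binary image classification.

Architecture (forward order):

1. fuzzification — each input pixel grid is mapped to one membership grid
   per Gaussian membership function (MF), default two MFs whose centres sit
   at the 25th/75th intensity percentiles of the training data;
2. fuzzy convolution — each convolution kernel Wt is itself fuzzified
   (Gaussian membership of its weights around a trainable centre Mz) and
   the fuzzified kernel is applied to every membership grid, either as an
   ordinary sum of products (default) or as a min-max composition;
3. activation + pooling — ReLU followed by max pooling (global by default);
4. defuzzification — centre of gravity across the MF axis: for kernel k,
   y_k = sum_m My[m,k] x[m,k] / sum_m x[m,k], a soft interpolation between
   the low- and high-intensity defuzzification centres;
5. fully connected output — a single sigmoid unit z = sigmoid(Wf . y) for
   the binary normal/abnormal decision.

Training is seeded mini-batch gradient descent on the cross-entropy loss.
The fully connected weights Wf and the three centre families My, Mz, Mx
each have their own learning rate; gradients are derived by the chain rule
through the sum-mode network (max-pool and ReLU pass subgradients at the
arg-max).  In min-max mode the kernel and fuzzification centres are frozen
and only Wf and My train.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "FCNNModel",
    "TrainConfig",
    "ConfusionCounts",
    "gaussian_membership",
    "fuzzify",
    "fuzzy_convolve",
    "activate_pool",
    "defuzzify",
    "forward",
    "cross_entropy",
    "init_model",
    "train",
    "predict",
    "train_test_split",
    "confusion_counts",
    "classification_metrics",
    "REFERENCE_CONFIG",
    "DESK_CONFIG",
]

_EPS = 1e-12

# Reference architecture from the published parameter table (text-CNN style
# full-width kernel strips on a 56x28 input) and the reduced configuration
# used for desk-scale experiments and tests.
REFERENCE_CONFIG = {
    "input_shape": (56, 28),
    "n_mf": 2,
    "kernel_heights": (3, 4, 5),
    "kernel_width": "full",
    "pool": "global",
}
DESK_CONFIG = {
    "input_shape": (16, 16),
    "n_mf": 2,
    "n_kernels": 8,
    "kernel_size": (3, 3),
    "pool": "global",
}


# --- layer primitives -----------------------------------------------------

def gaussian_membership(x, centre: float, width: float):
    """exp(-(x - c)^2 / (2 sigma^2)); peak 1 at the centre, range (0, 1]."""
    if width <= 0:
        raise ValueError("membership width must be positive")
    x = np.asarray(x, dtype=np.float64)
    return np.exp(-((x - centre) ** 2) / (2.0 * width * width))


def fuzzify(x, centres, widths) -> np.ndarray:
    """Stack one membership grid per MF; output shape (n_mf, *x.shape)."""
    centres = np.atleast_1d(np.asarray(centres, dtype=np.float64))
    widths = np.atleast_1d(np.asarray(widths, dtype=np.float64))
    if centres.shape != widths.shape:
        raise ValueError("centres and widths must align")
    return np.stack([gaussian_membership(x, c, s) for c, s in zip(centres, widths)])


def fuzzy_convolve(xhat, kernel, mode: str = "sum") -> np.ndarray:
    """Valid 2-D convolution of a membership grid with a fuzzified kernel.

    sum mode (default): ordinary sum of products.
    minmax mode: x_ij = max_{a,b} min(K[a,b], X[i+a, j+b]).
    """
    x = np.asarray(xhat, dtype=np.float64)
    k = np.asarray(kernel, dtype=np.float64)
    if k.shape[0] > x.shape[0] or k.shape[1] > x.shape[1]:
        raise ValueError("kernel larger than the input grid")
    windows = sliding_window_view(x, k.shape)
    if mode == "sum":
        return np.einsum("ijab,ab->ij", windows, k)
    if mode == "minmax":
        return np.minimum(windows, k).max(axis=(-2, -1))
    raise ValueError(f"unknown conv mode {mode!r}")


def activate_pool(x, pool: tuple[int, int] | None = None) -> np.ndarray:
    """ReLU then max pooling.

    ``pool=None`` pools the whole grid to one value; otherwise the grid is
    tiled with non-overlapping ``pool`` windows (which must fit exactly).
    """
    a = np.maximum(np.asarray(x, dtype=np.float64), 0.0)
    if pool is None:
        return np.asarray(a.max())
    ph, pw = pool
    h, w = a.shape
    if h % ph or w % pw:
        raise ValueError(f"pool window {pool} does not tile the {a.shape} grid")
    return a.reshape(h // ph, ph, w // pw, pw).max(axis=(1, 3)).reshape(-1)


def defuzzify(x, my, axis: int = 0) -> np.ndarray | float:
    """Centre-of-gravity defuzzification along ``axis``.

    y = sum(My * x) / sum(x); inputs must be non-negative.  Where the
    denominator is zero the fallback is the plain mean of the centres.
    """
    x = np.asarray(x, dtype=np.float64)
    my = np.asarray(my, dtype=np.float64)
    if x.shape != my.shape:
        raise ValueError("x and My must share a shape")
    if np.any(x < 0):
        raise ValueError("defuzzification inputs must be non-negative")
    num = (my * x).sum(axis=axis)
    den = x.sum(axis=axis)
    fallback = my.mean(axis=axis)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(den > 0, num / np.where(den > 0, den, 1.0), fallback)
    return float(out) if out.ndim == 0 else out


def cross_entropy(zhat, z) -> float:
    """Mean binary cross-entropy (natural log); scores clipped to avoid log 0."""
    zhat = np.clip(np.asarray(zhat, dtype=np.float64), _EPS, 1.0 - _EPS)
    z = np.asarray(z, dtype=np.float64)
    if zhat.shape != z.shape:
        raise ValueError("score and label vectors must align")
    return float(-np.mean(z * np.log(zhat) + (1.0 - z) * np.log(1.0 - zhat)))


def _sigmoid(u: float) -> float:
    return 1.0 / (1.0 + np.exp(-u))


# --- model ----------------------------------------------------------------

@dataclass
class FCNNModel:
    mx: np.ndarray        # (n_mf,) fuzzification centres
    sigma_x: np.ndarray   # (n_mf,)
    kernels: np.ndarray   # (n_k, kh, kw) crisp kernels Wt
    mz: np.ndarray        # (n_k,) kernel-fuzzification centres
    sigma_z: np.ndarray   # (n_k,)
    my: np.ndarray        # (n_mf, n_k) defuzzification centres
    wf: np.ndarray        # (n_k,) output weights
    bf: float = 0.0       # output bias
    conv_mode: str = "sum"

    @property
    def n_mf(self) -> int:
        return len(self.mx)

    @property
    def n_kernels(self) -> int:
        return self.kernels.shape[0]

    def fuzzified_kernels(self) -> np.ndarray:
        return np.stack(
            [gaussian_membership(self.kernels[k], self.mz[k], self.sigma_z[k])
             for k in range(self.n_kernels)]
        )


@dataclass
class TrainConfig:
    epochs: int = 40
    batch_size: int = 16
    lr_fc: float = 0.5       # fully connected weights
    lr_my: float = 0.05      # defuzzification centres
    lr_mz: float = 0.02      # kernel-fuzzification centres
    lr_mx: float = 0.02      # input-fuzzification centres
    seed: int = 0
    split: float = 0.75      # train fraction for the companion splitter


def _prep(images) -> np.ndarray:
    a = np.asarray(images)
    if a.ndim == 2:
        a = a[None]
    if a.dtype == np.uint8:
        a = a.astype(np.float64) / 255.0
    return a.astype(np.float64)


def init_model(
    images,
    n_mf: int = 2,
    n_kernels: int = 8,
    kernel_size: tuple[int, int] = (3, 3),
    seed: int = 0,
    conv_mode: str = "sum",
) -> FCNNModel:
    """Data-driven initialisation.

    MF centres at intensity percentiles spread across the observed range
    (1st/99th for the default two MFs, so the top MF sits at bright-lesion
    intensity rather than bulk-tissue intensity), widths half the centre
    spacing; kernels drawn from N(0, 0.5); defuzzification centres spread
    over [0, 1] per MF row; small random output weights, zero bias.
    """
    x = _prep(images)
    rng = np.random.default_rng(seed)
    qs = np.linspace(1, 99, n_mf)
    mx = np.percentile(x, qs)
    spacing = np.diff(mx).mean() if n_mf > 1 else 0.5
    spacing = max(float(spacing), 0.05)
    sigma_x = np.full(n_mf, spacing / 2.0)
    kernels = rng.normal(0.0, 0.5, size=(n_kernels, *kernel_size))
    mz = np.zeros(n_kernels)
    sigma_z = np.full(n_kernels, 0.7)
    my = np.tile(np.linspace(0.0, 1.0, n_mf)[:, None], (1, n_kernels))
    wf = rng.normal(0.0, 0.1, size=n_kernels)
    return FCNNModel(
        mx=mx, sigma_x=sigma_x, kernels=kernels, mz=mz, sigma_z=sigma_z,
        my=my, wf=wf, conv_mode=conv_mode,
    )


def _forward_single(model: FCNNModel, img: np.ndarray, cache: bool = False):
    xhat = fuzzify(img, model.mx, model.sigma_x)          # (n_mf, H, W)
    kmu = model.fuzzified_kernels()                       # (n_k, kh, kw)
    n_mf, n_k = model.n_mf, model.n_kernels
    pooled = np.empty((n_mf, n_k))
    argmax = np.empty((n_mf, n_k, 2), dtype=np.int64)
    for m in range(n_mf):
        windows = sliding_window_view(xhat[m], kmu.shape[1:])
        conv = np.einsum("ijab,kab->kij", windows, kmu) if model.conv_mode == "sum" \
            else np.stack([np.minimum(windows, kmu[k]).max(axis=(-2, -1))
                           for k in range(n_k)])
        for k in range(n_k):
            act = np.maximum(conv[k], 0.0)
            flat = int(np.argmax(act))
            pooled[m, k] = act.reshape(-1)[flat]
            argmax[m, k] = divmod(flat, act.shape[1])
    y = defuzzify(pooled, model.my, axis=0)               # (n_k,)
    u = float(model.wf @ y) + model.bf
    z = _sigmoid(u)
    if not cache:
        return z
    return z, {"xhat": xhat, "kmu": kmu, "pooled": pooled, "argmax": argmax, "y": y}


def forward(model: FCNNModel, img) -> float:
    """Class score in (0, 1); deterministic for fixed model and input."""
    x = _prep(img)
    if x.shape[0] != 1:
        raise ValueError("forward takes a single image")
    return float(_forward_single(model, x[0]))


def predict(model: FCNNModel, images) -> np.ndarray:
    """Scores for a stack of images."""
    x = _prep(images)
    return np.array([_forward_single(model, xi) for xi in x])


def _gradients(model: FCNNModel, img: np.ndarray, label: float):
    """Per-sample CE gradients for (wf, my, mz, mx); chain rule, sum mode."""
    z, c = _forward_single(model, img, cache=True)
    du = z - float(label)                     # dCE/du for one sample
    y, pooled, kmu, xhat, argmax = c["y"], c["pooled"], c["kmu"], c["xhat"], c["argmax"]
    n_mf, n_k = model.n_mf, model.n_kernels
    kh, kw = model.kernels.shape[1:]

    g_wf = du * y
    g_bf = du
    g_y = du * model.wf                       # (n_k,)
    g_my = np.zeros_like(model.my)
    g_x = np.zeros_like(pooled)
    for k in range(n_k):
        s = pooled[:, k].sum()
        if s > 0:
            g_my[:, k] = g_y[k] * pooled[:, k] / s
            g_x[:, k] = g_y[k] * (model.my[:, k] - y[k]) / s
        else:
            g_my[:, k] = g_y[k] / n_mf        # fallback y_k = mean(My[:,k])

    g_mz = np.zeros_like(model.mz)
    g_mx = np.zeros_like(model.mx)
    if model.conv_mode == "sum":
        dk_dmz = kmu * (model.kernels - model.mz[:, None, None]) \
            / (model.sigma_z[:, None, None] ** 2)
        for m in range(n_mf):
            dxh_dmx = xhat[m] * (img - model.mx[m]) / (model.sigma_x[m] ** 2)
            for k in range(n_k):
                if g_x[m, k] == 0.0 or pooled[m, k] <= 0.0:
                    continue
                p, q = argmax[m, k]
                win = xhat[m][p : p + kh, q : q + kw]
                g_mz[k] += g_x[m, k] * float((dk_dmz[k] * win).sum())
                dwin = dxh_dmx[p : p + kh, q : q + kw]
                g_mx[m] += g_x[m, k] * float((kmu[k] * dwin).sum())
    loss = cross_entropy(np.array([z]), np.array([float(label)]))
    return loss, {"wf": g_wf, "bf": g_bf, "my": g_my, "mz": g_mz, "mx": g_mx}


def train(model: FCNNModel, images, labels, cfg: TrainConfig | None = None):
    """Seeded mini-batch gradient descent; returns (model, per-epoch CE).

    The model's parameter arrays are updated in place.  Requires both
    classes to be present in the training labels.
    """
    cfg = cfg or TrainConfig()
    x = _prep(images)
    z = np.asarray(labels, dtype=np.float64).reshape(-1)
    if len(x) != len(z):
        raise ValueError("images and labels must align")
    if len(np.unique(z)) < 2:
        raise ValueError("training requires at least two classes")
    rng = np.random.default_rng(cfg.seed)
    trace: list[float] = []
    n = len(x)
    for _ in range(cfg.epochs):
        order = rng.permutation(n)
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            acc = {k: 0.0 for k in ("wf", "bf", "my", "mz", "mx")}
            for i in idx:
                _, g = _gradients(model, x[i], z[i])
                for k in acc:
                    acc[k] = acc[k] + g[k]
            b = len(idx)
            model.wf -= cfg.lr_fc * acc["wf"] / b
            model.bf -= cfg.lr_fc * acc["bf"] / b
            model.my -= cfg.lr_my * acc["my"] / b
            if model.conv_mode == "sum":
                model.mz -= cfg.lr_mz * acc["mz"] / b
                model.mx -= cfg.lr_mx * acc["mx"] / b
        trace.append(cross_entropy(predict(model, x), z))
    return model, trace


def train_test_split(labels, fraction: float = 0.75, seed: int = 0):
    """Stratified index split; returns (train_idx, test_idx)."""
    if not (0.0 < fraction < 1.0):
        raise ValueError("fraction must be in (0, 1)")
    z = np.asarray(labels).reshape(-1)
    rng = np.random.default_rng(seed)
    train_idx: list[int] = []
    test_idx: list[int] = []
    for cls in np.unique(z):
        idx = np.flatnonzero(z == cls)
        idx = idx[rng.permutation(len(idx))]
        cut = max(1, int(round(fraction * len(idx))))
        train_idx.extend(idx[:cut].tolist())
        test_idx.extend(idx[cut:].tolist())
    return np.array(sorted(train_idx)), np.array(sorted(test_idx))


# --- evaluation -----------------------------------------------------------

@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def confusion_counts(y_true, y_pred) -> ConfusionCounts:
    t = np.asarray(y_true).astype(int).reshape(-1)
    p = np.asarray(y_pred).astype(int).reshape(-1)
    if t.shape != p.shape:
        raise ValueError("label vectors must align")
    return ConfusionCounts(
        tp=int(np.sum((t == 1) & (p == 1))),
        fp=int(np.sum((t == 0) & (p == 1))),
        tn=int(np.sum((t == 0) & (p == 0))),
        fn=int(np.sum((t == 1) & (p == 0))),
    )


def classification_metrics(c: ConfusionCounts) -> dict:
    """Specificity, sensitivity (= recall), accuracy, precision, F-measure.

    A metric whose denominator is zero is reported as None (undefined),
    never raised.
    """
    if c.total <= 0:
        raise ValueError("empty confusion table")

    def ratio(num, den):
        return num / den if den > 0 else None

    specificity = ratio(c.tn, c.tn + c.fp)
    sensitivity = ratio(c.tp, c.tp + c.fn)
    accuracy = (c.tn + c.tp) / c.total
    precision = ratio(c.tp, c.tp + c.fp)
    recall = sensitivity
    if precision is None or recall is None or (precision + recall) == 0:
        f_measure = None
    else:
        f_measure = 2.0 * precision * recall / (precision + recall)
    return {
        "specificity": specificity,
        "sensitivity": sensitivity,
        "accuracy": accuracy,
        "precision": precision,
        "recall": recall,
        "f_measure": f_measure,
    }
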