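"""Dimensionality reduction and intensity segmentation.

Two classical preprocessing stages for the diagnosis pipeline:

* improved PCA — column-centred sample covariance, eigendecomposition,
  and component selection by a cumulative explained-variance (contribution
  rate) threshold, 85% by default;
* K-means — Lloyd iterations over pixel intensities with a deterministic
  tie-break and a non-increasing objective trace, used for brain / tumour
  segmentation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "IPCAModel",
    "ClusterModel",
    "fit_ipca",
    "transform_ipca",
    "inverse_transform_ipca",
    "kmeans_cluster",
    "segment_image",
]


# --- improved PCA ---------------------------------------------------------

@dataclass
class IPCAModel:
    mean_: np.ndarray          # (m,)
    eigenvalues: np.ndarray    # (m,), descending, non-negative
    components: np.ndarray     # (m, m), orthonormal columns
    contributions: np.ndarray  # (m,), sums to 1
    cumulative: np.ndarray     # (m,)
    n_selected: int
    threshold: float


def fit_ipca(data, threshold: float = 0.85) -> IPCAModel:
    """Fit the improved-PCA model.

    Columns are centred, the 1/n sample covariance is eigendecomposed, the
    spectrum is sorted descending, and ``n_selected`` is the smallest count
    whose cumulative contribution rate strictly exceeds ``threshold``.
    Eigenvector signs are fixed so the largest-magnitude entry of each
    component is positive.
    """
    x = np.asarray(data, dtype=np.float64)
    if x.ndim != 2:
        raise ValueError("data must be a 2-D (samples x features) matrix")
    n, m = x.shape
    if n < 2:
        raise ValueError("need at least 2 samples")
    if not (0.0 < threshold < 1.0):
        raise ValueError("threshold must be in (0, 1)")
    mean = x.mean(axis=0)
    xc = x - mean
    cov = (xc.T @ xc) / n
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    # sign convention for reproducibility
    flips = np.sign(evecs[np.argmax(np.abs(evecs), axis=0), np.arange(m)])
    flips[flips == 0] = 1.0
    evecs = evecs * flips
    total = evals.sum()
    contrib = evals / total if total > 0 else np.full(m, 1.0 / m)
    cum = np.cumsum(contrib)
    selected = int(np.argmax(cum > threshold)) + 1 if np.any(cum > threshold) else m
    return IPCAModel(
        mean_=mean,
        eigenvalues=evals,
        components=evecs,
        contributions=contrib,
        cumulative=cum,
        n_selected=selected,
        threshold=threshold,
    )


def transform_ipca(model: IPCAModel, data, n_components: int | None = None) -> np.ndarray:
    """Project data onto the leading components: z = E^T (x - mean)."""
    x = np.asarray(data, dtype=np.float64)
    if x.ndim != 2 or x.shape[1] != model.mean_.size:
        raise ValueError("data dimensionality does not match the model")
    k = model.n_selected if n_components is None else int(n_components)
    if not (1 <= k <= model.components.shape[1]):
        raise ValueError("n_components out of range")
    return (x - model.mean_) @ model.components[:, :k]


def inverse_transform_ipca(model: IPCAModel, z) -> np.ndarray:
    """Map projections back to the original space (exact with all components)."""
    z = np.asarray(z, dtype=np.float64)
    k = z.shape[1]
    return z @ model.components[:, :k].T + model.mean_


# --- K-means --------------------------------------------------------------

@dataclass
class ClusterModel:
    centres: np.ndarray        # (k, d)
    assignments: np.ndarray    # (n,)
    objective_trace: list      # D after each assignment step
    n_iter: int
    converged: bool
    seed: int


def _assign(points: np.ndarray, centres: np.ndarray) -> tuple[np.ndarray, float]:
    # argmin breaks ties toward the lowest centre index
    d2 = ((points[:, None, :] - centres[None, :, :]) ** 2).sum(axis=2)
    labels = np.argmin(d2, axis=1)
    obj = float(d2[np.arange(len(points)), labels].sum())
    return labels, obj


def kmeans_cluster(points, k: int, max_iter: int = 100, seed: int = 0) -> ClusterModel:
    """Lloyd's algorithm with seeded data-point initialisation.

    Centres are initialised from ``k`` distinct data points; each iteration
    assigns every point to its nearest centre (Euclidean, ties to the lowest
    index) and recomputes each centre as the mean of its members.  An empty
    cluster is re-seeded from the point currently farthest from its own
    centre.  The recorded objective trace is non-increasing.
    """
    x = np.asarray(points, dtype=np.float64)
    if x.ndim == 1:
        x = x[:, None]
    n = x.shape[0]
    if k < 1 or k > n:
        raise ValueError(f"k must be in 1..{n}, got {k}")
    if max_iter < 1:
        raise ValueError("max_iter must be >= 1")
    rng = np.random.default_rng(seed)
    centres = x[rng.choice(n, size=k, replace=False)].copy()
    trace: list[float] = []
    labels = np.full(n, -1)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        new_labels, obj = _assign(x, centres)
        trace.append(obj)
        if np.array_equal(new_labels, labels):
            converged = True
            labels = new_labels
            break
        labels = new_labels
        for j in range(k):
            members = x[labels == j]
            if len(members) == 0:
                d2 = ((x - centres[labels]) ** 2).sum(axis=1)
                centres[j] = x[int(np.argmax(d2))]
            else:
                centres[j] = members.mean(axis=0)
    return ClusterModel(
        centres=centres,
        assignments=labels,
        objective_trace=trace,
        n_iter=it,
        converged=converged,
        seed=seed,
    )


def segment_image(img, k: int, max_iter: int = 100, seed: int = 0):
    """K-means segmentation of pixel intensities.

    Returns ``(label_image, model)``.  Labels are relabelled by ascending
    centre intensity so that label 0 is always the darkest tissue class.
    """
    a = np.asarray(img)
    if a.ndim != 2:
        raise ValueError("expected a 2-D image")
    pts = a.reshape(-1, 1).astype(np.float64)
    model = kmeans_cluster(pts, k, max_iter=max_iter, seed=seed)
    order = np.argsort(model.centres[:, 0], kind="stable")
    remap = np.empty(k, dtype=np.int64)
    remap[order] = np.arange(k)
    model.centres = model.centres[order]
    model.assignments = remap[model.assignments]
    labels = model.assignments.reshape(a.shape)
    return labels, model
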