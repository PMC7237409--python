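"""Ordinary and generalized Procrustes analysis for 2D landmark configurations.

Superimposition removes position, scale and rotation so that only shape
remains.  Reflections are deliberately excluded from the rotation solution:
left/right chirality is standardized at ingestion (see
:func:`molarmorph.outlines.standardize_side`), so a fit that needed a
reflection would indicate a data error rather than a shape difference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ProcrustesFit",
    "centroid_size",
    "center",
    "align_pair",
    "gpa",
    "procrustes_distance",
    "tangent_project",
]


def center(points: np.ndarray) -> np.ndarray:
    """Translate a configuration so its centroid is at the origin."""
    p = np.asarray(points, dtype=float)
    return p - p.mean(axis=0)


def centroid_size(points: np.ndarray) -> float:
    """Square root of summed squared distances of landmarks from their centroid.

    The standard geometric-morphometric size measure; homogeneous of degree 1
    under scaling.
    """
    c = center(points)
    s = float(np.sqrt(np.sum(c * c)))
    if s <= 0.0:
        raise ValueError("degenerate configuration: all points coincide")
    return s


def align_pair(
    source: np.ndarray, target: np.ndarray, allow_scale: bool = True
) -> tuple[float, float, np.ndarray, float]:
    """Ordinary (pairwise) Procrustes fit of ``source`` onto ``target``.

    Returns ``(angle, scale, translation, residual)`` for the similarity
    transform — a proper rotation (no reflection), isotropic scale and
    translation — minimizing the summed squared distances between
    corresponding points.  ``residual`` is the minimized sum.

    The transformed source is
    ``scale * source @ R(angle).T + translation``.
    """
    src = np.asarray(source, dtype=float)
    tgt = np.asarray(target, dtype=float)
    if src.shape != tgt.shape:
        raise ValueError(f"point counts differ: {src.shape} vs {tgt.shape}")
    mu_s = src.mean(axis=0)
    mu_t = tgt.mean(axis=0)
    a = src - mu_s
    b = tgt - mu_t
    # cross-covariance; proper rotation via the 2D closed form
    sxx = float(np.sum(a * b))                       # trace(a^T b)
    sxy = float(np.sum(a[:, 0] * b[:, 1] - a[:, 1] * b[:, 0]))
    angle = float(np.arctan2(sxy, sxx))
    denom = float(np.sum(a * a))
    if denom <= 0.0 or float(np.sum(b * b)) <= 0.0:
        raise ValueError("degenerate configuration in pairwise alignment")
    if allow_scale:
        scale = float(np.hypot(sxx, sxy)) / denom
    else:
        scale = 1.0
    ca, sa = np.cos(angle), np.sin(angle)
    rot = np.array([[ca, -sa], [sa, ca]])
    fitted = scale * a @ rot.T
    translation = mu_t - scale * (mu_s @ rot.T)
    residual = float(np.sum((fitted - b) ** 2))
    return angle, scale, translation, residual


def _rotate_onto(config: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Optimally rotate a centered configuration onto a centered reference."""
    angle, _, _, _ = align_pair(config, reference, allow_scale=False)
    ca, sa = np.cos(angle), np.sin(angle)
    rot = np.array([[ca, -sa], [sa, ca]])
    return config @ rot.T


@dataclass
class ProcrustesFit:
    """Result of a generalized Procrustes analysis.

    All aligned configurations and the consensus have unit centroid size; the
    consensus is the (renormalized) mean of the aligned configurations.
    """

    aligned: np.ndarray            # (n, k, 2)
    consensus: np.ndarray          # (k, 2)
    centroid_sizes: np.ndarray     # (n,) original sizes
    iterations_used: int
    converged: bool

    @property
    def n_specimens(self) -> int:
        return self.aligned.shape[0]

    @property
    def n_landmarks(self) -> int:
        return self.aligned.shape[1]

    def tangent_coordinates(self) -> np.ndarray:
        return tangent_project(self)


def gpa(
    configs: np.ndarray | list[np.ndarray],
    tol: float = 1e-10,
    max_iter: int = 100,
) -> ProcrustesFit:
    """Generalized Procrustes analysis.

    Iteratively: scale every configuration to unit centroid size, rotate each
    onto the current consensus, recompute the consensus as the mean and
    renormalize it — until the root-mean-square displacement of the consensus
    falls below ``tol`` or ``max_iter`` is reached.
    """
    arr = np.asarray(configs, dtype=float)
    if arr.ndim != 3 or arr.shape[2] != 2:
        raise ValueError("configs must be (n, k, 2)")
    n = arr.shape[0]
    if n < 2:
        raise ValueError("GPA needs at least 2 configurations")
    sizes = np.array([centroid_size(c) for c in arr])
    aligned = np.array([center(c) / s for c, s in zip(arr, sizes)])

    consensus = aligned[0].copy()
    consensus /= centroid_size(consensus)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        aligned = np.array([_rotate_onto(c, consensus) for c in aligned])
        new_consensus = aligned.mean(axis=0)
        new_consensus = center(new_consensus) / centroid_size(new_consensus)
        # remove the arbitrary global rotation drift before measuring change
        new_consensus = _rotate_onto(new_consensus, consensus)
        shift = float(np.sqrt(np.mean((new_consensus - consensus) ** 2)))
        consensus = new_consensus
        if shift < tol:
            converged = True
            break
    aligned = np.array([_rotate_onto(c, consensus) for c in aligned])
    return ProcrustesFit(
        aligned=aligned,
        consensus=consensus,
        centroid_sizes=sizes,
        iterations_used=it,
        converged=converged,
    )


def procrustes_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Partial Procrustes distance between two configurations.

    Both configurations are scaled to unit centroid size, then optimally
    rotated; the distance is the square root of the residual sum of squares.
    Symmetric in its arguments.
    """
    pa = center(np.asarray(a, dtype=float))
    pb = center(np.asarray(b, dtype=float))
    pa /= centroid_size(pa)
    pb /= centroid_size(pb)
    _, _, _, residual = align_pair(pa, pb, allow_scale=False)
    return float(np.sqrt(max(residual, 0.0)))


def tangent_project(fit: ProcrustesFit) -> np.ndarray:
    """Project aligned configurations onto the tangent space at the consensus.

    Each aligned configuration, vectorized to 2k coordinates, is orthogonally
    projected onto the hyperplane orthogonal to the (unit-norm) vectorized
    consensus.  The consensus itself maps to the zero vector and the
    projection is idempotent.
    """
    c = fit.consensus.ravel()
    c = c / np.linalg.norm(c)
    x = fit.aligned.reshape(fit.n_specimens, -1)
    return x - np.outer(x @ c, c)
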