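"""Thin-plate-spline bending energy and sliding semi-landmark alignment.

Semi-landmarks are points that are homologous only as members of a curve, not
individually; before analysis they are allowed to slide along the outline's
tangent direction so that their placement stops contributing arbitrary
variation.  Two sliding criteria are provided:

* **BEM** (bending energy minimization): displacements minimize the
  thin-plate-spline bending energy of the map from the current consensus to
  each specimen;
* **PDP** (Procrustes distance projection): each semi-landmark's residual to
  its consensus point is orthogonally projected onto the tangent direction,
  minimizing the Procrustes distance to the consensus.

Both operate on unit-centroid-size, GPA-aligned shapes; the order is fixed as
scale -> align -> slide -> re-align, with the consensus updated each pass.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .outlines import LandmarkConfiguration, LandmarkScheme
from .procrustes import ProcrustesFit, gpa

__all__ = [
    "BendingEnergyOperator",
    "SlidingResult",
    "bending_energy_operator",
    "bending_energy",
    "slide_bem",
    "slide_pdp",
    "tangent_directions",
]


def _tps_kernel(r2: np.ndarray) -> np.ndarray:
    """U(r) = r^2 log r, written on squared distances; U(0) = 0."""
    with np.errstate(divide="ignore", invalid="ignore"):
        out = 0.5 * r2 * np.log(r2)  # r^2 log r = r^2 * 0.5 * log r^2
    out[~np.isfinite(out)] = 0.0
    return out


@dataclass
class BendingEnergyOperator:
    """Bending-energy quadratic form of a TPS anchored on a reference.

    ``matrix`` is the k x k bending-energy matrix: for a target configuration
    with coordinate vectors x, y (matched point-for-point to the reference),
    the bending energy of the reference -> target TPS map is
    ``x @ matrix @ x + y @ matrix @ y``.  The matrix is symmetric positive
    semi-definite with a 3-dimensional null space spanned by the constant
    vector and the reference coordinates (affine maps bend nothing).
    """

    reference: np.ndarray  # (k, 2)
    matrix: np.ndarray     # (k, k)

    def energy(self, target: np.ndarray) -> float:
        t = np.asarray(target, dtype=float)
        return float(t[:, 0] @ self.matrix @ t[:, 0] + t[:, 1] @ self.matrix @ t[:, 1])


def bending_energy_operator(reference: np.ndarray) -> BendingEnergyOperator:
    """Build the bending-energy matrix of a TPS anchored on ``reference``.

    Assembles the standard TPS system ``L = [[K, P], [P^T, 0]]`` with kernel
    ``U(r) = r^2 log r`` and affine part ``P = [1, x, y]``, inverts it, and
    takes the upper-left k x k block; symmetrized against round-off.
    """
    ref = np.asarray(reference, dtype=float)
    k = len(ref)
    if k < 4:
        raise ValueError("bending energy needs at least 4 reference points")
    d2 = np.sum((ref[:, None, :] - ref[None, :, :]) ** 2, axis=-1)
    if np.any(d2[~np.eye(k, dtype=bool)] == 0.0):
        raise ValueError("coincident reference points make the TPS system singular")
    K = _tps_kernel(d2)
    P = np.column_stack([np.ones(k), ref])
    L = np.zeros((k + 3, k + 3))
    L[:k, :k] = K
    L[:k, k:] = P
    L[k:, :k] = P.T
    try:
        Linv = np.linalg.inv(L)
    except np.linalg.LinAlgError as exc:
        raise ValueError("singular TPS system (degenerate reference)") from exc
    Be = Linv[:k, :k]
    Be = 0.5 * (Be + Be.T)
    return BendingEnergyOperator(reference=ref, matrix=Be)


def bending_energy(reference: np.ndarray, target: np.ndarray) -> float:
    """TPS bending energy of the map carrying ``reference`` onto ``target``."""
    return bending_energy_operator(reference).energy(target)


def tangent_directions(points: np.ndarray, is_sliding: np.ndarray) -> np.ndarray:
    """Unit tangent at each sliding point from its two outline neighbors.

    The tangent at point i is the normalized chord from point i-1 to i+1 with
    closed-curve wraparound; rows for fixed landmarks are zero.
    """
    nxt = np.roll(points, -1, axis=0)
    prv = np.roll(points, 1, axis=0)
    chord = nxt - prv
    norm = np.linalg.norm(chord, axis=1, keepdims=True)
    norm[norm == 0.0] = 1.0
    t = chord / norm
    t[~is_sliding] = 0.0
    return t


@dataclass
class SlidingResult:
    """Outcome of a sliding semi-landmark alignment."""

    fit: ProcrustesFit              # final GPA of the slid configurations
    slid: np.ndarray                # (n, k, 2) slid, aligned configurations
    objective_trajectory: np.ndarray  # objective after each pass
    method: str                     # "BEM" | "PDP"
    iterations: int
    converged: bool


def _check_inputs(configs: list[LandmarkConfiguration]) -> tuple[np.ndarray, np.ndarray, LandmarkScheme]:
    if len(configs) < 2:
        raise ValueError("sliding needs at least 2 specimens")
    scheme = configs[0].scheme
    for c in configs:
        if c.scheme.name != scheme.name:
            raise ValueError("all configurations must share one scheme")
    arr = np.array([c.points for c in configs], dtype=float)
    return arr, configs[0].is_sliding.copy(), scheme


def _slide_loop(
    configs: list[LandmarkConfiguration],
    method: str,
    tol: float,
    max_iter: int,
) -> SlidingResult:
    arr, is_sliding, _ = _check_inputs(configs)
    fit = gpa(arr)
    shapes = fit.aligned.copy()
    trajectory: list[float] = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        consensus = fit.consensus
        if method == "BEM":
            op = bending_energy_operator(consensus)
        total_obj = 0.0
        new_shapes = np.empty_like(shapes)
        for i, y in enumerate(shapes):
            t = tangent_directions(y, is_sliding)
            if method == "BEM":
                y2 = _bem_step(y, t, is_sliding, op)
                total_obj += op.energy(y2)
            else:
                y2 = _pdp_step(y, t, is_sliding, consensus)
                total_obj += float(np.sum((y2 - consensus) ** 2))
            new_shapes[i] = y2
        # a pass that no longer lowers the criterion (the consensus update can
        # raise it slightly) is discarded: the trajectory stays non-increasing
        if trajectory and total_obj > trajectory[-1]:
            converged = True
            it -= 1
            break
        trajectory.append(total_obj)
        # re-superimpose the slid configurations and update the consensus
        fit = gpa(new_shapes)
        shapes = fit.aligned.copy()
        if len(trajectory) >= 2:
            prev, cur = trajectory[-2], trajectory[-1]
            if abs(prev - cur) < tol * max(1.0, abs(prev)):
                converged = True
                break
    return SlidingResult(
        fit=fit,
        slid=shapes,
        objective_trajectory=np.array(trajectory),
        method=method,
        iterations=it,
        converged=converged,
    )


def _bem_step(
    y: np.ndarray, t: np.ndarray, is_sliding: np.ndarray, op: BendingEnergyOperator
) -> np.ndarray:
    """One BEM update: tangent displacements minimizing bending energy.

    With vectorized coordinates v = [x; y] and the block-diagonal bending form
    L2 = diag(Be, Be), each sliding point j moves by w_j along its tangent
    u_j; the minimizer of E(v + T w) is w = -(T' L2 T)^+ T' L2 v.
    """
    k = len(y)
    sl = np.flatnonzero(is_sliding)
    m = len(sl)
    Be = op.matrix
    v = np.concatenate([y[:, 0], y[:, 1]])
    # T columns: tangent direction of sliding point j in the 2k coordinate space
    T = np.zeros((2 * k, m))
    T[sl, np.arange(m)] = t[sl, 0]
    T[k + sl, np.arange(m)] = t[sl, 1]
    L2v = np.concatenate([Be @ y[:, 0], Be @ y[:, 1]])
    A = T[:k].T @ Be @ T[:k] + T[k:].T @ Be @ T[k:]
    b = T.T @ L2v
    w = -np.linalg.lstsq(A, b, rcond=None)[0]
    y2 = y.copy()
    y2[sl] += w[:, None] * t[sl]
    return y2


def _pdp_step(
    y: np.ndarray, t: np.ndarray, is_sliding: np.ndarray, consensus: np.ndarray
) -> np.ndarray:
    """One PDP update: project each residual onto the tangent direction."""
    y2 = y.copy()
    sl = np.flatnonzero(is_sliding)
    resid = consensus[sl] - y[sl]
    w = np.sum(resid * t[sl], axis=1)
    y2[sl] += w[:, None] * t[sl]
    return y2


def slide_bem(
    configs: list[LandmarkConfiguration],
    tol: float = 1e-8,
    max_iter: int = 3,
) -> SlidingResult:
    """Slide semi-landmarks by bending energy minimization against the consensus."""
    return _slide_loop(configs, "BEM", tol, max_iter)


def slide_pdp(
    configs: list[LandmarkConfiguration],
    tol: float = 1e-8,
    max_iter: int = 3,
) -> SlidingResult:
    """Slide semi-landmarks by Procrustes distance projection against the consensus."""
    return _slide_loop(configs, "PDP", tol, max_iter)
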