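"""Elliptic Fourier analysis (EFA) of closed outlines.

A closed outline, parameterized by cumulative arc length, is decomposed into a
sum of harmonic ellipses.  Each harmonic n contributes a coefficient quadruple
(a_n, b_n, c_n, d_n):

    x(t) = a0 + sum_n a_n cos(2 pi n t / T) + b_n sin(2 pi n t / T)
    y(t) = c0 + sum_n c_n cos(2 pi n t / T) + d_n sin(2 pi n t / T)

Coefficients are computed with the exact piecewise-linear (chain) formulas, so
no numerical quadrature is involved.  Two shape-variable variants are
supported:

* **NEF** (normalized elliptic Fourier): raw coefficients standardized by the
  first harmonic — rotation to the first ellipse's major axis, starting point
  moved to that axis, scale divided by the major semi-axis length.  Invariant
  to rotation, scaling and starting-point choice of the input outline.
* **EFAproc** (Procrustes-aligned elliptic Fourier): raw coefficients of
  outlines that were already superimposed by GPA; no first-harmonic
  normalization (the alignment removed size/rotation/start-point ambiguity),
  offset terms dropped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

from .procrustes import ProcrustesFit, centroid_size

logger = logging.getLogger(__name__)

__all__ = [
    "EllipticHarmonics",
    "efa_decompose",
    "efa_normalize",
    "efa_proc",
    "efa_reconstruct",
    "harmonic_power",
]


@dataclass
class EllipticHarmonics:
    """Per-harmonic Fourier coefficient quadruples of one closed outline."""

    coeffs: np.ndarray        # (H, 4): columns a, b, c, d
    offset: tuple[float, float]  # (a0, c0): outline centroid terms
    normalized: str = "raw"   # "raw" | "NEF" | "EFAproc"
    degenerate_first: bool = False

    def __post_init__(self) -> None:
        self.coeffs = np.asarray(self.coeffs, dtype=float)
        if self.coeffs.ndim != 2 or self.coeffs.shape[1] != 4 or self.coeffs.shape[0] < 1:
            raise ValueError("coeffs must be (H, 4) with H >= 1")

    @property
    def n_harmonics(self) -> int:
        return self.coeffs.shape[0]

    def flatten(self, drop_normalized_constants: bool = False) -> np.ndarray:
        """Coefficient vector; for NEF optionally drop the fixed a1, b1, c1."""
        v = self.coeffs.ravel()
        if drop_normalized_constants and self.normalized == "NEF":
            return np.delete(v, [0, 1, 2])
        return v


def efa_decompose(outline: np.ndarray, n_harmonics: int = 20) -> EllipticHarmonics:
    """Decompose a closed polygon into elliptic Fourier coefficients.

    Uses the chain (piecewise-linear) formulas on the arc-length
    parameterization; the polygon is traversed once, last vertex connecting
    back to the first.
    """
    pts = np.asarray(outline, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("outline must be (n, 2)")
    n = len(pts)
    if n < 2 * n_harmonics + 2:
        raise ValueError(
            f"{n} points cannot support {n_harmonics} harmonics "
            f"(need >= {2 * n_harmonics + 2})"
        )
    d = np.roll(pts, -1, axis=0) - pts          # edge vectors, closing edge last
    dt = np.linalg.norm(d, axis=1)
    if np.any(dt == 0.0):
        raise ValueError("zero-length segment (repeated consecutive points)")
    T = dt.sum()
    t = np.concatenate([[0.0], np.cumsum(dt)])  # cumulative arc length, t[n] = T
    dx, dy = d[:, 0], d[:, 1]

    h = np.arange(1, n_harmonics + 1)[:, None]  # (H, 1)
    w = 2.0 * np.pi * h / T
    cos_t = np.cos(w * t[None, :])              # (H, n+1)
    sin_t = np.sin(w * t[None, :])
    dcos = cos_t[:, 1:] - cos_t[:, :-1]
    dsin = sin_t[:, 1:] - sin_t[:, :-1]
    fac = T / (2.0 * np.pi**2 * h.ravel() ** 2)

    a = fac * np.sum((dx / dt)[None, :] * dcos, axis=1)
    b = fac * np.sum((dx / dt)[None, :] * dsin, axis=1)
    c = fac * np.sum((dy / dt)[None, :] * dcos, axis=1)
    dcoef = fac * np.sum((dy / dt)[None, :] * dsin, axis=1)

    # offset (centroid) terms from the exact line integral of the chain
    xi = pts[:, 0]
    yi = pts[:, 1]
    # integral of x(t) dt over each linear segment = dt * (x_i + dx/2)
    a0 = float(np.sum(dt * (xi + 0.5 * dx)) / T)
    c0 = float(np.sum(dt * (yi + 0.5 * dy)) / T)

    return EllipticHarmonics(
        coeffs=np.column_stack([a, b, c, dcoef]), offset=(a0, c0), normalized="raw"
    )


def _shift_start(coeffs: np.ndarray, theta: float) -> np.ndarray:
    """Advance the starting point by phase ``theta`` (first-harmonic radians)."""
    out = np.empty_like(coeffs)
    for i in range(coeffs.shape[0]):
        nth = (i + 1) * theta
        rot = np.array([[np.cos(nth), -np.sin(nth)], [np.sin(nth), np.cos(nth)]])
        m = coeffs[i].reshape(2, 2) @ rot
        out[i] = m.ravel()
    return out


def _rotate(coeffs: np.ndarray, psi: float) -> np.ndarray:
    """Rotate the outline (all harmonics) by ``-psi`` in the plane."""
    rot = np.array([[np.cos(psi), np.sin(psi)], [-np.sin(psi), np.cos(psi)]])
    out = np.empty_like(coeffs)
    for i in range(coeffs.shape[0]):
        out[i] = (rot @ coeffs[i].reshape(2, 2)).ravel()
    return out


def _normalize_candidate(coeffs: np.ndarray, theta: float) -> np.ndarray:
    shifted = _shift_start(coeffs, theta)
    a1, b1, c1, d1 = shifted[0]
    psi = np.arctan2(c1, a1)
    rotated = _rotate(shifted, psi)
    scale = rotated[0, 0]
    return rotated / scale


def efa_normalize(h: EllipticHarmonics, tol: float = 1e-6) -> EllipticHarmonics:
    """First-harmonic (NEF) normalization of raw elliptic Fourier coefficients.

    Standardizes starting point and rotation to the first harmonic's major
    axis and divides by the major semi-axis length, so that a1 = 1 and
    b1 = c1 = 0.  The 180-degree ambiguity of the major axis is broken
    deterministically by picking the candidate whose higher-harmonic
    coefficient vector is lexicographically largest; a degenerate (circular)
    first harmonic is flagged and its orientation taken from harmonic 2.
    """
    if h.normalized != "raw":
        raise ValueError("efa_normalize expects raw harmonics")
    coeffs = h.coeffs
    a1, b1, c1, d1 = coeffs[0]
    denom = a1**2 + c1**2 - b1**2 - d1**2
    num = 2.0 * (a1 * b1 + c1 * d1)
    degenerate = bool(np.hypot(num, denom) < tol * np.sum(coeffs[0] ** 2))
    if degenerate and h.n_harmonics >= 2:
        # near-circular first ellipse: orientation undefined; take the phase
        # from harmonic 2's axis instead (halved: harmonic 2 runs twice as fast)
        a2, b2, c2, d2 = coeffs[1]
        num = 2.0 * (a2 * b2 + c2 * d2)
        denom = a2**2 + c2**2 - b2**2 - d2**2
        theta0 = 0.25 * np.arctan2(num, denom)
        logger.info("degenerate first harmonic; orientation tie-break from harmonic 2")
    else:
        theta0 = 0.5 * np.arctan2(num, denom)
    # theta is defined modulo pi/2 by the arctan and modulo pi by the axis
    # ambiguity; enumerate the four starting-point candidates on the axis ends
    # and keep those that land on the MAJOR axis, then tie-break.
    candidates = []
    for kk in range(4):
        theta = theta0 + kk * np.pi / 2.0
        shifted1 = _shift_start(coeffs[:1], theta)
        axis_len = np.hypot(shifted1[0, 0], shifted1[0, 2])
        candidates.append((axis_len, theta))
    best_len = max(c[0] for c in candidates)
    # on a degenerate (circular) first ellipse all four candidates are on the
    # "major" axis to numerical noise; keep them all and let the deterministic
    # tie-break below decide
    slack = 1e-3 if degenerate else 1e-9
    majors = [theta for (l, theta) in candidates if l > best_len * (1.0 - slack)]
    normed = [_normalize_candidate(coeffs, theta) for theta in majors]
    # deterministic tie-break between the two major-axis ends: lexicographically
    # largest coefficient vector after rounding away float fuzz
    keys = [tuple(np.round(nc.ravel(), 9)) for nc in normed]
    best = normed[keys.index(max(keys))]
    return EllipticHarmonics(
        coeffs=best, offset=(0.0, 0.0), normalized="NEF", degenerate_first=degenerate
    )


def efa_proc(fit: ProcrustesFit, n_harmonics: int = 20) -> list[EllipticHarmonics]:
    """Raw elliptic Fourier coefficients of GPA-aligned outlines (EFAproc).

    The configurations must come out of a generalized Procrustes fit (unit
    centroid size, common orientation and starting landmark); the coefficients
    are then directly comparable without first-harmonic normalization.
    Offset terms are dropped: alignment already centered the data.
    """
    out = []
    for cfg in fit.aligned:
        cs = centroid_size(cfg)
        if abs(cs - 1.0) > 1e-6:
            raise ValueError(
                f"configuration centroid size {cs:.8f} != 1; run gpa() first"
            )
        h = efa_decompose(cfg, n_harmonics)
        out.append(replace(h, offset=(0.0, 0.0), normalized="EFAproc"))
    return out


def efa_reconstruct(h: EllipticHarmonics, n_points: int = 128) -> np.ndarray:
    """Evaluate the inverse Fourier sum at equally spaced parameter values."""
    t = np.arange(n_points) / n_points
    n = np.arange(1, h.n_harmonics + 1)[:, None]
    arg = 2.0 * np.pi * n * t[None, :]
    cos_a, sin_a = np.cos(arg), np.sin(arg)
    a, b, c, d = (h.coeffs[:, i][:, None] for i in range(4))
    x = h.offset[0] + np.sum(a * cos_a + b * sin_a, axis=0)
    y = h.offset[1] + np.sum(c * cos_a + d * sin_a, axis=0)
    return np.column_stack([x, y])


def harmonic_power(h: EllipticHarmonics) -> np.ndarray:
    """Cumulative fraction of harmonic power, to guide the choice of H.

    Power of harmonic n is (a_n^2 + b_n^2 + c_n^2 + d_n^2) / 2.
    """
    p = np.sum(h.coeffs**2, axis=1) / 2.0
    return np.cumsum(p) / p.sum()
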