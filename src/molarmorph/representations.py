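"""Build shape-variable matrices from raw outlines.

A "representation" is one of the four ways of turning a set of closed m1
outlines into a comparable variable matrix:

* ``BEM`` / ``PDP`` — semi-landmark configurations slid by bending-energy
  minimization or Procrustes-distance projection, then Procrustes tangent
  coordinates;
* ``EFAproc`` — GPA-aligned outlines decomposed into raw elliptic Fourier
  coefficients;
* ``NEF`` — per-outline elliptic Fourier coefficients normalized by the
  first harmonic.

Combined with the three acquisition schemes (LM1_SL63, LM6_SL52, LM5_SL48)
this yields the 12 candidate methods of the selection benchmark.
"""

from __future__ import annotations

import numpy as np

from .classify import REPRESENTATIONS
from .fourier import efa_decompose, efa_normalize, efa_proc
from .outlines import (
    SCHEMES,
    LandmarkConfiguration,
    RawOutline,
    apply_scheme,
    detect_anchors,
)
from .procrustes import gpa, tangent_project
from .sliding import slide_bem, slide_pdp

__all__ = ["make_configurations", "build_representation"]


def make_configurations(
    outlines: list[RawOutline], scheme_name: str
) -> list[LandmarkConfiguration]:
    """Apply an acquisition scheme to each outline, detecting its anchors.

    Anchor placement follows the scheme's rule: the single landmark of
    LM1_SL63 sits at the strongest cusp apex; LM6_SL52 uses the six sharpest
    cusp curvature maxima; LM5_SL48 the five sharpest inter-cusp valleys.
    """
    scheme = SCHEMES[scheme_name]
    kind = "valley" if scheme_name == "LM5_SL48" else "cusp"
    configs = []
    for o in outlines:
        anchors = detect_anchors(o, scheme.fixed_count, kind=kind)
        configs.append(apply_scheme(o, scheme, anchors))
    return configs


def build_representation(
    outlines: list[RawOutline],
    scheme_name: str,
    representation: str,
    n_harmonics: int = 20,
    sliding_iterations: int = 3,
) -> tuple[np.ndarray, list[str]]:
    """Return ``(features, specimen_ids)`` for one representation x scheme.

    Features are tangent coordinates (BEM/PDP), raw aligned Fourier
    coefficients (EFAproc) or normalized Fourier coefficients with the three
    fixed first-harmonic constants dropped (NEF).
    """
    if representation not in REPRESENTATIONS:
        raise ValueError(f"unknown representation {representation!r}")
    configs = make_configurations(outlines, scheme_name)
    ids = [c.specimen_id for c in configs]
    max_h = (SCHEMES[scheme_name].total - 2) // 2
    h = min(n_harmonics, max_h)

    if representation in ("BEM", "PDP"):
        slider = slide_bem if representation == "BEM" else slide_pdp
        result = slider(configs, max_iter=sliding_iterations)
        return tangent_project(result.fit), ids
    if representation == "EFAproc":
        fit = gpa(np.array([c.points for c in configs]))
        harmonics = efa_proc(fit, n_harmonics=h)
        return np.array([hh.flatten() for hh in harmonics]), ids
    # NEF: per-outline decomposition and first-harmonic normalization
    feats = []
    for c in configs:
        raw = efa_decompose(c.points, n_harmonics=h)
        nef = efa_normalize(raw)
        feats.append(nef.flatten(drop_normalized_constants=True))
    return np.array(feats), ids
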