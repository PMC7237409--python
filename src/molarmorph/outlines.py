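"""Outline ingestion and landmark/semi-landmark scheme application.

Outlines are ordered closed 2D polylines digitized from the occlusal view of a
first lower molar (m1).  They enter the pipeline from TPS landmark files (the
format written by the tpsDig family of digitizers) together with a specimen
metadata table, and are converted into one of three landmark/semi-landmark
acquisition schemes:

* ``LM1_SL63`` — a single fixed starting landmark plus 63 sliding
  semi-landmarks around the whole outline;
* ``LM6_SL52`` — six fixed landmarks at cusp curvature maxima plus 52
  semi-landmarks on the arcs between them;
* ``LM5_SL48`` — five fixed landmarks at the inter-cusp valleys plus 48
  semi-landmarks.

Semi-landmarks are placed by equidistant arc-length resampling of each arc
between consecutive fixed landmarks, with semi-landmark counts allocated to
arcs proportionally to arc length (largest-remainder rounding).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "RawOutline",
    "LandmarkScheme",
    "LandmarkConfiguration",
    "SpecimenMeta",
    "SCHEMES",
    "TAXA",
    "TpsParseError",
    "read_tps",
    "write_tps",
    "read_metadata",
    "write_metadata",
    "standardize_side",
    "signed_area",
    "detect_anchors",
    "apply_scheme",
    "resample_closed",
]

#: the six-taxon vocabulary of the modern reference panel: three commensal
#: house-mouse subspecies and three wild short-tailed mice.
TAXA = (
    "M. m. domesticus",
    "M. m. musculus",
    "M. m. castaneus",
    "M. macedonicus",
    "M. spicilegus",
    "M. cypriacus",
)


class TpsParseError(ValueError):
    """Raised when a TPS landmark file is malformed; carries the line number."""


@dataclass(frozen=True)
class LandmarkScheme:
    """One of the three outline acquisition schemes.

    ``fixed_count`` biologically homologous landmarks anchor the outline;
    ``sliding_count`` semi-landmarks fill the arcs between them.
    """

    name: str
    fixed_count: int
    sliding_count: int
    anchor_rule: str

    def __post_init__(self) -> None:
        if (self.fixed_count, self.sliding_count) not in {(1, 63), (6, 52), (5, 48)}:
            raise ValueError(
                f"unknown scheme ({self.fixed_count}, {self.sliding_count}); "
                "expected (1,63), (6,52) or (5,48)"
            )

    @property
    def total(self) -> int:
        return self.fixed_count + self.sliding_count


SCHEMES: dict[str, LandmarkScheme] = {
    "LM1_SL63": LandmarkScheme(
        "LM1_SL63", 1, 63, "single starting landmark at the strongest cusp apex"
    ),
    "LM6_SL52": LandmarkScheme(
        "LM6_SL52", 6, 52, "six landmarks at cusp curvature maxima"
    ),
    "LM5_SL48": LandmarkScheme(
        "LM5_SL48", 5, 48, "five landmarks at inter-cusp valley curvature extrema"
    ),
}


@dataclass
class RawOutline:
    """An ordered closed polyline digitized from one specimen's m1 outline."""

    specimen_id: str
    points: np.ndarray  # (n, 2)
    site_id: str = ""
    scale: float | None = None
    closed: bool = True

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise ValueError("points must be an (n, 2) array")
        if len(self.points) < 3:
            raise ValueError("an outline needs at least 3 points")
        if not np.all(np.isfinite(self.points)):
            raise ValueError("non-finite coordinates")
        seg = np.diff(self.points, axis=0)
        if np.any(np.all(seg == 0.0, axis=1)):
            raise ValueError("consecutive duplicate points in outline")

    @property
    def n_points(self) -> int:
        return len(self.points)


@dataclass
class LandmarkConfiguration:
    """Fixed landmarks + sliding semi-landmarks under one scheme."""

    specimen_id: str
    points: np.ndarray  # (k, 2)
    is_sliding: np.ndarray  # (k,) bool
    scheme: LandmarkScheme

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        self.is_sliding = np.asarray(self.is_sliding, dtype=bool)
        if len(self.points) != self.scheme.total:
            raise ValueError(
                f"{len(self.points)} points but scheme {self.scheme.name} "
                f"expects {self.scheme.total}"
            )
        if int(self.is_sliding.sum()) != self.scheme.sliding_count:
            raise ValueError("sliding flags do not match scheme counts")
        if not np.all(np.isfinite(self.points)):
            raise ValueError("non-finite coordinates")


@dataclass(frozen=True)
class SpecimenMeta:
    """Metadata row for one specimen."""

    specimen_id: str
    group: str  # taxon for moderns, site for archaeological specimens
    role: str  # "modern_reference" | "archaeological"
    side: str = "left"  # "left" | "right"

    def __post_init__(self) -> None:
        if self.role not in ("modern_reference", "archaeological"):
            raise ValueError(f"unknown role {self.role!r}")
        if self.side not in ("left", "right"):
            raise ValueError(f"unknown side {self.side!r}")
        if self.role == "modern_reference" and self.group not in TAXA:
            raise ValueError(f"unknown taxon label {self.group!r}")


# ---------------------------------------------------------------------------
# TPS landmark files
# ---------------------------------------------------------------------------

def read_tps(path: str | Path) -> list[RawOutline]:
    """Read a TPS landmark file into a list of :class:`RawOutline`.

    Accepts the common digitizer dialect: records introduced by ``LM=n`` (or
    curve records with ``POINTS=n``), followed by ``n`` coordinate lines of two
    whitespace-separated reals and optional ``IMAGE=``, ``ID=`` and ``SCALE=``
    lines.  When ``SCALE`` is present the stored coordinates are multiplied by
    it (units per pixel).  Unknown ``KEY=`` lines are skipped with a warning.
    """
    path = Path(path)
    outlines: list[RawOutline] = []
    record_pts: list[tuple[float, float]] | None = None
    declared: int = 0
    rec_meta: dict[str, str] = {}
    rec_scale: float | None = None
    n_records = 0

    def flush(lineno: int) -> None:
        nonlocal record_pts, rec_meta, rec_scale, n_records
        if record_pts is None:
            return
        if len(record_pts) != declared:
            raise TpsParseError(
                f"{path}:{lineno}: record declares {declared} points "
                f"but lists {len(record_pts)}"
            )
        pts = np.array(record_pts, dtype=float)
        if rec_scale is not None:
            pts = pts * rec_scale
        sid = rec_meta.get("ID", f"{path.stem}_{n_records}")
        outlines.append(
            RawOutline(
                specimen_id=sid,
                points=pts,
                site_id=rec_meta.get("IMAGE", ""),
                scale=rec_scale,
            )
        )
        n_records += 1
        record_pts, rec_meta, rec_scale = None, {}, None

    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            upper = line.upper()
            if upper.startswith(("LM=", "POINTS=", "OUTLINES=")):
                key, _, val = line.partition("=")
                if key.upper() == "OUTLINES":
                    # outline-count header for curve files; informational only
                    continue
                flush(lineno)
                try:
                    declared = int(val)
                except ValueError as exc:
                    raise TpsParseError(
                        f"{path}:{lineno}: bad point count {val!r}"
                    ) from exc
                record_pts = []
            elif "=" in line and not _is_coordinate(line):
                key, _, val = line.partition("=")
                key = key.strip().upper()
                if record_pts is None:
                    raise TpsParseError(
                        f"{path}:{lineno}: metadata line before any LM=/POINTS= header"
                    )
                if key == "SCALE":
                    try:
                        rec_scale = float(val)
                    except ValueError as exc:
                        raise TpsParseError(
                            f"{path}:{lineno}: bad SCALE value {val!r}"
                        ) from exc
                elif key in ("ID", "IMAGE"):
                    rec_meta[key] = val.strip()
                else:
                    logger.warning("%s:%d: ignoring unknown key %r", path, lineno, key)
            else:
                if record_pts is None:
                    raise TpsParseError(
                        f"{path}:{lineno}: coordinates before any LM=/POINTS= header"
                    )
                toks = line.split()
                if len(toks) != 2:
                    raise TpsParseError(
                        f"{path}:{lineno}: expected two coordinates, got {line!r}"
                    )
                try:
                    record_pts.append((float(toks[0]), float(toks[1])))
                except ValueError as exc:
                    raise TpsParseError(
                        f"{path}:{lineno}: non-numeric coordinate in {line!r}"
                    ) from exc
                if len(record_pts) > declared:
                    raise TpsParseError(
                        f"{path}:{lineno}: more coordinates than declared ({declared})"
                    )
    flush(lineno if outlines or record_pts is not None else 0)
    return outlines


def _is_coordinate(line: str) -> bool:
    toks = line.split()
    if len(toks) != 2:
        return False
    try:
        float(toks[0]), float(toks[1])
    except ValueError:
        return False
    return True


def write_tps(outlines: Iterable[RawOutline], path: str | Path) -> None:
    """Write outlines as a TPS landmark file (round-trips through read_tps).

    Coordinates are written at 12 significant digits; SCALE is not re-applied
    (stored coordinates are already in physical units).
    """
    path = Path(path)
    with open(path, "w") as fh:
        for o in outlines:
            fh.write(f"LM={o.n_points}\n")
            for x, y in o.points:
                fh.write(f"{x:.12g} {y:.12g}\n")
            if o.site_id:
                fh.write(f"IMAGE={o.site_id}\n")
            fh.write(f"ID={o.specimen_id}\n")


def read_metadata(path: str | Path) -> list[SpecimenMeta]:
    df = pd.read_csv(path, dtype=str).fillna({"side": "left"})
    required = {"specimen_id", "group", "role"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"metadata missing columns: {sorted(missing)}")
    if "side" not in df.columns:
        df["side"] = "left"
    return [
        SpecimenMeta(r.specimen_id, r.group, r.role, r.side)
        for r in df.itertuples(index=False)
    ]


def write_metadata(meta: Iterable[SpecimenMeta], path: str | Path) -> None:
    pd.DataFrame(
        [(m.specimen_id, m.group, m.role, m.side) for m in meta],
        columns=["specimen_id", "group", "role", "side"],
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Geometry helpers
# ---------------------------------------------------------------------------

def signed_area(points: np.ndarray) -> float:
    """Shoelace signed area of a closed polygon (positive = counter-clockwise)."""
    p = np.asarray(points, dtype=float)
    x, y = p[:, 0], p[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def standardize_side(outline: RawOutline, side: str) -> RawOutline:
    """Bring left and right molars to a common handedness.

    Right-side outlines are reflected about the vertical axis and their point
    order reversed; afterwards every outline is forced to counter-clockwise
    traversal (positive signed area) so that superimposition can use rotations
    only.  Left outlines are passed through (up to the orientation fix).
    """
    pts = outline.points
    if side == "right":
        pts = pts.copy()
        pts[:, 0] = -pts[:, 0]
        pts = pts[::-1]
    elif side != "left":
        raise ValueError(f"unknown side {side!r}")
    if signed_area(pts) < 0:
        pts = pts[::-1]
    return replace(outline, points=np.ascontiguousarray(pts))


def _turning_angles(points: np.ndarray) -> np.ndarray:
    """Signed exterior (turning) angle at each vertex of a closed polygon."""
    prev = np.roll(points, 1, axis=0)
    nxt = np.roll(points, -1, axis=0)
    v1 = points - prev
    v2 = nxt - points
    ang = np.arctan2(
        v1[:, 0] * v2[:, 1] - v1[:, 1] * v2[:, 0],
        v1[:, 0] * v2[:, 0] + v1[:, 1] * v2[:, 1],
    )
    return ang


def detect_anchors(
    outline: RawOutline,
    n_anchors: int,
    kind: str = "cusp",
    min_separation: float | None = None,
    smooth_window: int = 5,
) -> np.ndarray:
    """Pick ``n_anchors`` fixed-landmark vertex indices by discrete curvature.

    ``kind="cusp"`` selects the sharpest convex vertices (cusp apices on a
    counter-clockwise outline); ``kind="valley"`` the sharpest concave ones
    (inter-cusp notches).  Turning angles are smoothed over a small circular
    window first — per-vertex angles are dominated by digitization jitter, the
    accumulated turn over a short arc is not.  Vertices are taken greedily in
    order of curvature strength subject to a minimum arc-length separation
    (default: a quarter of the mean inter-anchor spacing), then returned
    sorted in traversal order.
    """
    pts = outline.points
    ang = _turning_angles(pts)
    if signed_area(pts) < 0:
        ang = -ang
    if smooth_window > 1:
        w = min(smooth_window | 1, len(ang))  # odd window, centered
        padded = np.concatenate([ang[-(w // 2):], ang, ang[: w // 2]])
        ang = np.convolve(padded, np.ones(w) / w, mode="valid")
    score = ang if kind == "cusp" else -ang
    if kind not in ("cusp", "valley"):
        raise ValueError(f"unknown anchor kind {kind!r}")
    seg = np.linalg.norm(np.diff(np.vstack([pts, pts[:1]]), axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg)])[:-1]
    perim = float(seg.sum())
    if min_separation is None:
        min_separation = 0.25 * perim / n_anchors

    order = np.argsort(score)[::-1]
    chosen: list[int] = []
    for idx in order:
        ok = True
        for c in chosen:
            d = abs(arc[idx] - arc[c])
            if min(d, perim - d) < min_separation:
                ok = False
                break
        if ok:
            chosen.append(int(idx))
        if len(chosen) == n_anchors:
            break
    if len(chosen) < n_anchors:
        raise ValueError(
            f"could not place {n_anchors} anchors with separation {min_separation:.3g}"
        )
    return np.array(sorted(chosen), dtype=int)


def resample_closed(points: np.ndarray, n: int, start_arc: float = 0.0) -> np.ndarray:
    """Resample a closed polyline at ``n`` equidistant arc-length positions."""
    pts = np.asarray(points, dtype=float)
    loop = np.vstack([pts, pts[:1]])
    seg = np.linalg.norm(np.diff(loop, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    perim = cum[-1]
    s = (start_arc + perim * np.arange(n) / n) % perim
    ix = np.searchsorted(cum, s, side="right") - 1
    ix = np.clip(ix, 0, len(seg) - 1)
    t = (s - cum[ix]) / seg[ix]
    return loop[ix] + t[:, None] * (loop[ix + 1] - loop[ix])


def _largest_remainder(weights: np.ndarray, total: int) -> np.ndarray:
    """Allocate ``total`` integer counts proportionally to ``weights``."""
    quota = weights / weights.sum() * total
    base = np.floor(quota).astype(int)
    rem = total - int(base.sum())
    if rem > 0:
        frac = quota - base
        # ties broken by segment order for determinism
        extra = np.argsort(-frac, kind="stable")[:rem]
        base[extra] += 1
    return base


def apply_scheme(
    outline: RawOutline,
    scheme: LandmarkScheme | str,
    anchors: Sequence[int] | np.ndarray,
) -> LandmarkConfiguration:
    """Convert a raw outline into a landmark/semi-landmark configuration.

    ``anchors`` are vertex indices of the fixed landmarks on the polyline, in
    traversal order.  Semi-landmarks are placed by equidistant arc-length
    resampling of each arc between consecutive fixed landmarks; the number of
    semi-landmarks per arc is proportional to the arc's length
    (largest-remainder rounding).  The first anchor becomes index 0 of the
    configuration and the outline is traversed counter-clockwise.
    """
    if isinstance(scheme, str):
        scheme = SCHEMES[scheme]
    anchors = np.asarray(anchors, dtype=int)
    if len(anchors) != scheme.fixed_count:
        raise ValueError(
            f"scheme {scheme.name} needs {scheme.fixed_count} anchors, got {len(anchors)}"
        )
    if len(anchors) > 1 and np.any(np.diff(anchors) <= 0):
        raise ValueError("anchors must be strictly increasing along the outline")
    pts = outline.points
    if signed_area(pts) < 0:
        # re-index anchors under reversal so they keep pointing at the same vertices
        n = len(pts)
        pts = pts[::-1]
        anchors = np.sort((n - 1 - anchors) % n)
    if len(pts) < scheme.total:
        warnings.warn(
            f"outline has {len(pts)} vertices, fewer than the scheme's "
            f"{scheme.total} output points; resampling will interpolate"
        )

    loop = np.vstack([pts, pts[:1]])
    seg = np.linalg.norm(np.diff(loop, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    perim = cum[-1]
    if perim <= 0:
        raise ValueError("outline too short to resample")
    anchor_arc = cum[anchors]

    if scheme.fixed_count == 1:
        # one closed arc starting and ending at the single anchor
        coords = resample_closed(pts, scheme.total, start_arc=float(anchor_arc[0]))
        sliding = np.ones(scheme.total, dtype=bool)
        sliding[0] = False
        return LandmarkConfiguration(outline.specimen_id, coords, sliding, scheme)

    # arc lengths between consecutive anchors (closed wrap)
    arc_len = np.diff(np.concatenate([anchor_arc, [anchor_arc[0] + perim]]))
    counts = _largest_remainder(arc_len, scheme.sliding_count)

    out_pts: list[np.ndarray] = []
    sliding_flags: list[bool] = []
    for j in range(scheme.fixed_count):
        s0 = anchor_arc[j]
        L = arc_len[j]
        m = counts[j]
        # anchor + m equally spaced interior semi-landmarks on this arc
        positions = s0 + L * np.arange(m + 1) / (m + 1)
        sub = _points_at_arc(loop, cum, positions % perim)
        out_pts.append(sub)
        sliding_flags.extend([False] + [True] * m)
    coords = np.vstack(out_pts)
    return LandmarkConfiguration(
        outline.specimen_id, coords, np.array(sliding_flags), scheme
    )


def _points_at_arc(loop: np.ndarray, cum: np.ndarray, s: np.ndarray) -> np.ndarray:
    seg = np.diff(cum)
    ix = np.searchsorted(cum, s, side="right") - 1
    ix = np.clip(ix, 0, len(seg) - 1)
    t = (s - cum[ix]) / seg[ix]
    return loop[ix] + t[:, None] * (loop[ix + 1] - loop[ix])


def configurations_to_frame(configs: Sequence[LandmarkConfiguration]) -> pd.DataFrame:
    """Export configurations as a wide CSV-style table (x1, y1, x2, y2, ...)."""
    k = configs[0].scheme.total
    cols = [c for i in range(1, k + 1) for c in (f"x{i}", f"y{i}")]
    rows = {c.specimen_id: c.points.ravel() for c in configs}
    return pd.DataFrame.from_dict(rows, orient="index", columns=cols).rename_axis(
        "specimen_id"
    )
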