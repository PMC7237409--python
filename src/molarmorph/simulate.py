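"""Synthetic molar-like outlines with known taxon structure.

Real m1 coordinate data are not bundled; instead this module generates closed
outlines that mimic the occlusal silhouette of a murine first lower molar —
an elongated ellipse with lobes — and plants a known taxon signal in them:

* a root template (64 vertices) carrying six graded cusps — a dominant
  anterior apex, a posterior apex and four lateral lobes; a qualitative
  mimic, not a biological model;
* per-taxon shape offsets of controlled Procrustes magnitude ``delta``,
  either spread over the whole outline or concentrated on a short arc of one
  lobe (``localized=True`` — the regime in which semi-landmark methods are
  expected to outperform whole-outline Fourier variables);
* within-taxon individual variation as Gaussian deviations in the Procrustes
  tangent space with root-mean-square Procrustes magnitude ``sigma``;
* per-vertex digitization jitter, and a random similarity transform
  (rotation, scale, translation) so that superimposition is genuinely
  exercised.

Effect sizes are therefore expressed in Procrustes-distance units, making
``delta / sigma`` a direct between/within separation ratio.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from shapely.geometry import LineString

from .fourier import EllipticHarmonics, efa_reconstruct
from .outlines import TAXA, RawOutline, SpecimenMeta, write_metadata, write_tps
from .procrustes import center, centroid_size, procrustes_distance

__all__ = [
    "TaxonTemplate",
    "SiteSpec",
    "SimulationDesign",
    "StudyData",
    "make_templates",
    "simulate_specimen",
    "simulate_study",
    "write_study",
    "training_design",
    "assignment_design",
]


def _is_simple(points: np.ndarray) -> bool:
    ring = LineString(np.vstack([points, points[:1]]))
    return bool(ring.is_simple)


def _clearance_ok(points: np.ndarray, min_clearance: float = 0.012, min_edge: float = 0.004) -> bool:
    """Reject outlines that nearly pinch shut or have collapsed edges.

    A template that passes within a few noise SDs of self-intersection would
    make specimen draws fail; the thresholds are expressed at unit centroid
    size.
    """
    n = len(points)
    edges = np.linalg.norm(np.diff(np.vstack([points, points[:1]]), axis=0), axis=1)
    if edges.min() < min_edge:
        return False
    dist = np.linalg.norm(points[:, None, :] - points[None, :, :], axis=-1)
    idx = np.arange(n)
    sep = np.abs(idx[:, None] - idx[None, :])
    sep = np.minimum(sep, n - sep)
    return bool(dist[sep > 2].min() >= min_clearance)


def _root_outline(n_vertices: int = 64) -> np.ndarray:
    """Cusped closed root outline at unit centroid size.

    An elongated base ellipse carrying six radial bumps of graded prominence:
    a dominant anterior apex, a posterior apex and four lateral lobes.  The
    grading keeps curvature-based anchor detection stable across noisy
    specimens (real m1 landmarks are anatomically distinct for the same
    reason); resemblance to a molar silhouette is qualitative only.
    """
    th = 2.0 * np.pi * np.arange(n_vertices) / n_vertices
    bumps = (
        (0.0, 0.24, 18.0),                 # anterior apex (dominant)
        (np.pi, 0.13, 12.0),               # posterior apex
        (np.deg2rad(62.0), 0.15, 14.0),    # lateral lobes, graded amplitudes
        (np.deg2rad(-62.0), 0.12, 14.0),
        (np.deg2rad(126.0), 0.10, 14.0),
        (np.deg2rad(-126.0), 0.085, 14.0),
    )
    r = np.ones(n_vertices)
    for phi, amp, kappa in bumps:
        r = r + amp * np.exp(kappa * (np.cos(th - phi) - 1.0))
    pts = np.column_stack([r * np.cos(th), 0.62 * r * np.sin(th)])
    pts = center(pts)
    return pts / centroid_size(pts)


def _similarity_basis(pts: np.ndarray) -> np.ndarray:
    """Orthonormal basis of the similarity directions at a centered shape."""
    k = len(pts)
    x, y = pts[:, 0], pts[:, 1]
    basis = np.column_stack(
        [
            np.concatenate([np.ones(k), np.zeros(k)]),   # translate x
            np.concatenate([np.zeros(k), np.ones(k)]),   # translate y
            np.concatenate([-y, x]),                     # rotate
            np.concatenate([x, y]),                      # scale
        ]
    )
    q, _ = np.linalg.qr(basis)
    return q


def _project_tangent(v: np.ndarray, pts: np.ndarray) -> np.ndarray:
    """Remove the similarity components of a vertex-displacement field."""
    q = _similarity_basis(pts)
    return v - q @ (q.T @ v)


@dataclass
class TaxonTemplate:
    """Mean outline of one synthetic taxon.

    ``offset`` is a vertex-displacement field applied to the root outline's
    vertices, scaled so the Procrustes distance between this taxon's mean and
    the root is ``delta``.  ``base`` records the root outline's elliptic
    Fourier description.
    """

    label: str
    base: EllipticHarmonics
    root_vertices: np.ndarray      # (k, 2) shared root outline
    offset: np.ndarray             # (k, 2) vertex displacement field
    delta: float
    localized: bool

    @property
    def vertices(self) -> np.ndarray:
        return self.root_vertices + self.offset


def make_templates(
    n_taxa: int,
    delta: float,
    localized: bool = False,
    seed: int | np.random.Generator | None = None,
    labels: list[str] | None = None,
) -> list[TaxonTemplate]:
    """Build ``n_taxa`` taxon mean outlines at Procrustes distance ``delta``
    from a shared cusped root outline.

    Offsets are smooth random displacement fields: global low-frequency bends
    by default, or (``localized=True``) Gaussian bumps concentrated on one
    lobe, each taxon on a different arc of the outline.  ``delta = 0`` yields
    identical templates.  An offset that would make the outline
    self-intersect is rejected with an error.
    """
    if n_taxa < 1:
        raise ValueError("n_taxa >= 1")
    if delta < 0:
        raise ValueError("delta >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    root_pts = _root_outline()
    from .fourier import efa_decompose

    base = efa_decompose(root_pts, n_harmonics=20)
    k = len(root_pts)
    if labels is None:
        labels = [TAXA[i] if i < len(TAXA) else f"taxon_{i}" for i in range(n_taxa)]

    templates = []
    t_param = np.arange(k) / k
    for i in range(n_taxa):
        cand = None
        for attempt in range(20):
            if delta == 0.0:
                off = np.zeros((k, 2))
                cand = root_pts
                break
            if localized:
                # Gaussian bump along the outline, pushed along the normal
                centre = (i / n_taxa + rng.uniform(0.0, 0.5 / n_taxa)) % 1.0
                width = 0.04
                dist = np.minimum(np.abs(t_param - centre), 1.0 - np.abs(t_param - centre))
                bump = np.exp(-0.5 * (dist / width) ** 2)
                tang = np.roll(root_pts, -1, axis=0) - np.roll(root_pts, 1, axis=0)
                normal = np.column_stack([tang[:, 1], -tang[:, 0]])
                normal /= np.linalg.norm(normal, axis=1, keepdims=True)
                sign = rng.choice([-1.0, 1.0])
                field_ = sign * bump[:, None] * normal
            else:
                # smooth global field from random low-order harmonics
                field_ = np.zeros((k, 2))
                for n in range(2, 7):
                    amp = rng.normal(size=4) / n
                    field_[:, 0] += amp[0] * np.cos(2 * np.pi * n * t_param) + amp[1] * np.sin(
                        2 * np.pi * n * t_param
                    )
                    field_[:, 1] += amp[2] * np.cos(2 * np.pi * n * t_param) + amp[3] * np.sin(
                        2 * np.pi * n * t_param
                    )
            v = _project_tangent(np.concatenate([field_[:, 0], field_[:, 1]]), root_pts)
            field_ = np.column_stack([v[:k], v[k:]])
            # scale so the realized Procrustes distance to the root is delta
            off = field_ / np.linalg.norm(field_) * delta
            for _ in range(3):
                d = procrustes_distance(root_pts, root_pts + off)
                if d > 0:
                    off *= delta / d
            cand = root_pts + off
            if _is_simple(cand) and _clearance_ok(cand):
                break
            cand = None
        if cand is None:
            raise ValueError(
                f"delta={delta} produces a self-intersecting or pinched template "
                f"for {labels[i]!r}"
            )
        templates.append(
            TaxonTemplate(
                label=labels[i],
                base=base,
                root_vertices=root_pts,
                offset=off,
                delta=delta,
                localized=localized,
            )
        )
    return templates


def simulate_specimen(
    template: TaxonTemplate,
    sigma: float,
    noise: float,
    seed: int | np.random.Generator | None = None,
    specimen_id: str = "spec",
    site_id: str = "",
    max_retries: int = 10,
) -> RawOutline:
    """Draw one specimen outline from a taxon template.

    The template's vertices are perturbed by an isotropic Gaussian deviation
    in the Procrustes tangent space whose root-mean-square Procrustes
    magnitude is ``sigma``.  With ``noise > 0`` the outline is then
    re-digitized — equidistant arc-length vertices from a random starting
    phase, mimicking an outline tool whose recorded vertices are not
    homologous points — and each vertex jittered with SD ``noise``
    (measurement error, in units of the unit-centroid-size template).
    Finally a random similarity transform carries it into "image"
    coordinates (rotation uniform on the circle, scale in [0.8, 1.25] x 100
    units, uniform translation).  Self-intersecting draws are resampled a
    bounded number of times.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    base = template.vertices
    k = len(base)
    m = 2 * k - 4  # shape degrees of freedom after removing similarity
    from .outlines import resample_closed

    for _ in range(max_retries):
        g = rng.normal(size=2 * k)
        tang = _project_tangent(g, base)
        dev = np.column_stack([tang[:k], tang[k:]]) * (sigma / np.sqrt(m) if sigma > 0 else 0.0)
        shape = base + dev
        if noise > 0:
            # re-digitize: equidistant arc-length vertices from a random
            # starting phase (recorded vertices are not homologous points),
            # then per-vertex measurement jitter
            seg = np.linalg.norm(
                np.diff(np.vstack([shape, shape[:1]]), axis=0), axis=1
            )
            shape = resample_closed(
                shape, len(shape), start_arc=rng.uniform(0.0, float(seg.sum()))
            )
            shape = shape + rng.normal(scale=noise, size=shape.shape)
        if _is_simple(shape):
            break
    else:
        raise ValueError("could not draw a simple (non-self-intersecting) outline")
    theta = rng.uniform(0.0, 2.0 * np.pi)
    scale = 100.0 * rng.uniform(0.8, 1.25)
    shift = rng.uniform(0.0, 500.0, size=2)
    rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
    pts = scale * shape @ rot.T + shift
    return RawOutline(specimen_id=specimen_id, points=pts, site_id=site_id)


@dataclass(frozen=True)
class SiteSpec:
    """Composition of one archaeological site."""

    site_id: str
    mix: dict           # taxon -> fraction (sums to 1)
    n: int

    def counts(self) -> dict:
        fracs = np.array(list(self.mix.values()), dtype=float)
        if abs(fracs.sum() - 1.0) > 1e-9:
            raise ValueError(f"site {self.site_id}: mixture fractions must sum to 1")
        quota = fracs * self.n
        base = np.floor(quota).astype(int)
        rem = self.n - int(base.sum())
        order = np.argsort(-(quota - base), kind="stable")
        for j in order[:rem]:
            base[j] += 1
        return dict(zip(self.mix.keys(), (int(v) for v in base)))


@dataclass
class SimulationDesign:
    """Full design of a synthetic study."""

    modern_counts: dict                 # taxon -> n
    sites: list[SiteSpec] = field(default_factory=list)
    delta: float = 0.05                 # between-taxon Procrustes offset
    sigma: float = 0.01                 # within-taxon Procrustes SD
    noise: float = 0.001                # digitization jitter SD (~1 px at typical image scale)
    localized: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.modern_counts.values()):
            raise ValueError("negative specimen count")
        if self.sigma < 0 or self.noise < 0 or self.delta < 0:
            raise ValueError("sigma, noise and delta must be >= 0")
        if not self.modern_counts and not self.sites:
            raise ValueError("empty design")


@dataclass
class StudyData:
    """A simulated study: outlines + metadata + ground truth."""

    outlines: list[RawOutline]
    meta: list[SpecimenMeta]
    truth: pd.DataFrame     # specimen_id, role, site_id, true_taxon

    def modern(self) -> tuple[list[RawOutline], list[SpecimenMeta]]:
        pairs = [(o, m) for o, m in zip(self.outlines, self.meta) if m.role == "modern_reference"]
        return [p[0] for p in pairs], [p[1] for p in pairs]

    def archaeological(self) -> tuple[list[RawOutline], list[SpecimenMeta]]:
        pairs = [(o, m) for o, m in zip(self.outlines, self.meta) if m.role == "archaeological"]
        return [p[0] for p in pairs], [p[1] for p in pairs]


def simulate_study(design: SimulationDesign) -> StudyData:
    """Simulate a modern reference panel plus site-grouped archaeological data.

    All taxa named anywhere in the design share one set of templates drawn at
    the design's ``delta``; modern specimens carry their taxon label,
    archaeological ones their site, and the truth table records both.
    """
    rng = np.random.default_rng(design.seed)
    taxa = list(
        dict.fromkeys(
            list(design.modern_counts) + [t for s in design.sites for t in s.mix]
        )
    )
    templates = {
        t.label: t
        for t in make_templates(
            len(taxa), design.delta, localized=design.localized, seed=rng, labels=taxa
        )
    }
    outlines: list[RawOutline] = []
    meta: list[SpecimenMeta] = []
    truth_rows = []
    counter = 0
    for taxon, n in design.modern_counts.items():
        for _ in range(n):
            sid = f"MOD{counter:04d}"
            counter += 1
            outlines.append(
                simulate_specimen(
                    templates[taxon], design.sigma, design.noise, rng, specimen_id=sid
                )
            )
            meta.append(SpecimenMeta(sid, taxon, "modern_reference"))
            truth_rows.append((sid, "modern_reference", "", taxon))
    for site in design.sites:
        for taxon, n in site.counts().items():
            for _ in range(n):
                sid = f"ARC{counter:04d}"
                counter += 1
                outlines.append(
                    simulate_specimen(
                        templates[taxon],
                        design.sigma,
                        design.noise,
                        rng,
                        specimen_id=sid,
                        site_id=site.site_id,
                    )
                )
                meta.append(SpecimenMeta(sid, site.site_id, "archaeological"))
                truth_rows.append((sid, "archaeological", site.site_id, taxon))
    truth = pd.DataFrame(
        truth_rows, columns=["specimen_id", "role", "site_id", "true_taxon"]
    )
    return StudyData(outlines=outlines, meta=meta, truth=truth)


def write_study(study: StudyData, out_dir: str | Path) -> dict:
    """Write a study to disk as TPS + metadata CSV + truth CSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "tps": out / "outlines.tps",
        "metadata": out / "metadata.csv",
        "truth": out / "truth.csv",
    }
    write_tps(study.outlines, paths["tps"])
    write_metadata(study.meta, paths["metadata"])
    study.truth.to_csv(paths["truth"], index=False)
    return paths


def training_design(seed: int = 0, **kw) -> SimulationDesign:
    """The three-taxon method-selection training design (30 + 30 + 20)."""
    return SimulationDesign(
        modern_counts={
            "M. m. domesticus": 30,
            "M. m. musculus": 30,
            "M. macedonicus": 20,
        },
        seed=seed,
        **kw,
    )


def assignment_design(seed: int = 0, **kw) -> SimulationDesign:
    """A paper-like assignment design: six-taxon modern panel + mixed sites.

    Moderns cover the three commensal subspecies (30 each) and the three wild
    species (20 each); archaeological sites include single-taxon deposits of
    varying size, one 50/50 mixed deposit and one single-specimen site.
    """
    sites = [
        SiteSpec("site_dom", {"M. m. domesticus": 1.0}, 15),
        SiteSpec("site_mus", {"M. m. musculus": 1.0}, 15),
        SiteSpec("site_cas", {"M. m. castaneus": 1.0}, 15),
        SiteSpec("site_mac", {"M. macedonicus": 1.0}, 15),
        SiteSpec("site_mix", {"M. m. domesticus": 0.5, "M. macedonicus": 0.5}, 20),
        SiteSpec("site_single", {"M. m. domesticus": 1.0}, 1),
    ]
    return SimulationDesign(
        modern_counts={
            "M. m. domesticus": 30,
            "M. m. musculus": 30,
            "M. m. castaneus": 30,
            "M. macedonicus": 20,
            "M. spicilegus": 20,
            "M. cypriacus": 20,
        },
        sites=sites,
        seed=seed,
        **kw,
    )
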