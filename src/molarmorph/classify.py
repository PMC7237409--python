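"""Dimensionality reduction, discriminant analysis and KNN assignment.

This is the statistical core of the numerical taxonomy: shape variables
(tangent coordinates or Fourier coefficients) are reduced by PCA, groups are
compared by MANOVA and ordinated by canonical variate analysis (CVA), the
taxonomic signal of a representation is scored by leave-one-out
cross-validated linear discriminant analysis (LDA), and archaeological
population mean shapes are assigned to taxa by a k-nearest-neighbour vote in
the CV1-CV2 plane with k = round(sqrt(N)).

All estimators here are written directly on the linear algebra; scikit-learn
is used only in the test suite as an independent cross-check.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, stats

__all__ = [
    "ShapeSpace",
    "DiscriminantModel",
    "CrossValidationReport",
    "CanonicalSpace",
    "KnnModel",
    "WilksResult",
    "pca_reduce",
    "lda_fit",
    "loocv_lda",
    "manova_wilks",
    "cva",
    "knn_classify",
    "knn_k",
    "compare_methods",
]


# ---------------------------------------------------------------------------
# PCA reduction
# ---------------------------------------------------------------------------

@dataclass
class ShapeSpace:
    """A reduced shape space: centered PCA scores and their basis."""

    scores: np.ndarray                 # (n, d)
    basis: np.ndarray                  # (p, d), orthonormal columns
    mean: np.ndarray                   # (p,)
    explained_variance_ratio: np.ndarray  # (d,)
    rule: str

    @property
    def n_components(self) -> int:
        return self.scores.shape[1]

    def transform(self, x: np.ndarray) -> np.ndarray:
        """Project new observations (rows of length p) into the score space."""
        return (np.atleast_2d(x) - self.mean) @ self.basis


def pca_reduce(
    data: np.ndarray,
    variance_fraction: float | None = 0.95,
    n_components: int | None = None,
    n_groups: int | None = None,
) -> ShapeSpace:
    """Principal-component reduction of a specimens x variables matrix.

    Retention rule: a fixed ``n_components`` if given, otherwise the smallest
    d whose cumulative explained variance reaches ``variance_fraction``.
    When ``n_groups`` is given, d is additionally capped at
    ``n_specimens - n_groups - 1`` so that downstream pooled within-group
    covariances stay invertible.  Components beyond the matrix rank are never
    returned (a warning is emitted if the request exceeded it).
    """
    x = np.asarray(data, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("data must be (n >= 2, p)")
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite values in data")
    mean = x.mean(axis=0)
    xc = x - mean
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    tol = s.max(initial=0.0) * max(x.shape) * np.finfo(float).eps
    rank = int(np.sum(s > tol))
    var = s**2 / (x.shape[0] - 1)
    evr = var / var.sum() if var.sum() > 0 else var

    if n_components is not None:
        d = n_components
        rule = f"fixed d={n_components}"
    else:
        if variance_fraction is None:
            raise ValueError("give either variance_fraction or n_components")
        d = int(np.searchsorted(np.cumsum(evr), variance_fraction - 1e-12) + 1)
        rule = f"variance_fraction={variance_fraction}"
    if n_groups is not None:
        cap = x.shape[0] - n_groups - 1
        if d > cap:
            d = max(1, cap)
            rule += f", capped at n-g-1={cap}"
    if d > rank:
        warnings.warn(f"requested {d} components but rank is {rank}; returning {rank}")
        d = rank
    d = max(d, 1)
    return ShapeSpace(
        scores=u[:, :d] * s[:d],
        basis=vt[:d].T,
        mean=mean,
        explained_variance_ratio=evr[:d],
        rule=rule,
    )


# ---------------------------------------------------------------------------
# Linear discriminant analysis
# ---------------------------------------------------------------------------

def _group_stats(x: np.ndarray, labels: np.ndarray):
    groups = np.array(sorted(set(labels)))
    means = np.array([x[labels == g].mean(axis=0) for g in groups])
    n = len(x)
    g = len(groups)
    w = np.zeros((x.shape[1], x.shape[1]))
    for i, lab in enumerate(groups):
        xc = x[labels == lab] - means[i]
        w += xc.T @ xc
    return groups, means, w, n, g


@dataclass
class DiscriminantModel:
    """LDA model: group means plus a pooled within-group covariance."""

    groups: np.ndarray              # (g,) labels
    means: np.ndarray               # (g, d)
    pooled_cov: np.ndarray          # (d, d)
    priors: np.ndarray              # (g,)

    def discriminant_scores(self, x: np.ndarray) -> np.ndarray:
        """Linear discriminant score of each observation for each group."""
        x = np.atleast_2d(x)
        try:
            ci = linalg.inv(self.pooled_cov)
        except linalg.LinAlgError as exc:
            raise ValueError(
                "singular pooled covariance; reduce dimensionality further"
            ) from exc
        lin = x @ ci @ self.means.T
        const = -0.5 * np.sum(self.means @ ci * self.means, axis=1) + np.log(self.priors)
        return lin + const

    def classify(self, x: np.ndarray) -> np.ndarray:
        scores = self.discriminant_scores(x)
        return self.groups[np.argmax(scores, axis=1)]

    def posteriors(self, x: np.ndarray) -> np.ndarray:
        s = self.discriminant_scores(x)
        s = s - s.max(axis=1, keepdims=True)
        e = np.exp(s)
        return e / e.sum(axis=1, keepdims=True)


def lda_fit(
    scores: np.ndarray,
    labels,
    priors: np.ndarray | None = None,
) -> DiscriminantModel:
    """Fit an LDA with pooled within-group covariance; equal priors by default.

    Equal priors are the sensible default here because reference-group sizes
    are sampling-design choices, not taxon prevalences.
    """
    x = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    groups, means, w, n, g = _group_stats(x, labels)
    if g < 2:
        raise ValueError("need at least 2 groups")
    counts = np.array([np.sum(labels == lab) for lab in groups])
    if np.any(counts < 2):
        raise ValueError("each group needs at least 2 members")
    pooled = w / (n - g)
    ev = np.linalg.eigvalsh(pooled)
    if ev[0] <= 1e-10 * max(ev[-1], 1e-300):
        raise ValueError("singular pooled covariance; reduce dimensionality further")
    if priors is None:
        priors = np.full(g, 1.0 / g)
    else:
        priors = np.asarray(priors, dtype=float)
        priors = priors / priors.sum()
    return DiscriminantModel(groups=groups, means=means, pooled_cov=pooled, priors=priors)


@dataclass
class CrossValidationReport:
    """Aggregate of a leave-one-out cross-validation run."""

    assignments: np.ndarray        # predicted label per specimen
    true_labels: np.ndarray
    confusion: pd.DataFrame        # rows true, columns predicted (counts)
    overall_rate: float
    per_group_rate: pd.Series
    flagged_folds: list[int] = field(default_factory=list)


def loocv_lda(scores: np.ndarray, labels, priors=None) -> CrossValidationReport:
    """Leave-one-out cross-validated LDA classification.

    Every specimen is classified by a model refit on the other N - 1; the
    refit is done naively per fold, so the result is exactly the estimator it
    claims to be.  Folds in which the held-out specimen's group falls below 2
    members are classified among the remaining groups and flagged.
    """
    x = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    n = len(x)
    preds = np.empty(n, dtype=labels.dtype)
    flagged: list[int] = []
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        xi, li = x[mask], labels[mask]
        keep = np.array([np.sum(li == lab) >= 2 for lab in li])
        if not keep.all():
            flagged.append(i)
            xi, li = xi[keep], li[keep]
        model = lda_fit(xi, li, priors)
        preds[i] = model.classify(x[i][None, :])[0]
    groups = sorted(set(labels) | set(preds))
    conf = pd.DataFrame(0, index=groups, columns=groups, dtype=int)
    for t, p in zip(labels, preds):
        conf.loc[t, p] += 1
    overall = float(np.mean(preds == labels))
    per_group = pd.Series(
        {g: float(np.mean(preds[labels == g] == g)) for g in sorted(set(labels))}
    )
    return CrossValidationReport(
        assignments=preds,
        true_labels=labels,
        confusion=conf,
        overall_rate=overall,
        per_group_rate=per_group,
        flagged_folds=flagged,
    )


# ---------------------------------------------------------------------------
# MANOVA and CVA
# ---------------------------------------------------------------------------

@dataclass
class WilksResult:
    wilks_lambda: float
    f_statistic: float
    df1: float
    df2: float
    p_value: float


def manova_wilks(scores: np.ndarray, labels) -> WilksResult:
    """One-way MANOVA via Wilks' Lambda with Rao's F approximation.

    Lambda = det(W) / det(W + B) with W, B the within- and between-group
    cross-product matrices.  For one variable and two groups the F statistic
    reduces to the squared two-sample t statistic.
    """
    x = np.atleast_2d(np.asarray(scores, dtype=float))
    if x.shape[1] == 0:
        raise ValueError("no variables")
    labels = np.asarray(labels)
    groups, means, w, n, g = _group_stats(x, labels)
    grand = x.mean(axis=0)
    counts = np.array([np.sum(labels == lab) for lab in groups])
    dm = means - grand
    b = (dm * counts[:, None]).T @ dm
    sign_w, logdet_w = np.linalg.slogdet(w)
    sign_t, logdet_t = np.linalg.slogdet(w + b)
    if sign_w <= 0:
        raise ValueError("singular within-group matrix")
    lam = float(np.exp(logdet_w - logdet_t))
    p = x.shape[1]
    q = g - 1
    s = np.sqrt((p**2 * q**2 - 4) / (p**2 + q**2 - 5)) if (p**2 + q**2 - 5) > 0 else 1.0
    m = n - 1 - (p + g) / 2.0
    df1 = p * q
    df2 = m * s - p * q / 2.0 + 1.0
    lam_s = lam ** (1.0 / s)
    f = (1.0 - lam_s) / lam_s * df2 / df1
    pval = float(stats.f.sf(f, df1, df2))
    return WilksResult(lam, float(f), float(df1), float(df2), pval)


@dataclass
class CanonicalSpace:
    """Canonical variate ordination of grouped observations.

    Axes maximize between-group relative to within-group variation and are
    scaled so the pooled within-group variance of every canonical variate
    is 1; new observations are projectable via :meth:`transform`.
    """

    scores: np.ndarray             # (n, c)
    axes: np.ndarray               # (d, c)
    grand_mean: np.ndarray         # (d,)
    group_centroids: pd.DataFrame  # groups x c
    eigenvalues: np.ndarray        # (c,) non-increasing
    groups: np.ndarray

    @property
    def n_axes(self) -> int:
        return self.axes.shape[1]

    def transform(self, x: np.ndarray) -> np.ndarray:
        return (np.atleast_2d(x) - self.grand_mean) @ self.axes


def cva(scores: np.ndarray, labels) -> CanonicalSpace:
    """Canonical variate analysis of a reduced shape space.

    Solves the generalized eigenproblem B a = lambda W a and rescales axes so
    each canonical variate has unit pooled within-group variance; returns
    c = min(g - 1, d) axes ordered by decreasing eigenvalue.
    """
    x = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    groups, means, w, n, g = _group_stats(x, labels)
    if g < 2:
        raise ValueError("need at least 2 groups")
    grand = x.mean(axis=0)
    counts = np.array([np.sum(labels == lab) for lab in groups])
    dm = means - grand
    b = (dm * counts[:, None]).T @ dm
    d = x.shape[1]
    c = min(g - 1, d)
    try:
        evals, evecs = linalg.eigh(b, w)
    except linalg.LinAlgError as exc:
        raise ValueError("singular within-group matrix") from exc
    order = np.argsort(evals)[::-1][:c]
    evals = evals[order]
    a = evecs[:, order]
    # eigh normalizes a' W a = I; rescale so a' (W/(n-g)) a = I
    a = a * np.sqrt(n - g)
    # deterministic sign: largest-|.| component of each axis positive
    for j in range(a.shape[1]):
        i = int(np.argmax(np.abs(a[:, j])))
        if a[i, j] < 0:
            a[:, j] = -a[:, j]
    cv_scores = (x - grand) @ a
    centroids = pd.DataFrame(
        (means - grand) @ a,
        index=list(groups),
        columns=[f"CV{j+1}" for j in range(c)],
    )
    return CanonicalSpace(
        scores=cv_scores,
        axes=a,
        grand_mean=grand,
        group_centroids=centroids,
        eigenvalues=np.maximum(evals, 0.0),
        groups=groups,
    )


# ---------------------------------------------------------------------------
# KNN in the CV1-CV2 plane
# ---------------------------------------------------------------------------

def knn_k(n_training: int) -> int:
    """k = round(sqrt(N)), at least 1 (N = number of training vectors)."""
    return max(1, int(round(np.sqrt(n_training))))


@dataclass
class KnnModel:
    """Training vectors in the CV1-CV2 plane with taxon labels."""

    training: np.ndarray   # (N, 2)
    labels: np.ndarray     # (N,)
    k: int | None = None
    ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.training = np.asarray(self.training, dtype=float)
        self.labels = np.asarray(self.labels)
        if len(self.training) == 0:
            raise ValueError("empty training set")
        if self.k is None:
            self.k = knn_k(len(self.training))
        if not 1 <= self.k <= len(self.training):
            raise ValueError(f"k={self.k} outside [1, {len(self.training)}]")
        if self.ids is None:
            self.ids = np.arange(len(self.training))


def knn_classify(model: KnnModel, query: np.ndarray):
    """Majority vote among the k nearest training vectors (Euclidean).

    Ties are broken deterministically: first by the smallest mean distance to
    the voting neighbours of that label, then lexicographically by label.
    Returns ``(label, vote_counts, neighbor_ids)``.
    """
    q = np.asarray(query, dtype=float).ravel()
    d = np.linalg.norm(model.training - q, axis=1)
    order = np.lexsort((model.ids, d))  # stable under exact distance ties
    nearest = order[: model.k]
    votes: dict = {}
    dists: dict = {}
    for idx in nearest:
        lab = model.labels[idx]
        votes[lab] = votes.get(lab, 0) + 1
        dists.setdefault(lab, []).append(d[idx])
    top = max(votes.values())
    tied = [lab for lab, v in votes.items() if v == top]
    winner = min(tied, key=lambda lab: (float(np.mean(dists[lab])), str(lab)))
    return winner, votes, model.ids[nearest]


# ---------------------------------------------------------------------------
# Representation x scheme benchmark
# ---------------------------------------------------------------------------

REPRESENTATIONS = ("BEM", "PDP", "EFAproc", "NEF")


def compare_methods(
    outlines,
    labels,
    representations=REPRESENTATIONS,
    schemes=("LM1_SL63", "LM6_SL52", "LM5_SL48"),
    n_harmonics: int = 20,
    variance_fraction: float = 0.95,
) -> "BenchmarkResults":
    """Score every representation x acquisition-scheme cell by LOOCV-LDA.

    For each cell the shape variables are built (sliding semi-landmark tangent
    coordinates or Fourier coefficients), reduced by PCA under the
    variance-fraction rule capped for covariance invertibility, and the
    overall and per-group leave-one-out correct classification rates
    recorded.  The winner is the cell with the highest overall rate, ties
    broken by the smaller number of shape variables (parsimony).
    """
    from .representations import build_representation

    labels = np.asarray(labels)
    groups = sorted(set(labels))
    if len(groups) < 3:
        raise ValueError("benchmark needs at least 3 groups")
    rows = []
    for scheme in schemes:
        for rep in representations:
            try:
                feats, _ = build_representation(
                    outlines, scheme, rep, n_harmonics=n_harmonics
                )
            except Exception as exc:  # representation inapplicable to scheme
                rows.append(
                    {
                        "representation": rep,
                        "scheme": scheme,
                        "n_vars": np.nan,
                        "d_retained": np.nan,
                        "overall_rate": np.nan,
                        "note": f"NA: {exc}",
                    }
                )
                continue
            space = pca_reduce(
                feats, variance_fraction=variance_fraction, n_groups=len(groups)
            )
            report = loocv_lda(space.scores, labels)
            row = {
                "representation": rep,
                "scheme": scheme,
                "n_vars": feats.shape[1],
                "d_retained": space.n_components,
                "overall_rate": report.overall_rate,
                "note": "",
            }
            for gname in groups:
                row[f"rate_{gname}"] = report.per_group_rate[gname]
            rows.append(row)
    table = pd.DataFrame(rows)
    return BenchmarkResults(table=table)


@dataclass
class BenchmarkResults:
    """Benchmark table over representation x scheme cells, with its winner."""

    table: pd.DataFrame

    @property
    def winner(self) -> tuple[str, str]:
        ok = self.table.dropna(subset=["overall_rate"])
        best = ok.sort_values(
            ["overall_rate", "n_vars"], ascending=[False, True], kind="stable"
        ).iloc[0]
        return best["representation"], best["scheme"]

    def summary(self) -> str:
        rep, scheme = self.winner
        lines = [
            "Representation x scheme benchmark (LOOCV-LDA overall correct rate)",
            self.table.to_string(index=False, float_format=lambda v: f"{v:.3f}"),
            f"winner: {rep} on {scheme}",
        ]
        return "\n".join(lines)
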