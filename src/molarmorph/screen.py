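"""Per-site Gaussian-mixture screening for sympatric taxa.

Before an archaeological deposit is treated as one biological population, its
specimens' shape scores are screened with model-based clustering: Gaussian
mixtures are fitted by expectation-maximization for 1..max_clusters components
across several covariance families, and the best model is chosen by BIC.  A
site whose best model has more than one cluster is split into
cluster-populations downstream, so that two sympatric taxa are never pooled
under one site name.

BIC convention used here: ``BIC = 2 log L - n_params log n`` — LARGER is
better (conventions differ between fields; this one makes the selection rule
"argmax BIC").
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

__all__ = ["ScreenResult", "MixtureFit", "fit_gmm", "screen_site", "COVARIANCE_FAMILIES"]

#: supported covariance families, named by shape x sharing
COVARIANCE_FAMILIES = ("spherical-equal", "diagonal-equal", "full-equal", "full-varying")


@dataclass
class MixtureFit:
    """One converged Gaussian mixture fit."""

    n_clusters: int
    family: str
    weights: np.ndarray          # (k,)
    means: np.ndarray            # (k, d)
    covariances: np.ndarray      # (k, d, d)
    log_likelihood: float
    bic: float
    responsibilities: np.ndarray  # (n, k)
    ll_trajectory: np.ndarray
    converged: bool
    degenerate: bool = False

    @property
    def assignments(self) -> np.ndarray:
        return np.argmax(self.responsibilities, axis=1)

    @property
    def uncertainty(self) -> np.ndarray:
        """1 - max posterior responsibility, per specimen."""
        return 1.0 - self.responsibilities.max(axis=1)


def _n_params(k: int, d: int, family: str) -> int:
    mean_p = k * d
    weight_p = k - 1
    if family == "spherical-equal":
        cov_p = 1
    elif family == "diagonal-equal":
        cov_p = d
    elif family == "full-equal":
        cov_p = d * (d + 1) // 2
    elif family == "full-varying":
        cov_p = k * d * (d + 1) // 2
    else:
        raise ValueError(f"unknown covariance family {family!r}")
    return mean_p + weight_p + cov_p


def _log_gauss(x: np.ndarray, mean: np.ndarray, cov: np.ndarray) -> np.ndarray:
    d = x.shape[1]
    sign, logdet = np.linalg.slogdet(cov)
    if sign <= 0:
        return np.full(len(x), -np.inf)
    xc = x - mean
    maha = np.sum(xc @ np.linalg.inv(cov) * xc, axis=1)
    return -0.5 * (d * np.log(2.0 * np.pi) + logdet + maha)


def _kmeanspp_init(x: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """k-means++-style seeding of component means."""
    n = len(x)
    centers = [x[rng.integers(n)]]
    for _ in range(1, k):
        d2 = np.min(
            [np.sum((x - c) ** 2, axis=1) for c in centers], axis=0
        )
        total = d2.sum()
        if total <= 0:
            centers.append(x[rng.integers(n)])
            continue
        centers.append(x[rng.choice(n, p=d2 / total)])
    return np.array(centers)


def _m_step(x, resp, family, var_floor):
    n, d = x.shape
    k = resp.shape[1]
    nk = resp.sum(axis=0) + 1e-300
    weights = nk / n
    means = (resp.T @ x) / nk[:, None]
    covs = np.empty((k, d, d))
    if family == "full-varying":
        for j in range(k):
            xc = x - means[j]
            covs[j] = (resp[:, j][:, None] * xc).T @ xc / nk[j]
    else:
        pooled = np.zeros((d, d))
        for j in range(k):
            xc = x - means[j]
            pooled += (resp[:, j][:, None] * xc).T @ xc
        pooled /= n
        if family == "spherical-equal":
            pooled = np.eye(d) * (np.trace(pooled) / d)
        elif family == "diagonal-equal":
            pooled = np.diag(np.diag(pooled))
        covs[:] = pooled
    covs += np.eye(d) * var_floor
    return weights, means, covs


def fit_gmm(
    x: np.ndarray,
    n_clusters: int,
    family: str = "full-equal",
    rng: np.random.Generator | None = None,
    n_restarts: int = 20,
    max_iter: int = 300,
    tol: float = 1e-8,
) -> MixtureFit:
    """Fit a Gaussian mixture by EM with multiple seeded restarts.

    The log-likelihood is non-decreasing across EM iterations within each
    restart; the best restart by final log-likelihood is returned.  A variance
    floor of 1e-8 x (data scale) guards against singular components; a fit
    that still collapses is marked degenerate.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    n, d = x.shape
    if rng is None:
        rng = np.random.default_rng()
    data_scale = float(np.mean(np.var(x, axis=0))) or 1.0
    var_floor = 1e-8 * data_scale

    best: MixtureFit | None = None
    for _ in range(max(1, n_restarts if n_clusters > 1 else 1)):
        means = (
            _kmeanspp_init(x, n_clusters, rng)
            if n_clusters > 1
            else x.mean(axis=0)[None, :]
        )
        weights = np.full(n_clusters, 1.0 / n_clusters)
        covs = np.tile(np.cov(x.T).reshape(d, d) + np.eye(d) * var_floor, (n_clusters, 1, 1))
        prev_ll = -np.inf
        traj = []
        converged = False
        resp = np.full((n, n_clusters), 1.0 / n_clusters)
        for _ in range(max_iter):
            # E step
            log_p = np.column_stack(
                [
                    np.log(weights[j] + 1e-300) + _log_gauss(x, means[j], covs[j])
                    for j in range(n_clusters)
                ]
            )
            m = log_p.max(axis=1, keepdims=True)
            log_norm = m + np.log(np.sum(np.exp(log_p - m), axis=1, keepdims=True))
            resp = np.exp(log_p - log_norm)
            ll = float(log_norm.sum())
            traj.append(ll)
            if ll - prev_ll < tol * max(1.0, abs(ll)) and np.isfinite(prev_ll):
                converged = True
                break
            prev_ll = ll
            # M step
            weights, means, covs = _m_step(x, resp, family, var_floor)
        ll = traj[-1]
        # a component that collapses onto a handful of points is a likelihood
        # singularity, not structure: flag fits whose smallest covariance
        # eigenvalue sits near the variance floor (far below the data scale)
        # or whose effective membership cannot determine a covariance
        min_eig = min(np.linalg.eigvalsh(c).min() for c in covs)
        nk_eff = resp.sum(axis=0)
        degenerate = bool(
            min_eig < max(10.0 * var_floor, 1e-4 * data_scale)
            or np.any(nk_eff < d + 1)
            or not np.isfinite(ll)
        )
        bic = 2.0 * ll - _n_params(n_clusters, d, family) * np.log(n)
        fit = MixtureFit(
            n_clusters=n_clusters,
            family=family,
            weights=weights,
            means=means,
            covariances=covs,
            log_likelihood=ll,
            bic=bic,
            responsibilities=resp,
            ll_trajectory=np.array(traj),
            converged=converged,
            degenerate=degenerate,
        )
        if best is None:
            best = fit
        elif best.degenerate and not fit.degenerate:
            best = fit
        elif fit.degenerate == best.degenerate and fit.log_likelihood > best.log_likelihood:
            best = fit
    assert best is not None
    return best


@dataclass
class ScreenResult:
    """Cluster screen of one site's specimens."""

    site_id: str
    candidates: list[tuple[int, str, float]]  # (k, family, BIC)
    selected: MixtureFit | None
    assignments: np.ndarray
    uncertainty: np.ndarray
    warning: str = ""

    @property
    def n_clusters(self) -> int:
        return 1 if self.selected is None else self.selected.n_clusters


def screen_site(
    site_scores: np.ndarray,
    site_id: str = "",
    max_clusters: int = 3,
    families=COVARIANCE_FAMILIES,
    seed: int | np.random.Generator | None = None,
    n_restarts: int = 20,
    min_n: int = 4,
) -> ScreenResult:
    """Screen one site's shape scores for multiple clusters.

    Fits mixtures for every cluster count in 1..max_clusters across the given
    covariance families and selects the model with maximal BIC; degenerate
    fits are excluded from the comparison.  Sites with fewer than ``min_n``
    specimens are passed through as a single cluster with a warning (small
    sites are retained in the analysis, never dropped).
    """
    x = np.atleast_2d(np.asarray(site_scores, dtype=float))
    n = len(x)
    rng = (
        seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    )
    if n < min_n:
        msg = f"site {site_id!r}: n={n} below minimum {min_n}; kept as one cluster"
        warnings.warn(msg)
        return ScreenResult(
            site_id=site_id,
            candidates=[],
            selected=None,
            assignments=np.zeros(n, dtype=int),
            uncertainty=np.zeros(n),
            warning=msg,
        )
    candidates: list[tuple[int, str, float]] = []
    fits: list[MixtureFit] = []
    for k in range(1, min(max_clusters, n - 1) + 1):
        for family in families:
            fit = fit_gmm(x, k, family=family, rng=rng, n_restarts=n_restarts)
            if fit.degenerate:
                logger.info("site %s: degenerate %d-cluster %s fit discarded", site_id, k, family)
                continue
            candidates.append((k, family, fit.bic))
            fits.append(fit)
    best = max(range(len(fits)), key=lambda i: fits[i].bic)
    sel = fits[best]
    return ScreenResult(
        site_id=site_id,
        candidates=candidates,
        selected=sel,
        assignments=sel.assignments,
        uncertainty=sel.uncertainty,
    )
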