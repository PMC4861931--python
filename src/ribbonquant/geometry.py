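"""Positional analysis: axis projection, ensemble alignment, EM/BIC
clustering, and quantile outlier maps.

Paired synapses are projected onto the two anatomical axes of the inner
hair cell — u along the modiolar-pillar axis, v along the
cuticular-habenular axis — then per-stack point clouds are aligned by
translating each stack's paired-synapse centroid to a common origin.  The
pooled ensemble is clustered with a full-covariance Gaussian-mixture EM,
and the number of positional populations is selected by the Bayes
information criterion (BIC), which penalizes over-assignment of clusters.
Volumetric outliers (components above a volume quantile, 0.9 by default)
are flagged and summarized by their mean position.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp

logger = logging.getLogger(__name__)

__all__ = [
    "project_to_axes",
    "fit_gaussian_mle",
    "align_ensemble",
    "ClusterResult",
    "em_cluster",
    "quantile_outlier_map",
]

_LOG2PI = np.log(2.0 * np.pi)


def _check_orthonormal(mp_axis, ch_axis, tol=1e-8):
    mp = np.asarray(mp_axis, dtype=float)
    ch = np.asarray(ch_axis, dtype=float)
    if (
        abs(np.linalg.norm(mp) - 1.0) > tol
        or abs(np.linalg.norm(ch) - 1.0) > tol
        or abs(float(mp @ ch)) > tol
    ):
        raise ValueError("axes must be orthonormal unit vectors")
    return mp, ch


def project_to_axes(
    positions: np.ndarray,
    soma_center: Sequence[float],
    modiolar_pillar_axis: Sequence[float],
    cuticular_habenular_axis: Sequence[float],
) -> np.ndarray:
    """Project 3D positions (µm) onto the cell's anatomical axes.

    Returns (n, 2) coordinates ``(u, v)`` where u is along the
    modiolar-pillar axis and v along the cuticular-habenular axis, both
    relative to the soma centre.  This is a rigid projection: pairwise
    distances among projected points never exceed the 3D distances.
    """
    mp, ch = _check_orthonormal(modiolar_pillar_axis, cuticular_habenular_axis)
    rel = np.atleast_2d(np.asarray(positions, dtype=float)) - np.asarray(
        soma_center, dtype=float
    )
    return np.column_stack([rel @ mp, rel @ ch])


def fit_gaussian_mle(points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Maximum-likelihood single-Gaussian fit: sample mean and the
    MLE (divide-by-n) covariance.  Requires at least 3 points."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.shape[0] < 3:
        raise ValueError("need at least 3 points for a Gaussian MLE fit")
    mean = pts.mean(axis=0)
    centred = pts - mean
    cov = centred.T @ centred / pts.shape[0]
    return mean, cov


def align_ensemble(
    stacks: Mapping[str, pd.DataFrame],
    min_pairs: int = 3,
) -> pd.DataFrame:
    """Pool per-stack projected synapse tables after centroid alignment.

    Each stack's points are translated so its (u, v) centroid lands on the
    origin — the common reference for all stacks.  Stacks with fewer than
    ``min_pairs`` points are excluded with a logged warning.  Input frames
    need columns u, v, volume and optionally pair_id.
    """
    frames = []
    for stack_id, df in stacks.items():
        if len(df) < min_pairs:
            logger.warning(
                "stack %r has %d paired synapses (< %d); excluded from the "
                "ensemble", stack_id, len(df), min_pairs,
            )
            continue
        out = df.copy()
        out["u"] = df["u"] - df["u"].mean()
        out["v"] = df["v"] - df["v"].mean()
        out["stack_id"] = stack_id
        if "pair_id" not in out:
            out["pair_id"] = np.arange(len(out))
        frames.append(out)
    if not frames:
        return pd.DataFrame(columns=["u", "v", "volume", "stack_id", "pair_id"])
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# Gaussian-mixture EM with BIC model selection
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ClusterResult:
    """Fitted mixture for the selected number of positional populations.

    ``bic_by_k`` maps each candidate k to its BIC score
    ``-2 logL + p ln n`` with ``p = (k - 1) + 2k + 3k`` free parameters
    (weights, 2D means, symmetric 2x2 covariances).  ``loglik_history`` is
    the per-iteration log-likelihood of the winning EM run (non-decreasing
    by the EM guarantee).
    """

    k: int
    means: np.ndarray  # (k, 2)
    covariances: np.ndarray  # (k, 2, 2)
    weights: np.ndarray  # (k,)
    responsibilities: np.ndarray  # (n, k)
    labels: np.ndarray  # (n,)
    log_likelihood: float
    bic_by_k: dict[int, float]
    loglik_history: tuple[float, ...]


class _SingularCovariance(Exception):
    pass


def _log_gauss_all(x, means, covs):
    """Log-density of every point under every 2D Gaussian component.

    Closed-form 2x2 inverse/determinant, vectorized over components; raises
    on a non-positive-definite covariance so the caller can restart with
    ridge regularization.
    """
    a = covs[:, 0, 0]
    b = covs[:, 0, 1]
    c = covs[:, 1, 1]
    det = a * c - b * b
    # det below ~1e-12 µm^4 is an operationally singular covariance (a
    # component collapsing onto a point); the caller restarts regularized
    if np.any(det <= 1e-12) or np.any(a <= 0.0):
        raise _SingularCovariance
    dx = x[:, 0][:, None] - means[:, 0][None, :]
    dy = x[:, 1][:, None] - means[:, 1][None, :]
    quad = (c * dx * dx - 2.0 * b * dx * dy + a * dy * dy) / det
    return -0.5 * (quad + np.log(det) + 2.0 * _LOG2PI)




def _kmeans_pp(x, k, rng):
    """Seeded k-means++ centre selection (D² sampling)."""
    n = x.shape[0]
    centers = [x[rng.integers(n)]]
    for _ in range(1, k):
        d2 = np.min(
            ((x[:, None, :] - np.asarray(centers)[None, :, :]) ** 2).sum(axis=2),
            axis=1,
        )
        total = d2.sum()
        if total <= 0:
            centers.append(x[rng.integers(n)])
            continue
        centers.append(x[rng.choice(n, p=d2 / total)])
    return np.asarray(centers)


def _em_run(x, k, rng, tol, max_iter, reg):
    n, d = x.shape
    means = _kmeans_pp(x, k, rng)
    base_cov = np.cov(x.T, ddof=0) + reg * np.eye(d)
    covs = np.repeat(base_cov[None], k, axis=0)
    weights = np.full(k, 1.0 / k)
    history = []
    prev = -np.inf
    resp = None
    eye = np.eye(d)
    for _ in range(max_iter):
        log_comp = np.log(weights)[None, :] + _log_gauss_all(x, means, covs)
        log_norm = logsumexp(log_comp, axis=1)
        ll = float(log_norm.sum())
        history.append(ll)
        resp = np.exp(log_comp - log_norm[:, None])
        if ll - prev < tol and np.isfinite(prev):
            break
        prev = ll
        nk = resp.sum(axis=0)
        nk = np.maximum(nk, 1e-12)
        weights = nk / n
        means = (resp.T @ x) / nk[:, None]
        diff = x[:, None, :] - means[None, :, :]  # (n, k, d)
        covs = (
            np.einsum("nk,nki,nkj->kij", resp, diff, diff) / nk[:, None, None]
            + reg * eye
        )
    # a converged component supported by less responsibility mass than a
    # full covariance needs (d + 1 points) is a likelihood spike, the
    # classic unbounded-MLE degeneracy of Gaussian mixtures — reject it
    if resp is not None and np.any(resp.sum(axis=0) < d + 1):
        raise _SingularCovariance
    return means, covs, weights, resp, history


def em_cluster(
    points: np.ndarray | pd.DataFrame,
    k_candidates: Sequence[int] = (1, 2, 3),
    seed: int = 0,
    n_restarts: int = 10,
    tol: float = 1e-8,
    max_iter: int = 500,
    reg_covar: float = 1e-6,
    force_k: int | None = None,
) -> ClusterResult:
    """Full-covariance Gaussian-mixture EM over candidate cluster counts.

    For each k, ``n_restarts`` EM runs start from seeded k-means++ centres;
    a run that hits a singular covariance is restarted with ridge
    regularization ``reg_covar * I`` on every covariance update.  The best
    run per k (highest converged log-likelihood) is scored with BIC and the
    k minimizing BIC is returned — unless ``force_k`` pins the choice (the
    two-population modiolar/pillar assumption), in which case BIC scores
    are still reported for all candidates.
    """
    if isinstance(points, pd.DataFrame):
        x = points[["u", "v"]].to_numpy(dtype=float)
    else:
        x = np.atleast_2d(np.asarray(points, dtype=float))
    if x.shape[1] != 2:
        raise ValueError("em_cluster expects 2D (u, v) points")
    n = x.shape[0]
    kmax = max(k_candidates)
    if n <= kmax * 3:
        raise ValueError(
            f"need more than {kmax * 3} points to consider k={kmax}"
        )
    if force_k is not None and force_k not in k_candidates:
        raise ValueError("force_k must be one of k_candidates")
    rng = np.random.default_rng(seed)
    best_by_k: dict[int, tuple] = {}
    bic_by_k: dict[int, float] = {}
    for k in sorted(k_candidates):
        best = None
        for _ in range(n_restarts):
            run_seed = int(rng.integers(2**31))
            try:
                fit = _em_run(
                    x, k, np.random.default_rng(run_seed), tol, max_iter, reg=0.0
                )
            except _SingularCovariance:
                try:
                    fit = _em_run(
                        x, k, np.random.default_rng(run_seed), tol, max_iter,
                        reg=reg_covar,
                    )
                except _SingularCovariance:
                    continue
            if best is None or fit[4][-1] > best[4][-1]:
                best = fit
        if best is None:
            raise RuntimeError(f"all EM restarts failed for k={k}")
        ll = best[4][-1]
        p = (k - 1) + 2 * k + 3 * k
        bic_by_k[k] = -2.0 * ll + p * np.log(n)
        best_by_k[k] = best
    k_sel = force_k if force_k is not None else min(bic_by_k, key=bic_by_k.get)
    means, covs, weights, resp, history = best_by_k[k_sel]
    return ClusterResult(
        k=k_sel,
        means=means,
        covariances=covs,
        weights=weights,
        responsibilities=resp,
        labels=np.argmax(resp, axis=1),
        log_likelihood=history[-1],
        bic_by_k=bic_by_k,
        loglik_history=tuple(history),
    )


def cluster_axis_angle(result: ClusterResult) -> float | None:
    """Angle (degrees) between the two cluster means' difference vector and
    the modiolar-pillar (u) axis; None unless exactly two clusters."""
    if result.k != 2:
        return None
    d = result.means[1] - result.means[0]
    return float(np.degrees(np.arctan2(abs(d[1]), abs(d[0]))))


# ---------------------------------------------------------------------------
# Quantile outlier map
# ---------------------------------------------------------------------------


def quantile_outlier_map(
    points: pd.DataFrame,
    q: float = 0.9,
) -> tuple[np.ndarray, dict]:
    """Flag volumetric outliers and summarize their positions.

    A point is an outlier iff its volume strictly exceeds the empirical
    q-quantile (linear interpolation between order statistics) of the
    pooled volumes.  Returns the boolean flags and a summary with the
    threshold and the mean (u, v) of flagged and unflagged points.
    Refuses fewer than 10 points — too few for a stable quantile.
    """
    if not 0.0 < q < 1.0:
        raise ValueError("q must be in (0, 1)")
    if len(points) < 10:
        raise ValueError("need at least 10 points for a stable quantile")
    vols = points["volume"].to_numpy(dtype=float)
    thr = float(np.quantile(vols, q, method="linear"))
    flags = vols > thr
    def _mean(col, sel):
        return float(points[col].to_numpy(dtype=float)[sel].mean()) if sel.any() else float("nan")
    summary = {
        "q": q,
        "volume_threshold": thr,
        "n_outliers": int(flags.sum()),
        "n_points": int(len(points)),
        "outlier_mean_u": _mean("u", flags),
        "outlier_mean_v": _mean("v", flags),
        "inlier_mean_u": _mean("u", ~flags),
        "inlier_mean_v": _mean("v", ~flags),
    }
    return flags, summary
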