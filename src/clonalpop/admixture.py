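"""Maximum-likelihood admixture model fitted by EM, with cross-validated
selection of the number of ancestral populations K.

Model: individual ``i``'s dosage at site ``j`` is Binomial(2, pi_ij) with
``pi_ij = sum_k q_ik * f_kj`` — ancestry proportions ``Q`` (rows on the
simplex) and population allele frequencies ``F`` in (0, 1).  The EM scheme
is the classic multiplicative update (each allele copy's population of
origin is the latent variable), which increases the log-likelihood at every
iteration.  Multi-start with Dirichlet/uniform initialization guards
against local optima; results are deterministic under a fixed seed.

K is selected by entry-masking cross-validation: a fraction of non-missing
calls is held out, the model refitted, and the held-out dosages predicted
as ``2 * pi_hat``; the K minimizing mean squared prediction error wins.
The fitted solution is identified only up to a permutation of the K labels
(label switching); :func:`align_q` matches labels against a reference.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .genotype import MISSING, GenotypeMatrix

logger = logging.getLogger(__name__)

_EPS = 1e-6


class AdmixtureError(ValueError):
    pass


def _dosage_and_mask(matrix: GenotypeMatrix) -> tuple[np.ndarray, np.ndarray]:
    G = matrix.calls.astype(float)
    valid = matrix.calls != MISSING
    G[~valid] = 0.0
    return G, valid


def loglik(matrix: GenotypeMatrix, Q: np.ndarray, F: np.ndarray) -> float:
    """Binomial admixture log-likelihood over non-missing calls.

    ``sum_ij [ g * ln(pi_ij) + (2 - g) * ln(1 - pi_ij) ]`` with
    ``pi = Q @ F`` clamped away from {0, 1}.  The Binomial(2, .)
    combinatorial constant is omitted, as it does not depend on (Q, F).
    """
    G, valid = _dosage_and_mask(matrix)
    Q = np.asarray(Q, dtype=float)
    F = np.asarray(F, dtype=float)
    if Q.shape[0] != matrix.n_samples or F.shape[1] != matrix.n_sites \
            or Q.shape[1] != F.shape[0]:
        raise AdmixtureError("shapes of matrix, Q, F do not agree")
    pi = np.clip(Q @ F, _EPS, 1.0 - _EPS)
    ll = np.where(valid, G * np.log(pi) + (2.0 - G) * np.log1p(-pi), 0.0)
    return float(ll.sum())


@dataclass
class EMResult:
    """One fitted admixture model."""

    Q: pd.DataFrame                 # samples x K, rows sum to 1
    F: np.ndarray                   # K x sites in (0, 1)
    loglik_trace: list[float]
    converged: bool
    seed: int

    @property
    def K(self) -> int:
        return self.Q.shape[1]

    @property
    def final_loglik(self) -> float:
        return self.loglik_trace[-1]


def _em_once(
    G: np.ndarray,
    valid: np.ndarray,
    K: int,
    rng: np.random.Generator,
    max_iter: int,
    tol: float,
) -> tuple[np.ndarray, np.ndarray, list[float], bool]:
    N, J = G.shape
    Q = rng.dirichlet(np.ones(K), size=N)
    F = rng.uniform(0.05, 0.95, size=(K, J))
    n_calls = valid.sum(axis=1, keepdims=True) * 2.0
    Gv = np.where(valid, G, 0.0)
    G2v = np.where(valid, 2.0 - G, 0.0)

    trace: list[float] = []
    converged = False
    prev = -np.inf
    for _ in range(max_iter):
        pi = np.clip(Q @ F, _EPS, 1.0 - _EPS)
        ll = float(
            (Gv * np.log(pi) + G2v * np.log1p(-pi)).sum()
        )
        trace.append(ll)
        if ll + 1e-9 * max(1.0, abs(ll)) < prev:
            raise AssertionError("EM log-likelihood decreased")
        if ll - prev < tol and np.isfinite(prev):
            converged = True
            break
        prev = ll

        # joint M-step: both updates use responsibilities from the OLD (Q, F)
        R = Gv / pi           # per-call alt-copy weight
        S = G2v / (1.0 - pi)  # per-call ref-copy weight
        num_alt = F * (Q.T @ R)          # K x J expected alt copies from k
        num_ref = (1.0 - F) * (Q.T @ S)
        Q_new = Q * (R @ F.T + S @ (1.0 - F).T) / n_calls
        F = np.clip(num_alt / np.clip(num_alt + num_ref, _EPS, None),
                    _EPS, 1.0 - _EPS)
        # rows sum to 1 analytically; renormalize to absorb the pi clamp drift
        Q = np.clip(Q_new, 0.0, None)
        Q /= Q.sum(axis=1, keepdims=True)
    return Q, F, trace, converged


def em_fit(
    matrix: GenotypeMatrix,
    K: int,
    n_starts: int = 8,
    max_iter: int = 2000,
    tol: float = 1e-5,
    seed: int = 0,
) -> EMResult:
    """Fit the K-population admixture model; best of ``n_starts`` EM runs.

    ``tol`` is the absolute log-likelihood improvement below which a run
    stops.  Raises :class:`AdmixtureError` for K < 1 or K > n_samples.
    """
    if K < 1:
        raise AdmixtureError("K must be >= 1")
    if K > matrix.n_samples:
        raise AdmixtureError(f"K={K} exceeds the {matrix.n_samples} samples")
    G, valid = _dosage_and_mask(matrix)
    if not valid.any(axis=1).all():
        bad = [matrix.sample_ids[i] for i in np.where(~valid.any(axis=1))[0]]
        raise AdmixtureError(f"samples with no calls: {bad}")
    ss = np.random.SeedSequence(seed)
    best: tuple[np.ndarray, np.ndarray, list[float], bool] | None = None
    for child in ss.spawn(n_starts):
        rng = np.random.default_rng(child)
        out = _em_once(G, valid, K, rng, max_iter, tol)
        if best is None or out[2][-1] > best[2][-1]:
            best = out
    Q, F, trace, converged = best
    Qdf = pd.DataFrame(Q, index=matrix.sample_ids,
                       columns=[f"pop{k + 1}" for k in range(K)])
    return EMResult(Qdf, F, trace, converged, seed)


def align_q(
    Q_est: pd.DataFrame | np.ndarray, Q_ref: pd.DataFrame | np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Resolve label switching: permute Q_est columns to best match Q_ref.

    Hungarian assignment on the column-pair mean absolute difference.
    Returns (aligned Q_est array, permutation) with
    ``aligned[:, k] = Q_est[:, perm[k]]``.
    """
    A = np.asarray(Q_est, dtype=float)
    B = np.asarray(Q_ref, dtype=float)
    if A.shape != B.shape:
        raise AdmixtureError("Q matrices must share a shape to align")
    K = A.shape[1]
    cost = np.zeros((K, K))
    for i in range(K):
        for j in range(K):
            cost[i, j] = np.abs(A[:, j] - B[:, i]).mean()
    _, perm = linear_sum_assignment(cost)
    return A[:, perm], perm


@dataclass
class CVReport:
    """Cross-validation curve over a K grid."""

    errors: pd.DataFrame            # columns: K, cv_error
    selected_K: int

    def __post_init__(self) -> None:
        best = self.errors.loc[self.errors["cv_error"].idxmin(), "K"]
        if int(best) != self.selected_K:
            raise ValueError("selected_K must attain the minimum CV error")


def cross_validate(
    matrix: GenotypeMatrix,
    K_grid: list[int],
    mask_fraction: float = 0.1,
    n_folds: int = 5,
    seed: int = 0,
    n_starts: int = 2,
    max_iter: int = 300,
    tol: float = 1e-3,
) -> CVReport:
    """Entry-masking cross-validation of K.

    Each fold masks ``mask_fraction`` of the non-missing calls (redrawn,
    bounded retries, if a sample or site would lose all its calls), refits
    the model on the remainder, and scores mean squared error between the
    held-out dosage ``g`` and its prediction ``2 * pi_hat``.  Ties on the
    grid resolve to the smaller K.
    """
    if not K_grid:
        raise AdmixtureError("K grid is empty")
    if not 0.0 < mask_fraction < 1.0:
        raise AdmixtureError("mask_fraction must lie strictly between 0 and 1")
    G0, valid0 = _dosage_and_mask(matrix)
    obs = np.argwhere(valid0)
    ss = np.random.SeedSequence(seed)
    fold_seeds = ss.spawn(n_folds)

    per_k_errors = {int(K): [] for K in K_grid}
    for fold, child in enumerate(fold_seeds):
        rng = np.random.default_rng(child)
        mask_idx = _draw_mask(obs, valid0, mask_fraction, rng)
        masked_calls = matrix.calls.copy()
        masked_calls[mask_idx[:, 0], mask_idx[:, 1]] = MISSING
        masked = GenotypeMatrix(matrix.samples, matrix.sites, masked_calls)
        held_g = G0[mask_idx[:, 0], mask_idx[:, 1]]
        for K in K_grid:
            fit = em_fit(masked, int(K), n_starts=n_starts, max_iter=max_iter,
                         tol=tol, seed=int(rng.integers(2**31)))
            pi = np.clip(fit.Q.to_numpy() @ fit.F, _EPS, 1.0 - _EPS)
            pred = 2.0 * pi[mask_idx[:, 0], mask_idx[:, 1]]
            per_k_errors[int(K)].append(float(np.mean((held_g - pred) ** 2)))
        logger.info("cross_validate: fold %d/%d done", fold + 1, n_folds)

    errors = pd.DataFrame(
        {"K": sorted(per_k_errors),
         "cv_error": [float(np.mean(per_k_errors[K])) for K in sorted(per_k_errors)]}
    )
    selected = int(errors.loc[errors["cv_error"].idxmin(), "K"])
    return CVReport(errors, selected)


def _draw_mask(
    obs: np.ndarray, valid: np.ndarray, fraction: float, rng: np.random.Generator,
    max_retries: int = 20,
) -> np.ndarray:
    n_mask = max(1, int(round(fraction * len(obs))))
    for _ in range(max_retries):
        pick = rng.choice(len(obs), size=n_mask, replace=False)
        idx = obs[pick]
        remaining = valid.copy()
        remaining[idx[:, 0], idx[:, 1]] = False
        if remaining.any(axis=1).all() and remaining.any(axis=0).all():
            return idx
    raise AdmixtureError(
        "could not draw a holdout mask leaving every sample and site with data"
    )


def write_q_table(result: EMResult, path) -> None:
    """Write Q as a whitespace-delimited table, one row per sample (.Q layout)."""
    with open(path, "w") as fh:
        for _, row in result.Q.iterrows():
            fh.write(" ".join(f"{v:.6f}" for v in row.to_numpy()) + "\n")
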