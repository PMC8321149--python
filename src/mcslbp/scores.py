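"""Supervised relevance scores for candidate LBP histograms and bins.

Both scores rely on a sparse-representation *soft* similarity matrix S over
the training samples: instead of the hard 0/1 same-class indicator, S_ij
measures how strongly sample j participates in a non-negative L1-penalized
least-squares reconstruction of sample i from its same-class peers.  Values
lie in [0, 1], the diagonal is 0 and cross-class entries are exactly 0.

Histogram score (SpASL-style): for one candidate histogram (a color space and
component pair), with d_J the Jeffrey distance between the per-sample
histograms,

    score = sum_ij S_ij d_J(H_i, H_j)^2 / sum_{y_i != y_j} d_J(H_i, H_j)^2 .

A small score means the histogram keeps sparse-similar same-class samples
close while separating classes; candidates are ranked ascending.  A candidate
identical across all samples has a zero denominator and scores +inf.

Bin score (supervised sparsity): with S~ the row-stochastic rescaling of S
and f one bin feature over the training samples,

    score = ||f - S~ f||^2 / Var(f) ,

again ranked ascending; a zero-variance bin scores +inf.  Both scores share
the plain ``(candidates, labels, S) -> scores`` shape so alternative
published scores can be substituted without touching the selection code.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import Lasso

logger = logging.getLogger(__name__)

#: Upper bound of the Jeffrey distance between unit-normalized histograms.
JEFFREY_MAX = 2.0 * np.log(2.0)


def jeffrey_distance(H: np.ndarray, K: np.ndarray) -> float:
    """Jeffrey (symmetrized KL-type) distance between two unit histograms.

    d = sum_b h ln(2h/(h+k)) + k ln(2k/(h+k)), with 0*ln(.) = 0 and empty
    bins contributing 0.  Symmetric, zero iff the histograms are equal, and
    bounded by 2 ln 2.
    """
    H = np.asarray(H, dtype=np.float64)
    K = np.asarray(K, dtype=np.float64)
    if H.shape != K.shape:
        raise ValueError(f"histogram lengths differ: {H.shape} vs {K.shape}")
    return float(_jeffrey_terms(H, K).sum())


def _jeffrey_terms(H: np.ndarray, K: np.ndarray) -> np.ndarray:
    """Per-bin Jeffrey terms with the 0*ln(.) = 0 convention."""
    m = H + K
    safe_m = np.where(m > 0, m, 1.0)
    th = H * np.log(np.where(H > 0, 2.0 * H / safe_m, 1.0))
    tk = K * np.log(np.where(K > 0, 2.0 * K / safe_m, 1.0))
    return th + tk


def pairwise_jeffrey(hists: np.ndarray) -> np.ndarray:
    """Symmetric matrix of Jeffrey distances between rows of (N, Q) hists."""
    hists = np.asarray(hists, dtype=np.float64)
    d = _jeffrey_terms(hists[:, None, :], hists[None, :, :]).sum(axis=-1)
    np.fill_diagonal(d, 0.0)
    return d


def sparse_similarity(
    features: np.ndarray,
    labels: np.ndarray,
    lam: float = 0.1,
    tol: float = 1e-6,
    max_iter: int = 1000,
) -> np.ndarray:
    """Sparse-representation soft similarity matrix over training samples.

    Each sample's L2-normalized descriptor is reconstructed from its
    same-class peers by non-negative L1-penalized least squares
    (objective (1/2)||x - Aw||^2 + lam ||w||_1, coordinate descent); the
    reconstruction weights of row i are rescaled by their maximum to [0, 1]
    and the matrix is symmetrized with the elementwise maximum.

    A class with a single training sample yields an all-zero row (logged).
    """
    X = np.asarray(features, dtype=np.float64)
    labels = np.asarray(labels)
    N = X.shape[0]
    if N < 2:
        raise ValueError("need at least two training samples")
    norms = np.linalg.norm(X, axis=1)
    Xn = X / np.where(norms > 0, norms, 1.0)[:, None]
    D = X.shape[1]
    # sklearn's Lasso objective is (1/(2*n)) ||y - Xw||^2 + alpha ||w||_1 with
    # n the length of y; alpha = lam / D recovers the unscaled objective.
    model = Lasso(alpha=lam / D, positive=True, fit_intercept=False,
                  tol=tol, max_iter=max_iter)
    S = np.zeros((N, N), dtype=np.float64)
    for i in range(N):
        peers = np.flatnonzero((labels == labels[i]) & (np.arange(N) != i))
        if peers.size == 0:
            logger.warning(
                "class %r has a single training sample; its similarity row is zero",
                labels[i],
            )
            continue
        with warnings.catch_warnings():
            # solver tolerance and iteration cap are fixed for determinism;
            # near-tolerance duality gaps are expected and harmless
            warnings.simplefilter("ignore", ConvergenceWarning)
            model.fit(Xn[peers].T, Xn[i])
        w = np.maximum(model.coef_, 0.0)
        wmax = w.max()
        if wmax > 0:
            S[i, peers] = w / wmax
    S = np.maximum(S, S.T)
    np.fill_diagonal(S, 0.0)
    return S


def spasl_histogram_score(
    hists: np.ndarray,
    labels: np.ndarray,
    S: np.ndarray,
) -> float:
    """SpASL-style relevance of one candidate histogram (lower = better)."""
    labels = np.asarray(labels)
    d2 = pairwise_jeffrey(hists) ** 2
    diff = labels[:, None] != labels[None, :]
    den = float(d2[diff].sum())
    if den == 0.0:
        return float("inf")
    num = float((np.asarray(S) * d2).sum())
    return num / den


def spasl_scores(
    hist_tensor: np.ndarray,
    labels: np.ndarray,
    S: np.ndarray,
) -> np.ndarray:
    """SpASL scores for all M candidate histograms in an (N, M, Q) tensor."""
    hist_tensor = np.asarray(hist_tensor)
    M = hist_tensor.shape[1]
    return np.array(
        [spasl_histogram_score(hist_tensor[:, m, :], labels, S) for m in range(M)]
    )


def _row_stochastic(S: np.ndarray) -> np.ndarray:
    S = np.asarray(S, dtype=np.float64)
    sums = S.sum(axis=1)
    return S / np.where(sums > 0, sums, 1.0)[:, None]


def sparsity_bin_score(f: np.ndarray, S: np.ndarray) -> float:
    """Supervised sparsity relevance of one bin feature (lower = better)."""
    return float(sparsity_bin_scores(np.asarray(f, dtype=np.float64)[:, None], S)[0])


def sparsity_bin_scores(F: np.ndarray, S: np.ndarray) -> np.ndarray:
    """Supervised sparsity scores for every column of (N, D) features.

    score_d = ||f_d - S~ f_d||^2 / Var(f_d); zero-variance columns get +inf.
    """
    F = np.asarray(F, dtype=np.float64)
    St = _row_stochastic(S)
    resid = F - St @ F
    num = np.einsum("nd,nd->d", resid, resid)
    var = F.var(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        scores = np.where(var > 0, num / np.where(var > 0, var, 1.0), np.inf)
    return scores
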