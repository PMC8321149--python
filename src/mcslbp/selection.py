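"""Embedded selection of LBP histograms and bins in a multi-space framework.

Three ranking strategies are provided over the candidate descriptor of
delta_max * NS histograms (Q bins each):

* **MCSHS** — rank whole histograms ascending by the SpASL-style score and
  keep the best prefix of histograms (each expands to its Q bins);
* **MCSBS** — rank the Q * delta_max * NS individual bins ascending by the
  supervised sparsity score and keep the best prefix of bins;
* **MCSHBS** — rank histograms, rank bins *within* each histogram
  independently, then interleave: first the group of every histogram's best
  bin taken in histogram-rank order, then the group of second-best bins, and
  so on — a Q-long sequence of M-uplets.

Each strategy is embedded: the candidate prefixes are evaluated by 1-NN/L1
accuracy on a validation subset, and the selected dimension is the prefix
maximizing that rate (ties go to the smallest, most compact prefix).  Prefix
accuracies are computed incrementally — appending one ranked unit updates the
pairwise L1 distances in place — so the whole curve costs one pass over the
distance contributions and equals from-scratch recomputation exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .lbp import DELTA_MAX, FeatureMatrix, LBPParams
from .scores import sparse_similarity, sparsity_bin_scores, spasl_scores

STRATEGIES = ("MCSHS", "MCSBS", "MCSHBS", "none")


@dataclass
class Ranking:
    """A permutation of candidate units with their aligned ascending scores."""

    order: np.ndarray
    scores: np.ndarray
    granularity: Literal["histogram", "bin"]

    def __post_init__(self) -> None:
        self.order = np.asarray(self.order, dtype=np.intp)
        self.scores = np.asarray(self.scores, dtype=np.float64)
        n = self.order.size
        if not np.array_equal(np.sort(self.order), np.arange(n)):
            raise ValueError("order must be a permutation of the candidates")


def _rank(scores: np.ndarray, granularity: str) -> Ranking:
    scores = np.asarray(scores, dtype=np.float64)
    if np.isnan(scores).any():
        raise ValueError("scores must not contain NaN")
    order = np.argsort(scores, kind="stable")  # ascending; ties by index
    return Ranking(order, scores, granularity)


def rank_histograms(scores: np.ndarray) -> Ranking:
    """Ascending stable ranking of candidate histograms (lower = better)."""
    return _rank(scores, "histogram")


def rank_bins_global(scores: np.ndarray) -> Ranking:
    """Ascending stable ranking of the concatenated candidate bins."""
    return _rank(scores, "bin")


def interleave_combined(
    histogram_order: np.ndarray,
    per_histogram_bin_orders: Sequence[np.ndarray],
) -> Ranking:
    """Combined bin ranking: groups of best bins in histogram-rank order.

    ``per_histogram_bin_orders[m]`` is the within-histogram ascending bin
    permutation of histogram m (original index).  The output visits, for each
    bin rank q, every histogram in ranked order, emitting the global column
    index of that histogram's q-th best bin — Q groups of M bins, a
    permutation of all M*Q columns that preserves every histogram's internal
    bin order.
    """
    histogram_order = np.asarray(histogram_order, dtype=np.intp)
    M = histogram_order.size
    if M == 0:
        raise ValueError("empty histogram order")
    Q = len(per_histogram_bin_orders[0])
    expected = np.arange(Q)
    for order in per_histogram_bin_orders:
        if not np.array_equal(np.sort(np.asarray(order)), expected):
            raise ValueError("each bin order must be a permutation of 0..Q-1")
    bin_orders = np.asarray(per_histogram_bin_orders, dtype=np.intp)  # (M, Q)
    # out[q*M + r] = global index of bin_orders[pi(r)][q] inside histogram pi(r)
    global_idx = histogram_order[None, :] * Q + bin_orders[histogram_order].T  # (Q, M)
    return Ranking(global_idx.ravel(), np.full(M * Q, np.nan), "bin")


def select_dimension(curve: np.ndarray) -> int:
    """Index of the first maximum of a per-prefix accuracy curve."""
    curve = np.asarray(curve)
    if curve.size == 0:
        raise ValueError("empty accuracy curve")
    return int(np.argmax(curve))


def accuracy_curve(
    units: Sequence[np.ndarray],
    train_values: np.ndarray,
    train_labels: np.ndarray,
    val_values: np.ndarray,
    val_labels: np.ndarray,
    stride: int = 1,
    block: int = 512,
) -> tuple[np.ndarray, np.ndarray]:
    """Validation 1-NN/L1 accuracy at each ranked prefix of feature units.

    ``units`` lists, in ranked order, the column indices that each unit
    contributes (a single bin or a Q-bin histogram block).  Returns the
    evaluated prefix sizes (in units) and their accuracies.  ``stride``
    evaluates every stride-th prefix (the final full prefix is always
    included); distances are accumulated incrementally in blocks, with
    results identical to recomputing each prefix from scratch.
    """
    if len(units) == 0:
        raise ValueError("no ranked units to evaluate")
    if val_values.shape[0] == 0:
        raise ValueError("empty validation set")
    if stride < 1:
        raise ValueError("stride must be >= 1")
    train_labels = np.asarray(train_labels)
    val_labels = np.asarray(val_labels)
    T = len(units)
    eval_prefixes = sorted(set(range(stride, T + 1, stride)) | {T})
    eval_mask = np.zeros(T + 1, dtype=bool)
    eval_mask[eval_prefixes] = True

    n_val, n_train = val_values.shape[0], train_values.shape[0]
    base = np.zeros((n_val, n_train))
    accs: list[float] = []
    for start in range(0, T, block):
        chunk = units[start:start + block]
        contrib = np.empty((len(chunk), n_val, n_train))
        for u, cols in enumerate(chunk):
            cols = np.atleast_1d(np.asarray(cols, dtype=np.intp))
            if cols.size == 1:
                c = cols[0]
                contrib[u] = np.abs(val_values[:, c, None] - train_values[None, :, c])
            else:
                diff = np.abs(val_values[:, None, cols] - train_values[None, :, cols])
                contrib[u] = diff.sum(axis=-1)
        np.cumsum(contrib, axis=0, out=contrib)
        contrib += base
        which = np.flatnonzero(eval_mask[start + 1:start + len(chunk) + 1])
        if which.size:
            nearest = np.argmin(contrib[which], axis=2)  # ties -> smallest index
            pred = train_labels[nearest]
            accs.extend(np.mean(pred == val_labels[None, :], axis=1).tolist())
        base = contrib[-1]
    return np.asarray(eval_prefixes, dtype=np.intp), np.asarray(accs)


@dataclass
class SelectionResult:
    """Outcome of one selection strategy run."""

    strategy: str
    granularity: str
    ranking_order: np.ndarray
    evaluated_prefixes: np.ndarray
    accuracy_curve: np.ndarray
    selected_units: int
    selected_columns: np.ndarray
    best_validation_accuracy: float
    histogram_scores: np.ndarray | None = None
    bin_scores: np.ndarray | None = None

    @property
    def selected_dimension(self) -> int:
        return int(self.selected_columns.size)

    def to_dict(self, provenance=None) -> dict:
        d = {
            "strategy": self.strategy,
            "granularity": self.granularity,
            "evaluated_prefixes": self.evaluated_prefixes.tolist(),
            "accuracy_curve": self.accuracy_curve.tolist(),
            "selected_units": self.selected_units,
            "selected_dimension": self.selected_dimension,
            "best_validation_accuracy": self.best_validation_accuracy,
            "selected_columns": self.selected_columns.tolist(),
        }
        if provenance is not None:
            d["selected_provenance"] = [
                {"space": p.space, "pair": list(p.pair), "bin": p.bin}
                for p in (provenance[c] for c in self.selected_columns)
            ]
        return d


def _histogram_tensor(values: np.ndarray, Q: int) -> np.ndarray:
    N, D = values.shape
    if D % Q:
        raise ValueError("feature count is not a multiple of Q")
    return values.reshape(N, D // Q, Q)


def run_strategy(
    strategy: str,
    train: FeatureMatrix,
    validation: FeatureMatrix,
    params: LBPParams = LBPParams(),
    lam: float = 0.1,
    stride: int = 1,
    similarity: np.ndarray | None = None,
) -> SelectionResult:
    """Run one full embedded selection strategy.

    ``similarity`` may carry a precomputed sparse similarity matrix of the
    training samples (it is a property of the samples, shared by every
    candidate); otherwise it is computed here from the full concatenated
    training descriptor.
    """
    if strategy not in STRATEGIES:
        raise ValueError(f"unknown strategy {strategy!r}; expected one of {STRATEGIES}")
    Q = params.Q
    D = train.n_features
    M = D // Q

    if strategy == "none":
        cols = np.arange(D, dtype=np.intp)
        prefixes, accs = accuracy_curve(
            [cols], train.values, train.labels, validation.values, validation.labels
        )
        return SelectionResult(
            strategy, "bin", cols, prefixes, accs, 1, cols, float(accs[0])
        )

    S = similarity
    if S is None:
        S = sparse_similarity(train.values, train.labels, lam=lam)

    hist_tensor = _histogram_tensor(train.values, Q)
    h_scores = b_scores = None
    if strategy in ("MCSHS", "MCSHBS"):
        h_scores = spasl_scores(hist_tensor, train.labels, S)
    if strategy in ("MCSBS", "MCSHBS"):
        b_scores = sparsity_bin_scores(train.values, S)

    if strategy == "MCSHS":
        ranking = rank_histograms(h_scores)
        units = [np.arange(m * Q, (m + 1) * Q, dtype=np.intp) for m in ranking.order]
        granularity = "histogram"
    elif strategy == "MCSBS":
        ranking = rank_bins_global(b_scores)
        units = [np.array([c]) for c in ranking.order]
        granularity = "bin"
    else:  # MCSHBS
        hist_ranking = rank_histograms(h_scores)
        per_hist_orders = [
            np.argsort(b_scores[m * Q:(m + 1) * Q], kind="stable") for m in range(M)
        ]
        ranking = interleave_combined(hist_ranking.order, per_hist_orders)
        units = [np.array([c]) for c in ranking.order]
        granularity = "bin"

    prefixes, accs = accuracy_curve(
        units, train.values, train.labels, validation.values, validation.labels,
        stride=stride,
    )
    best = select_dimension(accs)
    n_units = int(prefixes[best])
    cols = np.concatenate(units[:n_units])
    return SelectionResult(
        strategy, granularity, ranking.order, prefixes, accs,
        n_units, cols, float(accs[best]),
        histogram_scores=h_scores, bin_scores=b_scores,
    )
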