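"""Correlation-based feature subset selection (CFS) with best-first search.

CFS scores a candidate subset S of k features by the merit

    merit(S) = k * mean(r_cf) / sqrt(k + k*(k-1) * mean(r_ff))

where ``r_cf`` is the feature-class correlation of each member and
``r_ff`` the pairwise feature-feature correlation: subsets whose members
predict the class while being mutually non-redundant score highest.  Both
correlations are measured as symmetric uncertainty,
``2*I(a;b) / (H(a)+H(b))``, after equal-frequency discretisation of the
continuous features, so they live on [0, 1].

The subset space is explored with a greedy best-first search over
add-one-feature expansions, terminating after a fixed number of
consecutive non-improving expansions.  Because high-dimensional histogram
features produce thousands of candidates per expansion, the cache
evaluates whole rows of correlations at once (one contingency-table sweep
per feature column) instead of pair by pair.
"""

from __future__ import annotations

import heapq
import itertools
import math
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "default_bin_count",
    "discretize_equal_frequency",
    "symmetric_uncertainty",
    "CorrelationCache",
    "cfs_merit",
    "best_first_select",
    "save_selection",
    "load_selection",
]


def default_bin_count(n: int) -> int:
    """Discretisation alphabet size: min(10, sqrt(n)), at least 2."""
    return max(2, min(10, int(math.isqrt(n))))


def discretize_equal_frequency(x: np.ndarray, n_bins: int) -> np.ndarray:
    """Equal-frequency binning of a 1-D array into integer codes.

    Bin edges are interior quantiles; duplicate edges (from tied values)
    simply merge bins, so constant features collapse to one symbol.
    """
    x = np.asarray(x, dtype=float)
    edges = np.quantile(x, np.linspace(0, 1, n_bins + 1)[1:-1])
    return np.searchsorted(edges, x, side="right").astype(np.int64)


def _entropy(counts: np.ndarray) -> float:
    c = counts[counts > 0].astype(float)
    p = c / c.sum()
    return float(-(p * np.log(p)).sum())


def symmetric_uncertainty(a: np.ndarray, b: np.ndarray) -> float:
    """Symmetric uncertainty 2*I(a;b)/(H(a)+H(b)) of two discrete arrays.

    Ranges over [0, 1]: 0 for independent variables, 1 when one is a
    bijection of the other.  By convention 0 when either variable has zero
    entropy (a constant carries no information to share).
    """
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("inputs must be 1-D arrays of equal length")
    _, ai = np.unique(a, return_inverse=True)
    _, bi = np.unique(b, return_inverse=True)
    ka, kb = int(ai.max()) + 1, int(bi.max()) + 1
    joint = np.bincount(ai * kb + bi, minlength=ka * kb).reshape(ka, kb)
    ha = _entropy(joint.sum(axis=1))
    hb = _entropy(joint.sum(axis=0))
    if ha == 0.0 or hb == 0.0:
        return 0.0
    mi = ha + hb - _entropy(joint.ravel())
    return float(min(1.0, max(0.0, 2.0 * mi / (ha + hb))))


def _row_entropies(counts: np.ndarray) -> np.ndarray:
    """Entropy of each row of a (m, bins) count matrix, in nats."""
    c = counts.astype(float)
    tot = c.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(tot > 0, c / tot, 0.0)
        logp = np.where(p > 0, np.log(p), 0.0)
    return -(p * logp).sum(axis=1)


class CorrelationCache:
    """Lazily computed feature-class and feature-feature correlations.

    Correlations against a single column (the class, or one feature) are
    evaluated for *all* features in one vectorised contingency sweep and
    cached, which is what makes best-first search tractable on
    multi-thousand-bin histogram features.
    """

    def __init__(self, X: np.ndarray, y: Sequence, n_bins: int | None = None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be a 2-D feature matrix")
        n, self.n_features = X.shape
        bins = n_bins or default_bin_count(n)
        self._Xd = np.column_stack(
            [discretize_equal_frequency(X[:, j], bins) for j in range(self.n_features)]
        )
        self._width = int(self._Xd.max()) + 1 if self._Xd.size else 1
        _, self._yd = np.unique(np.asarray(y), return_inverse=True)
        self._hx = self._column_entropies()
        self._rcf: np.ndarray | None = None
        self._rff_rows: dict[int, np.ndarray] = {}

    def _column_entropies(self) -> np.ndarray:
        nf, w = self.n_features, self._width
        counts = np.zeros((nf, w), dtype=np.int64)
        cols = np.broadcast_to(np.arange(nf), self._Xd.shape)
        np.add.at(counts, (cols, self._Xd), 1)
        return _row_entropies(counts)

    def _su_against(self, codes: np.ndarray, h_other: float) -> np.ndarray:
        """Symmetric uncertainty of every feature against one code column."""
        nf, w = self.n_features, self._width
        ko = int(codes.max()) + 1
        joint = np.zeros((nf, ko * w), dtype=np.int64)
        cols = np.broadcast_to(np.arange(nf), self._Xd.shape)
        np.add.at(joint, (cols, codes[:, None] * w + self._Xd), 1)
        h_joint = _row_entropies(joint)
        mi = self._hx + h_other - h_joint
        denom = self._hx + h_other
        with np.errstate(divide="ignore", invalid="ignore"):
            su = np.where(denom > 0, 2.0 * mi / denom, 0.0)
        su[(self._hx == 0) | (h_other == 0)] = 0.0
        return np.clip(su, 0.0, 1.0)

    def r_cf_all(self) -> np.ndarray:
        if self._rcf is None:
            hy = _entropy(np.bincount(self._yd))
            self._rcf = self._su_against(self._yd, hy)
        return self._rcf

    def r_cf(self, j: int) -> float:
        return float(self.r_cf_all()[j])

    def r_ff_row(self, m: int) -> np.ndarray:
        """Correlations of feature m against every feature (r_ff(m,m)=1)."""
        if m not in self._rff_rows:
            row = self._su_against(self._Xd[:, m], float(self._hx[m]))
            row[m] = 1.0
            self._rff_rows[m] = row
        return self._rff_rows[m]

    def r_ff(self, i: int, j: int) -> float:
        if i == j:
            return 1.0
        if i in self._rff_rows:
            return float(self._rff_rows[i][j])
        if j in self._rff_rows:
            return float(self._rff_rows[j][i])
        return float(self.r_ff_row(i)[j])


def cfs_merit(subset: Iterable[int], cache: CorrelationCache) -> float:
    """CFS merit of a feature subset; 0 for the empty subset.

    With ``k = |S|`` the merit equals ``sum(r_cf) / sqrt(k + 2*sum(r_ff))``
    over member correlations and member pairs, the k-normalised form of
    ``k*mean(r_cf)/sqrt(k + k(k-1)*mean(r_ff))``.
    """
    s = sorted(set(subset))
    k = len(s)
    if k == 0:
        return 0.0
    sum_rcf = sum(cache.r_cf(j) for j in s)
    sum_rff = sum(cache.r_ff(a, b) for a, b in itertools.combinations(s, 2))
    denom = math.sqrt(k + 2.0 * sum_rff)
    return sum_rcf / denom if denom > 0 else 0.0


def best_first_select(
    X: np.ndarray,
    y: Sequence,
    stall_limit: int = 5,
    n_bins: int | None = None,
    cache: CorrelationCache | None = None,
) -> list[int]:
    """Best-first CFS subset search; returns sorted feature indices.

    Starting from the empty subset, the open list (a priority queue keyed
    on merit) is repeatedly popped and expanded by adding every unused
    feature; the search stops after ``stall_limit`` consecutive expansions
    that fail to improve the best merit seen.  If no subset achieves
    positive merit, the single feature with the highest class correlation
    is returned so downstream classifiers always have an input.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValueError("need a 2-D matrix with at least two features")
    if len(np.unique(np.asarray(y))) < 2:
        raise ValueError("need at least two classes")
    cache = cache or CorrelationCache(X, y, n_bins)
    nf = X.shape[1]
    rcf = cache.r_cf_all()

    counter = itertools.count()
    start: frozenset[int] = frozenset()
    # heap entries: (-merit, tiebreak, members, sum_rcf, sum_rff)
    heap: list[tuple[float, int, frozenset[int], float, float]] = [
        (0.0, next(counter), start, 0.0, 0.0)
    ]
    seen = {start}
    best_subset, best_merit = start, -math.inf
    stall = 0
    while heap and stall < stall_limit:
        neg_merit, _, node, sum_rcf, sum_rff = heapq.heappop(heap)
        if -neg_merit > best_merit + 1e-12:
            best_merit, best_subset = -neg_merit, node
            stall = 0
        else:
            stall += 1
        # vectorised merits of all add-one children
        k = len(node) + 1
        rff_to_node = np.zeros(nf)
        for m in node:
            rff_to_node += cache.r_ff_row(m)
        child_rcf = sum_rcf + rcf
        child_rff = sum_rff + rff_to_node
        merits = child_rcf / np.sqrt(k + 2.0 * child_rff)
        for f in range(nf):
            if f in node:
                continue
            child = node | {f}
            if child in seen:
                continue
            seen.add(child)
            heapq.heappush(
                heap,
                (-float(merits[f]), next(counter), child,
                 float(child_rcf[f]), float(child_rff[f])),
            )

    if not best_subset:
        return [int(np.argmax(rcf))]
    return sorted(best_subset)


def save_selection(indices: Sequence[int], path: str) -> None:
    """Persist a selected-feature index list as JSON (next to the
    feature CSV it refers to)."""
    import json

    with open(path, "w") as fh:
        json.dump({"selected": [int(i) for i in indices]}, fh)


def load_selection(path: str) -> list[int]:
    import json

    with open(path) as fh:
        return [int(i) for i in json.load(fh)["selected"]]
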