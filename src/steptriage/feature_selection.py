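"""Correlation-based feature-subset selection (CFS) with best-first search.

The subset evaluator rewards features that correlate with the activity class
and penalizes features that correlate with each other:

    merit(S) = k * mean(r_cf) / sqrt(k + k*(k-1) * mean(r_ff))

where k = |S|, r_cf is the feature–class correlation and r_ff the pairwise
feature–feature correlation, both measured as symmetric uncertainty

    SU(x, y) = 2 * I(x; y) / (H(x) + H(y))

on discretized attributes (continuous descriptors are pre-binned by equal
frequency into at most 10 bins). The search is greedy hill-climbing over
subsets with backtracking: a priority queue keyed by merit, expanding the best
unexpanded subset by single-feature additions and/or deletions, stopping after
a fixed number of consecutive non-improving expansions.
"""

from __future__ import annotations

import heapq
import itertools
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .descriptors import DescriptorTable
from .errors import ValidationError

MAX_BINS = 10
_EPS = 1e-12


@dataclass(frozen=True)
class SubsetEvaluation:
    """A scored feature subset; ``merit`` is 0 for the empty subset."""

    subset: tuple[str, ...]
    merit: float
    r_cf_mean: float
    r_ff_mean: float

    @property
    def k(self) -> int:
        return len(self.subset)


def discretize(values: np.ndarray, max_bins: int = MAX_BINS) -> np.ndarray:
    """Equal-frequency binning into at most ``max_bins`` integer categories."""
    values = np.asarray(values)
    unique = np.unique(values)
    if len(unique) <= max_bins:
        return np.searchsorted(unique, values)
    binned = pd.qcut(values, q=max_bins, labels=False, duplicates="drop")
    return np.asarray(binned, dtype=int)


def _entropy(codes: np.ndarray) -> float:
    _, counts = np.unique(codes, return_counts=True)
    p = counts / counts.sum()
    return float(-(p * np.log2(p)).sum())


def symmetric_uncertainty(x: np.ndarray, y: np.ndarray) -> float:
    """2*I(x;y)/(H(x)+H(y)) on discretized attributes; 0 when either entropy is 0."""
    x = np.asarray(x)
    y = np.asarray(y)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("symmetric_uncertainty requires two equally long 1-D attributes")
    hx, hy = _entropy(x), _entropy(y)
    if hx <= 0.0 or hy <= 0.0:
        return 0.0
    # joint entropy via a single fused integer code (faster than a crosstab)
    xc = np.unique(x, return_inverse=True)[1]
    yc = np.unique(y, return_inverse=True)[1]
    _, joint = np.unique(xc * (yc.max() + 1) + yc, return_counts=True)
    p = joint / joint.sum()
    h_xy = float(-(p * np.log2(p)).sum())
    mi = hx + hy - h_xy
    su = 2.0 * mi / (hx + hy)
    return float(min(max(su, 0.0), 1.0))


class _CorrelationCache:
    """Lazily computed symmetric uncertainties over a discretized table."""

    def __init__(self, table: DescriptorTable, labels: Sequence[int]):
        labels = np.asarray(labels, dtype=int)
        if labels.shape[0] != len(table.compound_ids):
            raise ValidationError("labels length does not match table rows")
        self.names = table.column_names
        self.index = {n: i for i, n in enumerate(self.names)}
        self.codes = [discretize(table.values[:, j]) for j in range(len(self.names))]
        self.y = labels
        self._cf: dict[int, float] = {}
        self._ff: dict[tuple[int, int], float] = {}

    def r_cf(self, name: str) -> float:
        i = self.index[name]
        if i not in self._cf:
            self._cf[i] = symmetric_uncertainty(self.codes[i], self.y)
        return self._cf[i]

    def r_ff(self, a: str, b: str) -> float:
        i, j = sorted((self.index[a], self.index[b]))
        if (i, j) not in self._ff:
            self._ff[(i, j)] = symmetric_uncertainty(self.codes[i], self.codes[j])
        return self._ff[(i, j)]


def _evaluate(subset: tuple[str, ...], cache: _CorrelationCache) -> SubsetEvaluation:
    k = len(subset)
    if k == 0:
        return SubsetEvaluation(subset=(), merit=0.0, r_cf_mean=0.0, r_ff_mean=0.0)
    r_cf = float(np.mean([cache.r_cf(f) for f in subset]))
    if k == 1:
        r_ff = 0.0
    else:
        r_ff = float(np.mean([cache.r_ff(a, b) for a, b in itertools.combinations(subset, 2)]))
    denom = np.sqrt(k + k * (k - 1) * r_ff)
    merit = k * r_cf / denom if denom > 0 else 0.0
    return SubsetEvaluation(subset=subset, merit=merit, r_cf_mean=r_cf, r_ff_mean=r_ff)


def cfs_merit(
    subset: Sequence[str], table: DescriptorTable, labels: Sequence[int]
) -> SubsetEvaluation:
    """CFS merit of an explicit subset of the table's columns."""
    cache = _CorrelationCache(table, labels)
    unknown = [n for n in subset if n not in cache.index]
    if unknown:
        raise ValidationError(f"unknown columns: {unknown}")
    return _evaluate(tuple(sorted(subset)), cache)


def best_first_search(
    table: DescriptorTable,
    labels: Sequence[int],
    direction: str = "forward",
    stale_limit: int = 5,
) -> SubsetEvaluation:
    """Best-first subset search over CFS merit.

    Ties in merit are broken lexicographically on the (sorted) column-name
    tuples, making the result deterministic. ``stale_limit`` is the number of
    consecutive expansions of non-improving subsets tolerated before stopping.
    """
    if direction not in ("forward", "backward", "bidirectional"):
        raise ValidationError(f"unknown search direction {direction!r}")
    if stale_limit < 0:
        raise ValidationError("stale_limit must be >= 0")
    if not table.columns:
        raise ValidationError("table has no candidate columns")

    cache = _CorrelationCache(table, labels)
    all_names = tuple(sorted(cache.names))

    start: tuple[str, ...] = all_names if direction == "backward" else ()
    add_allowed = direction in ("forward", "bidirectional")
    drop_allowed = direction in ("backward", "bidirectional")

    start_eval = _evaluate(start, cache)
    best = start_eval
    heap: list[tuple[float, tuple[str, ...]]] = [(-start_eval.merit, start)]
    evaluated: dict[tuple[str, ...], SubsetEvaluation] = {start: start_eval}
    expanded: set[tuple[str, ...]] = set()
    stale = 0

    while heap:
        neg_merit, subset = heapq.heappop(heap)
        if subset in expanded:
            continue
        expanded.add(subset)
        node = evaluated[subset]
        if node.merit > best.merit + _EPS:
            best = node
            stale = 0
        elif subset != start:
            stale += 1
            if stale > stale_limit:
                break

        children: list[tuple[str, ...]] = []
        current = set(subset)
        if add_allowed:
            for name in all_names:
                if name not in current:
                    children.append(tuple(sorted(current | {name})))
        if drop_allowed and len(subset) > 1:
            for name in subset:
                children.append(tuple(sorted(current - {name})))
        for child in children:
            if child not in evaluated:
                evaluated[child] = _evaluate(child, cache)
                heapq.heappush(heap, (-evaluated[child].merit, child))
    return best


def exhaustive_search(
    table: DescriptorTable, labels: Sequence[int]
) -> SubsetEvaluation:
    """Brute-force argmax of merit over all non-empty subsets (oracle; small tables only)."""
    cache = _CorrelationCache(table, labels)
    names = sorted(cache.names)
    if len(names) > 20:
        raise ValidationError("exhaustive search is limited to 20 features")
    best = _evaluate((), cache)
    for k in range(1, len(names) + 1):
        for combo in itertools.combinations(names, k):
            ev = _evaluate(combo, cache)
            if ev.merit > best.merit + _EPS:
                best = ev
    return best


def write_selected(evaluation: SubsetEvaluation, path: str | Path) -> None:
    Path(path).write_text("".join(f"{name}\n" for name in evaluation.subset))


def read_selected(path: str | Path) -> list[str]:
    return [
        line.strip()
        for line in Path(path).read_text().splitlines()
        if line.strip() and not line.startswith("#")
    ]
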