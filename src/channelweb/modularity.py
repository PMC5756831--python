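"""Weighted directed modularity and merge gains for flow networks.

Modularity for a weighted directed network is

    Q = (1/2W) * sum_ij [ w_ij - w_i_out * w_j_in / (2W) ] * delta(c_i, c_j)

where ``w_ij`` is the internal carbon flux from i to j, ``w_i_out`` and
``w_j_in`` are row/column strengths, ``2W`` the total internal flow, and
``delta`` is 1 when i and j share a compartment. Boundary flows (imports,
exports, respiration) do not enter; self-loops do, and are within-
compartment by definition.

Merging two compartments changes Q by

    dQ(c, d) = e_cd + e_dc - (a_c_out * a_d_in + a_d_out * a_c_in)

with ``e_cd`` the fraction of total flow running from compartment c to d
and ``a_c_out/in`` the compartments' strength fractions — the basis of the
incremental bookkeeping used during greedy merging.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .errors import InputError, NumericalError
from .network_io import FlowNetwork


@dataclass(frozen=True)
class Partition:
    """Assignment of every node to a compartment.

    ``labels`` are non-negative integers forming a contiguous 0..S_c-1 set;
    ``merge_trace`` optionally records the accepted merges as
    ``(label_a, label_b, delta_q)`` tuples in order.
    """

    labels: np.ndarray
    merge_trace: tuple[tuple[int, int, float], ...] = field(default=())

    def __post_init__(self):
        labels = np.asarray(self.labels, dtype=int)
        if labels.ndim != 1 or labels.size == 0:
            raise InputError("partition labels must be a non-empty 1-d array")
        uniq = np.unique(labels)
        if uniq[0] != 0 or not np.array_equal(uniq, np.arange(uniq.size)):
            raise InputError("partition labels must form a contiguous 0..k-1 set")
        object.__setattr__(self, "labels", labels)

    @property
    def n_compartments(self) -> int:
        return int(self.labels.max()) + 1

    def merge(self, a: int, b: int, delta_q: float = np.nan) -> "Partition":
        """New partition with compartments ``a`` and ``b`` joined."""
        if a == b:
            raise InputError("cannot merge a compartment with itself")
        a, b = sorted((a, b))
        labels = self.labels.copy()
        labels[labels == b] = a
        labels[labels > b] -= 1
        return Partition(labels, self.merge_trace + ((a, b, float(delta_q)),))

    def same_compartment_matrix(self) -> np.ndarray:
        return self.labels[:, None] == self.labels[None, :]


def canonical_labels(labels: np.ndarray) -> Partition:
    """Relabel an arbitrary label vector to contiguous first-appearance order."""
    labels = np.asarray(labels)
    seen: dict = {}
    out = np.empty(labels.size, dtype=int)
    for i, lab in enumerate(labels):
        key = lab.item() if hasattr(lab, "item") else lab
        if key not in seen:
            seen[key] = len(seen)
        out[i] = seen[key]
    return Partition(out)


def same_partition(a: Partition | np.ndarray, b: Partition | np.ndarray) -> bool:
    """True when two labelings induce the same grouping (up to relabeling)."""
    la = a.labels if isinstance(a, Partition) else np.asarray(a)
    lb = b.labels if isinstance(b, Partition) else np.asarray(b)
    return np.array_equal(canonical_labels(la).labels, canonical_labels(lb).labels)


def _totals(net: FlowNetwork):
    w = net.F
    two_w = w.sum()
    if two_w <= 0:
        raise NumericalError("zero total internal flow; modularity undefined")
    return w, w.sum(axis=1), w.sum(axis=0), two_w


def modularity(net: FlowNetwork, part: Partition) -> float:
    """Weighted directed modularity of ``part`` on the internal flux matrix."""
    w, w_out, w_in, two_w = _totals(net)
    if part.labels.size != net.S:
        raise InputError("partition does not cover the network's nodes")
    same = part.same_compartment_matrix()
    q = (w[same].sum() - (np.outer(w_out, w_in)[same]).sum() / two_w) / two_w
    return float(q)


@dataclass(frozen=True)
class MergeGainMatrix:
    """Symmetric matrix of modularity gains for merging label pairs."""

    values: np.ndarray  # (k, k), diagonal NaN

    def best_pair(self) -> tuple[int, int, float]:
        """Max-gain unordered pair; ties go to the smallest (a, b) pair."""
        k = self.values.shape[0]
        best = (-1, -1, -np.inf)
        for a in range(k):
            for b in range(a + 1, k):
                if self.values[a, b] > best[2]:
                    best = (a, b, float(self.values[a, b]))
        return best


def _compartment_totals(net: FlowNetwork, part: Partition):
    """Per-compartment flow fractions: e[c, d], a_out[c], a_in[c]."""
    w, w_out, w_in, two_w = _totals(net)
    k = part.n_compartments
    onehot = np.zeros((net.S, k))
    onehot[np.arange(net.S), part.labels] = 1.0
    e = onehot.T @ w @ onehot / two_w
    a_out = onehot.T @ w_out / two_w
    a_in = onehot.T @ w_in / two_w
    return e, a_out, a_in


def modularity_from_totals(e: np.ndarray, a_out: np.ndarray, a_in: np.ndarray) -> float:
    return float(np.trace(e) - a_out @ a_in)


def merge_gain(e, a_out, a_in, a: int, b: int) -> float:
    return float(e[a, b] + e[b, a] - (a_out[a] * a_in[b] + a_out[b] * a_in[a]))


def merge_gain_matrix(net: FlowNetwork, part: Partition) -> MergeGainMatrix:
    """Gain dQ for every unordered pair of current compartments.

    Each entry equals ``modularity(merged) - modularity(current)`` exactly
    (the identity is exercised against brute-force recomputation in tests).
    """
    if part.n_compartments < 2:
        raise InputError("need at least two compartments to compute merge gains")
    e, a_out, a_in = _compartment_totals(net, part)
    k = part.n_compartments
    gains = np.full((k, k), np.nan)
    for a, b in itertools.combinations(range(k), 2):
        gains[a, b] = gains[b, a] = merge_gain(e, a_out, a_in, a, b)
    return MergeGainMatrix(gains)
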