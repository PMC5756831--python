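"""Basal reliance: how much of each node's carbon comes from each energy origin.

Every consumer's carbon can be traced back through the flux matrix to the
basal nodes (producers and detritus pools) that inject energy into the web.
The fractional reliance of consumer *C* on basal node *b* is defined
recursively: it is the diet-proportion-weighted average of the reliances of
the resources it consumes,

    reliance(C) = sum_R  P[R, C] * reliance(R)

where ``P[R, C]`` is the share of C's internal diet supplied by resource R.
Basal nodes are absorbing sources: their reliance is fixed at themselves,
so recycling flows *into* detritus are never traversed. Cycles among
consumers are handled by solving the linear system exactly rather than by
iterating up trophic levels; on acyclic webs the two coincide.

Nodes grouped by their dominant (arg-max) basal source form the seed
subgroups of the compartment-detection algorithm.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import NumericalError
from .network_io import FlowNetwork

#: reliance rows are accepted as conserved when they sum to 1 within this
ROW_SUM_TOL = 1e-9


def diet_proportions(net: FlowNetwork, imports_as_source: bool = False) -> np.ndarray:
    """Diet matrix ``P`` with ``P[i, j]`` = share of j's diet supplied by i.

    Columns are normalized over internal inflows only; a node fed purely by
    imports gets an all-zero column. With ``imports_as_source`` the import
    flow is kept in the denominator (used when imports are treated as a
    pseudo-basal origin).
    """
    T = net.F.sum(axis=0)
    if imports_as_source:
        T = T + net.imports
    with np.errstate(invalid="ignore", divide="ignore"):
        P = np.where(T > 0, net.F / np.where(T > 0, T, 1.0), 0.0)
    return P


@dataclass(frozen=True)
class BasalRelianceMatrix:
    """Fractional reliance of every node on every basal node.

    ``values[i, k]`` is the fraction of node i's carbon originating from the
    k-th basal node (column order given by ``basal_indices``). Basal rows
    are unit self-vectors; rows of nodes unreachable from the basal set are
    all zero and listed in ``unreachable``.
    """

    node_ids: tuple[str, ...]
    basal_indices: tuple[int, ...]
    values: np.ndarray
    P: np.ndarray
    unreachable: tuple[int, ...]

    @property
    def basal_ids(self) -> tuple[str, ...]:
        return tuple(self.node_ids[i] for i in self.basal_indices)


def basal_reliance(net: FlowNetwork, imports_as_source: bool = False) -> BasalRelianceMatrix:
    """Solve the basal-reliance system for every node.

    Basal nodes (producers and detritus) are absorbing: row_b = e_b. Every
    other row satisfies ``row_i = sum_j P[j, i] row_j``, solved as one linear
    system. Nodes with no path from any basal node come out all-zero and are
    flagged rather than raising.
    """
    basal = np.nonzero(net.basal_mask)[0]
    if basal.size == 0:
        raise NumericalError("no basal node (producer or detritus) in the network")
    P = diet_proportions(net, imports_as_source=imports_as_source)
    S = net.S
    nb = basal.size

    # nodes with no directed path from any basal node have structurally zero
    # reliance; dropping them first keeps the linear system nonsingular
    # (every remaining consumer cycle then has positive basal leakage)
    reach = np.zeros(S, dtype=bool)
    reach[basal] = True
    stack = list(basal)
    while stack:
        i = stack.pop()
        for j in np.nonzero(P[i, :] > 0)[0]:
            if not reach[j]:
                reach[j] = True
                stack.append(j)

    basal_set = set(basal.tolist())
    consumers = np.array(
        [i for i in range(S) if i not in basal_set and reach[i]], dtype=int
    )
    R = np.zeros((S, nb))
    for k, b in enumerate(basal):
        R[b, k] = 1.0
    if consumers.size:
        # row_i = sum_{j basal} P[j,i] e_j + sum_{j consumer} P[j,i] row_j
        A = P[np.ix_(consumers, consumers)].T  # A[i,j] = P[cons_j, cons_i]
        Bmat = P[np.ix_(basal, consumers)].T @ R[basal]  # direct basal diet share
        M = np.eye(consumers.size) - A
        try:
            Rc = np.linalg.solve(M, Bmat)
        except np.linalg.LinAlgError as exc:
            raise NumericalError(f"singular basal-reliance system: {exc}") from exc
        R[consumers] = Rc
    R = np.clip(R, 0.0, None)
    unreachable = tuple(int(i) for i in range(S) if not reach[i])
    return BasalRelianceMatrix(
        node_ids=net.node_ids,
        basal_indices=tuple(int(b) for b in basal),
        values=R,
        P=P,
        unreachable=unreachable,
    )


def basal_reliance_fixed_point(
    net: FlowNetwork, tol: float = 1e-12, max_iter: int = 100_000
) -> np.ndarray:
    """Reliance by fixed-point iteration (independent check of the solver).

    Iterates ``row_i <- sum_j P[j, i] row_j`` from zero with basal rows held
    at their unit vectors, to an elementwise tolerance.
    """
    basal = np.nonzero(net.basal_mask)[0]
    P = diet_proportions(net)
    S, nb = net.S, basal.size
    R = np.zeros((S, nb))
    R[basal, np.arange(nb)] = 1.0
    for _ in range(max_iter):
        Rn = P.T @ R
        Rn[basal] = 0.0
        Rn[basal, np.arange(nb)] = 1.0
        if np.max(np.abs(Rn - R)) < tol:
            return Rn
        R = Rn
    raise NumericalError("fixed-point reliance iteration did not converge")


@dataclass(frozen=True)
class SubgroupAssignment:
    """Seed subgroups by dominant basal source.

    ``labels[i]`` is the subgroup of node i; subgroups 0..n_basal-1
    correspond to the basal nodes in ``basal_indices`` order, and each
    unreachable node gets its own singleton subgroup after those. ``margin``
    is the gap between a node's largest and second-largest reliance entries
    (diagnostic for near-ties).
    """

    node_ids: tuple[str, ...]
    labels: np.ndarray
    basal_indices: tuple[int, ...]
    margin: np.ndarray

    @property
    def n_subgroups(self) -> int:
        return int(self.labels.max()) + 1


def dominant_source_groups(br: BasalRelianceMatrix) -> SubgroupAssignment:
    """Assign every node to the subgroup of its dominant basal source.

    Each basal node seeds its own subgroup and is assigned to it. Exact
    ties go to the tied basal node with the lowest node-table index.
    Unreachable nodes become singleton subgroups so that the merge phase
    can still absorb them.
    """
    S = len(br.node_ids)
    values = br.values
    labels = np.full(S, -1, dtype=int)
    margin = np.zeros(S)
    unreachable = set(br.unreachable)
    # basal column order follows node-table order of basal nodes, so argmax's
    # first-max tie-break is exactly "lowest node-table index"
    for i in range(S):
        if i in unreachable:
            continue
        row = values[i]
        k = int(np.argmax(row))
        labels[i] = k
        if row.size > 1:
            margin[i] = float(row[k] - np.partition(row, -2)[-2])
        else:
            margin[i] = float(row[k])
    nxt = values.shape[1]
    for i in sorted(unreachable):
        labels[i] = nxt
        nxt += 1
    return SubgroupAssignment(
        node_ids=br.node_ids,
        labels=labels,
        basal_indices=br.basal_indices,
        margin=margin,
    )
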