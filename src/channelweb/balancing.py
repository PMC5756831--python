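"""Steady-state balancing of flow networks by iterative input/output averaging.

Ecological network analysis assumes every node is at steady state: total
inflow (imports + intake) equals total outflow (exports + respiration +
losses to other nodes). Field data rarely balance exactly, so before
analysis each node's flows are nudged toward a common throughflow.

The scheme used here is an input/output averaging iteration: at every step
each node's target throughflow is the arithmetic mean of its current total
input and total output; incoming flows (including imports) are rescaled
toward the target, and outgoing flows (including exports and respiration)
likewise. An internal flux ``F[i, j]`` belongs to both node *i*'s output
and node *j*'s input, so it receives the average of the two rescaling
factors. The iteration preserves the zero/nonzero structure of the flux
matrix and converges quickly on mildly unbalanced webs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import NumericalError
from .network_io import FlowNetwork, validate_network


@dataclass(frozen=True)
class BalanceTrace:
    """Convergence log: max relative residual after each iteration."""

    max_residual: tuple[float, ...]
    iterations: int
    converged: bool


def balance_flows(
    net: FlowNetwork,
    tol: float = 1e-6,
    max_iter: int = 10_000,
    return_trace: bool = False,
):
    """Return a steady-state copy of ``net``.

    Parameters
    ----------
    net
        Input network; total throughflow must be positive.
    tol
        Relative tolerance: on return every node's residual satisfies
        ``|inflow - outflow| <= tol * throughflow``.
    max_iter
        Iteration cap; exceeding it raises :class:`NumericalError` carrying
        the worst remaining residual.
    return_trace
        If true, also return a :class:`BalanceTrace`.

    Notes
    -----
    A node whose residual is nonzero but that structurally lacks either
    inputs or outputs cannot be balanced by rescaling and raises
    :class:`NumericalError` naming the node.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    F = net.F.copy()
    imports = net.imports.copy()
    exports = net.exports.copy()
    respiration = net.respiration.copy()
    if F.sum() + imports.sum() + exports.sum() + respiration.sum() <= 0:
        raise NumericalError("network has zero total throughflow")

    def residuals(F, imports, exports, respiration):
        fin = imports + F.sum(axis=0)
        fout = exports + respiration + F.sum(axis=1)
        through = np.maximum(fin, fout)
        rel = np.where(through > 0, (fin - fout) / np.where(through > 0, through, 1.0), 0.0)
        return fin, fout, rel

    fin, fout, rel = residuals(F, imports, exports, respiration)
    # structurally one-sided nodes with a residual cannot be repaired
    for i in range(net.S):
        if abs(rel[i]) > tol:
            if fin[i] == 0:
                raise NumericalError(
                    f"node {net.node_ids[i]} has outputs but no inputs; cannot balance"
                )
            if fout[i] == 0:
                raise NumericalError(
                    f"node {net.node_ids[i]} has inputs but no outputs; cannot balance"
                )

    trace = [float(np.max(np.abs(rel)))]
    it = 0
    while np.max(np.abs(rel)) > tol and it < max_iter:
        target = 0.5 * (fin + fout)
        s_in = np.where(fin > 0, target / np.where(fin > 0, fin, 1.0), 1.0)
        s_out = np.where(fout > 0, target / np.where(fout > 0, fout, 1.0), 1.0)
        # F[i, j] sits in i's output and j's input: average the two factors
        F *= 0.5 * (s_out[:, None] + s_in[None, :])
        imports *= s_in
        exports *= s_out
        respiration *= s_out
        fin, fout, rel = residuals(F, imports, exports, respiration)
        trace.append(float(np.max(np.abs(rel))))
        it += 1

    converged = bool(np.max(np.abs(rel)) <= tol)
    if not converged:
        raise NumericalError(
            f"balancing did not converge in {max_iter} iterations; "
            f"worst relative residual {np.max(np.abs(rel)):.3g}"
        )
    out = net.with_flows(F=F, imports=imports, exports=exports, respiration=respiration)
    if return_trace:
        return out, BalanceTrace(tuple(trace), iterations=it, converged=converged)
    return out


def is_balanced(net: FlowNetwork, tol: float = 1e-6) -> bool:
    return validate_network(net, tol=tol).balanced
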