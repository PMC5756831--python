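"""Removal-effect statistics and their within/between-compartment contrast.

The removal effect of losing node k on node i is the biomass-scaled
log-ratio

    RE_i = log[(B_i^+ + 1) / (B_i^- + 1)] / (B_k + 1)

with B_i^+ and B_i^- the average biomasses of i with and without k, and
B_k the biomass of the removed node; the added ones keep small B_k from
inflating RE. If compartments buffer perturbations, the average effect
magnitude should be larger inside the removed node's compartment than
outside it — tested with a paired t test across webs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .dynamics import RemovalRun
from .errors import InputError
from .modularity import Partition


def removal_effect(b_plus: float, b_minus: float, b_k: float) -> float:
    """RE of one node: natural-log ratio scaled by the removed biomass."""
    if min(b_plus, b_minus, b_k) < 0:
        raise InputError("biomasses must be non-negative")
    return math.log((b_plus + 1.0) / (b_minus + 1.0)) / (b_k + 1.0)


@dataclass(frozen=True)
class RemovalOutcome:
    """Per-node removal effects of one experiment plus compartment means.

    ``re`` holds RE for every node (NaN at the removed node); the within
    mean covers nodes sharing the removed node's compartment (itself
    excluded) and the between mean all remaining nodes. ``within_mean`` is
    NaN when the removed node's compartment is a singleton.
    """

    removed_id: str
    removed_index: int
    removed_compartment: int
    b_k: float
    re: np.ndarray
    within_mean: float
    between_mean: float
    n_within: int
    n_between: int
    signed: bool


def removal_effects(run: RemovalRun) -> np.ndarray:
    """Vector of RE values for one removal run (NaN at the removed node)."""
    re = np.array(
        [
            removal_effect(bp, bm, run.b_k)
            for bp, bm in zip(run.b_plus, run.b_minus)
        ]
    )
    re[run.removed_index] = np.nan
    return re


def aggregate_re(run: RemovalRun, part: Partition, signed: bool = False) -> RemovalOutcome:
    """Within- and between-compartment mean removal effects.

    By default effect magnitudes ``|RE|`` are averaged so that positive and
    negative responses cannot cancel; ``signed=True`` averages raw values.
    """
    if part.labels.size != run.b_plus.size:
        raise InputError("partition does not cover the experiment's nodes")
    re = removal_effects(run)
    k = run.removed_index
    comp = int(part.labels[k])
    vals = re if signed else np.abs(re)
    within_idx = np.nonzero((part.labels == comp) & (np.arange(re.size) != k))[0]
    between_idx = np.nonzero(part.labels != comp)[0]
    within = float(np.mean(vals[within_idx])) if within_idx.size else float("nan")
    between = float(np.mean(vals[between_idx])) if between_idx.size else float("nan")
    return RemovalOutcome(
        removed_id=run.removed_id,
        removed_index=k,
        removed_compartment=comp,
        b_k=run.b_k,
        re=re,
        within_mean=within,
        between_mean=between,
        n_within=int(within_idx.size),
        n_between=int(between_idx.size),
        signed=signed,
    )


def paired_t_test(
    x: np.ndarray, y: np.ndarray, alternative: str = "two-sided"
) -> tuple[float, int, float]:
    """Paired t test on matched samples; returns (t, df, p).

    Zero variance of the differences yields t = +/-inf (p = 0) when the
    mean difference is nonzero, and t = 0, p = 1 when the samples agree
    exactly.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise InputError("paired samples must be 1-d and of equal length")
    n = x.size
    if n < 2:
        raise InputError("paired t test needs at least 2 pairs")
    diff = x - y
    df = n - 1
    sd = diff.std(ddof=1)
    if sd == 0:
        if np.allclose(diff, 0):
            return 0.0, df, 1.0
        return math.copysign(math.inf, diff.mean()), df, 0.0
    t = diff.mean() / (sd / math.sqrt(n))
    if alternative == "two-sided":
        p = 2.0 * stats.t.sf(abs(t), df)
    elif alternative == "greater":
        p = float(stats.t.sf(t, df))
    elif alternative == "less":
        p = float(stats.t.cdf(t, df))
    else:
        raise InputError(f"unknown alternative {alternative!r}")
    return float(t), df, float(p)
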