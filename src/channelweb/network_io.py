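"""Quantitative flow networks: the in-memory container and text formats.

A flow network holds, per node, a category (producer, consumer, decomposer
or detritus), a standing stock of carbon (g C m^-2) and the three boundary
flows (import, export, respiration, g C m^-2 day^-1), together with an
S x S matrix ``F`` of internal carbon fluxes where ``F[i, j]`` is the flux
from node ``i`` to node ``j``.

Two interchange formats are supported: a pair of TSV tables (nodes + edges)
and a single JSON document. Both use node ids, never matrix indices, and
round-trip all quantities at full double precision.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import InputError

CATEGORIES = ("producer", "consumer", "decomposer", "detritus")
#: categories that act as energy origins
BASAL_CATEGORIES = ("producer", "detritus")

NODE_COLUMNS = ["id", "name", "category", "biomass", "import", "export", "respiration"]
EDGE_COLUMNS = ["source", "target", "flux"]


@dataclass(frozen=True)
class FlowNetwork:
    """A quantitative (carbon-flux) food web.

    Parameters
    ----------
    node_ids
        Unique node identifiers; their order defines matrix indices.
    names
        Human-readable node names.
    category
        Per-node category, one of ``producer``, ``consumer``, ``decomposer``,
        ``detritus``.
    biomass
        Standing stock per node, g C m^-2.
    imports, exports, respiration
        Boundary flows per node, g C m^-2 day^-1.
    F
        S x S internal flux matrix; ``F[i, j]`` is the carbon flux from node
        ``i`` to node ``j``, g C m^-2 day^-1.
    """

    node_ids: tuple[str, ...]
    names: tuple[str, ...]
    category: tuple[str, ...]
    biomass: np.ndarray
    imports: np.ndarray
    exports: np.ndarray
    respiration: np.ndarray
    F: np.ndarray
    meta: dict = field(default_factory=dict, compare=False)

    def __post_init__(self):
        ids = tuple(str(i) for i in self.node_ids)
        object.__setattr__(self, "node_ids", ids)
        object.__setattr__(self, "names", tuple(str(n) for n in self.names))
        object.__setattr__(self, "category", tuple(str(c) for c in self.category))
        S = len(ids)
        if S < 2:
            raise InputError(f"a flow network needs at least 2 nodes, got {S}")
        if len(set(ids)) != S:
            raise InputError("node ids are not unique")
        for attr in ("biomass", "imports", "exports", "respiration"):
            v = np.asarray(getattr(self, attr), dtype=float)
            if v.shape != (S,):
                raise InputError(f"{attr} must have one value per node")
            if np.any(v < 0) or not np.all(np.isfinite(v)):
                raise InputError(f"{attr} contains negative or non-finite values")
            object.__setattr__(self, attr, v)
        F = np.asarray(self.F, dtype=float)
        if F.shape != (S, S):
            raise InputError(f"F must be {S}x{S}, got {F.shape}")
        if np.any(F < 0) or not np.all(np.isfinite(F)):
            raise InputError("F contains negative or non-finite fluxes")
        object.__setattr__(self, "F", F)
        bad = set(self.category) - set(CATEGORIES)
        if bad:
            raise InputError(f"unknown node categories: {sorted(bad)}")
        if not any(c in BASAL_CATEGORIES for c in self.category):
            raise InputError("no basal node (producer or detritus) present")

    # -- basic accessors ---------------------------------------------------

    @property
    def S(self) -> int:
        """Number of nodes."""
        return len(self.node_ids)

    def index(self, node_id: str) -> int:
        try:
            return self.node_ids.index(node_id)
        except ValueError:
            raise InputError(f"unknown node id: {node_id!r}") from None

    @property
    def basal_mask(self) -> np.ndarray:
        """Boolean mask of basal nodes (producers and detritus pools)."""
        return np.array([c in BASAL_CATEGORIES for c in self.category])

    @property
    def living_mask(self) -> np.ndarray:
        """Boolean mask of living nodes (everything but detritus)."""
        return np.array([c != "detritus" for c in self.category])

    def inflow(self) -> np.ndarray:
        """Total inflow per node: imports + internal intake."""
        return self.imports + self.F.sum(axis=0)

    def outflow(self) -> np.ndarray:
        """Total outflow per node: exports + respiration + internal losses."""
        return self.exports + self.respiration + self.F.sum(axis=1)

    def throughflow(self) -> np.ndarray:
        return np.maximum(self.inflow(), self.outflow())

    def with_flows(self, F=None, imports=None, exports=None, respiration=None) -> "FlowNetwork":
        """Copy of the network with some flow fields replaced."""
        kw = {}
        if F is not None:
            kw["F"] = np.asarray(F, dtype=float)
        if imports is not None:
            kw["imports"] = np.asarray(imports, dtype=float)
        if exports is not None:
            kw["exports"] = np.asarray(exports, dtype=float)
        if respiration is not None:
            kw["respiration"] = np.asarray(respiration, dtype=float)
        return replace(self, **kw)


@dataclass(frozen=True)
class ValidationReport:
    """Steady-state residuals and structural warnings for a flow network.

    ``residual[i] = inflow_i - outflow_i``; a balanced web has residuals of
    zero (within tolerance) at every node.
    """

    residual: np.ndarray
    relative_residual: np.ndarray
    warnings: tuple[str, ...]
    tol: float

    @property
    def balanced(self) -> bool:
        return bool(np.all(np.abs(self.relative_residual) <= self.tol))

    @property
    def max_relative_residual(self) -> float:
        return float(np.max(np.abs(self.relative_residual)))


def validate_network(net: FlowNetwork, tol: float = 1e-6) -> ValidationReport:
    """Check steady state and report structural oddities.

    The residual at node *j* is ``(imports_j + sum_i F[i, j]) -
    (exports_j + respiration_j + sum_k F[j, k])``. Relative residuals are
    scaled by node throughflow (nodes with zero throughflow get 0).
    """
    residual = net.inflow() - net.outflow()
    through = net.throughflow()
    with np.errstate(invalid="ignore", divide="ignore"):
        rel = np.where(through > 0, residual / np.where(through > 0, through, 1.0), 0.0)
    warnings = []
    diag = np.diag(net.F)
    for i in np.nonzero(diag > 0)[0]:
        warnings.append(f"self-loop on node {net.node_ids[i]} (flux {diag[i]:g})")
    degree = (net.F.sum(axis=0) + net.F.sum(axis=1)) > 0
    for i in np.nonzero(~degree)[0]:
        warnings.append(f"node {net.node_ids[i]} has no internal fluxes (isolated)")
    living = net.living_mask
    for i in np.nonzero(living & (net.biomass == 0))[0]:
        warnings.append(f"living node {net.node_ids[i]} has zero biomass")
    return ValidationReport(
        residual=residual,
        relative_residual=rel,
        warnings=tuple(warnings),
        tol=tol,
    )


# -- readers / writers -----------------------------------------------------


def _check_nodes_frame(nodes: pd.DataFrame, origin: str) -> pd.DataFrame:
    missing = [c for c in NODE_COLUMNS if c not in nodes.columns]
    if missing:
        raise InputError(f"{origin}: missing node columns {missing}")
    nodes = nodes.copy()
    nodes["id"] = nodes["id"].astype(str)
    if nodes["id"].duplicated().any():
        dup = nodes.loc[nodes["id"].duplicated(), "id"].iloc[0]
        raise InputError(f"{origin}: duplicate node id {dup!r}")
    return nodes


def _network_from_frames(nodes: pd.DataFrame, edges: pd.DataFrame, origin: str,
                         meta: dict | None = None) -> FlowNetwork:
    nodes = _check_nodes_frame(nodes, origin)
    ids = list(nodes["id"])
    idx = {nid: k for k, nid in enumerate(ids)}
    S = len(ids)
    F = np.zeros((S, S))
    seen: set[tuple[str, str]] = set()
    for _, row in edges.iterrows():
        s, t = str(row["source"]), str(row["target"])
        if s not in idx:
            raise InputError(f"{origin}: edge source {s!r} not in node table")
        if t not in idx:
            raise InputError(f"{origin}: edge target {t!r} not in node table")
        if (s, t) in seen:
            raise InputError(f"{origin}: duplicate edge ({s!r}, {t!r})")
        seen.add((s, t))
        flux = float(row["flux"])
        if flux < 0:
            raise InputError(f"{origin}: negative flux on edge ({s!r}, {t!r})")
        F[idx[s], idx[t]] = flux
    return FlowNetwork(
        node_ids=tuple(ids),
        names=tuple(str(n) for n in nodes["name"]),
        category=tuple(str(c).strip().lower() for c in nodes["category"]),
        biomass=nodes["biomass"].to_numpy(dtype=float),
        imports=nodes["import"].to_numpy(dtype=float),
        exports=nodes["export"].to_numpy(dtype=float),
        respiration=nodes["respiration"].to_numpy(dtype=float),
        F=F,
        meta=meta or {},
    )


def read_flow_network(node_table: str | Path, edge_table: str | Path) -> FlowNetwork:
    """Read a network from a node TSV and an edge TSV.

    Node-table order defines matrix indices. Missing edges are zero fluxes.
    """
    try:
        nodes = pd.read_csv(node_table, sep="\t", float_precision="round_trip")
        edges = pd.read_csv(edge_table, sep="\t", float_precision="round_trip")
    except (OSError, ValueError) as exc:
        raise InputError(f"cannot read tables: {exc}") from exc
    for col in EDGE_COLUMNS:
        if col not in edges.columns:
            raise InputError(f"{edge_table}: missing edge column {col!r}")
    return _network_from_frames(nodes, edges, origin=str(node_table))


def read_json(path: str | Path) -> FlowNetwork:
    """Read a network from the single-document JSON interchange format."""
    try:
        with open(path) as fh:
            doc = json.load(fh)
    except (OSError, json.JSONDecodeError) as exc:
        raise InputError(f"cannot read {path}: {exc}") from exc
    if "nodes" not in doc or "edges" not in doc:
        raise InputError(f"{path}: JSON document needs 'nodes' and 'edges' arrays")
    nodes = pd.DataFrame(doc["nodes"])
    edges = pd.DataFrame(doc["edges"], columns=EDGE_COLUMNS)
    meta = {k: v for k, v in doc.items() if k not in ("nodes", "edges")}
    return _network_from_frames(nodes, edges, origin=str(path), meta=meta)


def to_frames(net: FlowNetwork) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Node and edge tables (only nonzero fluxes become edges)."""
    nodes = pd.DataFrame(
        {
            "id": net.node_ids,
            "name": net.names,
            "category": net.category,
            "biomass": net.biomass,
            "import": net.imports,
            "export": net.exports,
            "respiration": net.respiration,
        }
    )
    src, tgt = np.nonzero(net.F)
    edges = pd.DataFrame(
        {
            "source": [net.node_ids[i] for i in src],
            "target": [net.node_ids[j] for j in tgt],
            "flux": net.F[src, tgt],
        }
    )
    return nodes, edges


def write_flow_network(net: FlowNetwork, node_table: str | Path, edge_table: str | Path) -> None:
    """Write a network as node/edge TSVs with 17 significant digits."""
    nodes, edges = to_frames(net)
    nodes.to_csv(node_table, sep="\t", index=False, float_format="%.17g")
    edges.to_csv(edge_table, sep="\t", index=False, float_format="%.17g")


def write_json(net: FlowNetwork, path: str | Path) -> None:
    """Write a network as a single JSON document (lossless interchange form)."""
    nodes, edges = to_frames(net)
    doc = {
        "nodes": nodes.to_dict(orient="records"),
        "edges": edges.to_dict(orient="records"),
        "units": {"stock": "gC/m2", "flow": "gC/m2/day"},
    }
    doc.update({k: v for k, v in net.meta.items() if k not in doc})
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


def read_network(path: str | Path) -> FlowNetwork:
    """Read a network from a JSON file, or from ``<stem>_nodes/_edges.tsv``."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        return read_json(path)
    raise InputError(
        f"{path}: expected a .json network document "
        "(use read_flow_network for TSV node/edge tables)"
    )
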