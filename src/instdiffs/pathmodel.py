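"""Causally ordered path model over the full measure set.

Following the nested-regression approach to path analysis on observed
variables, each measure (in causal order, skipping the causally first)
is regressed on all causally prior measures.  Responses with more than
three candidates go through windowed g-prior BMA (``rotation_select``);
responses with three or fewer candidates use the weakly regularized
small-model fit with a 0.05 inclusion criterion.  An edge enters the
model when the candidate's Bayes factor reaches 3 (tiered further at
10, 30 and 100); pairs whose BF falls below 1/3 are recorded as
null-supported.  Because every edge runs from a lower to a higher
causal rank the resulting graph is acyclic by construction, and the
indirect effect along any route is the product of its edge
coefficients, signs multiplying in the usual path algebra.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .bma import (
    BMAFit,
    enumerate_bma,
    evidence_tier,
    pip_to_bf,
    rotation_select,
    small_model_fit,
)
from .registry import MeasureDefinition, SchoolMeasureMatrix, causal_order

__all__ = [
    "PathEdge",
    "PathModel",
    "PathModelBuilder",
    "build_path_model",
    "chain_effect",
    "reduced_model",
    "export_graph",
]

EDGE_TIERS = ("moderate", "strong10", "strong30", "strong100")
NULL_TIERS = ("null_moderate", "null_strong")


@dataclass(frozen=True)
class PathEdge:
    source: str
    target: str
    beta: float
    bf: float
    tier: str

    @property
    def sign(self) -> str:
        return "+" if self.beta >= 0 else "-"


@dataclass
class PathModel:
    """Acyclic edge set plus bookkeeping over all evaluated pairs."""

    nodes: list[str]
    ranks: dict[str, int]
    edges: list[PathEdge] = field(default_factory=list)
    evaluated_pairs: int = 0
    tier_counts: dict[str, int] = field(default_factory=dict)
    pair_table: pd.DataFrame | None = None

    def edge(self, source: str, target: str) -> PathEdge:
        for e in self.edges:
            if e.source == source and e.target == target:
                return e
        raise KeyError(f"no edge {source} -> {target}")

    def has_edge(self, source: str, target: str) -> bool:
        return any(e.source == source and e.target == target for e in self.edges)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def count_at_least(self, bf: float) -> int:
        return sum(1 for e in self.edges if e.bf >= bf)

    def to_networkx(self) -> nx.DiGraph:
        graph = nx.DiGraph()
        for node in self.nodes:
            graph.add_node(node, causal_rank=self.ranks[node])
        for e in self.edges:
            graph.add_edge(
                e.source, e.target, beta=e.beta, bf=e.bf, tier=e.tier, sign=e.sign
            )
        return graph


class PathModelBuilder(BaseEstimator):
    """Fit the full causally ordered path model.

    Parameters
    ----------
    g : float or "uip"
        Zellner g for the BMA stages.
    edge_bf : float, default=3.0
        Minimum Bayes factor for an edge to enter the model.
    null_bf : float, default=1/3
        Below this the pair is recorded as null-supported.
    window, retain : int
        Rotation parameters passed to ``rotation_select``.

    Attributes (after :meth:`fit`)
    ------------------------------
    model_ : PathModel
    fits_ : dict mapping each response to its BMAFit or SmallModelFit.
    """

    def __init__(
        self,
        g: float | str = "uip",
        edge_bf: float = 3.0,
        null_bf: float = 1.0 / 3.0,
        window: int = 8,
        retain: int = 5,
    ):
        self.g = g
        self.edge_bf = edge_bf
        self.null_bf = null_bf
        self.window = window
        self.retain = retain

    def fit(
        self,
        X: SchoolMeasureMatrix | pd.DataFrame,
        registry: Sequence[MeasureDefinition],
    ):
        matrix = X if isinstance(X, SchoolMeasureMatrix) else SchoolMeasureMatrix(X)
        if not matrix.is_complete:
            raise ValueError("path modelling requires a complete matrix")
        reg = [d for d in registry if d.name in set(matrix.measure_names)]
        order = causal_order(reg)
        if len(order) < 2:
            raise ValueError("need at least 2 measures")
        ranks = {d.name: d.causal_rank for d in reg}
        reg_pos = {d.name: i for i, d in enumerate(reg)}
        values = matrix.values.loc[:, order]

        edges: list[PathEdge] = []
        rows: list[dict] = []
        fits: dict[str, object] = {}
        for resp_idx, response in enumerate(order[1:], start=1):
            prior = order[:resp_idx]
            r_rank = ranks[response]
            tied = [c for c in prior if ranks[c] == r_rank]
            if tied:
                raise ValueError(
                    f"causal rank tie between response {response!r} and {tied}"
                )
            # causally closest first: smallest rank gap, ties by registry order
            cand_order = sorted(
                prior, key=lambda c: (r_rank - ranks[c], reg_pos[c])
            )
            y = values[response]
            Xc = values.loc[:, cand_order]
            if len(cand_order) <= 3:
                fit = small_model_fit(y, Xc)
                fits[response] = fit
                for c in cand_order:
                    included = c in fit.included
                    rows.append(
                        {
                            "source": c,
                            "target": response,
                            "pip": np.nan,
                            "bf": np.nan,
                            "tier": "moderate" if included else "inconclusive",
                            "beta": float(fit.coef[c]),
                            "method": "small_model",
                        }
                    )
                    if included:
                        edges.append(
                            PathEdge(
                                source=c,
                                target=response,
                                beta=float(fit.coef[c]),
                                bf=np.nan,
                                tier="moderate",
                            )
                        )
            else:
                if len(cand_order) <= self.window:
                    fit = enumerate_bma(y, Xc, g=self.g)
                else:
                    fit = rotation_select(
                        y, Xc, g=self.g, window=self.window, retain=self.retain
                    )
                fits[response] = fit
                for c in cand_order:
                    pip = float(fit.pip[c])
                    bf = pip_to_bf(pip)
                    tier = evidence_tier(bf)
                    beta = float(fit.beta_conditional[c])
                    rows.append(
                        {
                            "source": c,
                            "target": response,
                            "pip": pip,
                            "bf": bf,
                            "tier": tier,
                            "beta": beta,
                            "method": "bma",
                        }
                    )
                    if bf >= self.edge_bf:
                        edges.append(
                            PathEdge(
                                source=c,
                                target=response,
                                beta=beta,
                                bf=bf,
                                tier=tier,
                            )
                        )
        pair_table = pd.DataFrame(rows)
        tier_counts = pair_table["tier"].value_counts().to_dict()
        self.model_ = PathModel(
            nodes=order,
            ranks=ranks,
            edges=edges,
            evaluated_pairs=len(pair_table),
            tier_counts=tier_counts,
            pair_table=pair_table,
        )
        self.fits_ = fits
        return self


def build_path_model(
    matrix: SchoolMeasureMatrix | pd.DataFrame,
    registry: Sequence[MeasureDefinition],
    g: float | str = "uip",
    edge_bf: float = 3.0,
    null_bf: float = 1.0 / 3.0,
) -> PathModel:
    """Fit the causally ordered path model; see :class:`PathModelBuilder`."""
    return (
        PathModelBuilder(g=g, edge_bf=edge_bf, null_bf=null_bf)
        .fit(matrix, registry)
        .model_
    )


def chain_effect(model: PathModel, route: Sequence[str]) -> tuple[float, str]:
    """Indirect effect along a route: product of betas, signs multiply.

    E.g. signs (-, +, -) compose to +; (-, -, +, -) compose to -.
    """
    if len(route) < 2:
        raise ValueError("route needs at least two nodes")
    product = 1.0
    for a, b in zip(route[:-1], route[1:]):
        product *= model.edge(a, b).beta  # KeyError if edge missing
    return float(product), "+" if product >= 0 else "-"


def reduced_model(model: PathModel, focal: str) -> PathModel:
    """Subgraph of paths that reach or leave a focal measure.

    Direct edges touching the focal node are kept at any tier; edges on
    indirect routes to or from it survive only at the strong tiers
    (BF >= 10).  Nodes left without edges are dropped (except the focal
    node itself).
    """
    if focal not in model.nodes:
        raise KeyError(f"focal measure {focal!r} not in model")
    graph = model.to_networkx()
    strong = {
        (e.source, e.target)
        for e in model.edges
        if e.tier in ("strong10", "strong30", "strong100")
    }
    keep: set[tuple[str, str]] = set()
    for e in model.edges:
        if e.source == focal or e.target == focal:
            keep.add((e.source, e.target))
    # strong edges lying on a directed path through strong edges to/from focal
    strong_graph = nx.DiGraph(list(strong))
    for s, t in strong:
        touches_focal = False
        if strong_graph.has_node(t) and focal in strong_graph.nodes:
            touches_focal = nx.has_path(strong_graph, t, focal) if t != focal else True
        if not touches_focal and strong_graph.has_node(s) and focal in strong_graph.nodes:
            touches_focal = nx.has_path(strong_graph, focal, s) if s != focal else True
        if touches_focal:
            keep.add((s, t))
    edges = [e for e in model.edges if (e.source, e.target) in keep]
    nodes = {focal} | {e.source for e in edges} | {e.target for e in edges}
    ordered_nodes = [n for n in model.nodes if n in nodes]
    return PathModel(
        nodes=ordered_nodes,
        ranks={n: model.ranks[n] for n in ordered_nodes},
        edges=edges,
        evaluated_pairs=model.evaluated_pairs,
        tier_counts=model.tier_counts,
        pair_table=model.pair_table,
    )


def export_graph(model: PathModel, format: str = "edge_csv") -> str:
    """Serialize the model as DOT, GraphML or a long-format edge CSV."""
    if format == "edge_csv":
        rows = [
            {
                "source": e.source,
                "target": e.target,
                "beta": e.beta,
                "bf": e.bf,
                "tier": e.tier,
                "sign": e.sign,
            }
            for e in model.edges
        ]
        buf = io.StringIO()
        pd.DataFrame(
            rows, columns=["source", "target", "beta", "bf", "tier", "sign"]
        ).to_csv(buf, index=False)
        return buf.getvalue()
    if format == "graphml":
        graph = model.to_networkx()
        # GraphML cannot carry NaN edge attributes portably
        for _u, _v, data in graph.edges(data=True):
            if isinstance(data.get("bf"), float) and np.isnan(data["bf"]):
                data["bf"] = -1.0
        return "\n".join(nx.generate_graphml(graph))
    if format == "dot":
        lines = ["digraph paths {"]
        for node in model.nodes:
            lines.append(f'  "{node}" [causal_rank={model.ranks[node]}];')
        for e in model.edges:
            bf = "nan" if np.isnan(e.bf) else f"{e.bf:.3g}"
            lines.append(
                f'  "{e.source}" -> "{e.target}" '
                f'[beta={e.beta:.4f}, bf="{bf}", tier="{e.tier}", sign="{e.sign}"];'
            )
        lines.append("}")
        return "\n".join(lines)
    raise ValueError(f"unknown format {format!r}")
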