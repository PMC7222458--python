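"""Synthetic school-level data with known causal structure.

Three generators mirror the statistical structure the analysis assumes:

* :func:`generate_from_dag` simulates standardized measures from a
  linear-Gaussian structural causal model whose edges respect the causal
  ranking, so path-model recovery can be tested against known truth;
* :func:`inject_missingness` masks cells either completely at random
  (emulating the ~11% missingness density of the study data) or in
  structural blocks (new schools missing historical measures);
* :func:`generate_panel` draws unit x occasion panels with a target
  intraclass correlation, for which Cronbach's alpha has the closed
  Spearman-Brown form alpha = k*icc / (1 + (k-1)*icc).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .registry import OccasionPanel, SchoolMeasureMatrix

__all__ = [
    "SyntheticSpec",
    "MissingnessSpec",
    "PanelSpec",
    "generate_from_dag",
    "implied_covariance",
    "inject_missingness",
    "generate_panel",
    "study_like_dag",
]


@dataclass
class SyntheticSpec:
    """A linear-Gaussian causal DAG over standardized measures.

    ``nodes`` are (name, causal_rank) pairs; every edge must run from a
    lower-ranked to a higher-ranked node, which guarantees acyclicity.
    Residual standard deviations are solved so each node has unit
    variance; if the structural part alone implies variance > 1 the spec
    is infeasible and generation raises rather than silently rescaling.
    """

    nodes: list[tuple[str, int]]
    edges: list[tuple[str, str, float]] = field(default_factory=list)
    n_units: int = 29
    seed: int = 0

    def __post_init__(self) -> None:
        names = [n for n, _ in self.nodes]
        if len(set(names)) != len(names):
            raise ValueError("duplicate node names")
        ranks = dict(self.nodes)
        for src, dst, _beta in self.edges:
            if src not in ranks or dst not in ranks:
                raise ValueError(f"edge ({src}, {dst}) references unknown node")
            if ranks[src] >= ranks[dst]:
                raise ValueError(
                    f"edge {src}->{dst} does not run from lower to higher causal rank"
                )


@dataclass
class MissingnessSpec:
    mode: str = "mcar"  # "mcar" | "block"
    rate: float = 0.0
    block: tuple[Sequence[str], Sequence[str]] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in {"mcar", "block"}:
            raise ValueError(f"unknown missingness mode {self.mode!r}")
        if not 0.0 <= self.rate <= 1.0:
            raise ValueError("rate must be in [0, 1]")
        if self.mode == "block" and self.block is None:
            raise ValueError("block mode requires a (units, measures) block")


@dataclass
class PanelSpec:
    icc: float
    occasions: int
    n_units: int
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.icc <= 1.0:
            raise ValueError("icc must be in [0, 1]")
        if self.occasions < 2:
            raise ValueError("at least 2 occasions required")


def implied_covariance(spec: SyntheticSpec) -> pd.DataFrame:
    """Model-implied covariance of the DAG (unit variances by design).

    Built node by node in causal order:
    cov(new, old) = sum_j beta_j * cov(parent_j, old), and the residual
    variance of each node is 1 minus the variance explained by its
    parents.  For standardized variables the implied correlation of any
    pair equals the sum over tracing paths of products of betas.
    """
    order = [n for n, _ in sorted(spec.nodes, key=lambda t: t[1])]
    idx = {n: i for i, n in enumerate(order)}
    p = len(order)
    cov = np.zeros((p, p))
    parents: dict[str, list[tuple[str, float]]] = {n: [] for n in order}
    for src, dst, beta in spec.edges:
        parents[dst].append((src, beta))
    for node in order:
        i = idx[node]
        pars = parents[node]
        if pars:
            pidx = np.array([idx[s] for s, _ in pars])
            betas = np.array([b for _, b in pars])
            explained = float(betas @ cov[np.ix_(pidx, pidx)] @ betas)
            if explained > 1.0 + 1e-12:
                raise ValueError(
                    f"infeasible variance budget at node {node!r}: structural "
                    f"variance {explained:.3f} exceeds 1"
                )
            cov[i, :] = betas @ cov[pidx, :]
            cov[:, i] = cov[i, :]
        cov[i, i] = 1.0
    return pd.DataFrame(cov, index=order, columns=order)


def generate_from_dag(spec: SyntheticSpec) -> SchoolMeasureMatrix:
    """Simulate ``n_units`` rows from the structural model.

    Nodes are generated in topological (causal-rank) order as
    ``node = sum(beta * parent) + Gaussian residual`` with the residual
    SD solved for unit node variance.  Deterministic given the seed.
    """
    cov = implied_covariance(spec)  # validates feasibility & acyclicity
    order = list(cov.columns)
    parents: dict[str, list[tuple[str, float]]] = {n: [] for n in order}
    for src, dst, beta in spec.edges:
        parents[dst].append((src, beta))
    rng = np.random.default_rng(spec.seed)
    data: dict[str, np.ndarray] = {}
    idx = {n: i for i, n in enumerate(order)}
    c = cov.to_numpy()
    for node in order:
        pars = parents[node]
        structural = np.zeros(spec.n_units)
        explained = 0.0
        if pars:
            pidx = np.array([idx[s] for s, _ in pars])
            betas = np.array([b for _, b in pars])
            explained = float(betas @ c[np.ix_(pidx, pidx)] @ betas)
            structural = sum(b * data[s] for s, b in pars)
        resid_sd = float(np.sqrt(max(0.0, 1.0 - explained)))
        data[node] = structural + rng.normal(0.0, resid_sd, size=spec.n_units)
    values = pd.DataFrame(
        {n: data[n] for n in order},
        index=[f"unit{i:03d}" for i in range(spec.n_units)],
    )
    return SchoolMeasureMatrix(values)


def inject_missingness(
    matrix: SchoolMeasureMatrix, mspec: MissingnessSpec
) -> SchoolMeasureMatrix:
    """Mask cells MCAR at a given rate, or an exact structural block."""
    out = matrix.copy()
    if mspec.mode == "mcar":
        rng = np.random.default_rng(mspec.seed)
        mask = pd.DataFrame(
            rng.random(out.values.shape) < mspec.rate,
            index=out.values.index,
            columns=out.values.columns,
        )
        out.values = out.values.mask(mask)
    else:
        units, measures = mspec.block  # type: ignore[misc]
        bad_u = [u for u in units if u not in out.values.index]
        bad_m = [m for m in measures if m not in out.values.columns]
        if bad_u or bad_m:
            raise KeyError(f"block references unknown units {bad_u} / measures {bad_m}")
        out.values.loc[list(units), list(measures)] = np.nan
    return out


def generate_panel(pspec: PanelSpec) -> OccasionPanel:
    """Unit x occasion panel with a target between-unit variance share.

    unit value at each occasion = shared trait (variance ``icc``) +
    occasion noise (variance ``1 - icc``), giving expected alpha of
    k*icc / (1 + (k-1)*icc) for k occasions.
    """
    rng = np.random.default_rng(pspec.seed)
    trait = rng.normal(0.0, np.sqrt(pspec.icc), size=(pspec.n_units, 1))
    noise = rng.normal(
        0.0, np.sqrt(1.0 - pspec.icc), size=(pspec.n_units, pspec.occasions)
    )
    values = pd.DataFrame(
        trait + noise,
        index=[f"unit{i:03d}" for i in range(pspec.n_units)],
        columns=[f"occ{j}" for j in range(pspec.occasions)],
    )
    return OccasionPanel(measure_name="synthetic", values=values)


def study_like_dag(
    n_units: int = 29, seed: int = 0, n_nodes: int = 29
) -> SyntheticSpec:
    """A compact stand-in for the study's structural model (synthetic).

    A chain-plus-shortcuts DAG over ``n_nodes`` standardized measures
    emulating an "academic backbone": early attainment nodes feed
    mid-course and postgraduate outcome nodes with standardized paths of
    0.3-0.8, other nodes being exogenous noise.  Useful as a default
    fixture; it is not a reconstruction of the published model.
    """
    nodes = [(f"m{i:02d}", (i + 1) * 10) for i in range(n_nodes)]
    edges: list[tuple[str, str, float]] = []
    backbone = [0, 3, 7, 12, 18, min(24, n_nodes - 1)]
    backbone = sorted(set(b for b in backbone if b < n_nodes))
    for a, b in zip(backbone[:-1], backbone[1:]):
        edges.append((f"m{a:02d}", f"m{b:02d}", 0.7))
    if n_nodes > 20:
        edges.append(("m01", "m10", 0.5))
        edges.append(("m10", "m20", -0.4))
        edges.append(("m05", "m20", 0.3))
    return SyntheticSpec(nodes=nodes, edges=edges, n_units=n_units, seed=seed)
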