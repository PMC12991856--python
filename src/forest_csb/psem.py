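"""Piecewise structural equation models over plot-level features.

Each endogenous node of a :class:`~forest_csb.dag.CausalGraph` gets its own
linear mixed model (crossed random intercepts for site, forest type and
management), fitted on a prepared frame in which log-flagged nodes are
log-transformed and every column is scaled to mean 0 / sd 1, so path
coefficients are directly comparable (standardized).  Overall fit is judged
by tests of directed separation: every basis-set claim is tested by adding
the claimed-independent predictor to the response's mixed model, and the
claim p-values are combined into Fisher's C = -2 sum ln(p), chi-square with
2k degrees of freedom under the causal model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .dag import CausalGraph, IndependenceClaim, basis_set
from .lmm import MixedLMResult, fit_mixed_lm

__all__ = [
    "NodeFit",
    "DSepResult",
    "PsemFit",
    "prepare_model_frame",
    "fit_node",
    "fishers_c",
    "fit_psem",
]

logger = logging.getLogger(__name__)

DEFAULT_GROUPS = ("site", "forest_type", "management")


@dataclass
class NodeFit:
    """One node's mixed model: standardized coefficients and variance parts."""

    response: str
    predictors: list[str]
    coefficients: dict[str, float]
    std_errors: dict[str, float]
    p_values: dict[str, float]
    random_variances: dict[str, float]
    residual_variance: float
    marginal_r2: float
    n_obs: int


@dataclass
class DSepResult:
    """Directed-separation test: claims, per-claim p-values and Fisher's C."""

    claims: list[IndependenceClaim]
    p_values: list[float]
    C: float
    df: int
    p_C: float


@dataclass
class PsemFit:
    node_fits: list[NodeFit]
    dsep: DSepResult
    correlated_error_r: dict[tuple[str, str], float] = field(default_factory=dict)

    def fit_for(self, response: str) -> NodeFit:
        for nf in self.node_fits:
            if nf.response == response:
                return nf
        raise KeyError(response)

    def coefficient(self, parent: str, child: str) -> float:
        return self.fit_for(child).coefficients[parent]


def prepare_model_frame(features: pd.DataFrame, graph: CausalGraph) -> pd.DataFrame:
    """Log-transform flagged nodes, then z-score every graph column.

    Raises if a log-flagged column has non-positive values (no offset is
    applied; the generator and the harmonized data keep carbon stocks
    strictly positive) or if any column is constant.
    """
    missing = [n for n in graph.nodes if n not in features.columns]
    if missing:
        raise ValueError(f"features table lacks graph columns: {missing}")
    out = features.copy()
    for node in graph.nodes:
        col = out[node].astype(float)
        if col.isna().any():
            raise ValueError(f"column {node!r} contains missing values")
        if graph.transforms.get(node) == "log":
            if (col <= 0).any():
                raise ValueError(
                    f"column {node!r} has non-positive values; the log transform "
                    "uses no offset by design"
                )
            col = np.log(col)
        sd = col.std(ddof=1)
        if not np.isfinite(sd) or sd == 0:
            raise ValueError(f"column {node!r} is constant; cannot scale")
        out[node] = (col - col.mean()) / sd
    return out


def fit_node(
    response: str,
    parents: list[str],
    groups: dict[str, np.ndarray],
    data: pd.DataFrame,
) -> NodeFit:
    """REML mixed model of one endogenous node on its parents.

    ``data`` must be a prepared frame; an intercept is always included.
    Grouping factors with a single observed level are dropped from the
    random structure (their variance is not identifiable) with a log note.
    """
    y = data[response].to_numpy(dtype=float)
    X = np.column_stack(
        [np.ones(len(data))] + [data[p].to_numpy(dtype=float) for p in parents]
    )
    res = fit_mixed_lm(y, X, groups, names=["intercept"] + list(parents))
    if res.dropped_groups:
        logger.info(
            "fit_node(%s): dropped single-level grouping factors %s",
            response,
            res.dropped_groups,
        )
    return NodeFit(
        response=response,
        predictors=list(parents),
        coefficients={p: res.coef(p) for p in parents},
        std_errors={p: float(res.bse[res.names.index(p)]) for p in parents},
        p_values={p: res.pvalue(p) for p in parents},
        random_variances=dict(res.vc),
        residual_variance=res.resid_var,
        marginal_r2=res.marginal_r2,
        n_obs=len(data),
    )


def fishers_c(p_values, clamp: bool = False) -> tuple[float, int, float]:
    """Fisher's C over independence-claim p-values.

    C = -2 sum ln(p_i), df = 2k, p_C = chi-square upper tail.  With no
    claims returns (0.0, 0, 1.0).  p = 0 raises unless ``clamp`` substitutes
    the smallest positive float.
    """
    ps = list(p_values)
    if not ps:
        return 0.0, 0, 1.0
    clean = []
    for p in ps:
        if not (0.0 <= p <= 1.0):
            raise ValueError(f"p-value {p} outside [0, 1]")
        if p == 0.0:
            if not clamp:
                raise ValueError("p-value of exactly 0; enable clamp to proceed")
            p = np.nextafter(0.0, 1.0)
        clean.append(p)
    C = -2.0 * float(np.sum(np.log(clean)))
    df = 2 * len(clean)
    p_C = float(stats.chi2.sf(C, df))
    return C, df, p_C


def _group_arrays(data: pd.DataFrame, group_cols) -> dict[str, np.ndarray]:
    missing = [g for g in group_cols if g not in data.columns]
    if missing:
        raise ValueError(f"grouping columns missing from data: {missing}")
    return {g: data[g].to_numpy() for g in group_cols}


def fit_psem(
    features: pd.DataFrame,
    graph: CausalGraph,
    group_cols=DEFAULT_GROUPS,
    prepared: bool = False,
) -> PsemFit:
    """Fit the full piecewise SEM: one mixed model per endogenous node plus
    the directed-separation tests.

    Claim p-values come from the t test on the claimed-independent
    predictor's slope in a mixed model of the claim's response on that
    predictor plus the claim's conditioning set, with the same random
    structure as the node models.  Correlated-error pairs are reported as
    Pearson correlations of the prepared columns.
    """
    frame = features if prepared else prepare_model_frame(features, graph)
    groups = _group_arrays(frame, group_cols)

    node_fits = [
        fit_node(node, graph.parents(node), groups, frame)
        for node in graph.topological_order()
        if graph.parents(node)
    ]

    claims = basis_set(graph)
    p_values = []
    for claim in claims:
        predictors = [claim.x] + [c for c in claim.conditioning if c != claim.x]
        fit = fit_node(claim.y, predictors, groups, frame)
        p_values.append(fit.p_values[claim.x])
    C, df, p_C = fishers_c(p_values)
    dsep = DSepResult(claims=claims, p_values=p_values, C=C, df=df, p_C=p_C)

    cerr = {}
    for pair in sorted(tuple(sorted(p)) for p in graph.correlated_errors):
        a, b = pair
        cerr[(a, b)] = float(np.corrcoef(frame[a], frame[b])[0, 1])
    return PsemFit(node_fits=node_fits, dsep=dsep, correlated_error_r=cerr)
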