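"""Direct, indirect, total and mediator effects by path tracing, with
nonparametric bootstrap confidence intervals.

On a fitted piecewise SEM the standardized effect of x on y decomposes as

    direct(x, y)   = coefficient of the edge x -> y (0 if absent)
    indirect(x, y) = sum over directed paths x -> ... -> y of length >= 2
                     of the product of edge coefficients
    total          = direct + indirect
    mediator m     = sum over those paths that pass through m

Graphs are small (<= 12 nodes), so paths are enumerated exhaustively by
depth-first search.  Confidence intervals come from resampling plots with
replacement (stratified by site so no random-effect level empties), refitting
every node model per replicate and recomputing the decomposition; percentile
intervals at the requested level.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dag import CausalGraph
from .psem import DEFAULT_GROUPS, PsemFit, NodeFit, fit_node, prepare_model_frame, _group_arrays

__all__ = ["path_effects", "bootstrap_effects", "effect_table"]

logger = logging.getLogger(__name__)

EFFECT_COLUMNS = ["predictor", "response", "effect_type", "estimate"]


def _edge_coefficients(graph: CausalGraph, node_fits: list[NodeFit]) -> dict[tuple[str, str], float]:
    coef = {}
    by_response = {nf.response: nf for nf in node_fits}
    for a, b in graph.edges:
        nf = by_response.get(b)
        if nf is None or a not in nf.coefficients:
            raise ValueError(f"no fitted coefficient for edge {a} -> {b}")
        coef[(a, b)] = nf.coefficients[a]
    return coef


def _all_paths(graph: CausalGraph) -> dict[tuple[str, str], list[list[str]]]:
    """All directed paths between every ordered pair, by DFS."""
    children: dict[str, list[str]] = {n: [] for n in graph.nodes}
    for a, b in graph.edges:
        children[a].append(b)
    paths: dict[tuple[str, str], list[list[str]]] = {}

    def dfs(start: str, node: str, trail: list[str]):
        for ch in children[node]:
            new = trail + [ch]
            paths.setdefault((start, ch), []).append(new)
            dfs(start, ch, new)

    for n in graph.nodes:
        dfs(n, n, [n])
    return paths


def path_effects(graph: CausalGraph, node_fits: list[NodeFit]) -> pd.DataFrame:
    """Point-estimate effect decomposition for every ancestor/descendant pair.

    Returns a long table (predictor, response, effect_type, estimate) with
    effect_type in {direct, indirect, total, mediator:<node>}.  The identity
    total = direct + indirect holds exactly row-wise.
    """
    coef = _edge_coefficients(graph, node_fits)
    paths = _all_paths(graph)
    rows = []
    for (x, y), plist in sorted(paths.items()):
        direct = coef.get((x, y), 0.0)
        indirect = 0.0
        through: dict[str, float] = {}
        for path in plist:
            if len(path) < 3:
                continue
            prod = 1.0
            for a, b in zip(path, path[1:]):
                prod *= coef[(a, b)]
            indirect += prod
            for m in path[1:-1]:
                through[m] = through.get(m, 0.0) + prod
        rows.append((x, y, "direct", direct))
        rows.append((x, y, "indirect", indirect))
        rows.append((x, y, "total", direct + indirect))
        for m in sorted(through):
            rows.append((x, y, f"mediator:{m}", through[m]))
    return pd.DataFrame(rows, columns=EFFECT_COLUMNS)


def _stratified_resample(
    frame: pd.DataFrame, strata: np.ndarray, rng: np.random.Generator
) -> pd.DataFrame:
    """Resample rows with replacement within each stratum (same sizes)."""
    idx_parts = []
    for level in np.unique(strata):
        members = np.flatnonzero(strata == level)
        idx_parts.append(rng.choice(members, size=len(members), replace=True))
    idx = np.concatenate(idx_parts)
    return frame.iloc[idx].reset_index(drop=True)


def bootstrap_effects(
    features: pd.DataFrame,
    graph: CausalGraph,
    group_cols=DEFAULT_GROUPS,
    nboot: int = 999,
    seed: int | None = None,
    ci_level: float = 0.95,
    stratify_by: str = "site",
    max_redraws: int = 100,
) -> pd.DataFrame:
    """Bootstrap the effect decomposition.

    Plots are resampled with replacement, stratified by ``stratify_by`` so
    random-effect levels of that factor keep their sample sizes; node models
    are refit and effects recomputed per replicate.  A replicate in which
    some other grouping factor collapses to a single level is redrawn (at
    most ``max_redraws`` times, then the degenerate component is simply
    dropped by the fitter).  Returns the effect table with percentile CI
    columns (lower, upper) and a ``significant`` flag (CI excludes 0).
    Deterministic for a fixed seed.
    """
    if nboot < 1:
        raise ValueError("nboot must be >= 1")
    if not 0 < ci_level < 1:
        raise ValueError("ci_level must be in (0, 1)")
    rng = np.random.default_rng(seed)
    frame = prepare_model_frame(features, graph)
    strata = frame[stratify_by].to_numpy()

    endo = [n for n in graph.topological_order() if graph.parents(n)]
    point_fits = [
        fit_node(n, graph.parents(n), _group_arrays(frame, group_cols), frame)
        for n in endo
    ]
    point = path_effects(graph, point_fits)

    draws = np.empty((nboot, len(point)))
    b = 0
    while b < nboot:
        boot = _stratified_resample(frame, strata, rng)
        n_redraw = 0
        while any(
            boot[g].nunique() < 2 for g in group_cols if g != stratify_by
        ) and n_redraw < max_redraws:
            boot = _stratified_resample(frame, strata, rng)
            n_redraw += 1
        if n_redraw:
            logger.info("bootstrap replicate %d: redrew %d times", b, n_redraw)
        groups = _group_arrays(boot, group_cols)
        fits = [fit_node(n, graph.parents(n), groups, boot) for n in endo]
        draws[b] = path_effects(graph, fits)["estimate"].to_numpy()
        b += 1

    alpha = 1.0 - ci_level
    lower = np.percentile(draws, 100 * alpha / 2, axis=0)
    upper = np.percentile(draws, 100 * (1 - alpha / 2), axis=0)
    out = point.copy()
    out["lower"] = lower
    out["upper"] = upper
    out["significant"] = (out["lower"] > 0) | (out["upper"] < 0)
    return out


def effect_table(fit: PsemFit, graph: CausalGraph) -> pd.DataFrame:
    """Point-estimate effect table from an already-fitted piecewise SEM."""
    return path_effects(graph, fit.node_fits)
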