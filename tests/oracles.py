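"""Independent reference implementations used as test oracles.

Everything here is deliberately coded from scratch against the published
formulas (explicit loops, product-form binomial ratios, plain bisection)
rather than calling the package's own numerical paths.
"""

from __future__ import annotations

import numpy as np


# -- deadwood typology -------------------------------------------------------

def oracle_diameter_class(d: float) -> int:
    bounds = [25.0, 35.0, 50.0]
    cls = 1
    for b in bounds:
        if d >= b:
            cls += 1
    return cls


def oracle_deadwood_type_richness(pieces) -> int:
    seen = set()
    for p in pieces:
        larger = p.d1 if p.d2 is None else max(p.d1, p.d2)
        seen.add((oracle_diameter_class(larger), p.position, p.decay_stage))
    return len(seen)


# -- coverage-based rarefaction / extrapolation ------------------------------

def _ratio(T: int, y: int, t: float) -> float:
    """C(T-y, t)/C(T, t) via the telescoping product, 0 beyond T-y."""
    if t > T - y:
        return 0.0
    r = 1.0
    for j in range(int(y)):
        r *= (T - t - j) / (T - j)
    return r


def oracle_coverage(y: list[int], T: int, t: float) -> float:
    U = sum(y)
    if t < T:
        return 1.0 - sum((yi / U) * _ratio(T, yi, t) for yi in y)
    Q1 = sum(1 for yi in y if yi == 1)
    Q2 = sum(1 for yi in y if yi == 2)
    if Q1 == 0:
        return 1.0
    A = (T - 1) * Q1 / ((T - 1) * Q1 + 2 * Q2) if ((T - 1) * Q1 + 2 * Q2) else 1.0
    return 1.0 - (Q1 / U) * A ** (t - T + 1)


def oracle_richness(y: list[int], T: int, t: float) -> float:
    if t <= T:
        return sum(1.0 - _ratio(T, yi, t) for yi in y)
    S_obs = len(y)
    Q1 = sum(1 for yi in y if yi == 1)
    Q2 = sum(1 for yi in y if yi == 2)
    if Q2 > 0:
        q0 = (T - 1) / T * Q1 * Q1 / (2 * Q2)
    else:
        q0 = (T - 1) / T * Q1 * (Q1 - 1) / 2
    if q0 == 0:
        return float(S_obs)
    return S_obs + q0 * (1.0 - (1.0 - Q1 / (Q1 + T * q0)) ** (t - T))


def oracle_richness_at_coverage(y: list[int], T: int, target: float) -> float:
    """Richness at the effort whose estimated coverage hits the target;
    integer-effort formulas with straight-line interpolation in between."""
    c_ref = oracle_coverage(y, T, T)
    if abs(target - c_ref) < 1e-12:
        return float(len(y))
    if target < c_ref:
        cov = [oracle_coverage(y, T, k) for k in range(1, T + 1)]
        ric = [oracle_richness(y, T, k) for k in range(1, T + 1)]
        if cov[0] >= target:
            return ric[0]
        for k in range(T - 1):
            if cov[k] <= target <= cov[k + 1]:
                span = cov[k + 1] - cov[k]
                w = 0.0 if span == 0 else (target - cov[k]) / span
                return ric[k] * (1 - w) + ric[k + 1] * w
        return float(len(y))
    # extrapolation: invert 1 - target = (Q1/U) A^(t-T+1)
    U = sum(y)
    Q1 = sum(1 for yi in y if yi == 1)
    Q2 = sum(1 for yi in y if yi == 2)
    if Q1 == 0:
        return float(len(y))
    A = (T - 1) * Q1 / ((T - 1) * Q1 + 2 * Q2) if ((T - 1) * Q1 + 2 * Q2) else 1.0
    if A >= 1.0:
        return oracle_richness(y, T, float("inf")) if False else float(len(y)) + (
            (T - 1) / T * Q1 * (Q1 - 1) / 2 if Q2 == 0 else (T - 1) / T * Q1 * Q1 / (2 * Q2)
        )
    t = T - 1 + np.log((1.0 - target) * U / Q1) / np.log(A)
    t = max(t, float(T))
    return oracle_richness(y, T, t)


# -- d-separation ------------------------------------------------------------

def oracle_claims_are_d_separations(graph) -> bool:
    """Every basis-set claim must be a d-separation of the DAG (networkx)."""
    import networkx as nx

    from forest_csb.dag import basis_set

    g = graph.to_networkx()
    for claim in basis_set(graph, include_exogenous_pairs=True):
        if not nx.is_d_separator(g, {claim.x}, {claim.y}, set(claim.conditioning)):
            return False
    return True
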