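"""Synthetic forest-plot generator.

Generates plot-level causal data and the raw artefacts derived from them
(tree lists, deadwood piece lists, species-incidence matrices) with the
statistical structure the downstream analysis assumes, so the whole
pipeline is testable without any field data.

The causal layer is a linear Gaussian structural causal model over the
conceptual graph: exogenous drivers (stand age, tree species richness, mean
annual temperature, annual precipitation — the last two correlated) are
standard normal; every endogenous node is the coefficient-weighted sum of
its standardized parents plus crossed random intercepts (site, forest type,
management) plus Gaussian noise.  Residual standard deviations are derived
analytically from the implied covariance so every node has unit marginal
variance — the generating path coefficients therefore ARE the standardized
coefficients a correct fit should recover.  Raw-scale columns (age in
years, dbh in cm, carbon stocks in t/ha, ...) are fixed affine (or
log-linear, for the carbon pools) maps of the z-scores whose ranges span
the observed ranges of the study system (e.g. stand age 5-212 y).

The realization layer turns the per-plot targets into inventories: a tree
list whose species count and mean dbh hit the targets, a deadwood list with
exactly the target number of distinct (diameter class, position, decay
stage) combinations, and per-site incidence matrices whose plot-level
observed richness is monotone in the generating richness driver
(independent Bernoulli detections per species and sampling unit).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .biodiversity import MAX_DEADWOOD_TYPES, IncidenceMatrix
from .dag import CausalGraph, default_generating_coefficients, default_graph
from .harmonize import DeadwoodPiece, PlotMeta, TreeRecord

__all__ = ["GeneratorParams", "SyntheticDataset", "generate_plot_features", "realize_inventories"]

GROUP_FACTORS = ("site", "forest_type", "management")

# Raw-scale maps: node -> (center, scale); carbon pools are log-linear
# (value = exp(center + scale * z)), everything else affine.
RAW_SCALE = {
    "stand_age": (110.0, 50.0),
    "tree_richness": (4.0, 2.5),
    "mean_temp": (8.1, 0.9),
    "annual_precip": (840.0, 140.0),
    "mean_dbh": (35.0, 11.0),
    "dw_type_richness": (11.0, 5.0),
    "c_living": (4.6, 1.1),   # log t/ha: median ~100, range ~0.5-360
    "c_dead": (1.1, 1.5),     # log t/ha: median ~3, heavy spread
    "rich_plants": (0.5, 0.15),
    "rich_fungi": (0.5, 0.15),
    "rich_beetles": (0.5, 0.15),
    "rich_birds": (0.5, 0.15),
}
LOG_NODES = ("c_living", "c_dead")

# Diameter-class bounds (cm) used when realizing deadwood pieces; the upper
# bound of class 4 is only a sampling range, the class itself is open-ended.
CLASS_BOUNDS = [(15.0, 25.0), (25.0, 35.0), (35.0, 50.0), (50.0, 80.0)]
POSITIONS = ("log", "snag", "stump")
CONIFER_FRACTION_BY_TYPE = (0.85, 0.15, 0.5, 0.35, 0.65)

DEFAULT_SPECIES_POOLS = {
    "rich_plants": 120,
    "rich_birds": 60,
    "rich_fungi": 150,
    "rich_beetles": 100,
}


@dataclass
class GeneratorParams:
    """Study-condition parameters of the synthetic forest."""

    n_plots: int = 301
    n_sites: int = 16
    n_forest_types: int = 5
    n_managements: int = 4
    path_coefficients: dict[tuple[str, str], float] = field(
        default_factory=default_generating_coefficients
    )
    random_intercept_sd: dict[str, float] = field(
        default_factory=lambda: {"site": 0.2, "forest_type": 0.2, "management": 0.2}
    )
    residual_sd: dict[str, float] = field(default_factory=dict)  # node -> sd; else derived
    temp_precip_correlation: float = -0.3
    species_pool_sizes: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_SPECIES_POOLS)
    )
    detection_prob: float = 1.0
    plot_area_ha: float = 1.0
    height_missing_prob: float = 0.2
    seed: int = 0
    graph: CausalGraph = field(default_factory=default_graph)

    def __post_init__(self):
        if not (self.n_plots >= self.n_sites >= 1):
            raise ValueError("need n_plots >= n_sites >= 1")
        if self.n_forest_types < 1 or self.n_managements < 1:
            raise ValueError("need at least one forest type and management")
        for k, sd in {**self.random_intercept_sd, **self.residual_sd}.items():
            if sd < 0:
                raise ValueError(f"sd for {k!r} must be >= 0, got {sd}")
        if not -1 < self.temp_precip_correlation < 1:
            raise ValueError("temp_precip_correlation must be in (-1, 1)")
        if not 0 < self.detection_prob <= 1:
            raise ValueError("detection_prob must be in (0, 1]")
        edge_set = set(self.graph.edges)
        for edge in self.path_coefficients:
            if tuple(edge) not in edge_set:
                raise ValueError(
                    f"path coefficient for non-edge {edge}; add it to the graph first"
                )


@dataclass
class SyntheticDataset:
    plot_features: pd.DataFrame
    trees: list[TreeRecord]
    deadwood: list[DeadwoodPiece]
    metas: dict[str, PlotMeta]
    incidence: list[IncidenceMatrix]
    truth: GeneratorParams


def _balanced_allocation(n: int, levels: list[str], rng: np.random.Generator) -> np.ndarray:
    """Assign n items to levels as evenly as possible, in random order."""
    reps = int(np.ceil(n / len(levels)))
    pool = np.array((levels * reps)[:n])
    rng.shuffle(pool)
    return pool


def _raw_from_z(node: str, z: np.ndarray) -> np.ndarray:
    center, scale = RAW_SCALE[node]
    if node in LOG_NODES:
        return np.exp(center + scale * z)
    return center + scale * z


def _z_from_raw(node: str, raw: np.ndarray) -> np.ndarray:
    center, scale = RAW_SCALE[node]
    if node in LOG_NODES:
        return (np.log(raw) - center) / scale
    return (raw - center) / scale


def generate_plot_features(params: GeneratorParams) -> pd.DataFrame:
    """Draw the plot-level causal table.

    Returns one row per plot: grouping factors, every graph node on its raw
    scale, and a ``z_<node>`` column with the underlying standardized value.
    Deterministic under a fixed seed.
    """
    rng = np.random.default_rng(params.seed)
    graph = params.graph
    n = params.n_plots
    coeffs = {tuple(e): c for e, c in params.path_coefficients.items()}

    sites = _balanced_allocation(n, [f"S{i+1:02d}" for i in range(params.n_sites)], rng)
    ftypes = _balanced_allocation(
        n, [f"FT{i+1}" for i in range(params.n_forest_types)], rng
    )
    mgmts = _balanced_allocation(
        n, [f"M{i+1}" for i in range(params.n_managements)], rng
    )
    factor_values = {"site": sites, "forest_type": ftypes, "management": mgmts}

    order = graph.topological_order()
    exog = set(graph.exogenous)
    z: dict[str, np.ndarray] = {}

    # Exogenous draws: unit normal; temperature and precipitation correlated.
    rho = params.temp_precip_correlation
    if "mean_temp" in exog and "annual_precip" in exog:
        cov = np.array([[1.0, rho], [rho, 1.0]])
        tp = rng.multivariate_normal([0.0, 0.0], cov, size=n)
        z["mean_temp"], z["annual_precip"] = tp[:, 0], tp[:, 1]
    for node in order:
        if node in exog and node not in z:
            z[node] = rng.normal(size=n)

    # Implied covariance of the standardized variables, built in topological
    # order; used to derive residual sds that give unit marginal variance.
    sigma = {}
    for node in order:
        if node in exog:
            sigma[(node, node)] = 1.0
    if "mean_temp" in exog and "annual_precip" in exog:
        sigma[("mean_temp", "annual_precip")] = rho
        sigma[("annual_precip", "mean_temp")] = rho
    done = [node for node in order if node in exog]
    for a in done:
        for b in done:
            sigma.setdefault((a, b), 1.0 if a == b else 0.0)

    re_var_total = sum(sd * sd for sd in params.random_intercept_sd.values())

    for node in order:
        if node in exog:
            continue
        parents = graph.parents(node)
        beta = np.array([coeffs.get((p, node), 0.0) for p in parents])
        # fixed-part variance from the running covariance
        var_fixed = 0.0
        for bi, pi in zip(beta, parents):
            for bj, pj in zip(beta, parents):
                var_fixed += bi * bj * sigma[(pi, pj)]
        if node in params.residual_sd:
            resid_sd = params.residual_sd[node]
            var_node = var_fixed + re_var_total + resid_sd**2
        else:
            resid_var = 1.0 - var_fixed - re_var_total
            if resid_var <= 0:
                raise ValueError(
                    f"node {node!r}: fixed-part variance {var_fixed:.3f} plus random "
                    f"intercepts {re_var_total:.3f} exceed 1; cannot standardize"
                )
            resid_sd = float(np.sqrt(resid_var))
            var_node = 1.0

        value = np.zeros(n)
        for b, p in zip(beta, parents):
            value += b * z[p]
        for factor, sd in params.random_intercept_sd.items():
            levels = np.unique(factor_values[factor])
            u = rng.normal(0.0, sd, size=len(levels))
            idx = {lv: i for i, lv in enumerate(levels)}
            value += u[[idx[v] for v in factor_values[factor]]]
        value += rng.normal(0.0, resid_sd, size=n)
        z[node] = value

        # extend covariance
        for other in done:
            cov_no = float(sum(b * sigma[(p, other)] for b, p in zip(beta, parents)))
            sigma[(node, other)] = cov_no
            sigma[(other, node)] = cov_no
        sigma[(node, node)] = var_node
        done.append(node)

    data = {
        "plot_id": [f"P{i+1:04d}" for i in range(n)],
        "site": sites,
        "forest_type": ftypes,
        "management": mgmts,
    }
    for node in graph.nodes:
        data[node] = _raw_from_z(node, z[node])
    for node in graph.nodes:
        data[f"z_{node}"] = z[node]
    return pd.DataFrame(data)


# ---------------------------------------------------------------------------
# Realization
# ---------------------------------------------------------------------------

def _realize_trees(
    plot_id: str,
    k_species: int,
    mean_dbh: float,
    n_stems: int,
    height_missing_prob: float,
    rng: np.random.Generator,
) -> list[TreeRecord]:
    n_stems = max(n_stems, k_species, 5)
    e = rng.lognormal(0.0, 0.35, size=n_stems)
    dbh = 11.0 + (mean_dbh - 11.0) * e / e.mean()
    species = [f"sp{j+1:02d}" for j in range(k_species)]
    labels = species + [species[rng.integers(k_species)] for _ in range(n_stems - k_species)]
    height = 1.3 + 30.0 * (1.0 - np.exp(-0.04 * dbh)) + rng.normal(0.0, 1.5, n_stems)
    height = np.maximum(height, 1.4)
    missing = rng.random(n_stems) < height_missing_prob
    return [
        TreeRecord(
            plot_id=plot_id,
            species=labels[i],
            dbh=float(dbh[i]),
            height=None if missing[i] else float(height[i]),
            alive=True,
        )
        for i in range(n_stems)
    ]


def _piece_for_combo(
    plot_id: str,
    combo: tuple[int, str, int],
    conifer_p: float,
    size_factor: float,
    rng: np.random.Generator,
) -> DeadwoodPiece:
    dclass, position, stage = combo
    lo, hi = CLASS_BOUNDS[dclass - 1]
    d1 = float(rng.uniform(lo + 0.25, hi - 0.25))
    group = "coniferous" if rng.random() < conifer_p else "broadleaved"
    if position == "log":
        d2 = float(d1 * rng.uniform(0.5, 0.9))
        length = float(rng.uniform(3.0, 15.0) * size_factor)
    elif position == "snag":
        d2 = None
        length = float(rng.uniform(6.0, 20.0) * size_factor)
    else:  # stump
        d2 = float(d1 * rng.uniform(0.85, 1.0))
        length = float(rng.uniform(0.3, 1.0) * size_factor)
    return DeadwoodPiece(
        plot_id=plot_id,
        position=position,
        d1=d1,
        d2=d2,
        length=max(length, 0.1),
        decay_stage=stage,
        wood_group=group,
    )


ALL_COMBOS = [
    (c, p, s)
    for c in range(1, 5)
    for p in POSITIONS
    for s in range(1, 6)
]


def _realize_deadwood(
    plot_id: str,
    target_richness: int,
    conifer_p: float,
    size_factor: float,
    rng: np.random.Generator,
) -> list[DeadwoodPiece]:
    if not 0 <= target_richness <= MAX_DEADWOOD_TYPES:
        raise ValueError(
            f"deadwood type richness target {target_richness} outside 0..{MAX_DEADWOOD_TYPES}"
        )
    if target_richness == 0:
        return []
    idx = rng.choice(len(ALL_COMBOS), size=target_richness, replace=False)
    combos = [ALL_COMBOS[i] for i in idx]
    pieces = [
        _piece_for_combo(plot_id, combo, conifer_p, size_factor, rng)
        for combo in combos
    ]
    n_extra = int(rng.poisson(1.2 * target_richness))
    for _ in range(n_extra):
        combo = combos[rng.integers(len(combos))]
        pieces.append(_piece_for_combo(plot_id, combo, conifer_p, size_factor, rng))
    return pieces


def _realize_incidence(
    features: pd.DataFrame, params: GeneratorParams, rng: np.random.Generator
) -> list[IncidenceMatrix]:
    out = []
    for taxon, pool in sorted(params.species_pool_sizes.items()):
        z_col = f"z_{taxon}"
        for site, grp in features.groupby("site", sort=True):
            species = [f"{taxon[5:]}_{j+1:03d}" for j in range(pool)]
            alpha = rng.normal(-1.2, 1.0, size=pool)
            units = list(grp["plot_id"])
            zvals = grp[z_col].to_numpy()
            logits = alpha[:, None] + 1.1 * zvals[None, :]
            prob = params.detection_prob / (1.0 + np.exp(-logits))
            mat = (rng.random((pool, len(units))) < prob).astype(int)
            df = pd.DataFrame(mat, index=species, columns=units)
            out.append(
                IncidenceMatrix(
                    taxon_group=taxon,
                    site=str(site),
                    matrix=df,
                    unit_plots={u: u for u in units},
                )
            )
    return out


def realize_inventories(
    features: pd.DataFrame, params: GeneratorParams
) -> SyntheticDataset:
    """Materialize tree lists, deadwood lists, plot metadata and incidence
    matrices from a generated feature table.

    Integer targets (tree species count, deadwood type richness) are the
    rounded raw columns, clipped to their feasible/observed ranges; the
    clipped and rounded targets are stored as ``tree_richness_target`` and
    ``dw_richness_target`` columns.  Recomputing the structural summaries on
    the realized inventories recovers the richness targets exactly and the
    mean-dbh target up to the living-tree filter.
    """
    rng = np.random.default_rng(params.seed + 1)
    feats = features.copy()

    k_species = (
        feats["tree_richness"].round().clip(1, 14).astype(int).to_numpy()
    )
    dw_target_raw = feats["dw_type_richness"].round().astype(int)
    if (dw_target_raw > MAX_DEADWOOD_TYPES).any():
        raise ValueError(
            f"deadwood type richness target exceeds {MAX_DEADWOOD_TYPES}"
        )
    dw_target = dw_target_raw.clip(1, MAX_DEADWOOD_TYPES).to_numpy()
    mean_dbh_target = feats["mean_dbh"].clip(12.0, 102.0).to_numpy()
    feats["tree_richness_target"] = k_species
    feats["dw_richness_target"] = dw_target
    feats["mean_dbh_target"] = mean_dbh_target

    z_cliv = _z_from_raw("c_living", feats["c_living"].to_numpy())
    z_cdead = _z_from_raw("c_dead", feats["c_dead"].to_numpy())
    # stem density and piece size track the carbon drivers so the realized
    # carbon stocks correlate with (and roughly span the magnitude of) the
    # generated ones
    n_stems = np.clip(np.round(300.0 * np.exp(0.8 * z_cliv)), 30, 900).astype(int)
    dw_size_factor = np.clip(np.exp(0.8 * z_cdead), 0.15, 8.0)

    ftype_levels = sorted(feats["forest_type"].unique())
    conifer_p = {
        ft: CONIFER_FRACTION_BY_TYPE[i % len(CONIFER_FRACTION_BY_TYPE)]
        for i, ft in enumerate(ftype_levels)
    }

    trees: list[TreeRecord] = []
    deadwood: list[DeadwoodPiece] = []
    metas: dict[str, PlotMeta] = {}
    for i, row in enumerate(feats.itertuples()):
        pid = row.plot_id
        metas[pid] = PlotMeta(
            plot_id=pid,
            site=row.site,
            forest_type=row.forest_type,
            management=row.management,
            stand_age=float(np.clip(row.stand_age, 5.0, 212.0)),
            plot_area=params.plot_area_ha,
            mean_temp=float(row.mean_temp),
            annual_precip=float(row.annual_precip),
        )
        trees.extend(
            _realize_trees(
                pid,
                int(k_species[i]),
                float(mean_dbh_target[i]),
                int(n_stems[i]),
                params.height_missing_prob,
                rng,
            )
        )
        deadwood.extend(
            _realize_deadwood(
                pid,
                int(dw_target[i]),
                conifer_p[row.forest_type],
                float(dw_size_factor[i]),
                rng,
            )
        )

    incidence = _realize_incidence(feats, params, rng)
    return SyntheticDataset(
        plot_features=feats,
        trees=trees,
        deadwood=deadwood,
        metas=metas,
        incidence=incidence,
        truth=params,
    )
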