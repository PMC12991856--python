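"""Harmonization of raw forest inventories.

Field protocols differ between sites, so plot-level inventories are brought
onto a common contract before any accounting: living trees below 11 cm dbh
are dropped, lying deadwood below a 15 cm diameter threshold (applied to the
larger end diameter — the conservative inclusion rule) is dropped, decay
stages from protocol-specific codes are mapped onto the common 1-5 ordinal
scale (1 undecayed ... 5 almost decomposed), quantities are extrapolated to
one hectare, and missing tree heights are imputed by predictive mean
matching on an allometric height model.

Units: dbh and diameters in cm, heights and lengths in m, areas in ha.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "TreeRecord",
    "DeadwoodPiece",
    "PlotMeta",
    "filter_living_trees",
    "filter_lying_deadwood",
    "per_hectare",
    "harmonize_decay_stage",
    "impute_heights",
    "read_trees",
    "read_deadwood",
    "read_plots",
    "write_trees",
    "write_deadwood",
    "write_plots",
]

POSITIONS = ("log", "snag", "stump")
WOOD_GROUPS = ("coniferous", "broadleaved")


@dataclass(frozen=True)
class TreeRecord:
    """One standing stem (living or dead) from the tree inventory."""

    plot_id: str
    species: str
    dbh: float  # cm
    height: float | None = None  # m; > 1.3 when present
    alive: bool = True

    def __post_init__(self):
        if not np.isfinite(self.dbh) or self.dbh <= 0:
            raise ValueError(f"dbh must be finite and positive, got {self.dbh}")
        if self.height is not None and self.height <= 1.3:
            raise ValueError(
                f"height must exceed breast height (1.3 m), got {self.height}"
            )


@dataclass(frozen=True)
class DeadwoodPiece:
    """One deadwood element: lying log, standing snag, or stump."""

    plot_id: str
    position: str  # log | snag | stump
    d1: float  # cm
    d2: float | None  # cm; second diameter, may be missing
    length: float  # m (height for snags/stumps)
    decay_stage: int  # 1..5
    wood_group: str  # coniferous | broadleaved
    species: str | None = None

    def __post_init__(self):
        if self.position not in POSITIONS:
            raise ValueError(f"position must be one of {POSITIONS}, got {self.position!r}")
        if self.d1 <= 0:
            raise ValueError(f"d1 must be positive, got {self.d1}")
        if self.d2 is not None and self.d2 < 0:
            raise ValueError(f"d2 must be non-negative, got {self.d2}")
        if self.length < 0:
            raise ValueError(f"length must be non-negative, got {self.length}")
        if self.decay_stage not in (1, 2, 3, 4, 5):
            raise ValueError(f"decay_stage must be in 1..5, got {self.decay_stage}")
        if self.wood_group not in WOOD_GROUPS:
            raise ValueError(
                f"wood_group must be one of {WOOD_GROUPS}, got {self.wood_group!r}"
            )

    @property
    def larger_diameter(self) -> float:
        return self.d1 if self.d2 is None else max(self.d1, self.d2)


@dataclass(frozen=True)
class PlotMeta:
    """Plot metadata: grouping factors, stand age, area, climate."""

    plot_id: str
    site: str
    forest_type: str
    management: str
    stand_age: float  # years since planting or last regeneration cut
    plot_area: float  # ha
    mean_temp: float  # deg C
    annual_precip: float  # mm

    def __post_init__(self):
        if self.plot_area <= 0:
            raise ValueError(f"plot_area must be positive, got {self.plot_area}")
        if self.stand_age < 0:
            raise ValueError(f"stand_age must be >= 0, got {self.stand_age}")


# ---------------------------------------------------------------------------
# Threshold filters and scaling
# ---------------------------------------------------------------------------

def filter_living_trees(
    trees: Sequence[TreeRecord], min_dbh: float = 11.0
) -> list[TreeRecord]:
    """Keep trees with dbh >= ``min_dbh`` (cm); order preserved."""
    return [t for t in trees if t.dbh >= min_dbh]


def filter_lying_deadwood(
    pieces: Sequence[DeadwoodPiece], min_diameter: float = 15.0
) -> list[DeadwoodPiece]:
    """Apply the lying-deadwood diameter threshold.

    Lying pieces (logs and stumps) are kept when their larger end diameter
    is >= ``min_diameter``; standing pieces (snags) pass through unchanged.
    """
    return [
        p
        for p in pieces
        if p.position == "snag" or p.larger_diameter >= min_diameter
    ]


def per_hectare(value: float, area: float) -> float:
    """Scale a per-plot quantity to one hectare."""
    if area <= 0:
        raise ValueError(f"plot area must be positive, got {area}")
    return value / area


def harmonize_decay_stage(raw_label, protocol_map: Mapping, protocol: str = "?") -> int:
    """Map a protocol-specific decay code onto the common 1-5 scale."""
    if raw_label not in protocol_map:
        raise KeyError(
            f"decay label {raw_label!r} not mapped by protocol {protocol!r}"
        )
    stage = int(protocol_map[raw_label])
    if stage not in (1, 2, 3, 4, 5):
        raise ValueError(
            f"protocol {protocol!r} maps {raw_label!r} to {stage}, outside 1..5"
        )
    return stage


# ---------------------------------------------------------------------------
# Height imputation: allometric model + predictive mean matching
# ---------------------------------------------------------------------------

def _allometric(d, a, b, c):
    # Monotone saturating height-diameter curve; h -> 1.3 as d -> 0.
    return 1.3 + a * (1.0 - np.exp(-b * d)) ** c

_P0 = (25.0, 0.05, 1.0)
_BOUNDS = ([1.0, 1e-4, 0.2], [80.0, 1.0, 5.0])


def _fit_allometry(dbh: np.ndarray, height: np.ndarray):
    """Fit h = 1.3 + a(1 - exp(-b d))^c; fall back to c = 1, then to a
    saturating curve through the mean point."""
    try:
        popt, _ = curve_fit(
            _allometric, dbh, height, p0=_P0, bounds=_BOUNDS, maxfev=5000
        )
        return lambda d: _allometric(np.asarray(d, float), *popt)
    except Exception:
        pass
    try:
        popt, _ = curve_fit(
            lambda d, a, b: _allometric(d, a, b, 1.0),
            dbh,
            height,
            p0=_P0[:2],
            bounds=([1.0, 1e-4], [80.0, 1.0]),
            maxfev=5000,
        )
        return lambda d: _allometric(np.asarray(d, float), *popt, 1.0)
    except Exception:
        a = max(float(np.mean(height)) - 1.3, 1.0) / max(
            1.0 - np.exp(-0.05 * float(np.mean(dbh))), 1e-6
        )
        return lambda d: _allometric(np.asarray(d, float), a, 0.05, 1.0)


def impute_heights(
    trees: Sequence[TreeRecord],
    meta: Mapping[str, PlotMeta] | None = None,
    min_donors: int = 5,
    n_donors: int = 5,
    seed: int | None = None,
) -> list[TreeRecord]:
    """Fill missing heights by predictive mean matching.

    Donor strata are tried from fine to coarse — plot, then site, then
    forest type (when ``meta`` provides them), then the full pool — the
    first stratum with at least ``min_donors`` height-observed trees wins.
    Within the stratum a monotone allometric height model is fitted on the
    observed pairs; each missing height receives the *observed* height of
    one of the ``n_donors`` donors whose predicted heights are nearest the
    target's prediction (drawn uniformly, seeded; ``n_donors=1`` is the
    deterministic nearest-donor rule).  Observed heights are never altered,
    and every imputed value lies inside the observed donor range.
    """
    trees = list(trees)
    observed = [t for t in trees if t.height is not None]
    if not observed:
        if not trees:
            return []
        raise ValueError("no observed heights anywhere; cannot impute")
    rng = np.random.default_rng(seed)

    def stratum_key(t: TreeRecord, level: str):
        if level == "plot":
            return t.plot_id
        if meta is None or t.plot_id not in meta:
            return None
        m = meta[t.plot_id]
        return m.site if level == "site" else m.forest_type

    levels = ["plot", "site", "forest_type", "pool"]
    # Pre-index observed trees per stratum value at each level.
    donors_at: dict[tuple[str, object], list[TreeRecord]] = {}
    for t in observed:
        for level in levels[:-1]:
            key = stratum_key(t, level)
            if key is not None:
                donors_at.setdefault((level, key), []).append(t)

    model_cache: dict = {}

    def donors_for(t: TreeRecord) -> tuple[str, object, list[TreeRecord]]:
        for level in levels[:-1]:
            key = stratum_key(t, level)
            pool = donors_at.get((level, key), [])
            if len(pool) >= min_donors:
                return level, key, pool
        return "pool", None, observed

    out: list[TreeRecord] = []
    for t in trees:
        if t.height is not None:
            out.append(t)
            continue
        level, key, pool = donors_for(t)
        ck = (level, key)
        if ck not in model_cache:
            d = np.array([p.dbh for p in pool])
            h = np.array([p.height for p in pool])
            model_cache[ck] = (_fit_allometry(d, h), d, h)
        predict, d, h = model_cache[ck]
        pred_pool = predict(d)
        target = float(predict(t.dbh))
        order = np.argsort(np.abs(pred_pool - target), kind="stable")
        k = min(n_donors, len(pool))
        pick = order[int(rng.integers(k))] if k > 1 else order[0]
        out.append(replace(t, height=float(h[pick])))
    return out


# ---------------------------------------------------------------------------
# Delimited-table IO (CSV, header row, empty field = missing)
# ---------------------------------------------------------------------------

TREE_COLUMNS = ["plot_id", "species", "dbh_cm", "height_m", "alive"]
DEADWOOD_COLUMNS = [
    "plot_id", "position", "d1_cm", "d2_cm", "length_m",
    "decay_stage", "wood_group", "species",
]
PLOT_COLUMNS = [
    "plot_id", "site", "forest_type", "management", "stand_age_y",
    "area_ha", "mean_temp_c", "annual_precip_mm",
]


def read_trees(path) -> list[TreeRecord]:
    df = pd.read_csv(path, dtype={"plot_id": str, "species": str},
                     float_precision="round_trip")
    return [
        TreeRecord(
            plot_id=row.plot_id,
            species=row.species,
            dbh=float(row.dbh_cm),
            height=None if pd.isna(row.height_m) else float(row.height_m),
            alive=bool(row.alive),
        )
        for row in df.itertuples()
    ]


def write_trees(trees: Iterable[TreeRecord], path) -> None:
    pd.DataFrame(
        [(t.plot_id, t.species, t.dbh, t.height, t.alive) for t in trees],
        columns=TREE_COLUMNS,
    ).to_csv(path, index=False, float_format="%.17g")


def read_deadwood(path) -> list[DeadwoodPiece]:
    df = pd.read_csv(path, dtype={"plot_id": str, "species": str},
                     float_precision="round_trip")
    return [
        DeadwoodPiece(
            plot_id=row.plot_id,
            position=row.position,
            d1=float(row.d1_cm),
            d2=None if pd.isna(row.d2_cm) else float(row.d2_cm),
            length=float(row.length_m),
            decay_stage=int(row.decay_stage),
            wood_group=row.wood_group,
            species=None if pd.isna(row.species) else row.species,
        )
        for row in df.itertuples()
    ]


def write_deadwood(pieces: Iterable[DeadwoodPiece], path) -> None:
    pd.DataFrame(
        [
            (p.plot_id, p.position, p.d1, p.d2, p.length, p.decay_stage,
             p.wood_group, p.species)
            for p in pieces
        ],
        columns=DEADWOOD_COLUMNS,
    ).to_csv(path, index=False, float_format="%.17g")


def read_plots(path) -> dict[str, PlotMeta]:
    df = pd.read_csv(
        path, dtype={"plot_id": str, "site": str, "forest_type": str, "management": str}
    )
    metas = [
        PlotMeta(
            plot_id=row.plot_id,
            site=row.site,
            forest_type=row.forest_type,
            management=row.management,
            stand_age=float(row.stand_age_y),
            plot_area=float(row.area_ha),
            mean_temp=float(row.mean_temp_c),
            annual_precip=float(row.annual_precip_mm),
        )
        for row in df.itertuples()
    ]
    return {m.plot_id: m for m in metas}


def write_plots(metas: Iterable[PlotMeta], path) -> None:
    pd.DataFrame(
        [
            (m.plot_id, m.site, m.forest_type, m.management, m.stand_age,
             m.plot_area, m.mean_temp, m.annual_precip)
            for m in metas
        ],
        columns=PLOT_COLUMNS,
    ).to_csv(path, index=False, float_format="%.17g")
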