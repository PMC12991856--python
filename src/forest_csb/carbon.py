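"""Plot-level aboveground carbon stocks in living wood and deadwood.

Stem volumes: living trees use a cylindrical stem with a form factor
(default 0.5; the volume model is a configuration knob), lying deadwood the
truncated-cone formula, standing deadwood the cone formula times 0.3.
Volumes are multiplied by basic wood density (species-specific where known,
otherwise a wood-group default), deadwood additionally by a decay correction
that depends on decay stage, deadwood position and wood group.  Biomass
converts to carbon with a fraction of 0.48 for living and 0.485 for dead
wood, and totals are extrapolated to one hectare.

The decay-correction defaults shipped here follow the pattern of published
density-reduction tables for temperate species (multipliers non-increasing
with decay stage, smaller for broadleaves in late decay); they are plain
data and fully overridable from CSV.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .harmonize import DeadwoodPiece, PlotMeta, TreeRecord, per_hectare

__all__ = [
    "DensityTable",
    "CarbonStocks",
    "truncated_cone_volume",
    "standing_dead_volume",
    "living_tree_volume",
    "deadwood_density",
    "plot_carbon_stocks",
    "LIVING_CARBON_FRACTION",
    "DEADWOOD_CARBON_FRACTION",
]

logger = logging.getLogger(__name__)

LIVING_CARBON_FRACTION = 0.48
DEADWOOD_CARBON_FRACTION = 0.485
SNAG_VOLUME_FACTOR = 0.3

# Default basic densities (t/m3, oven-dry mass per green volume).
DEFAULT_GROUP_DENSITY = {"coniferous": 0.43, "broadleaved": 0.58}

# Default decay-correction multipliers by (decay_stage, position, wood_group):
# remaining density fraction, non-increasing in decay stage.
_LYING = {
    "coniferous": (1.00, 0.92, 0.77, 0.55, 0.38),
    "broadleaved": (1.00, 0.88, 0.70, 0.48, 0.30),
}
_STANDING = {
    "coniferous": (1.00, 0.95, 0.85, 0.70, 0.55),
    "broadleaved": (1.00, 0.93, 0.80, 0.62, 0.45),
}
DEFAULT_DECAY_CORRECTIONS: dict[tuple[int, str, str], float] = {}
for _stage in range(1, 6):
    for _group in ("coniferous", "broadleaved"):
        DEFAULT_DECAY_CORRECTIONS[(_stage, "log", _group)] = _LYING[_group][_stage - 1]
        DEFAULT_DECAY_CORRECTIONS[(_stage, "stump", _group)] = _LYING[_group][_stage - 1]
        DEFAULT_DECAY_CORRECTIONS[(_stage, "snag", _group)] = _STANDING[_group][_stage - 1]


@dataclass
class DensityTable:
    """Basic wood densities and decay-correction multipliers."""

    species_density: dict[str, float] = field(default_factory=dict)
    group_density: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_GROUP_DENSITY)
    )
    decay_correction: dict[tuple[int, str, str], float] = field(
        default_factory=lambda: dict(DEFAULT_DECAY_CORRECTIONS)
    )
    source: str = "package defaults (synthetic-analysis table, overridable)"

    def __post_init__(self):
        for sp, d in {**self.species_density, **self.group_density}.items():
            if d <= 0:
                raise ValueError(f"density for {sp!r} must be positive, got {d}")
        for key, m in self.decay_correction.items():
            if not 0 < m <= 1:
                raise ValueError(f"decay multiplier {key} = {m} outside (0, 1]")

    def base_density(self, species: str | None, wood_group: str) -> float:
        if species is not None and species in self.species_density:
            return self.species_density[species]
        if species is not None and species not in self.species_density:
            logger.debug("species %r not in density table; using %s default",
                         species, wood_group)
        if wood_group not in self.group_density:
            raise KeyError(f"no default density for wood group {wood_group!r}")
        return self.group_density[wood_group]

    def correction(self, decay_stage: int, position: str, wood_group: str) -> float:
        key = (decay_stage, position, wood_group)
        if key not in self.decay_correction:
            raise KeyError(f"no decay correction for {key}")
        return self.decay_correction[key]

    # -- CSV round trip ----------------------------------------------------
    @classmethod
    def from_csv(cls, density_path=None, corrections_path=None) -> "DensityTable":
        table = cls()
        if density_path is not None:
            df = pd.read_csv(density_path)
            table.species_density = dict(
                zip(df["species"].astype(str), df["density_t_m3"].astype(float))
            )
        if corrections_path is not None:
            df = pd.read_csv(corrections_path)
            table.decay_correction = {
                (int(r.decay_stage), str(r.position), str(r.wood_group)): float(r.multiplier)
                for r in df.itertuples()
            }
        return cls(
            species_density=table.species_density,
            group_density=table.group_density,
            decay_correction=table.decay_correction,
        )

    def corrections_to_csv(self, path) -> None:
        pd.DataFrame(
            [(s, p, g, m) for (s, p, g), m in sorted(self.decay_correction.items())],
            columns=["decay_stage", "position", "wood_group", "multiplier"],
        ).to_csv(path, index=False)


@dataclass(frozen=True)
class CarbonStocks:
    plot_id: str
    c_living: float  # t/ha
    c_dead: float  # t/ha


# ---------------------------------------------------------------------------
# Volume formulas (diameters in cm, lengths in m, volume in m3)
# ---------------------------------------------------------------------------

def truncated_cone_volume(d1: float, d2: float, length: float) -> float:
    """Truncated-cone volume: V = pi L / 12 * (D1^2 + D1 D2 + D2^2)."""
    if d1 < 0 or d2 < 0 or length < 0:
        raise ValueError("diameters and length must be non-negative")
    D1, D2 = d1 / 100.0, d2 / 100.0
    return math.pi * length / 12.0 * (D1 * D1 + D1 * D2 + D2 * D2)


def standing_dead_volume(
    dbh: float, height: float, factor: float = SNAG_VOLUME_FACTOR
) -> float:
    """Standing deadwood volume: cone formula times a reduction factor (0.3)."""
    if dbh < 0 or height < 0:
        raise ValueError("dbh and height must be non-negative")
    D = dbh / 100.0
    return factor * math.pi / 12.0 * D * D * height


def living_tree_volume(dbh: float, height: float, form_factor: float = 0.5) -> float:
    """Living stem volume: cylinder times a form factor (default 0.5)."""
    if dbh < 0 or height < 0:
        raise ValueError("dbh and height must be non-negative")
    if not 0 < form_factor <= 1:
        raise ValueError(f"form_factor must be in (0, 1], got {form_factor}")
    D = dbh / 100.0
    return form_factor * math.pi / 4.0 * D * D * height


def deadwood_density(piece: DeadwoodPiece, table: DensityTable) -> float:
    """Decay-corrected density (t/m3) of one deadwood piece."""
    base = table.base_density(piece.species, piece.wood_group)
    return base * table.correction(piece.decay_stage, piece.position, piece.wood_group)


def _piece_volume(piece: DeadwoodPiece) -> float:
    if piece.position == "snag":
        return standing_dead_volume(piece.d1, piece.length)
    d2 = piece.d1 if piece.d2 is None else piece.d2
    return truncated_cone_volume(piece.d1, d2, piece.length)


def plot_carbon_stocks(
    trees: Sequence[TreeRecord],
    deadwood: Sequence[DeadwoodPiece],
    meta: PlotMeta,
    density: DensityTable | None = None,
    form_factor: float = 0.5,
    dead_tree_wood_groups: Mapping[str, str] | None = None,
    living_fraction: float = LIVING_CARBON_FRACTION,
    dead_fraction: float = DEADWOOD_CARBON_FRACTION,
) -> CarbonStocks:
    """Carbon stocks (t/ha) of one plot from harmonized inventories.

    Living trees: form-factor volume x species density x 0.48.  Standing
    dead trees from the tree inventory contribute to the deadwood pool via
    the standing-deadwood (0.3 x cone) rule, treated as undecayed snags;
    deadwood pieces use their measured geometry and decay-corrected density,
    times 0.485.  ``dead_tree_wood_groups`` maps species of dead trees onto
    a wood group (default broadleaved).
    """
    density = density or DensityTable()
    c_living_t = 0.0
    c_dead_t = 0.0
    for t in trees:
        if t.height is None:
            raise ValueError(
                f"tree on plot {t.plot_id} has no height after imputation"
            )
        if t.alive:
            vol = living_tree_volume(t.dbh, t.height, form_factor)
            base = density.base_density(t.species, "broadleaved")
            c_living_t += living_fraction * vol * base
        else:
            group = (dead_tree_wood_groups or {}).get(t.species, "broadleaved")
            vol = standing_dead_volume(t.dbh, t.height)
            dens = density.base_density(t.species, group) * density.correction(
                1, "snag", group
            )
            c_dead_t += dead_fraction * vol * dens
    for p in deadwood:
        c_dead_t += dead_fraction * _piece_volume(p) * deadwood_density(p, density)
    return CarbonStocks(
        plot_id=meta.plot_id,
        c_living=per_hectare(c_living_t, meta.plot_area),
        c_dead=per_hectare(c_dead_t, meta.plot_area),
    )


def carbon_table(stocks: Iterable[CarbonStocks]) -> pd.DataFrame:
    return pd.DataFrame(
        [(s.plot_id, s.c_living, s.c_dead) for s in stocks],
        columns=["plot_id", "c_living_t_ha", "c_dead_t_ha"],
    )
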