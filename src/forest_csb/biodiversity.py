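"""Structural and biodiversity statistics.

Structure: plot-level tree species richness, mean dbh, and deadwood type
richness — the number of unique (diameter class, deadwood position, decay
stage) combinations, each combination treated like a "species" (4 diameter
classes x 3 positions x 5 decay stages = 60 possible types).

Biodiversity: species richness from sample-based incidence data,
standardized for unequal sampling effort by coverage-based rarefaction/
extrapolation.  Sampling units are binary detection columns; the estimated
sample coverage is the Good-Turing-corrected fraction of total incidence
probability represented by the detected species.  Expected richness per
site is the richness of the (possibly fractional) number of sampling units
at which estimated coverage equals a target (default 95%); the standardized
richness of a plot is observed plot richness divided by that site-level
expectation.

The rarefaction/extrapolation formulas follow the standard sample-based
incidence framework (Chao-type):

* reference coverage (T units, incidence frequencies Y_i, U = sum Y_i,
  Q1/Q2 = uniques/duplicates):
      C_hat(T) = 1 - (Q1/U) * [(T-1)Q1 / ((T-1)Q1 + 2 Q2)]
* interpolated richness and coverage at t <= T use the hypergeometric
  absence probability  r_i(t) = C(T-Y_i, t) / C(T, t):
      S(t) = sum_i (1 - r_i(t)),   C_hat(t) = 1 - sum_i (Y_i/U) r_i(t)
* extrapolation beyond T uses the Chao2-type estimate of undetected
  richness  Q0 = ((T-1)/T) Q1^2 / (2 Q2)   (Q1(Q1-1)/2 if Q2 = 0):
      S(T+t*) = S_obs + Q0 [1 - (1 - Q1/(Q1 + T Q0))^t*]
      C_hat(T+t*) = 1 - (Q1/U) A^(t*+1),  A = (T-1)Q1 / ((T-1)Q1 + 2 Q2)

Within the sample, S and C_hat are evaluated at integer unit counts and
interpolated linearly between adjacent integers; the effort solving
C_hat(t) = target is the first (fractional) unit count whose interpolated
coverage reaches the target.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .harmonize import DeadwoodPiece, TreeRecord

__all__ = [
    "IncidenceMatrix",
    "StandardizedRichness",
    "diameter_class",
    "deadwood_type_richness",
    "structural_summaries",
    "sample_coverage",
    "expected_richness_at_coverage",
    "standardize_richness",
    "incidence_from_long",
    "incidence_to_long",
]

logger = logging.getLogger(__name__)

N_DIAMETER_CLASSES = 4
N_POSITIONS = 3
N_DECAY_STAGES = 5
MAX_DEADWOOD_TYPES = N_DIAMETER_CLASSES * N_POSITIONS * N_DECAY_STAGES  # 60


# ---------------------------------------------------------------------------
# Structure
# ---------------------------------------------------------------------------

def diameter_class(d: float) -> int:
    """Deadwood diameter class: [15,25) -> 1, [25,35) -> 2, [35,50) -> 3,
    [50,inf) -> 4.  Lower-inclusive; below 15 cm is outside the harmonized
    domain and raises."""
    if d < 15:
        raise ValueError(f"diameter {d} cm below the 15 cm harmonization threshold")
    if d < 25:
        return 1
    if d < 35:
        return 2
    if d < 50:
        return 3
    return 4


def deadwood_type_richness(pieces: Sequence[DeadwoodPiece]) -> int:
    """Number of unique (diameter class, position, decay stage) combinations."""
    types = {
        (diameter_class(p.larger_diameter), p.position, p.decay_stage)
        for p in pieces
    }
    return len(types)


def structural_summaries(trees: Sequence[TreeRecord]) -> tuple[int, float]:
    """(tree species richness, mean dbh in cm) over filtered living trees."""
    if not trees:
        raise ValueError("cannot compute mean dbh of an empty tree list")
    richness = len({t.species for t in trees})
    mean_dbh = float(np.mean([t.dbh for t in trees]))
    return richness, mean_dbh


# ---------------------------------------------------------------------------
# Incidence matrices
# ---------------------------------------------------------------------------

@dataclass
class IncidenceMatrix:
    """Species x sampling-unit binary detections for one taxon at one site."""

    taxon_group: str
    site: str
    matrix: pd.DataFrame  # rows: species, columns: sampling units, 0/1
    unit_plots: dict[str, str] = field(default_factory=dict)  # unit -> plot_id

    def __post_init__(self):
        vals = self.matrix.to_numpy()
        if vals.size == 0 or self.matrix.shape[1] < 1:
            raise ValueError("incidence matrix needs at least one sampling unit")
        if not np.isin(vals, (0, 1)).all():
            raise ValueError("incidence entries must be 0/1")
        self.matrix = self.matrix.astype(int)

    @property
    def n_units(self) -> int:
        return self.matrix.shape[1]

    def frequencies(self) -> np.ndarray:
        """Incidence frequencies Y_i (detections per species), detected only."""
        y = self.matrix.to_numpy().sum(axis=1)
        return y[y > 0]

    def observed_richness(self) -> int:
        return int((self.matrix.to_numpy().sum(axis=1) > 0).sum())

    def observed_richness_by_plot(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for plot in sorted(set(self.unit_plots.values())):
            units = [u for u, p in self.unit_plots.items() if p == plot]
            sub = self.matrix[units].to_numpy()
            out[plot] = int((sub.sum(axis=1) > 0).sum())
        return out


@dataclass(frozen=True)
class StandardizedRichness:
    plot_id: str
    taxon_group: str
    observed: int
    expected_site: float
    ratio: float


# ---------------------------------------------------------------------------
# Coverage-based standardization
# ---------------------------------------------------------------------------

def _q_counts(y: np.ndarray) -> tuple[float, float, float]:
    U = float(y.sum())
    Q1 = float((y == 1).sum())
    Q2 = float((y == 2).sum())
    return U, Q1, Q2


def _reference_coverage(T: int, y: np.ndarray) -> float:
    U, Q1, Q2 = _q_counts(y)
    if U == 0:
        raise ValueError("no detections; coverage undefined")
    if Q1 == 0:
        return 1.0
    denom = (T - 1) * Q1 + 2 * Q2
    bracket = (T - 1) * Q1 / denom if denom > 0 else 1.0
    return 1.0 - (Q1 / U) * bracket


def sample_coverage(incidence: IncidenceMatrix) -> float:
    """Estimated sample coverage of the reference sample."""
    return _reference_coverage(incidence.n_units, incidence.frequencies())


def _absence_ratio(T: int, y: float, t: float) -> float:
    """r = C(T-y, t) / C(T, t), the probability that a species detected in
    y of T units is absent from a subsample of t units; extended to real t
    via log-gamma, 0 when t > T - y."""
    if t > T - y:
        return 0.0
    return float(
        np.exp(
            gammaln(T - y + 1) - gammaln(T - y - t + 1)
            - gammaln(T + 1) + gammaln(T - t + 1)
        )
    )


def _interpolated_richness(T: int, y: np.ndarray, t: int) -> float:
    """Rarefied richness at an integer number of units t <= T."""
    return float(sum(1.0 - _absence_ratio(T, yi, t) for yi in y))


def _interpolated_coverage(T: int, y: np.ndarray, t: int) -> float:
    """Estimated coverage of a subsample of t < T units (t = T uses the
    Good-Turing reference-sample estimator instead)."""
    if t >= T:
        return _reference_coverage(T, y)
    U = float(y.sum())
    return 1.0 - float(sum((yi / U) * _absence_ratio(T, yi, t) for yi in y))


def _undetected_richness(T: int, Q1: float, Q2: float) -> float:
    if Q1 == 0:
        return 0.0
    if Q2 > 0:
        return (T - 1) / T * Q1 * Q1 / (2 * Q2)
    return (T - 1) / T * Q1 * (Q1 - 1) / 2.0


def expected_richness_at_coverage(
    incidence: IncidenceMatrix, target_coverage: float = 0.95
) -> float:
    """Expected species richness at the effort whose coverage equals the target.

    Interpolates (coverage-based rarefaction over sampling units) when the
    reference sample already exceeds the target coverage, extrapolates with
    the asymptotic (Chao2-type) richness estimator otherwise.  When the
    target is not attainable (no duplicate detections to estimate undetected
    richness from), the asymptotic estimate is returned with a log note.
    """
    if not 0 < target_coverage < 1:
        raise ValueError(f"target coverage must be in (0, 1), got {target_coverage}")
    T = incidence.n_units
    y = incidence.frequencies().astype(float)
    if y.size == 0 or y.sum() == 0:
        raise ValueError("no detections; expected richness undefined")
    s_obs = float(y.size)
    U, Q1, Q2 = _q_counts(y)
    c_ref = _reference_coverage(T, y)

    if abs(target_coverage - c_ref) < 1e-12:
        return s_obs
    if target_coverage < c_ref:
        # Rarefaction: richness and coverage are evaluated at integer unit
        # counts and interpolated linearly between them; the solution is the
        # first unit count whose (interpolated) coverage reaches the target,
        # clamped at one unit (effort below one unit is not meaningful).
        cov = [_interpolated_coverage(T, y, k) for k in range(1, T + 1)]
        ric = [_interpolated_richness(T, y, k) for k in range(1, T)] + [s_obs]
        if cov[0] >= target_coverage:
            return ric[0]
        for k in range(len(cov) - 1):
            lo, hi = cov[k], cov[k + 1]
            if lo <= target_coverage <= hi:
                frac = 0.0 if hi == lo else (target_coverage - lo) / (hi - lo)
                return ric[k] + frac * (ric[k + 1] - ric[k])
        return s_obs  # coverage tops out below the target within the sample

    # Extrapolation.
    q0 = _undetected_richness(T, Q1, Q2)
    A_denom = (T - 1) * Q1 + 2 * Q2
    A = (T - 1) * Q1 / A_denom if A_denom > 0 else 1.0
    if Q1 == 0 or A >= 1.0 or q0 == 0.0:
        logger.info(
            "coverage target %.3f not attainable (Q1=%g, Q2=%g); returning "
            "asymptotic richness", target_coverage, Q1, Q2,
        )
        return s_obs + q0
    # 1 - target = (Q1/U) * A**(t*+1)
    t_extra = np.log((1.0 - target_coverage) * U / Q1) / np.log(A) - 1.0
    t_extra = max(t_extra, 0.0)
    return s_obs + q0 * (1.0 - (1.0 - Q1 / (Q1 + T * q0)) ** t_extra)


def standardize_richness(
    observed_by_plot: dict[str, int],
    expected_by_site: dict[str, float],
    plot_sites: dict[str, str],
    taxon_group: str,
) -> list[StandardizedRichness]:
    """Observed plot richness / expected site richness, per plot.

    All plots of one site share the denominator.  A plot whose site has no
    expectation raises; expectations must be positive.
    """
    out = []
    for plot, obs in sorted(observed_by_plot.items()):
        site = plot_sites.get(plot)
        if site is None or site not in expected_by_site:
            raise KeyError(f"plot {plot!r}: no expected richness for site {site!r}")
        expected = expected_by_site[site]
        if expected <= 0:
            raise ValueError(f"expected richness for site {site!r} must be > 0")
        out.append(
            StandardizedRichness(
                plot_id=plot,
                taxon_group=taxon_group,
                observed=int(obs),
                expected_site=float(expected),
                ratio=float(obs) / float(expected),
            )
        )
    return out


# ---------------------------------------------------------------------------
# Long-format incidence IO
# ---------------------------------------------------------------------------

LONG_COLUMNS = ["taxon_group", "site", "plot_id", "sampling_unit", "species"]


def incidence_from_long(df: pd.DataFrame) -> list[IncidenceMatrix]:
    """Build per-(taxon, site) incidence matrices from a long detection table.

    ``df`` columns: taxon_group, site, plot_id, sampling_unit, species — one
    row per detection.  Units absent for a species get 0.
    """
    missing = [c for c in LONG_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"long incidence table lacks columns {missing}")
    out = []
    for (taxon, site), grp in df.groupby(["taxon_group", "site"], sort=True):
        units = sorted(grp["sampling_unit"].astype(str).unique())
        species = sorted(grp["species"].astype(str).unique())
        mat = pd.DataFrame(0, index=species, columns=units)
        for r in grp.itertuples():
            mat.loc[str(r.species), str(r.sampling_unit)] = 1
        unit_plots = (
            grp.drop_duplicates("sampling_unit")
            .set_index(grp.drop_duplicates("sampling_unit")["sampling_unit"].astype(str))[
                "plot_id"
            ]
            .astype(str)
            .to_dict()
        )
        out.append(
            IncidenceMatrix(
                taxon_group=str(taxon), site=str(site), matrix=mat, unit_plots=unit_plots
            )
        )
    return out


def incidence_to_long(matrices: Iterable[IncidenceMatrix]) -> pd.DataFrame:
    rows = []
    for im in matrices:
        for sp in im.matrix.index:
            for unit in im.matrix.columns:
                if im.matrix.loc[sp, unit]:
                    rows.append(
                        (im.taxon_group, im.site, im.unit_plots.get(unit, ""), unit, sp)
                    )
    return pd.DataFrame(rows, columns=LONG_COLUMNS)
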