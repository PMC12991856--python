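"""End-to-end orchestration: simulate -> harmonize -> features -> SEM -> effects.

`compute_features` turns harmonized inventories plus incidence data into the
plot-level model table (one column per graph node); `run_pipeline` drives
the whole chain from a :class:`RunConfig` and writes the standard artifact
files (features.csv, carbon.csv, fits.csv, dsep.csv, gof.json, effects.csv,
run.log).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .biodiversity import (
    IncidenceMatrix,
    deadwood_type_richness,
    expected_richness_at_coverage,
    incidence_from_long,
    sample_coverage,
    standardize_richness,
    structural_summaries,
)
from .carbon import DensityTable, carbon_table, plot_carbon_stocks
from .dag import CausalGraph, default_graph, parse_graph, serialize_graph
from .effects import bootstrap_effects
from .harmonize import (
    DeadwoodPiece,
    PlotMeta,
    TreeRecord,
    filter_living_trees,
    filter_lying_deadwood,
    impute_heights,
    read_deadwood,
    read_plots,
    read_trees,
    write_deadwood,
    write_plots,
    write_trees,
)
from .psem import PsemFit, fit_psem
from .synthetic import GeneratorParams, generate_plot_features, realize_inventories

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "compute_features", "run_pipeline"]


@dataclass
class RunConfig:
    """Validated configuration of one pipeline run."""

    output_dir: str = "results/run"
    # either a simulate block ...
    simulate: dict | None = None
    # ... or input paths
    trees_path: str | None = None
    deadwood_path: str | None = None
    plots_path: str | None = None
    incidence_path: str | None = None
    graph_path: str | None = None
    # thresholds
    min_dbh: float = 11.0
    min_dw_diameter: float = 15.0
    coverage: float = 0.95
    # carbon constants
    living_carbon_fraction: float = 0.48
    dead_carbon_fraction: float = 0.485
    form_factor: float = 0.5
    density_path: str | None = None
    decay_corrections_path: str | None = None
    # bootstrap
    nboot: int = 999
    seed: int = 1
    ci_level: float = 0.95

    def __post_init__(self):
        if not 0 < self.coverage < 1:
            raise ValueError(f"coverage must be in (0, 1), got {self.coverage}")
        for name in ("living_carbon_fraction", "dead_carbon_fraction", "form_factor"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.nboot < 1:
            raise ValueError("nboot must be >= 1")
        if self.simulate is None and not all(
            (self.trees_path, self.deadwood_path, self.plots_path, self.incidence_path)
        ):
            raise ValueError(
                "config needs either a simulate block or all four input paths"
            )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def graph(self) -> CausalGraph:
        if self.graph_path is None:
            return default_graph()
        return parse_graph(Path(self.graph_path).read_text())


def compute_features(
    trees: list[TreeRecord],
    deadwood: list[DeadwoodPiece],
    metas: dict[str, PlotMeta],
    incidence: list[IncidenceMatrix],
    min_dbh: float = 11.0,
    min_dw_diameter: float = 15.0,
    coverage: float = 0.95,
    density: DensityTable | None = None,
    form_factor: float = 0.5,
    living_fraction: float = 0.48,
    dead_fraction: float = 0.485,
    impute_seed: int = 0,
):
    """Plot-level model variables from harmonized raw data.

    Returns ``(features, carbon)``: the features table has one row per plot
    with grouping factors, stand age and climate from the metadata,
    recomputed structural summaries (tree species richness, mean dbh,
    deadwood type richness), carbon stocks, and the coverage-standardized
    richness ratio per taxon.
    """
    trees = [t for t in trees if t.dbh >= min_dbh]
    trees = impute_heights(trees, metas, seed=impute_seed)
    living = filter_living_trees([t for t in trees if t.alive], min_dbh)
    standing_dead = [t for t in trees if not t.alive]
    pieces = filter_lying_deadwood(deadwood, min_dw_diameter)

    by_plot_trees: dict[str, list[TreeRecord]] = {p: [] for p in metas}
    for t in living:
        by_plot_trees.setdefault(t.plot_id, []).append(t)
    by_plot_dead_trees: dict[str, list[TreeRecord]] = {p: [] for p in metas}
    for t in standing_dead:
        by_plot_dead_trees.setdefault(t.plot_id, []).append(t)
    by_plot_pieces: dict[str, list[DeadwoodPiece]] = {p: [] for p in metas}
    for p in pieces:
        by_plot_pieces.setdefault(p.plot_id, []).append(p)

    rows = []
    stocks = []
    for pid, meta in sorted(metas.items()):
        plot_trees = by_plot_trees.get(pid, [])
        if not plot_trees:
            raise ValueError(f"plot {pid!r} has no living trees after harmonization")
        richness, mean_dbh = structural_summaries(plot_trees)
        dwr = deadwood_type_richness(by_plot_pieces.get(pid, []))
        cs = plot_carbon_stocks(
            plot_trees + by_plot_dead_trees.get(pid, []),
            by_plot_pieces.get(pid, []),
            meta,
            density=density,
            form_factor=form_factor,
            living_fraction=living_fraction,
            dead_fraction=dead_fraction,
        )
        stocks.append(cs)
        rows.append(
            {
                "plot_id": pid,
                "site": meta.site,
                "forest_type": meta.forest_type,
                "management": meta.management,
                "stand_age": meta.stand_age,
                "mean_temp": meta.mean_temp,
                "annual_precip": meta.annual_precip,
                "tree_richness": richness,
                "mean_dbh": mean_dbh,
                "dw_type_richness": dwr,
                "c_living": cs.c_living,
                "c_dead": cs.c_dead,
            }
        )
    features = pd.DataFrame(rows)

    plot_sites = {pid: m.site for pid, m in metas.items()}
    taxa = sorted({im.taxon_group for im in incidence})
    for taxon in taxa:
        mats = [im for im in incidence if im.taxon_group == taxon]
        expected_by_site = {
            im.site: expected_richness_at_coverage(im, coverage) for im in mats
        }
        observed: dict[str, int] = {pid: 0 for pid in metas}
        for im in mats:
            observed.update(im.observed_richness_by_plot())
        records = standardize_richness(observed, expected_by_site, plot_sites, taxon)
        ratio = {r.plot_id: r.ratio for r in records}
        features[taxon] = features["plot_id"].map(ratio)
    return features, carbon_table(stocks)


def _fits_table(fit: PsemFit) -> pd.DataFrame:
    rows = []
    for nf in fit.node_fits:
        for p in nf.predictors:
            rows.append(
                (nf.response, p, nf.coefficients[p], nf.std_errors[p],
                 nf.p_values[p], nf.marginal_r2)
            )
    return pd.DataFrame(
        rows, columns=["response", "predictor", "estimate", "se", "p", "marginal_r2"]
    )


def _dsep_table(fit: PsemFit) -> pd.DataFrame:
    return pd.DataFrame(
        [(c.label(), p) for c, p in zip(fit.dsep.claims, fit.dsep.p_values)],
        columns=["claim", "p"],
    )


def run_pipeline(config: RunConfig) -> Path:
    """Run the configured pipeline; returns the output directory.

    Writes features.csv, carbon.csv, fits.csv, dsep.csv, gof.json,
    effects.csv and run.log (config echo plus package version).  Raises on
    any stage error (schema violations, impossible transforms, ...).
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines = [f"forest-csb {__version__}", f"config: {dataclasses.asdict(config)}"]

    graph = config.graph()
    density = DensityTable.from_csv(config.density_path, config.decay_corrections_path)

    if config.simulate is not None:
        sim_kwargs = dict(config.simulate)
        sim_kwargs.setdefault("seed", config.seed)
        params = GeneratorParams(**sim_kwargs)
        feats = generate_plot_features(params)
        dataset = realize_inventories(feats, params)
        trees, deadwood, metas, incidence = (
            dataset.trees, dataset.deadwood, dataset.metas, dataset.incidence,
        )
        write_trees(trees, out / "trees.csv")
        write_deadwood(deadwood, out / "deadwood.csv")
        write_plots(metas.values(), out / "plots.csv")
        log_lines.append(f"simulated {params.n_plots} plots (seed {params.seed})")
    else:
        trees = read_trees(config.trees_path)
        deadwood = read_deadwood(config.deadwood_path)
        metas = read_plots(config.plots_path)
        incidence = incidence_from_long(pd.read_csv(config.incidence_path))
        log_lines.append(
            f"read {len(trees)} trees, {len(deadwood)} deadwood pieces, "
            f"{len(metas)} plots"
        )

    features, carbon = compute_features(
        trees, deadwood, metas, incidence,
        min_dbh=config.min_dbh,
        min_dw_diameter=config.min_dw_diameter,
        coverage=config.coverage,
        density=density,
        form_factor=config.form_factor,
        living_fraction=config.living_carbon_fraction,
        dead_fraction=config.dead_carbon_fraction,
        impute_seed=config.seed,
    )
    features.to_csv(out / "features.csv", index=False)
    carbon.to_csv(out / "carbon.csv", index=False)

    fit = fit_psem(features, graph)
    _fits_table(fit).to_csv(out / "fits.csv", index=False)
    _dsep_table(fit).to_csv(out / "dsep.csv", index=False)
    gof = {
        "C": fit.dsep.C,
        "df": fit.dsep.df,
        "p_C": fit.dsep.p_C,
        "n_claims": len(fit.dsep.claims),
        "correlated_errors": {f"{a}~~{b}": r for (a, b), r in fit.correlated_error_r.items()},
    }
    (out / "gof.json").write_text(json.dumps(gof, indent=2, sort_keys=True) + "\n")

    effects = bootstrap_effects(
        features, graph, nboot=config.nboot, seed=config.seed,
        ci_level=config.ci_level,
    )
    effects.to_csv(out / "effects.csv", index=False)

    (out / "graph.txt").write_text(serialize_graph(graph))
    log_lines.append(
        f"fisher C = {fit.dsep.C:.3f}, df = {fit.dsep.df}, p = {fit.dsep.p_C:.3f}"
    )
    (out / "run.log").write_text("\n".join(log_lines) + "\n")
    return out
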