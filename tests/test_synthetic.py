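"""Synthetic forest generator: causal structure, realization round trips."""

import numpy as np
import pandas as pd
import pytest

from forest_csb.biodiversity import deadwood_type_richness, structural_summaries
from forest_csb.dag import CausalGraph, default_graph
from forest_csb.harmonize import filter_living_trees
from forest_csb.lmm import fit_mixed_lm
from forest_csb.synthetic import (
    GeneratorParams,
    _realize_deadwood,
    generate_plot_features,
    realize_inventories,
)


def zero_coefficients():
    return {e: 0.0 for e in default_graph().edges}


class TestParamsValidation:
    def test_plots_vs_sites(self):
        with pytest.raises(ValueError):
            GeneratorParams(n_plots=5, n_sites=10)

    def test_negative_sd_rejected(self):
        with pytest.raises(ValueError):
            GeneratorParams(random_intercept_sd={"site": -0.1})

    def test_coefficient_for_non_edge_rejected(self):
        coeffs = zero_coefficients()
        coeffs[("rich_birds", "stand_age")] = 0.3
        with pytest.raises(ValueError, match="non-edge"):
            GeneratorParams(path_coefficients=coeffs)

    def test_correlation_domain(self):
        with pytest.raises(ValueError):
            GeneratorParams(temp_precip_correlation=1.0)


class TestGeneratePlotFeatures:
    def test_deterministic_under_fixed_seed(self):
        a = generate_plot_features(GeneratorParams(n_plots=60, n_sites=6, seed=11))
        b = generate_plot_features(GeneratorParams(n_plots=60, n_sites=6, seed=11))
        pd.testing.assert_frame_equal(a, b)

    def test_null_model_has_vanishing_correlations(self):
        params = GeneratorParams(
            n_plots=2000, n_sites=10, seed=21,
            path_coefficients=zero_coefficients(),
            random_intercept_sd={"site": 0.0, "forest_type": 0.0, "management": 0.0},
        )
        feats = generate_plot_features(params)
        nodes = [n for n in default_graph().nodes
                 if n not in ("mean_temp", "annual_precip")]
        z = feats[[f"z_{n}" for n in nodes]].to_numpy()
        corr = np.corrcoef(z.T)
        off = corr[~np.eye(len(nodes), dtype=bool)]
        assert np.abs(off).max() < 0.08

    def test_monte_carlo_recovers_generating_coefficient(self):
        coeffs = zero_coefficients()
        coeffs[("stand_age", "mean_dbh")] = 0.6
        params = GeneratorParams(
            n_plots=2000, n_sites=10, seed=31, path_coefficients=coeffs,
            random_intercept_sd={"site": 0.0, "forest_type": 0.0, "management": 0.0},
        )
        feats = generate_plot_features(params)
        r = np.corrcoef(feats["z_stand_age"], feats["z_mean_dbh"])[0, 1]
        assert r == pytest.approx(0.6, abs=0.05)

    def test_unit_marginal_variance_of_endogenous_nodes(self):
        # without random intercepts the derived residual sds must give unit
        # variance tightly; with few-level intercepts (5 forest types, 4
        # managements) the sample variance itself is noisy, so only loosely
        no_re = GeneratorParams(
            n_plots=4000, n_sites=16, seed=41,
            random_intercept_sd={"site": 0.0, "forest_type": 0.0, "management": 0.0},
        )
        feats = generate_plot_features(no_re)
        for node in default_graph().endogenous:
            assert feats[f"z_{node}"].var() == pytest.approx(1.0, abs=0.07)
        feats = generate_plot_features(GeneratorParams(n_plots=4000, n_sites=16, seed=41))
        for node in default_graph().endogenous:
            assert feats[f"z_{node}"].var() == pytest.approx(1.0, abs=0.2)

    def test_temp_precip_correlation(self):
        feats = generate_plot_features(GeneratorParams(n_plots=4000, n_sites=16, seed=51))
        r = np.corrcoef(feats["z_mean_temp"], feats["z_annual_precip"])[0, 1]
        assert r == pytest.approx(-0.3, abs=0.05)

    def test_positive_intraclass_correlation_within_sites(self):
        params = GeneratorParams(n_plots=1200, n_sites=24, seed=61)
        feats = generate_plot_features(params)
        res = fit_mixed_lm(
            feats["z_mean_dbh"].to_numpy(),
            np.ones((len(feats), 1)),
            {"site": feats["site"].to_numpy()},
        )
        icc = res.vc["site"] / (res.vc["site"] + res.resid_var)
        assert icc > 0.005

    def test_balanced_group_allocation(self):
        feats = generate_plot_features(GeneratorParams(n_plots=301, n_sites=16, seed=71))
        counts = feats["site"].value_counts()
        assert counts.max() - counts.min() <= 1
        assert feats["plot_id"].is_unique
        # every plot has exactly one site/forest type/management
        assert feats.groupby("plot_id")[["site", "forest_type", "management"]].nunique().max().max() == 1

    def test_infeasible_standardization_raises(self):
        coeffs = zero_coefficients()
        for parent in ("stand_age", "tree_richness", "mean_temp", "annual_precip"):
            coeffs[(parent, "mean_dbh")] = 0.9
        with pytest.raises(ValueError, match="exceed"):
            generate_plot_features(GeneratorParams(path_coefficients=coeffs))


class TestRealizeInventories:
    @pytest.fixture(scope="class")
    def dataset(self):
        params = GeneratorParams(n_plots=60, n_sites=6, seed=81)
        feats = generate_plot_features(params)
        return realize_inventories(feats, params)

    def test_deterministic(self):
        params = GeneratorParams(n_plots=30, n_sites=3, seed=91)
        feats = generate_plot_features(params)
        a = realize_inventories(feats, params)
        b = realize_inventories(feats, params)
        assert a.trees == b.trees
        assert a.deadwood == b.deadwood

    def test_zero_target_gives_empty_deadwood(self, rng):
        assert _realize_deadwood("P", 0, 0.5, 1.0, rng) == []

    def test_full_target_covers_all_sixty_combinations(self, rng):
        pieces = _realize_deadwood("P", 60, 0.5, 1.0, rng)
        assert deadwood_type_richness(pieces) == 60

    def test_infeasible_target_raises(self, rng):
        with pytest.raises(ValueError):
            _realize_deadwood("P", 61, 0.5, 1.0, rng)

    def test_deadwood_round_trip_on_many_random_plots(self, rng):
        for _ in range(1000):
            target = int(rng.integers(0, 61))
            pieces = _realize_deadwood("P", target, 0.5, float(rng.uniform(0.3, 3)), rng)
            assert deadwood_type_richness(pieces) == target

    def test_structural_round_trip(self, dataset):
        feats = dataset.plot_features
        for row in feats.itertuples():
            trees = filter_living_trees(
                [t for t in dataset.trees if t.plot_id == row.plot_id]
            )
            richness, mean_dbh = structural_summaries(trees)
            assert richness == row.tree_richness_target
            assert mean_dbh == pytest.approx(row.mean_dbh_target, abs=1e-6)
            pieces = [p for p in dataset.deadwood if p.plot_id == row.plot_id]
            assert deadwood_type_richness(pieces) == row.dw_richness_target

    def test_observed_richness_monotone_in_driver(self, dataset):
        feats = dataset.plot_features.set_index("plot_id")
        obs, z = [], []
        for im in dataset.incidence:
            if im.taxon_group != "rich_birds":
                continue
            for plot, count in im.observed_richness_by_plot().items():
                obs.append(count)
                z.append(feats.loc[plot, "z_rich_birds"])
        assert np.corrcoef(z, obs)[0, 1] > 0.5

    def test_every_plot_has_metadata_and_positive_deadwood(self, dataset):
        assert set(dataset.metas) == set(dataset.plot_features["plot_id"])
        per_plot = {p: 0 for p in dataset.metas}
        for piece in dataset.deadwood:
            per_plot[piece.plot_id] += 1
        assert min(per_plot.values()) >= 1
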