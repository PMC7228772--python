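"""Synthetic-study generator: tiling, counts, phenotypes, expression, RLBA."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from phipdiscover import (
    PlantedTruth,
    SimulationConfig,
    SyntheticProteome,
    aggregate_by_gene,
    fold_change,
    normalize_to_percent,
    simulate_counts,
    simulate_expression,
    simulate_phenotypes,
    simulate_study,
    tile_proteome,
)
from phipdiscover.tissue import specificity_ratios


def _protein(length: int, gene: str = "G1") -> SyntheticProteome:
    return SyntheticProteome(protein_id=f"P_{gene}", gene=gene,
                             sequence="A" * length)


class TestTiling:
    @pytest.mark.parametrize(
        "length, windows",
        [
            (49, [(1, 49)]),                 # exactly one window fits
            (73, [(1, 49), (25, 73)]),       # regular second start at 25
            (50, [(1, 49), (2, 50)]),        # C-terminus-anchored final tile
            (30, [(1, 30)]),                 # short protein: one full tile
            (121, [(1, 49), (25, 73), (49, 97), (73, 121)]),
        ],
    )
    def test_window_coordinates(self, length, windows):
        lib = tile_proteome([_protein(length)])
        assert list(zip(lib["start"], lib["end"])) == windows

    def test_invalid_overlap_rejected(self):
        with pytest.raises(ValueError):
            tile_proteome([_protein(100)], tile_len=49, overlap=49)

    @settings(derandomize=True, max_examples=50)
    @given(length=st.integers(1, 600))
    def test_every_residue_covered_and_steps_regular(self, length):
        lib = tile_proteome([_protein(length)])
        covered = np.zeros(length + 1, dtype=bool)
        for s, e in zip(lib["start"], lib["end"]):
            assert 1 <= s <= e <= length
            covered[s:e + 1] = True
        assert covered[1:].all()
        starts = list(lib["start"])
        assert starts[0] == 1
        # all but (possibly) the final anchored tile advance by 24
        for a, b in zip(starts, starts[1:-1]):
            assert b - a == 24
        if length > 49:
            assert (lib["end"] - lib["start"] + 1 == 49).all()

    def test_gene_symbols_and_tile_ids_unique(self, tiny_study):
        lib = tiny_study.library
        assert lib["tile_id"].is_unique
        assert lib.groupby("gene")["protein_id"].nunique().eq(1).all()


class TestCounts:
    def test_bit_identical_under_same_seed(self, tiny_config):
        a = simulate_study(tiny_config)
        b = simulate_study(tiny_config)
        pd.testing.assert_frame_equal(a.counts.counts, b.counts.counts)
        pd.testing.assert_frame_equal(a.phenotypes, b.phenotypes)
        pd.testing.assert_frame_equal(a.expression, b.expression)
        pd.testing.assert_frame_equal(a.rlba, b.rlba)
        assert a.truth.to_table().equals(b.truth.to_table())

    def test_columns_sum_exactly_to_depth(self, tiny_study, tiny_config):
        depths = tiny_study.counts.counts.sum(axis=0)
        assert (depths == tiny_config.reads_per_sample).all()

    def test_roles_and_cohorts_populated(self, tiny_study, tiny_config):
        roles = tiny_study.counts.roles
        assert (roles == "case").sum() == tiny_config.n_cases
        assert (roles == "control").sum() == tiny_config.n_controls
        assert (roles == "mock").sum() == tiny_config.n_mock

    def test_null_simulation_folds_concentrate_near_one(self):
        """Without planted antigens, gene folds over the mock mean hug 1."""
        config = SimulationConfig(n_planted=0, seed=21)
        study = simulate_study(config)
        gene = aggregate_by_gene(normalize_to_percent(study.counts),
                                 study.library)
        fold = fold_change(gene, study.counts.sample_ids("mock"),
                           mock_depths=study.counts.depths)
        inside = ((fold >= 0.5) & (fold <= 2.0)).to_numpy().mean()
        assert inside >= 0.90

    def test_null_case_and_control_columns_exchangeable(self):
        """With no planted truth, case and control columns share a distribution."""
        from scipy.stats import mannwhitneyu

        config = SimulationConfig(n_planted=0, seed=22)
        study = simulate_study(config)
        norm = normalize_to_percent(study.counts)
        top_share = norm.max(axis=0)  # per-sample share of the hottest tile
        cases = top_share[study.counts.sample_ids("case")]
        controls = top_share[study.counts.sample_ids("control")]
        assert mannwhitneyu(cases, controls).pvalue > 0.01

    def test_single_strong_antigen_exceeds_tenfold(self):
        """One antigen, factor 100, all tiles reactive: fold >= 10 in its sample."""
        config = SimulationConfig(n_genes=50, n_cases=3, n_controls=2, n_mock=3,
                                  n_planted=0, seed=13)
        rng = np.random.default_rng(0)
        from phipdiscover import random_proteome
        library = tile_proteome(random_proteome(config, rng))
        gene = "GENE0007"
        truth = PlantedTruth(
            antigen_genes=[gene],
            reactive_map={gene: ["CASE-001"]},
            epitope_map={gene: library.loc[library["gene"] == gene,
                                           "tile_id"].tolist()},
            enrichment_factor={gene: 100.0},
        )
        counts = simulate_counts(config, library, truth,
                                 np.random.default_rng(1))
        fold = fold_change(
            aggregate_by_gene(normalize_to_percent(counts), library),
            counts.sample_ids("mock"), mock_depths=counts.depths)
        assert fold.loc[gene, "CASE-001"] >= 10.0
        assert fold.loc[gene, "CASE-002"] < 10.0  # non-reactive case untouched

    def test_stray_epitope_tile_rejected(self, tiny_config, tiny_study):
        truth = tiny_study.truth
        bad = PlantedTruth(
            antigen_genes=truth.antigen_genes,
            reactive_map=truth.reactive_map,
            epitope_map={**truth.epitope_map,
                         truth.antigen_genes[0]: ["no_such_tile"]},
            enrichment_factor=truth.enrichment_factor,
        )
        with pytest.raises(ValueError, match="no_such_tile"):
            simulate_counts(tiny_config, tiny_study.library, bad)


class TestTruth:
    def test_invariants(self, tiny_study, tiny_config):
        truth, lib = tiny_study.truth, tiny_study.library
        lo, hi = tiny_config.enrichment_factor_range
        for gene in truth.antigen_genes:
            assert lo <= truth.enrichment_factor[gene] <= hi
            gene_tiles = set(lib.loc[lib["gene"] == gene, "tile_id"])
            assert set(truth.epitope_map[gene]) <= gene_tiles
            r_lo, r_hi = tiny_config.reactive_cases_range
            assert r_lo <= len(truth.reactive_map[gene]) <= r_hi

    def test_factor_below_one_rejected(self):
        with pytest.raises(ValueError):
            PlantedTruth(antigen_genes=["g"], reactive_map={}, epitope_map={},
                         enrichment_factor={"g": 0.5})

    def test_penetrance_below_background_rejected(self):
        with pytest.raises(ValueError):
            PlantedTruth(antigen_genes=["g"], reactive_map={}, epitope_map={},
                         enrichment_factor={"g": 5.0},
                         phenotype_links={"P": ("g", 0.1, 0.5)})


class TestPhenotypes:
    def _truth(self, reactive, pen, bg):
        return PlantedTruth(
            antigen_genes=["g"], reactive_map={"g": reactive},
            epitope_map={"g": []}, enrichment_factor={"g": 10.0},
            phenotype_links={"P": ("g", pen, bg)})

    def test_deterministic_link_equals_reactivity_indicator(self):
        cases = [f"c{i}" for i in range(10)]
        truth = self._truth(cases[:4], pen=1.0, bg=0.0)
        table = simulate_phenotypes(truth, cases, np.random.default_rng(0),
                                    n_phenotypes=1)
        expected = [1] * 4 + [0] * 6
        assert list(table["P"]) == expected

    def test_penetrance_binomial_check(self):
        """0.8 penetrance over 1000 reactive cases: fraction within 3 SDs."""
        cases = [f"c{i}" for i in range(1000)]
        truth = self._truth(cases, pen=0.8, bg=0.1)
        table = simulate_phenotypes(truth, cases, np.random.default_rng(1),
                                    n_phenotypes=1)
        frac = table["P"].mean()
        assert abs(frac - 0.8) <= 3 * np.sqrt(0.8 * 0.2 / 1000)

    def test_seeded_reproducibility_and_width(self):
        cases = [f"c{i}" for i in range(12)]
        truth = self._truth(cases[:5], pen=0.9, bg=0.05)
        a = simulate_phenotypes(truth, cases, np.random.default_rng(3))
        b = simulate_phenotypes(truth, cases, np.random.default_rng(3))
        pd.testing.assert_frame_equal(a, b)
        assert a.shape == (12, 24)  # padded to the full manifestation count

    def test_invalid_rates_rejected(self):
        cases = ["c0"]
        truth = self._truth(cases, pen=0.9, bg=0.05)
        truth.phenotype_links["P"] = ("g", 1.5, 0.0)
        with pytest.raises(ValueError):
            simulate_phenotypes(truth, cases, np.random.default_rng(0))


class TestExpression:
    def test_shape_and_nonnegative(self):
        genes = [f"g{i}" for i in range(30)]
        expr = simulate_expression(genes, n_tissues=74,
                                   rng=np.random.default_rng(0))
        assert expr.shape == (30, 74)
        assert (expr.to_numpy() >= 0).all()

    def test_restricted_genes_have_high_ratio(self):
        genes = [f"g{i}" for i in range(40)]
        restricted = {"g0", "g1", "g2"}
        expr = simulate_expression(genes, restricted_genes=restricted,
                                   rng=np.random.default_rng(1))
        ratios = specificity_ratios(expr)
        assert (ratios[list(restricted)] >= 0.9).all()

    def test_broad_genes_near_uniform_ratio(self):
        genes = [f"g{i}" for i in range(40)]
        expr = simulate_expression(genes, n_tissues=74,
                                   rng=np.random.default_rng(2))
        ratios = specificity_ratios(expr)
        uniform = 1.0 / 74
        assert ((ratios > 0.5 * uniform) & (ratios < 1.5 * uniform)).all()

    def test_unknown_restricted_gene_rejected(self):
        with pytest.raises(ValueError):
            simulate_expression(["a"], restricted_genes={"b"},
                                rng=np.random.default_rng(0))


class TestConfig:
    @pytest.mark.parametrize("kwargs", [
        dict(n_cases=0), dict(epitope_fraction=0.0), dict(epitope_fraction=1.2),
        dict(n_planted=300), dict(enrichment_factor_range=(0.5, 2.0)),
    ])
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SimulationConfig(**kwargs)

    def test_default_design_mirrors_study_cohorts(self):
        config = SimulationConfig()
        assert (config.n_cases, config.n_controls, config.n_mock) == (39, 28, 17)
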