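"""The synthetic breeding-program generator and its statistical contracts."""

import numpy as np
import pandas as pd
import pytest

import gsdesign as g
from gsdesign.simulate import (TrialConfig, _spatial_field, simulate_trial,
                               write_fixture)


@pytest.fixture(scope="module")
def cohort_panel():
    cfg = g.SimulationConfig(n_pops=3, n_lines_per_pop=120, n_markers=400,
                             n_chromosomes=5, n_cohorts=4,
                             selection_intensity=0.2,
                             selected_trait="trait_quant", seed=13)
    return cfg, *g.simulate_panel(cfg)


class TestPanel:
    def test_maf_spectrum_spans_the_filter_range(self, cohort_panel):
        _, G, _, _ = cohort_panel
        assert G.maf.min() < 0.05          # mass near the filter bound
        assert G.maf.max() > 0.4
        assert (G.maf <= 0.5 + 1e-12).all()

    def test_breeding_values_are_exact_qtl_sums(self, cohort_panel):
        _, G, _, truth = cohort_panel
        order = {m: i for i, m in enumerate(G.marker_ids)}
        for trait, (qtl_ids, eff) in truth.qtl.items():
            cols = [order[m] for m in qtl_ids]
            expected = G.calls[:, cols] @ eff
            np.testing.assert_allclose(
                truth.breeding_values[trait].to_numpy(), expected)

    def test_selection_raises_cohort_means_monotonically(self, cohort_panel):
        _, _, _, truth = cohort_panel
        tbv = truth.breeding_values["trait_quant"]
        means = [tbv[truth.cohort == c].mean() for c in range(4)]
        assert all(a < b for a, b in zip(means, means[1:]))

    def test_selection_shifts_qtl_frequencies_most(self, cohort_panel):
        """Allele-frequency change between first and last cohort, projected
        on the effect direction, exceeds the drift seen at neutral markers."""
        _, G, _, truth = cohort_panel
        order = {m: i for i, m in enumerate(G.marker_ids)}
        qtl_ids, eff = truth.qtl["trait_quant"]
        qtl_cols = np.array([order[m] for m in qtl_ids])
        first = G.calls[(truth.cohort == 0).to_numpy()]
        last = G.calls[(truth.cohort == 3).to_numpy()]
        shift = (last.mean(axis=0) - first.mean(axis=0)) / 2.0
        signed = shift[qtl_cols] * np.sign(eff)
        neutral = np.delete(np.arange(G.n_markers), qtl_cols)
        assert signed.mean() > np.abs(shift[neutral]).mean()

    def test_labels_cover_every_line(self, cohort_panel):
        _, G, _, truth = cohort_panel
        assert set(truth.population.index) == set(G.line_ids)
        assert truth.cohort.notna().all()

    def test_low_divergence_gives_no_pca_separation(self):
        cfg = g.SimulationConfig(n_pops=2, n_lines_per_pop=50, n_markers=200,
                                 n_chromosomes=3, divergence=0.005,
                                 n_cohorts=1, selected_trait=None, seed=2)
        G, _, truth = g.simulate_panel(cfg)
        pc = g.pca_scores(G, 1)
        pop = (truth.population == "P1").to_numpy()
        side = pc.scores[:, 0] > np.median(pc.scores[:, 0])
        agreement = max(np.mean(side == pop), np.mean(side == ~pop))
        assert agreement < 0.75


class TestTrial:
    def test_realised_heritability_matches_target(self):
        cfg = g.SimulationConfig(n_pops=3, n_lines_per_pop=700, n_markers=300,
                                 n_chromosomes=5, n_cohorts=1,
                                 selected_trait=None, seed=5)
        G, _, truth = g.simulate_panel(cfg)
        layout, phen, _ = simulate_trial(G, truth, TrialConfig(n_cols=40),
                                         seed=6)
        test = ~layout.is_check
        for trait, h2 in truth.h2.items():
            tbv = truth.breeding_values[trait].loc[
                layout.line_ids[test]].to_numpy()
            realised = np.var(tbv) / np.var(phen[trait].to_numpy()[test])
            assert realised == pytest.approx(h2, abs=0.05)

    def test_check_density_and_uniqueness(self, cohort_panel):
        cfg, G, _, truth = cohort_panel
        layout, _, _ = simulate_trial(G, truth, TrialConfig(), seed=1)
        n = layout.n_plots
        assert layout.is_check.sum() == int(np.ceil(n / 11))
        # every non-check line appears exactly once
        test_ids, counts = np.unique(layout.line_ids[~layout.is_check],
                                     return_counts=True)
        assert (counts == 1).all()

    def test_independent_errors_at_zero_rho(self):
        fld = _spatial_field(np.random.default_rng(0), 80, 80, 0.0, 0.0)
        rows = fld.ravel()
        lag1 = np.corrcoef(fld[:-1].ravel(), fld[1:].ravel())[0, 1]
        assert lag1 == pytest.approx(0.0, abs=0.05)
        assert np.var(rows) == pytest.approx(1.0, abs=0.05)

    def test_row_autocorrelation_matches_rho(self):
        fld = _spatial_field(np.random.default_rng(1), 90, 90, 0.5, 0.0)
        lag1 = np.corrcoef(fld[:-1].ravel(), fld[1:].ravel())[0, 1]
        assert lag1 == pytest.approx(0.5, abs=0.05)

    def test_perfect_heritability_reproduces_breeding_values(self):
        spec = (g.TraitSpec("exact", n_qtl=10, h2=1.0),)
        cfg = g.SimulationConfig(n_pops=2, n_lines_per_pop=40, n_markers=100,
                                 n_chromosomes=3, n_cohorts=1,
                                 trait_specs=spec, selected_trait=None,
                                 seed=8)
        G, _, truth = g.simulate_panel(cfg)
        layout, phen, _ = simulate_trial(G, truth, TrialConfig(), seed=9)
        test = ~layout.is_check
        tbv = truth.breeding_values["exact"].loc[
            layout.line_ids[test]].to_numpy()
        np.testing.assert_allclose(phen["exact"].to_numpy()[test], tbv)

    def test_capacity_violation_reports_required_rows(self, cohort_panel):
        _, G, _, truth = cohort_panel
        with pytest.raises(ValueError, match="need at least"):
            simulate_trial(G, truth, TrialConfig(n_rows=3, n_cols=10), seed=0)


class TestFixtures:
    def test_roundtrip_and_determinism(self, tmp_path):
        from gsdesign import io

        cfg = g.SimulationConfig(n_pops=2, n_lines_per_pop=30, n_markers=60,
                                 n_chromosomes=3, n_cohorts=2, seed=17)
        b = g.simulate_bundle(cfg)
        d1, d2 = tmp_path / "a", tmp_path / "b"
        paths = write_fixture(b, d1)
        write_fixture(g.simulate_bundle(cfg), d2)

        for p1 in sorted(d1.iterdir()):  # same seed -> byte-identical files
            assert p1.read_bytes() == (d2 / p1.name).read_bytes()

        G2 = io.read_genotypes(paths["genotypes"])
        np.testing.assert_allclose(G2.calls, b.G.calls)
        assert list(G2.line_ids) == list(b.G.line_ids)
        m2 = io.read_map(paths["map"])
        assert list(m2.marker_ids) == list(b.genetic_map.marker_ids)
        np.testing.assert_allclose(m2.position, b.genetic_map.position)
        layout2, phen2 = io.read_phenotypes(paths["phenotypes"])
        np.testing.assert_array_equal(layout2.rows, b.layout.rows)
        np.testing.assert_array_equal(layout2.line_ids, b.layout.line_ids)
        pd.testing.assert_frame_equal(phen2, b.phenotypes)

    def test_existing_directory_needs_overwrite_flag(self, tmp_path):
        cfg = g.SimulationConfig(n_pops=2, n_lines_per_pop=20, n_markers=30,
                                 n_chromosomes=2, n_cohorts=1, seed=3)
        b = g.simulate_bundle(cfg)
        write_fixture(b, tmp_path / "x")
        with pytest.raises(FileExistsError):
            write_fixture(b, tmp_path / "x")
        write_fixture(b, tmp_path / "x", overwrite=True)
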