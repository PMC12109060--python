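"""Generator ground-truth consistency, determinism and null behaviour."""

import numpy as np
import pandas as pd
import pytest

from teashuttle import deg, screen, simulate
from teashuttle.errors import InvalidConfigError


class TestConfig:
    def test_defaults_mirror_study_design(self):
        cfg = simulate.SimConfig()
        assert cfg.group_sizes == {"LaBC": 29, "LbBC": 30, "Her2BC": 30,
                                   "TNBC": 41, "normal": 11}

    def test_invalid_configs_raise(self):
        with pytest.raises(InvalidConfigError):
            simulate.generate_expression(
                simulate.SimConfig(n_genes=5, n_spiked=6))
        with pytest.raises(InvalidConfigError):
            simulate.SimConfig(frac_es_positive=1.5).validate()


class TestDeterminism:
    def test_every_generator_is_seed_stable(self, small_cfg):
        s1, _ = simulate.generate_expression(small_cfg)
        s2, _ = simulate.generate_expression(small_cfg)
        pd.testing.assert_frame_equal(s1.matrix, s2.matrix)
        c1, _ = simulate.generate_compound_library(small_cfg)
        c2, _ = simulate.generate_compound_library(small_cfg)
        pd.testing.assert_frame_equal(c1, c2)
        e1, _ = simulate.generate_ppi(small_cfg)
        e2, _ = simulate.generate_ppi(small_cfg)
        pd.testing.assert_frame_equal(e1, e2)
        m1, _ = simulate.generate_mfc_series(small_cfg)
        m2, _ = simulate.generate_mfc_series(small_cfg)
        np.testing.assert_array_equal(m1[0].voltage_v, m2[0].voltage_v)
        v1 = simulate.generate_voltammogram(small_cfg, 2)
        v2 = simulate.generate_voltammogram(small_cfg, 2)
        np.testing.assert_array_equal(v1.cycles[1]["forward"],
                                      v2.cycles[1]["forward"])

    def test_different_seeds_differ(self):
        a, _ = simulate.generate_expression(simulate.small_test_config(1))
        b, _ = simulate.generate_expression(simulate.small_test_config(2))
        assert not a.matrix.equals(b.matrix)


class TestExpression:
    def test_spike_within_analytic_se(self):
        """Spiked mean differences sit within 3 SE of the designed
        log2 fold change (SE of a two-group mean difference)."""
        cfg = simulate.SimConfig(
            seed=7, n_genes=100, n_spiked=20, spike_log2fc=2.0,
            noise_sd=0.3, group_sizes={"LaBC": 30, "normal": 11})
        study, truth = simulate.generate_expression(cfg)
        se = 0.3 * np.sqrt(1 / 30 + 1 / 11)
        t_cols = study.samples_of("LaBC")
        n_cols = study.samples_of("normal")
        diffs = (study.matrix[t_cols].mean(axis=1)
                 - study.matrix[n_cols].mean(axis=1))
        for g in truth.spiked_genes["LaBC"]["up"]:
            assert abs(diffs[g] - 2.0) < 3 * se
        for g in truth.spiked_genes["LaBC"]["down"]:
            assert abs(diffs[g] + 2.0) < 3 * se

    def test_null_false_positive_rate(self):
        """With no spikes, BH-adjusted calls stay at or below the nominal
        rate (within binomial error) across seeds."""
        n_pos = n_tot = 0
        for seed in range(20):
            cfg = simulate.SimConfig(
                seed=seed, n_genes=80, n_spiked=0,
                group_sizes={"LaBC": 6, "normal": 5})
            study, _ = simulate.generate_expression(cfg)
            table = deg.moderated_t(study, "LaBC")
            n_pos += int((table["adj_p"] < 0.05).sum())
            n_tot += len(table)
        se = np.sqrt(0.05 * 0.95 / n_tot)
        assert n_pos / n_tot <= 0.05 + 3 * se


class TestCompounds:
    def test_motifs_truly_present_in_smiles(self, compound_pair):
        lib, truth = compound_pair
        for row in lib.itertuples(index=False):
            es, _ = screen.es_classify(row.smiles)
            assert es == (row.compound_id
                          in truth.es_positive_compound_ids)

    def test_fraction_respected(self):
        cfg = simulate.small_test_config(5, frac_es_positive=0.25)
        _, truth = simulate.generate_compound_library(cfg)
        assert len(truth.es_positive_compound_ids) == \
            round(cfg.n_compounds * 0.25)


class TestPPI:
    def test_clique_edges_present_and_high_confidence(self, ppi_pair):
        edges, truth = ppi_pair
        members = truth.planted_clique_members
        pairs = {frozenset((a, b))
                 for a, b, s in edges.itertuples(index=False)
                 if s >= 700}
        import itertools
        for a, b in itertools.combinations(sorted(members), 2):
            assert frozenset((a, b)) in pairs

    def test_zero_prob_no_clique_empty_after_pruning(self):
        from teashuttle import network
        cfg = simulate.small_test_config(
            6, ppi_edge_prob=0.0, planted_clique_size=0)
        edges, _ = simulate.generate_ppi(cfg)
        assert network.build_network(edges).number_of_nodes() == 0


class TestPlates:
    def test_noiseless_calibration_recovery(self):
        from teashuttle import assay
        for name in ("TPC", "TFC", "TCTC", "FRAP"):
            cfg = simulate.small_test_config(7)
            plate, truth = simulate.generate_plate(cfg, name)
            curve = assay.fit_calibration(plate)
            slope, intercept = truth.calibration[name]
            assert curve.slope == pytest.approx(slope, rel=1e-12)
            assert curve.intercept == pytest.approx(intercept, abs=1e-12)

    def test_noisy_slope_recovery_within_5_percent(self):
        from teashuttle import assay
        errs = []
        for seed in range(60):
            cfg = simulate.small_test_config(seed, plate_noise_sd=0.01)
            plate, truth = simulate.generate_plate(cfg, "TPC")
            curve = assay.fit_calibration(plate)
            errs.append(abs(curve.slope / truth.calibration["TPC"][0] - 1))
        assert np.median(errs) < 0.05


class TestMFCAndCV:
    def test_plateau_ratio_recovers_amplification(self):
        from teashuttle import electrochem
        cfg = simulate.small_test_config(8)
        series, truth = simulate.generate_mfc_series(
            cfg, {"blank1": 1.0, "x": 2.0})
        recs = electrochem.amplification(
            [electrochem.power_density(s) for s in series])
        amp = {r.condition_id: r.amplification for r in recs}
        assert amp["x"] == pytest.approx(2.0, rel=1e-12)

    def test_noisy_amplification_recovery(self):
        from teashuttle import electrochem
        cfg = simulate.small_test_config(9, mfc_voltage_noise_sd=0.001)
        series, truth = simulate.generate_mfc_series(cfg)
        recs = electrochem.amplification(
            [electrochem.power_density(s) for s in series])
        for r in recs:
            assert r.amplification == pytest.approx(
                truth.mfc_amplification[r.condition_id], rel=0.05)

    def test_loop_area_closed_form(self):
        from teashuttle import electrochem
        cfg = simulate.small_test_config(10)
        vg = simulate.generate_voltammogram(cfg, n_cycles=1)
        expected = simulate.gaussian_pair_loop_area(
            cfg.cv_peak_current, 0.15, cfg.cv_capacitive_gap, -1.5, 1.5)
        assert electrochem.cv_loop_area(vg, 1) == pytest.approx(
            expected, rel=1e-3)
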