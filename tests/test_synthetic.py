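"""Synthetic panel, query, plate and study generation."""

import numpy as np
import pandas as pd
import pytest

from fishauth import taxa
from fishauth.barcode import percent_identity
from fishauth.synthetic import (
    BARCODE_LENGTH,
    DivergenceSpecError,
    SimulationConfig,
    simulate_metadata,
    simulate_plate,
    simulate_plates,
    simulate_queries,
    simulate_reference_panel,
    simulate_study,
)
from fishauth.tree import p_distance


class TestReferencePanel:
    def test_zero_divergence_pair_is_identical(self):
        panel = simulate_reference_panel(
            [("Sp a", "g"), ("Sp b", "g")], {("Sp a", "Sp b"): 0.0}, length=300, seed=1
        )
        a, b = panel.records
        assert a.sequence == b.sequence
        assert percent_identity(a.sequence, b.sequence) == 1.0

    def test_two_percent_target_gives_thirteen_sites(self):
        panel = simulate_reference_panel(
            [("Sp a", "ga"), ("Sp b", "gb")], {("Sp a", "Sp b"): 0.02}, length=655, seed=1
        )
        a, b = panel.records
        mismatches = sum(x != y for x, y in zip(a.sequence, b.sequence))
        assert abs(mismatches - 0.02 * 655) <= 3  # 13.1 expected

    def test_default_panel_divergences_hit_targets(self, panel):
        targets = taxa.default_divergence_spec()
        for (sa, sb), target in targets.items():
            realized = p_distance(
                panel.record_for_species(sa).sequence,
                panel.record_for_species(sb).sequence,
            )
            assert abs(realized - target) <= 0.005

    def test_congeners_identical_and_cross_groups_diverged(self, panel):
        by_group = {}
        for rec in panel.records:
            by_group.setdefault(rec.group, []).append(rec.sequence)
        for seqs in by_group.values():
            assert len(set(seqs)) == 1
        groups = list(by_group)
        for i, ga in enumerate(groups):
            for gb in groups[i + 1 :]:
                ident = percent_identity(by_group[ga][0], by_group[gb][0])
                assert ident < 0.98  # > 2% divergence everywhere

    def test_sequences_use_acgt_only(self, panel):
        for rec in panel.records:
            assert set(rec.sequence) <= set("ACGT")
            assert len(rec.sequence) == BARCODE_LENGTH

    def test_triangle_violation_reports_triple(self):
        spec = {
            ("Sp a", "Sp b"): 0.2,
            ("Sp a", "Sp c"): 0.01,
            ("Sp b", "Sp c"): 0.01,
        }
        with pytest.raises(DivergenceSpecError, match="triangle"):
            simulate_reference_panel(
                [("Sp a", "ga"), ("Sp b", "gb"), ("Sp c", "gc")], spec, length=655, seed=0
            )

    def test_zero_divergence_across_groups_rejected(self):
        with pytest.raises(DivergenceSpecError, match="different groups"):
            simulate_reference_panel(
                [("Sp a", "ga"), ("Sp b", "gb")], {("Sp a", "Sp b"): 0.0}, length=300, seed=0
            )

    def test_deterministic_under_seed(self):
        p1 = simulate_reference_panel(seed=42)
        p2 = simulate_reference_panel(seed=42)
        assert [r.sequence for r in p1.records] == [r.sequence for r in p2.records]


class TestQueries:
    def test_zero_error_rate_reproduces_reference(self, panel):
        config = SimulationConfig(seed=3, n_samples=5, chimera_fraction=0.0)
        _, truth = simulate_metadata(config)
        queries = simulate_queries(panel, truth, seq_error_rate=0.0, seed=1)
        for sid, row in truth.iterrows():
            ref = panel.record_for_species(row["true_species"]).sequence
            assert queries[f"{sid}/rep1"] == ref
            assert queries[f"{sid}/rep2"] == ref

    def test_error_rate_mean_matches_expectation(self, panel):
        """Mean mismatch count over 1000 replicates ~ 655 * 0.002 = 1.31."""
        config = SimulationConfig(
            seed=3, n_samples=500, chimera_fraction=0.0, mislabel_matrix={}
        )
        _, truth = simulate_metadata(config)
        queries = simulate_queries(panel, truth, seq_error_rate=0.002, seed=9)
        refs = {
            sp: panel.record_for_species(sp).sequence
            for sp in truth["true_species"].unique()
        }
        counts = [
            sum(x != y for x, y in zip(seq, refs[truth.loc[qid.split("/")[0], "true_species"]]))
            for qid, seq in queries.items()
        ]
        assert len(counts) == 1000
        assert abs(np.mean(counts) - 1.31) <= 0.2

    def test_chimera_with_single_component_rejected(self, panel):
        config = SimulationConfig(seed=3, n_samples=3, chimera_fraction=1.0)
        _, truth = simulate_metadata(config)
        truth.loc[truth.index[0], "chimera_components"] = "Gadus morhua"
        with pytest.raises(ValueError, match="2 component"):
            simulate_queries(panel, truth, 0.0, seed=1)

    def test_replicate_mode_puts_one_component_per_replicate(self, panel):
        config = SimulationConfig(
            seed=6, n_samples=20, chimera_fraction=1.0, chimera_mode="replicates"
        )
        _, truth = simulate_metadata(config)
        queries = simulate_queries(panel, truth, 0.0, seed=2)
        for sid, row in truth.iterrows():
            comp1, comp2 = row["chimera_components"].split("+")
            assert queries[f"{sid}/rep1"] == panel.record_for_species(comp1).sequence
            assert queries[f"{sid}/rep2"] == panel.record_for_species(comp2).sequence


class TestMetadata:
    def test_planted_rate_unbiased_over_seeds(self, rules):
        """Mean realised planted rate is within 2 MC standard errors of
        the configured expectation."""
        config = SimulationConfig(seed=0, n_samples=371)
        expect = config.expected_mislabel_rate(rules)
        rates = []
        for seed in range(400):
            _, truth = simulate_metadata(config, seed=seed)
            rates.append(truth["planted_mislabel"].mean())
        rates = np.asarray(rates)
        se = rates.std(ddof=1) / np.sqrt(len(rates))
        assert abs(rates.mean() - expect) <= 2 * se + 1e-12

    def test_empty_study_is_valid(self):
        config = SimulationConfig(seed=1, n_samples=0)
        study = simulate_study(config)
        assert study.samples == [] and len(study.truth) == 0
        assert study.queries == {}

    def test_bad_distributions_rejected(self):
        with pytest.raises(ValueError, match="sums to"):
            SimulationConfig(label_distribution={("Cod", "NA"): 0.5})
        with pytest.raises(ValueError, match="chimera_fraction"):
            SimulationConfig(chimera_fraction=1.5)

    def test_chimera_components_listed_iff_chimeric(self):
        config = SimulationConfig(seed=4, n_samples=200, chimera_fraction=0.3)
        _, truth = simulate_metadata(config)
        chimeric = truth["is_chimera"]
        assert (truth.loc[chimeric, "chimera_components"].str.contains("\\+")).all()
        assert (truth.loc[~chimeric, "chimera_components"] == "").all()


class TestPlates:
    def test_plate_layout_and_roles(self):
        config = SimulationConfig(seed=5, n_samples=30)
        samples, truth = simulate_metadata(config)
        plate = simulate_plate(samples, truth, config, seed=1)
        assert len(plate.wells("NTC")) == 8
        assert len(plate.wells("POS_COD")) == 2
        assert len(plate.wells("POS_HAD")) == 2
        assert len(plate.wells("SAMPLE")) == 30

    def test_target_well_endpoint_near_plateau(self):
        config = SimulationConfig(seed=5, n_samples=0)
        amp = config.amplification
        # a morhua-template well on the COD dye rises above A/2
        samples, truth = simulate_metadata(
            SimulationConfig(seed=5, n_samples=20, chimera_fraction=0.0)
        )
        plate = simulate_plate(samples, truth, SimulationConfig(seed=5), seed=1)
        ep = plate.endpoint_table()
        for row in ep[ep["role"] == "SAMPLE"].itertuples():
            is_target = (
                taxa.DYE_TARGETS[row.dye] == truth.loc[row.sample_id, "true_species"]
            )
            if is_target:
                assert row.delta_rn >= amp.plateau / 2
            else:
                assert abs(row.delta_rn - 0.05) <= 4 * 0.02  # bleed +- 4 sd

    def test_ntc_endpoints_near_bleed_offset(self):
        config = SimulationConfig(seed=5, n_samples=10)
        samples, truth = simulate_metadata(config)
        plate = simulate_plate(samples, truth, config, seed=1)
        for dye in plate.dyes:
            values = plate.ntc_endpoints(dye)
            assert np.all(np.abs(values - config.bleed_offset) <= 4 * config.ntc_noise_sd)

    def test_more_than_capacity_split_across_plates(self):
        config = SimulationConfig(seed=5, n_samples=200)
        samples, truth = simulate_metadata(config)
        plates = simulate_plates(samples, truth, config, seed=1)
        assert len(plates) == 3  # 84 + 84 + 32
        with pytest.raises(ValueError, match="capacity"):
            simulate_plate(samples, truth, config, seed=1)

    def test_fewer_than_eight_ntcs_refused(self):
        config = SimulationConfig(seed=5, n_samples=5)
        samples, truth = simulate_metadata(config)
        with pytest.raises(ValueError, match="NTC"):
            simulate_plate(samples, truth, config, seed=1, n_ntc=7)


class TestDeterminism:
    def test_identical_config_gives_byte_identical_study(self, tmp_path):
        config = SimulationConfig(seed=99, n_samples=50)
        a, b = simulate_study(config), simulate_study(config)
        assert a.queries == b.queries
        pd.testing.assert_frame_equal(a.truth, b.truth)
        for pa, pb in zip(a.plates, b.plates):
            pd.testing.assert_frame_equal(pa.df, pb.df)
        da, db = tmp_path / "a", tmp_path / "b"
        a.write(da)
        b.write(db)
        for f in sorted(da.iterdir()):
            assert f.read_bytes() == (db / f.name).read_bytes()
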