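"""Synthetic-study generator: determinism, truth consistency, calibration."""

import numpy as np
import pandas as pd
import pytest

from qdtherm import (AnomalySpec, RunConfig, SyntheticConfig,
                     ThermometryAssay, generate_study, inject_qc_anomalies)
from qdtherm.simulate import SimulationError


class TestDeterminism:
    def test_same_seed_identical_tables(self):
        a = generate_study(SyntheticConfig(seed=5, n_animals_per_group=2))
        b = generate_study(SyntheticConfig(seed=5, n_animals_per_group=2))
        pd.testing.assert_frame_equal(a.kinetics, b.kinetics)
        pd.testing.assert_frame_equal(a.a280, b.a280)
        pd.testing.assert_frame_equal(a.truth.replicates, b.truth.replicates)

    def test_same_seed_identical_files(self, tmp_path):
        for name in ("one", "two"):
            generate_study(SyntheticConfig(seed=9, n_animals_per_group=2)
                           ).write(tmp_path / name)
        for f in (tmp_path / "one").iterdir():
            assert f.read_bytes() == (tmp_path / "two" / f.name).read_bytes()

    def test_different_seeds_differ(self):
        a = generate_study(SyntheticConfig(seed=1, n_animals_per_group=2))
        b = generate_study(SyntheticConfig(seed=2, n_animals_per_group=2))
        assert not a.kinetics.equals(b.kinetics)


class TestStructure:
    def test_schema_and_counts(self, default_dataset):
        cfg = default_dataset.config
        n_preps = 2 * cfg.n_animals_per_group * cfg.preps_per_animal
        n_wells = n_preps * 2 * cfg.replicates
        assert default_dataset.kinetics.shape == (cfg.n_timepoints,
                                                  n_wells + 1)
        assert len(default_dataset.layout) == n_wells
        assert len(default_dataset.metadata) == n_preps
        assert len(default_dataset.densitometry) == 2 * n_preps

    def test_truth_index_identity(self, default_dataset):
        """index = (rho_atp - rho_blank)/concentration holds exactly."""
        reps = default_dataset.truth.replicates
        implied = (reps["true_rho_atp"] - reps["true_rho_blank"]) \
            / reps["true_concentration_mg_per_ml"]
        np.testing.assert_allclose(implied, reps["true_index"], rtol=1e-12)

    def test_noise_regimes_ordered(self):
        with pytest.raises(SimulationError):
            SyntheticConfig(noise_sd_early=0.02, noise_sd_late=0.01)

    def test_negative_mean_config_rejected(self):
        with pytest.raises(SimulationError):
            SyntheticConfig(group_index_means=(-0.1, 1.0))


class TestZeroNoiseRecovery:
    def test_pipeline_recovers_truth_within_estimator_bias(self):
        """With no noise and no biological spread, every recovered index
        matches ground truth within the documented degree-2 bias bound."""
        cfg = SyntheticConfig(
            seed=0, n_animals_per_group=1, replicates=6,
            group_index_means=(0.5, 0.5), group_index_sds=(0.0, 0.0),
            noise_sd_early=0.0, noise_sd_late=0.0,
            blank_rate_mean=0.0, concentration_cv=0.0,
            a280_reading_sd=0.0)
        ds = generate_study(cfg)
        res = ThermometryAssay.from_synthetic(ds).fit()
        truth = ds.truth.replicates.set_index(
            ["preparation_id", "replicate_index"])
        for rec in res.records:
            true_idx = truth.loc[(rec.preparation_id, rec.replicate_index),
                                 "true_index"]
            assert rec.efficiency_index == pytest.approx(true_idx, rel=0.05)


class TestAnomalies:
    def make(self, spec):
        ds = generate_study(SyntheticConfig(seed=3, n_animals_per_group=2))
        return inject_qc_anomalies(ds, spec)

    def test_planted_negative_excluded_as_negative(self):
        ds = self.make(AnomalySpec(n_negative=1))
        res = ThermometryAssay.from_synthetic(ds).fit()
        planted = ds.truth.replicates.query("planted == 'negative'")
        by_key = {(r.preparation_id, r.replicate_index): r
                  for r in res.records}
        for _, row in planted.iterrows():
            rec = by_key[(row["preparation_id"], row["replicate_index"])]
            assert rec.qc_status == "excluded_negative"

    def test_planted_outlier_excluded_outside_sd(self):
        ds = self.make(AnomalySpec(n_outlier=1))
        res = ThermometryAssay.from_synthetic(ds).fit()
        planted = ds.truth.replicates.query("planted == 'outlier'")
        by_key = {(r.preparation_id, r.replicate_index): r
                  for r in res.records}
        for _, row in planted.iterrows():
            rec = by_key[(row["preparation_id"], row["replicate_index"])]
            # a 10x-group-mean replicate must deviate by > 1 sample SD
            assert rec.qc_status == "excluded_outside_sd"

    def test_over_planting_rejected(self):
        ds = generate_study(SyntheticConfig(seed=3, n_animals_per_group=2))
        with pytest.raises(SimulationError):
            inject_qc_anomalies(ds, AnomalySpec(n_negative=3, n_outlier=2))

    def test_truth_ledger_tags_planted_wells(self):
        ds = self.make(AnomalySpec(n_negative=1, n_outlier=1))
        counts = ds.truth.replicates["planted"].value_counts()
        n_preps = len(ds.truth.preparations)
        assert counts.get("negative", 0) == n_preps
        assert counts.get("outlier", 0) == n_preps

    def test_clean_sextuplicates_keep_most_replicates(self):
        """Without planted anomalies at default noise, QC never decimates
        a preparation: nearly every prep keeps at least 2 of 6 replicates
        and close to 4 survive on average (the strict 1-SD band alone
        trims ~1.9 of 6 i.i.d. replicates in expectation; natural
        negatives in the low-index group add a little more)."""
        included = []
        for seed in range(30):
            ds = generate_study(SyntheticConfig(
                seed=seed, n_animals_per_group=2))
            res = ThermometryAssay.from_synthetic(ds).fit()
            included.extend(p.n_included for p in res.preparations)
        included = np.array(included)
        assert (included >= 2).mean() >= 0.95
        assert included.mean() >= 3.5
        assert (included >= 1).all()  # no preparation failed outright


class TestCalibration:
    def test_animal_mean_dispersion_matches_group_sd(self):
        """The realised dispersion of per-animal mean true indices matches
        the configured group SDs within 15 % (many seeds pooled)."""
        con, exp = [], []
        for seed in range(300):
            cfg = SyntheticConfig(seed=seed)
            ds = generate_study(cfg)
            reps = ds.truth.replicates.merge(
                ds.truth.preparations[["preparation_id", "group",
                                       "animal_id"]], on="preparation_id")
            means = reps.groupby(["group", "animal_id"])["true_index"].mean()
            con.extend(means["CON"].values)
            exp.extend(means["EXP"].values)
        assert np.std(con, ddof=1) == pytest.approx(0.25, rel=0.15)
        assert np.std(exp, ddof=1) == pytest.approx(0.44, rel=0.15)
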