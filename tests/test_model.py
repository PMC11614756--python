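"""The assay Model/Results surface: fitting, stratified comparison, output."""

import numpy as np
import pytest

import matplotlib

matplotlib.use("Agg")

from qdtherm import RunConfig, SyntheticConfig, ThermometryAssay, \
    generate_study
from qdtherm.isoforms import HIGH_IIA, MAIN


@pytest.fixture(scope="module")
def fitted(default_dataset):
    return ThermometryAssay.from_synthetic(default_dataset).fit()


class TestFit:
    def test_record_count_matches_atp_wells(self, default_dataset, fitted):
        n_atp = (default_dataset.layout["condition"] == "ATP").sum()
        assert len(fitted.records) == n_atp

    def test_qc_statuses_partition_records(self, fitted):
        statuses = {r.qc_status for r in fitted.records}
        assert statuses <= {"included", "excluded_negative",
                            "excluded_outside_sd"}
        n_inc = sum(r.included for r in fitted.records)
        n_exc = sum(not r.included for r in fitted.records)
        assert n_inc + n_exc == len(fitted.records)

    def test_group_summaries_present(self, fitted):
        assert fitted.group_summary("CON") is not None
        assert fitted.group_summary("EXP") is not None
        assert fitted.group_summary("CON").n_animals == 5

    def test_group_means_separate_in_expected_direction(self, fitted):
        con = fitted.group_summary("CON").mean_index
        exp = fitted.group_summary("EXP").mean_index
        assert exp > con  # steeper decay, lower efficiency after ICU exposure

    def test_summary_text_mentions_key_quantities(self, fitted):
        text = fitted.summary()
        assert "t-test" in text
        assert "CON" in text and "EXP" in text
        assert "lower myosin efficiency" in text

    def test_records_frame_shape(self, fitted):
        df = fitted.records_frame()
        assert len(df) == len(fitted.records)
        assert "efficiency_index" in df.columns


class TestScaleInvariance:
    def test_end_to_end_raw_intensity_rescaling(self, default_dataset):
        """Multiplying every raw fluorescence value by a constant changes
        no efficiency index beyond floating rounding."""
        base = ThermometryAssay.from_synthetic(default_dataset).fit()
        scaled_ds = default_dataset.scale_intensities(7.3)
        scaled = ThermometryAssay.from_synthetic(scaled_ds).fit()
        a = np.array([r.efficiency_index for r in base.records])
        b = np.array([r.efficiency_index for r in scaled.records])
        np.testing.assert_allclose(b, a, rtol=1e-9)
        assert [r.qc_status for r in base.records] == \
            [r.qc_status for r in scaled.records]


@pytest.fixture(scope="module")
def high_iia_fit():
    ds = generate_study(SyntheticConfig(seed=21, n_high_iia_animals=2))
    return ds, ThermometryAssay.from_synthetic(ds).fit()


class TestStratifiedComparison:

    def test_high_iia_preps_form_separate_stratum(self, high_iia_fit):
        ds, res = high_iia_fit
        high = {p for p, s in res.strata.items() if s == HIGH_IIA}
        truth_high = set(ds.truth.preparations.loc[
            ds.truth.preparations["fraction_IIa"] > 0.10, "preparation_id"])
        assert high == truth_high
        assert len(high) == 2

    def test_main_comparison_excludes_high_iia_preps(self, high_iia_fit):
        _, res = high_iia_fit
        assert res.comparison is not None
        exp_main = [a for a in res.animals
                    if a.group == "EXP" and a.stratum == MAIN]
        assert res.comparison.n_b == len(exp_main) == 3

    def test_high_iia_stratum_reported_separately(self, high_iia_fit):
        _, res = high_iia_fit
        gs = res.group_summary("EXP", stratum=HIGH_IIA)
        assert gs is not None and gs.n_animals == 2

    def test_whole_animal_exclusion_flag(self):
        ds = generate_study(SyntheticConfig(
            seed=21, n_high_iia_animals=2, preps_per_animal=2))
        cfg = RunConfig(exclude_whole_animal_high_iia=True)
        res = ThermometryAssay.from_synthetic(ds, cfg).fit()
        high_animals = {a.animal_id for a in res.animals
                        if a.stratum == HIGH_IIA}
        main_exp = [a for a in res.animals
                    if a.group == "EXP" and a.stratum == MAIN
                    and a.animal_id not in high_animals]
        assert res.comparison.n_b == len(main_exp)


class TestDegenerateStudies:
    def test_too_few_animals_yields_no_comparison(self):
        ds = generate_study(SyntheticConfig(seed=2, n_animals_per_group=1))
        res = ThermometryAssay.from_synthetic(ds).fit()
        assert res.comparison is None
        assert any("fewer than 2 animals" in w for w in res.warnings)


class TestPlots:
    def test_plot_smoke(self, default_dataset, fitted):
        assay = ThermometryAssay.from_synthetic(default_dataset)
        fig1, _ = fitted.plot_traces(assay.traces)
        fig2, _ = fitted.plot_indices()
        assert fig1.axes and fig2.axes
        import matplotlib.pyplot as plt
        plt.close("all")
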