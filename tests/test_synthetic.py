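"""Generator contracts: determinism, noise degeneracy, sampling structure."""

import numpy as np
import pandas as pd
import pytest

from rumenbatch import presets, synthetic
from rumenbatch.errors import InvalidInputError


def small_config(**kw):
    defaults = dict(n_bottles_per_treatment=2, n_runs=1, n_blanks=2, seed=42)
    defaults.update(kw)
    return synthetic.SyntheticConfig(**defaults)


def spec_with(means, sds=None, label="T", **kw):
    sds = sds if sds is not None else {k: 0.0 for k in means}
    defaults = dict(label=label, endpoint_means=means, endpoint_sds=sds,
                    gas_asymptote_ml=58.5, gas_rate_per_h=0.15)
    defaults.update(kw)
    return synthetic.TreatmentSpec(**defaults)


class TestValidation:
    def test_nonpositive_rate_rejected(self):
        with pytest.raises(InvalidInputError):
            spec_with({"ph": 6.8}, gas_rate_per_h=0.0)

    def test_sd_required_for_every_mean(self):
        with pytest.raises(InvalidInputError):
            synthetic.TreatmentSpec(label="T", endpoint_means={"ph": 6.8},
                                    endpoint_sds={}, gas_asymptote_ml=1.0,
                                    gas_rate_per_h=0.1)

    def test_ch4_fraction_bounds(self):
        with pytest.raises(InvalidInputError):
            spec_with({"ph": 6.8}, ch4_fraction_curve=1.2)

    def test_timepoints_must_increase(self):
        with pytest.raises(InvalidInputError):
            small_config(timepoints_h=(3, 3, 6))

    def test_mismatched_quantity_sets_rejected(self):
        s1 = spec_with({"ph": 6.8}, label="A")
        s2 = spec_with({"mcp": 4.0}, label="B")
        with pytest.raises(InvalidInputError):
            synthetic.generate_endpoint_tables(small_config(), [s1, s2])


class TestGasTimecourse:
    def test_zero_noise_reaches_asymptote(self):
        cfg = small_config(gas_noise_cv=0.0, n_blanks=0,
                           blank_asymptote_ml=0.0)
        df = synthetic.generate_gas_timecourse(cfg, spec_with({"ph": 6.8}))
        total = df[df["bottle_id"] == "T-r1-b1"]["volume_mL"].sum()
        assert total == pytest.approx(58.5 * (1 - np.exp(-0.15 * 72)),
                                      rel=1e-12)
        assert total == pytest.approx(58.5, abs=1e-2)

    def test_exact_blank_cancellation_without_noise(self):
        cfg = small_config(gas_noise_cv=0.0, n_blanks=3)
        df = synthetic.generate_gas_timecourse(cfg, spec_with({"ph": 6.8}))
        blanks = df[df["is_blank"]]
        bottle = df[df["bottle_id"] == "T-r1-b1"].set_index("time_h")
        blank_mean = blanks.groupby("time_h")["volume_mL"].mean()
        net = bottle["volume_mL"] - blank_mean
        cfg0 = small_config(gas_noise_cv=0.0, n_blanks=0,
                            blank_asymptote_ml=0.0)
        df0 = synthetic.generate_gas_timecourse(cfg0, spec_with({"ph": 6.8}))
        expected = df0[df0["bottle_id"] == "T-r1-b1"].set_index("time_h")
        assert np.allclose(net, expected["volume_mL"])

    def test_determinism_byte_identical(self):
        spec = spec_with({"ph": 6.8}, sds={"ph": 0.2})
        a = synthetic.generate_gas_timecourse(small_config(), spec)
        b = synthetic.generate_gas_timecourse(small_config(), spec)
        assert a.to_csv() == b.to_csv()

    def test_substreams_independent_of_other_tables(self):
        """Gas draws are identical whether or not endpoint tables are made."""
        spec = spec_with({"ph": 6.8}, sds={"ph": 0.2})
        cfg = small_config()
        alone = synthetic.generate_gas_timecourse(cfg, spec)
        synthetic.generate_endpoint_tables(cfg, [spec])
        again = synthetic.generate_gas_timecourse(cfg, spec)
        pd.testing.assert_frame_equal(alone, again)


class TestEndpointTables:
    def test_zero_sd_returns_means_exactly(self):
        means = {"ph": 6.83, "acetate": 38.3, "alanine": 131.0,
                 "bacteria": 11.9}
        tables = synthetic.generate_endpoint_tables(
            small_config(ct_noise_sd=0.0), [spec_with(means)])
        assert (tables["chemistry"]["ph"] == 6.83).all()
        assert (tables["chemistry"]["acetate"] == 38.3).all()
        assert (tables["amino_acids"]["alanine"] == 131.0).all()

    def test_truncation_no_negatives(self):
        means = {"x": 0.0}
        tables = synthetic.generate_endpoint_tables(
            small_config(n_bottles_per_treatment=200),
            [spec_with(means, sds={"x": 1.0})])
        assert (tables["chemistry"]["x"] >= 0).all()

    def test_law_of_large_numbers_on_published_means(self):
        cfg = synthetic.SyntheticConfig(n_bottles_per_treatment=200,
                                        n_runs=1, seed=7)
        specs = synthetic.default_treatment_specs()
        tables = synthetic.generate_endpoint_tables(cfg, specs)
        chem = tables["chemistry"]
        for trt in presets.TREATMENTS:
            sub = chem[chem["treatment"] == trt]
            for q, (by_trt, sem) in presets.CHEMISTRY.items():
                sd = presets.sd_from_sem(sem)
                tol = 3 * sd / np.sqrt(200) + 1e-9
                assert abs(sub[q].mean() - by_trt[trt]) < tol, (trt, q)

    def test_qpcr_plate_shape(self):
        means = {"bacteria": 11.9, "methanogens": 10.0}
        tables = synthetic.generate_endpoint_tables(
            small_config(), [spec_with(means, sds={k: 0.03 for k in means})])
        plate = tables["qpcr"]
        assert set(plate["role"]) == {"standard", "unknown"}
        assert (plate[plate["role"] == "standard"]
                .groupby("target_group").size() == 6).all()
        # one unknown per bottle per group
        assert (plate["role"] == "unknown").sum() == 2 * 2


class TestOtuTable:
    def test_row_sums_equal_depth(self):
        comps = {"A": [0.5, 0.3, 0.2], "B": [0.2, 0.3, 0.5]}
        table = synthetic.generate_otu_table(small_config(), comps, depth=500,
                                             n_samples_per_group=4)
        counts = table.drop(columns=["sample_id", "group"])
        assert (counts.sum(axis=1) == 500).all()

    def test_single_taxon_composition(self):
        table = synthetic.generate_otu_table(
            small_config(), {"A": [1.0, 0.0], "B": [1.0, 0.0]}, depth=123,
            n_samples_per_group=3)
        counts = table.drop(columns=["sample_id", "group"])
        assert (counts.iloc[:, 0] == 123).all()
        assert (counts.iloc[:, 1] == 0).all()

    def test_binomial_limit_without_overdispersion(self):
        table = synthetic.generate_otu_table(
            small_config(), {"A": [0.5, 0.5]}, depth=1000,
            overdispersion=np.inf, n_samples_per_group=500)
        counts = table.drop(columns=["sample_id", "group"])
        tol = 3 * np.sqrt(250.0) / np.sqrt(500)
        assert abs(counts.iloc[:, 0].mean() - 500.0) < tol

    def test_negative_probability_rejected(self):
        with pytest.raises(InvalidInputError):
            synthetic.generate_otu_table(small_config(),
                                         {"A": [1.5, -0.5]}, depth=10)

    def test_composition_must_sum_to_one(self):
        with pytest.raises(InvalidInputError):
            synthetic.generate_otu_table(small_config(),
                                         {"A": [0.5, 0.4]}, depth=10)

    def test_determinism(self):
        comps = presets.group_compositions()
        a = synthetic.generate_otu_table(small_config(), comps, depth=200)
        b = synthetic.generate_otu_table(small_config(), comps, depth=200)
        pd.testing.assert_frame_equal(a, b)


def test_default_specs_cover_all_published_quantities():
    specs = synthetic.default_treatment_specs()
    assert [s.label for s in specs] == list(presets.TREATMENTS)
    names = set(specs[0].endpoint_means)
    assert set(presets.CHEMISTRY) <= names
    assert set(presets.AMINO_ACIDS) <= names
    assert set(presets.MICROBES_LOG10) <= names
    for spec in specs:
        frac = np.atleast_1d(np.asarray(spec.ch4_fraction_curve, float))[0]
        assert 0 < frac < 0.2
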