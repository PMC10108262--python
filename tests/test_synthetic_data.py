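"""Simulator structure: determinism, variance components, record round-trips."""

import logging

import numpy as np
import pandas as pd
import pytest

from tpcgrowth.fit import DEFAULT_PROPORTIONAL_EFFECTS, TPCFixedEffects
from tpcgrowth.growth import dry_mass_from_gut_length
from tpcgrowth.synthetic import (
    GeneratingModel,
    SchemaError,
    StudyDesign,
    compute_rate_table,
    default_absolute_model,
    default_proportional_model,
    generate_growth_table,
    generate_individual_records,
    read_rate_table,
    read_records,
    write_rate_table,
    write_records,
)


class TestStudyDesign:
    def test_default_matches_experimental_layout(self, default_design):
        assert len(default_design.populations) == 3
        assert default_design.clones_per_population == 10
        assert default_design.temperatures == (12.0, 15.0, 17.0, 19.0, 22.0, 24.0, 26.0)
        assert default_design.replicates_per_clone_per_temperature == 8
        assert default_design.n_individuals == 1680

    @pytest.mark.parametrize("kwargs", [
        {"clones_per_population": 0},
        {"replicates_per_clone_per_temperature": 0},
        {"temperatures": (12.0, 12.0)},
        {"temperatures": (15.0, 12.0)},
    ])
    def test_invalid_design_rejected(self, kwargs):
        with pytest.raises(ValueError):
            StudyDesign(**kwargs)


class TestGeneratingModel:
    @pytest.mark.parametrize("kwargs", [
        {"sd_clone_intercept": -0.1}, {"sd_residual": -1.0},
        {"corr_intercept_slope": 1.5},
    ])
    def test_invalid_model_rejected(self, kwargs, proportional_model):
        base = dict(
            fixed=proportional_model.fixed,
            sd_clone_intercept=proportional_model.sd_clone_intercept,
            sd_clone_slope=proportional_model.sd_clone_slope,
            sd_residual=proportional_model.sd_residual,
        )
        base.update(kwargs)
        with pytest.raises(ValueError):
            GeneratingModel(**base)

    def test_population_missing_from_fixed_effects(self, default_design, proportional_model):
        model = GeneratingModel(
            fixed=TPCFixedEffects(scale="proportional",
                                  coefficients={"Norway": (0.1674, 0.0235, -0.0002)}),
            sd_clone_intercept=0.0, sd_clone_slope=0.0, sd_residual=0.01,
        )
        with pytest.raises(ValueError, match="Belgium"):
            generate_growth_table(default_design, model, seed=1)


class TestGrowthTable:
    def test_seed_determinism_byte_identical(self, small_design, proportional_model):
        a = generate_growth_table(small_design, proportional_model, seed=42)
        b = generate_growth_table(small_design, proportional_model, seed=42)
        assert a.to_csv(index=False) == b.to_csv(index=False)
        c = generate_growth_table(small_design, proportional_model, seed=43)
        assert not a["growth_rate"].equals(c["growth_rate"])

    def test_design_conservation(self, default_design, proportional_model):
        table = generate_growth_table(default_design, proportional_model, seed=0)
        assert len(table) == 1680
        counts = table.groupby(["population", "clone", "temperature_C"]).size()
        assert (counts == 8).all()

    def test_zero_noise_rows_equal_population_intercept_at_center(
        self, default_design, noiseless_model
    ):
        table = generate_growth_table(default_design, noiseless_model, seed=5)
        at12 = table[table["temperature_C"] == 12.0]
        for pop, (a, _, _) in DEFAULT_PROPORTIONAL_EFFECTS.coefficients.items():
            vals = at12.loc[at12["population"] == pop, "growth_rate"]
            assert np.allclose(vals, a, atol=1e-12), pop
        norway12 = at12.loc[at12["population"] == "Norway", "growth_rate"]
        assert np.allclose(norway12, 0.1674)

    def test_residual_sd_recovered(self, default_design):
        model = GeneratingModel(
            fixed=DEFAULT_PROPORTIONAL_EFFECTS,
            sd_clone_intercept=0.0, sd_clone_slope=0.0, sd_residual=0.02,
        )
        table = generate_growth_table(default_design, model, seed=11)
        tc = table["temperature_C"] - 12.0
        expected = np.array([
            DEFAULT_PROPORTIONAL_EFFECTS.predict(p, t)
            for p, t in zip(table["population"], table["temperature_C"])
        ])
        resid = table["growth_rate"].to_numpy() - expected
        n = len(resid)
        mc_se = 0.02 / np.sqrt(2 * n)
        assert abs(resid.std(ddof=0) - 0.02) < 3 * mc_se

    def test_clone_variance_components_recovered(self):
        """With residual noise off, per-clone regressions recover the clone
        deviations exactly; their sample SDs estimate the generating SDs."""
        design = StudyDesign(
            populations=("Norway",), clones_per_population=500,
            replicates_per_clone_per_temperature=1,
        )
        model = GeneratingModel(
            fixed=DEFAULT_PROPORTIONAL_EFFECTS,
            sd_clone_intercept=0.0019, sd_clone_slope=0.0023, sd_residual=0.0,
        )
        table = generate_growth_table(design, model, seed=21)
        tc = table["temperature_C"].to_numpy() - 12.0
        dev = table["growth_rate"].to_numpy() - DEFAULT_PROPORTIONAL_EFFECTS.predict(
            "Norway", table["temperature_C"].to_numpy()
        )
        ints, slopes = [], []
        for _, grp in pd.DataFrame({"clone": table["clone"], "tc": tc, "dev": dev}).groupby("clone"):
            coef = np.polyfit(grp["tc"], grp["dev"], 1)
            slopes.append(coef[0])
            ints.append(coef[1])
        n = len(ints)
        for sample, sd_true in ((ints, 0.0019), (slopes, 0.0023)):
            mc_se = sd_true / np.sqrt(2 * n)
            assert abs(np.std(sample, ddof=1) - sd_true) < 3 * mc_se
        # deviations drawn once per clone: exact linearity within clone
        grp0 = table[table["clone"] == table["clone"].iloc[0]]
        resid = np.polyval(
            np.polyfit(grp0["temperature_C"] - 12.0, grp0["growth_rate"], 2),
            grp0["temperature_C"] - 12.0,
        ) - grp0["growth_rate"]
        assert np.max(np.abs(resid)) < 1e-12


class TestIndividualRecords:
    def test_rates_recomputed_from_records_match_latent(self, small_design, proportional_model):
        records = generate_individual_records(small_design, proportional_model, seed=9)
        latent = generate_growth_table(small_design, proportional_model, seed=9)
        rates = compute_rate_table(records, scale="proportional")
        np.testing.assert_allclose(
            rates["growth_rate"].to_numpy(), latent["growth_rate"].to_numpy(), rtol=1e-10
        )

    def test_known_growth_round_trip(self):
        """GL 1 -> 2 mm over 10 d corresponds to g = 2.75*ln(2)/10."""
        records = pd.DataFrame({
            "population": ["Norway"], "clone": ["Norway-c01"], "temperature_C": [17.0],
            "gut_length_neonate_mm": [1.0], "gut_length_mature_mm": [2.0],
            "age_at_maturity_days": [10.0], "survived": [True],
        })
        rates = compute_rate_table(records, scale="proportional")
        assert rates["growth_rate"].iloc[0] == pytest.approx(2.75 * np.log(2) / 10, rel=1e-12)
        assert rates["growth_rate"].iloc[0] == pytest.approx(0.1906, abs=5e-5)

    def test_mass_ratio_under_known_rate(self, small_design):
        """g = 0.1 /d over 10 d multiplies dry mass by e."""
        model = GeneratingModel(
            fixed=TPCFixedEffects(
                scale="proportional",
                coefficients={p: (0.1, 0.0, 0.0) for p in small_design.populations},
            ),
            sd_clone_intercept=0.0, sd_clone_slope=0.0, sd_residual=0.0,
        )
        records = generate_individual_records(
            small_design, model, seed=2, maturity_model=lambda T: 10.0, age_cv=0.0,
        )
        m0 = dry_mass_from_gut_length(records["gut_length_neonate_mm"].to_numpy())
        m1 = dry_mass_from_gut_length(records["gut_length_mature_mm"].to_numpy())
        np.testing.assert_allclose(m1 / m0, np.e, rtol=1e-10)

    def test_zero_growth_keeps_size(self, small_design):
        model = GeneratingModel(
            fixed=TPCFixedEffects(
                scale="proportional",
                coefficients={p: (0.0, 0.0, 0.0) for p in small_design.populations},
            ),
            sd_clone_intercept=0.0, sd_clone_slope=0.0, sd_residual=0.0,
        )
        records = generate_individual_records(small_design, model, seed=3)
        np.testing.assert_allclose(
            records["gut_length_mature_mm"], records["gut_length_neonate_mm"], rtol=1e-12
        )

    def test_absolute_scale_model_rejected(self, small_design):
        with pytest.raises(ValueError, match="proportional"):
            generate_individual_records(small_design, default_absolute_model(), seed=1)

    def test_nonpositive_maturity_model_rejected(self, small_design, proportional_model):
        with pytest.raises(ValueError, match="maturity"):
            generate_individual_records(
                small_design, proportional_model, seed=1, maturity_model=lambda T: T - 30.0
            )

    def test_dropout_marks_nonsurvivors(self, default_design, proportional_model):
        records = generate_individual_records(
            default_design, proportional_model, seed=4, dropout_probability=0.2
        )
        dead = ~records["survived"]
        assert 0.1 < dead.mean() < 0.3
        assert records.loc[dead, "gut_length_mature_mm"].isna().all()
        rates = compute_rate_table(records)
        assert len(rates) == int(records["survived"].sum())


class TestFileRoundTrips:
    def test_records_round_trip(self, small_design, proportional_model, tmp_path):
        records = generate_individual_records(small_design, proportional_model, seed=6)
        path = tmp_path / "records.csv"
        write_records(records, path)
        back = read_records(path)
        pd.testing.assert_frame_equal(back, records.reset_index(drop=True), check_dtype=False)

    def test_empty_records_round_trip(self, tmp_path):
        empty = pd.DataFrame(
            columns=["population", "clone", "temperature_C", "gut_length_neonate_mm",
                     "gut_length_mature_mm", "age_at_maturity_days", "survived"]
        )
        path = tmp_path / "empty.csv"
        write_records(empty, path)
        assert len(read_records(path)) == 0

    def test_default_design_row_count_conserved(self, default_design, proportional_model, tmp_path):
        records = generate_individual_records(default_design, proportional_model, seed=8)
        path = tmp_path / "records.csv"
        write_records(records, path)
        assert len(read_records(path)) == 1680

    def test_missing_column_names_the_column(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("population,clone,temperature_C\nNorway,c1,12\n")
        with pytest.raises(SchemaError, match="gut_length_neonate_mm"):
            read_records(path)

    def test_extra_archive_columns_ignored_with_notice(self, tmp_path, caplog):
        # archive-style file with extra bookkeeping columns
        path = tmp_path / "archive.csv"
        path.write_text(
            "population,clone,temperature_C,gut_length_neonate_mm,"
            "gut_length_mature_mm,age_at_maturity_days,survived,batch,notes\n"
            "Norway,Norway-c01,12,0.4,0.9,20,True,1,ok\n"
        )
        with caplog.at_level(logging.INFO, logger="tpcgrowth.synthetic"):
            df = read_records(path)
        assert list(df.columns) == [
            "population", "clone", "temperature_C", "gut_length_neonate_mm",
            "gut_length_mature_mm", "age_at_maturity_days", "survived",
        ]
        assert any("batch" in rec.message for rec in caplog.records)

    def test_rate_table_round_trip(self, small_design, proportional_model, tmp_path):
        table = generate_growth_table(small_design, proportional_model, seed=12)
        path = tmp_path / "rates.csv"
        write_rate_table(table, path)
        back = read_rate_table(path)
        np.testing.assert_allclose(back["growth_rate"], table["growth_rate"])

    def test_survivor_invariant_checked_on_read(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text(
            "population,clone,temperature_C,gut_length_neonate_mm,"
            "gut_length_mature_mm,age_at_maturity_days,survived\n"
            "Norway,Norway-c01,12,0.5,0.4,20,True\n"
        )
        with pytest.raises(ValueError, match="mature"):
            read_records(path)
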