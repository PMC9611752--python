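"""Ingestion, filters, coarse-graining, and the balanced-resample mixture."""

import numpy as np
import pandas as pd
import pytest

from synpid import (
    CohortConfig,
    GeneratorConfig,
    PersonTable,
    PipelineError,
    apply_filters,
    balanced_resample_mixture,
    coarse_grain_income,
    decade_analysis,
    effective_pid,
    generate_population,
    load_person_table,
    mutual_information,
)

COLUMN_MAP = {c: c for c in
              ("race", "sex", "age", "nativity", "employment", "income", "health")}


def small_table(rows):
    return PersonTable(df=pd.DataFrame(rows))


def base_row(**kw):
    row = {
        "race": "White",
        "sex": "Male",
        "age": 40,
        "nativity": "Native",
        "employment": "Full-time",
        "income": 50_000.0,
        "health": 3,
    }
    row.update(kw)
    return row


class TestLoadPersonTable:
    def test_well_formed_file(self, tmp_path):
        path = tmp_path / "people.csv"
        pd.DataFrame([base_row(), base_row(sex="Female"), base_row(age=30)]).to_csv(
            path, index=False
        )
        table = load_person_table(path, COLUMN_MAP)
        assert len(table) == 3

    def test_out_of_support_health_dropped(self, tmp_path):
        path = tmp_path / "people.csv"
        pd.DataFrame([base_row(), base_row(health=9)]).to_csv(path, index=False)
        table = load_person_table(path, COLUMN_MAP)
        assert len(table) == 1
        assert "1 rows dropped" in table.provenance

    def test_missing_mapped_column(self, tmp_path):
        path = tmp_path / "people.csv"
        pd.DataFrame([base_row()]).drop(columns=["health"]).to_csv(path, index=False)
        with pytest.raises(ValueError, match="health"):
            load_person_table(path, COLUMN_MAP)

    def test_generator_output_round_trips(self, tmp_path):
        table = generate_population(GeneratorConfig(n=500, seed=3))
        path = tmp_path / "synthetic.csv"
        table.to_csv(path)
        back = load_person_table(path, COLUMN_MAP)
        assert len(back) == len(table)
        pd.testing.assert_frame_equal(
            back.df, table.df, check_exact=False, rtol=0, atol=1e-9
        )


class TestApplyFilters:
    def test_age_boundaries_inclusive(self):
        table = small_table(
            [base_row(age=24), base_row(age=25), base_row(age=65), base_row(age=66)]
        )
        kept = apply_filters(table, CohortConfig())
        assert sorted(kept.df["age"]) == [25, 65]

    def test_non_native_excluded(self):
        table = small_table([base_row(), base_row(nativity="Foreign-born")])
        assert len(apply_filters(table, CohortConfig())) == 1

    def test_multiracial_excluded(self):
        table = small_table([base_row(), base_row(race="Multiracial")])
        assert len(apply_filters(table, CohortConfig())) == 1

    def test_part_time_excluded(self):
        table = small_table([base_row(), base_row(employment="Part-time")])
        assert len(apply_filters(table, CohortConfig())) == 1

    def test_empty_result_names_filter(self):
        table = small_table([base_row(age=20), base_row(age=70)])
        with pytest.raises(PipelineError, match="age"):
            apply_filters(table, CohortConfig())


class TestCoarseGrainIncome:
    @pytest.mark.parametrize(
        "income, expected",
        [
            (0, "Low"),
            (27_499, "Low"),
            (27_500, "Lower-Middle"),
            (52_499, "Lower-Middle"),
            (52_500, "Upper-Middle"),
            (77_499, "Upper-Middle"),
            (77_500, "High"),
            (250_000, "High"),
        ],
    )
    def test_bracket_boundaries(self, income, expected):
        assert coarse_grain_income(income) == expected

    def test_negative_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            coarse_grain_income(-1.0)

    def test_vectorized(self):
        out = coarse_grain_income(np.array([0.0, 30_000.0, 80_000.0]))
        assert list(out) == ["Low", "Lower-Middle", "High"]


def balanced_toy_table(per_cell=40, seed=0):
    """Table whose four identity cells have equal counts."""
    rng = np.random.default_rng(seed)
    rows = []
    for race in ("White", "Black"):
        for sex in ("Male", "Female"):
            for _ in range(per_cell):
                rows.append(
                    base_row(
                        race=race,
                        sex=sex,
                        income=float(rng.choice([10_000, 40_000, 60_000, 90_000])),
                        health=int(rng.integers(1, 6)),
                    )
                )
    return small_table(rows)


class TestBalancedResampleMixture:
    def test_identity_case_recovers_empirical_distribution(self):
        """One full-cell draw without replacement is the empirical table."""
        table = balanced_toy_table()
        config = CohortConfig(n_resamples=1, cell_size=40, seed=5)
        eff = balanced_resample_mixture(table, ("race", "sex"), "income", config)
        from synpid import plug_in_distribution

        emp = plug_in_distribution(table, ("race", "sex", "income"), config)
        assert np.allclose(eff.dist.probs, emp.probs)

    def test_flatness_exact_for_any_seed(self):
        table = generate_population(GeneratorConfig(n=4000, seed=1))
        for seed in (0, 1, 99):
            eff = balanced_resample_mixture(
                table, ("race", "sex"), "income",
                CohortConfig(n_resamples=7, seed=seed),
            )
            assert eff.predictor_marginal_flatness == 0.0

    def test_mixture_of_identical_replicates_is_the_replicate(self):
        table = balanced_toy_table()
        one = balanced_resample_mixture(
            table, ("race", "sex"), "income",
            CohortConfig(n_resamples=1, cell_size=40, seed=2),
        )
        many = balanced_resample_mixture(
            table, ("race", "sex"), "income",
            CohortConfig(n_resamples=25, cell_size=40, seed=2),
        )
        assert np.allclose(one.dist.probs, many.dist.probs)

    def test_independent_outcome_mi_shrinks_with_n(self):
        config = CohortConfig(n_resamples=20, seed=7)
        mis = []
        for n in (400, 40_000):
            table = generate_population(
                GeneratorConfig(
                    n=n, main_effect_race=0, main_effect_sex=0, shared_effect=0,
                    latent_coupling=0.0, interaction_effect=0, seed=11,
                )
            )
            eff = balanced_resample_mixture(
                table, ("race", "sex"), "income", config
            )
            mis.append(
                mutual_information(eff.dist, ("race", "sex"), "income")
            )
        assert mis[1] < mis[0]
        assert mis[1] < 0.002

    def test_seeded_bit_reproducibility(self):
        table = generate_population(GeneratorConfig(n=3000, seed=4))
        cfg = CohortConfig(n_resamples=10, seed=42)
        a = balanced_resample_mixture(table, ("race", "sex"), "income", cfg)
        b = balanced_resample_mixture(table, ("race", "sex"), "income", cfg)
        assert np.array_equal(a.dist.probs, b.dist.probs)
        c = balanced_resample_mixture(
            table, ("race", "sex"), "income",
            CohortConfig(n_resamples=10, seed=43),
        )
        assert not np.array_equal(a.dist.probs, c.dist.probs)

    def test_empty_predictor_cell_is_reported(self):
        # both categories observed marginally, but Black women absent
        rows = [
            base_row(race="White", sex="Male"),
            base_row(race="White", sex="Female"),
            base_row(race="Black", sex="Male"),
        ]
        with pytest.raises(PipelineError, match="Black.*Female"):
            balanced_resample_mixture(
                small_table(rows), ("race", "sex"), "income",
                CohortConfig(n_resamples=1),
            )


class TestEffectivePid:
    def test_pure_parity_population_is_synergy_dominated(self):
        gen = GeneratorConfig(
            n=20_000, main_effect_race=0, main_effect_sex=0, shared_effect=0,
            latent_coupling=0.0, interaction_effect=0, parity_weight=15_000,
            income_noise_sd=0, seed=6,
        )
        eff = balanced_resample_mixture(
            generate_population(gen), ("race", "sex"), "income",
            CohortConfig(n_resamples=20, seed=1),
        )
        from synpid import classify_atoms

        c = classify_atoms(effective_pid(eff))
        assert c.fractions["synergistic"] > 0.95

    def test_constant_outcome_has_no_information(self):
        gen = GeneratorConfig(
            n=2_000, main_effect_race=0, main_effect_sex=0, shared_effect=0,
            latent_coupling=0.0, interaction_effect=0, income_noise_sd=0, seed=6,
        )
        eff = balanced_resample_mixture(
            generate_population(gen), ("race", "sex"), "income",
            CohortConfig(n_resamples=5, seed=1),
        )
        r = effective_pid(eff)
        assert r.joint_mi == pytest.approx(0.0, abs=1e-12)
        assert r.fractions is None

    def test_unknown_method_rejected(self):
        gen = GeneratorConfig(n=1000, seed=0)
        eff = balanced_resample_mixture(
            generate_population(gen), ("race", "sex"), "income",
            CohortConfig(n_resamples=2, seed=1),
        )
        with pytest.raises(ValueError, match="imin"):
            effective_pid(eff, method="mystery")


class TestDecadeAnalysis:
    def test_single_year_reports_zero_sd(self):
        table = generate_population(GeneratorConfig(n=6_000, seed=9))
        table.year = 2020
        res = decade_analysis(
            [table],
            triads=[(("race", "sex"), "income")],
            config=CohortConfig(n_resamples=10, seed=3),
        )
        assert (res.summary["sd_fraction"].dropna() == 0).all()
        assert len(res.wms) == 1

    def test_three_source_triad_with_broja_unsupported(self):
        table = generate_population(GeneratorConfig(n=2_000, seed=9))
        with pytest.raises(ValueError, match="two sources"):
            decade_analysis(
                [table],
                triads=[(("race", "sex", "income"), "health")],
                config=CohortConfig(n_resamples=2),
                method="broja",
            )

    def test_fraction_sd_shrinks_with_per_year_n(self):
        """Stability over replicate years improves with sample size."""
        def sd_at(n):
            tables = []
            for year in range(4):
                t = generate_population(GeneratorConfig(n=n, seed=100 + year))
                t.year = 2011 + year
                tables.append(t)
            res = decade_analysis(
                tables,
                triads=[(("race", "sex"), "income")],
                config=CohortConfig(n_resamples=10, seed=0),
            )
            return res.summary["sd_fraction"].max()

        assert sd_at(20_000) < sd_at(800)

    def test_default_triads_run_end_to_end(self):
        table = generate_population(GeneratorConfig(n=8_000, seed=12))
        table.year = 2019
        res = decade_analysis(
            [table], config=CohortConfig(n_resamples=5, seed=1)
        )
        assert set(res.wms["triad"]) == {
            "(race, sex -> income)",
            "(race, income -> health)",
            "(race, sex, income -> health)",
        }
        # 4 + 4 + 18 atoms in the tidy frame
        assert len(res.tidy) == 26
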