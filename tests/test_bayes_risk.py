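"""The Bayes posterior-risk computation, prior calibration and diagnostics."""

import pytest
from hypothesis import given, strategies as st

from bayesrisk import (
    DomainError,
    ValidationError,
    build_risk_table,
    calibrate_prior,
    implied_prior,
    posterior_risk,
    rank_top_factors,
    render_chance,
    total_probability_diagnostic,
)
from bayesrisk.tables_io import (
    CaseSeries,
    FactorSummary,
    LevelSummary,
    PopulationReference,
)

fractions = st.floats(min_value=1e-6, max_value=1.0, exclude_max=False)
priors = st.floats(min_value=1e-6, max_value=1.0, exclude_max=True)


class TestPosteriorRisk:
    def test_age_60_69_row(self):
        post = posterior_risk(0.275, 0.0355, 0.056)
        assert post == pytest.approx(0.43380, abs=5e-6)
        assert render_chance(post) == "43.38"

    def test_cataract_row(self):
        post = posterior_risk(0.11, 0.04, 0.056)
        assert post == pytest.approx(0.15400, abs=5e-6)
        assert render_chance(post) == "15.4"

    @given(fractions, priors)
    def test_independence_leaves_prior_unchanged(self, q, p):
        assert posterior_risk(q, q, p) == pytest.approx(p)

    def test_inconsistent_inputs_exceed_one_not_clamped(self):
        post = posterior_risk(0.5, 0.01, 0.5)
        assert post == pytest.approx(25.0)

    def test_zero_population_proportion_rejected(self):
        with pytest.raises(DomainError):
            posterior_risk(0.5, 0.0, 0.056)


class TestImpliedPrior:
    def test_inversion_of_age_row(self):
        assert implied_prior(0.4338, 0.275, 0.0355) == pytest.approx(
            0.05600, abs=5e-6
        )

    def test_inversion_of_male_row(self):
        assert implied_prior(0.0509, 0.525, 0.5778) == pytest.approx(
            0.05602, abs=5e-6
        )

    @given(priors, fractions)
    def test_inversion_of_independence_identity(self, p, q):
        assert implied_prior(p, q, q) == pytest.approx(p)

    def test_zero_case_proportion_rejected(self):
        with pytest.raises(DomainError):
            implied_prior(0.1, 0.0, 0.5)

    @given(fractions, fractions, priors)
    def test_forward_backward_consistency(self, case_p, pop_p, prior):
        post = posterior_risk(case_p, pop_p, prior)
        assert implied_prior(post, case_p, pop_p) == pytest.approx(
            prior, rel=1e-12
        )


class TestCalibratePrior:
    def test_published_table_rows_share_a_prior(
        self, hail_cases, hail_pop, hail_published
    ):
        triples = [
            (
                hail_published[lev.level_label],
                lev.case_proportion,
                hail_pop.proportion(lev.level_label),
            )
            for lev in hail_cases.iter_levels()
        ]
        cal = calibrate_prior(triples)
        assert len(cal.implied) == 14
        assert cal.prior == pytest.approx(0.0560, abs=5e-5)
        assert cal.dispersion < 1e-3
        assert cal.consistent()

    def test_round_trip_with_known_prior(self):
        rows = [(posterior_risk(c, p, 0.021), c, p)
                for c, p in [(0.3, 0.1), (0.25, 0.5), (0.45, 0.4)]]
        cal = calibrate_prior(rows)
        assert cal.prior == pytest.approx(0.021, rel=1e-12)
        assert cal.dispersion == pytest.approx(0.0, abs=1e-15)

    def test_corrupted_row_inflates_dispersion(self):
        rows = [(posterior_risk(c, p, 0.021), c, p)
                for c, p in [(0.3, 0.1), (0.25, 0.5), (0.45, 0.4)]]
        post, c, p = rows[0]
        rows[0] = (post * 1.1, c, p)  # 10% perturbation of one posterior
        cal = calibrate_prior(rows)
        assert not cal.consistent()
        assert cal.dispersion > 1e-3

    def test_single_row_rejected(self):
        with pytest.raises(DomainError):
            calibrate_prior([(0.1, 0.2, 0.3)])


class TestBuildRiskTable:
    def test_all_14_published_chances_reproduced(self, hail_risk_table):
        expected = {
            "40–49 years": "8.42",
            "50–59 years": "22.78",
            "60–69 years": "43.38",
            "70–79 years": "35.52",
            "≥80 years": "37.33",
            "Male": "5.09",
            "Female": "6.3",
            "Illiterate": "22.58",
            "Literate": "5.49",
            "Diabetes Mellitus": "16.1",
            "Hypertension": "4.59",
            "Asthma": "2.77",
            "CVD": "1.02",
            "Cataract": "15.4",
        }
        assert len(hail_risk_table.rows) == 14
        for level, want in expected.items():
            assert render_chance(hail_risk_table.row(level).posterior) == want
        assert hail_risk_table.prior_provenance == "calibrated"
        assert not hail_risk_table.infeasible_rows

    def test_observed_prior_documents_sensitivity(self, hail_cases, hail_pop):
        table = build_risk_table(hail_cases, hail_pop, prior="observed")
        assert table.prior == pytest.approx(200 / 9407)
        assert table.row("60–69 years").posterior == pytest.approx(
            0.1647, abs=5e-5
        )
        assert table.prior_provenance == "observed_prevalence"

    def test_missing_population_entry_names_level(self, hail_cases):
        pop = PopulationReference(entries={"Male": 0.5778})
        with pytest.raises(ValidationError, match="40–49 years"):
            build_risk_table(hail_cases, pop, prior=0.056)

    def test_table_without_comorbidities_builds(self, hail_cases, hail_pop):
        trimmed = CaseSeries(
            disease_label=hail_cases.disease_label,
            n_cases=hail_cases.n_cases,
            n_screened=hail_cases.n_screened,
            factors=tuple(
                f for f in hail_cases.factors if f.name != "comorbidity"
            ),
        )
        table = build_risk_table(trimmed, hail_pop, prior=0.056)
        assert len(table.rows) == 9
        with pytest.raises(KeyError):
            table.row("Cataract")


class TestRanking:
    def test_top_7_set(self, hail_risk_table):
        top = rank_top_factors(hail_risk_table, 7)
        assert {label for label, _ in top} == {
            "60–69 years",
            "≥80 years",
            "70–79 years",
            "50–59 years",
            "Illiterate",
            "Diabetes Mellitus",
            "Cataract",
        }
        posts = [p for _, p in top]
        assert posts == sorted(posts, reverse=True)

    def test_top_1(self, hail_risk_table):
        [(label, post)] = rank_top_factors(hail_risk_table, 1)
        assert label == "60–69 years"
        assert post == pytest.approx(0.43380, abs=5e-5)

    def test_k_zero(self, hail_risk_table):
        assert rank_top_factors(hail_risk_table, 0) == []

    def test_ties_broken_lexicographically(self, hail_pop):
        cases = CaseSeries(
            disease_label="d",
            n_cases=200,
            n_screened=1000,
            factors=(
                FactorSummary(
                    "gender",
                    True,
                    (
                        LevelSummary("gender", "Male", 100, 0.5),
                        LevelSummary("gender", "Female", 100, 0.5),
                    ),
                ),
            ),
        )
        pop = PopulationReference(entries={"Male": 0.5, "Female": 0.5})
        table = build_risk_table(cases, pop, prior=0.1)
        top = rank_top_factors(table, 2)
        assert [label for label, _ in top] == ["Female", "Male"]


class TestTotalProbability:
    def test_age_coverage_is_partial(self, hail_risk_table, hail_pop):
        check = total_probability_diagnostic(hail_risk_table, "age", hail_pop)
        assert check.coverage == pytest.approx(0.3092, abs=1e-9)
        assert check.case_proportion_sum == pytest.approx(1.0)

    def test_gender_marginalizes_back_to_prior(self, hail_risk_table, hail_pop):
        check = total_probability_diagnostic(hail_risk_table, "gender", hail_pop)
        assert check.coverage == pytest.approx(1.0, abs=1e-12)
        assert check.reconstructed_prior == pytest.approx(
            hail_risk_table.prior, rel=1e-9
        )

    def test_single_total_level_returns_prior_exactly(self):
        cases = CaseSeries(
            disease_label="d",
            n_cases=10,
            n_screened=100,
            factors=(
                FactorSummary(
                    "f", True, (LevelSummary("f", "all", 10, 1.0),)
                ),
            ),
        )
        pop = PopulationReference(entries={"all": 1.0})
        table = build_risk_table(cases, pop, prior=0.3)
        check = total_probability_diagnostic(table, "f", pop)
        assert check.reconstructed_prior == pytest.approx(0.3, rel=1e-15)

    def test_unknown_factor_rejected(self, hail_risk_table, hail_pop):
        with pytest.raises(ValidationError):
            total_probability_diagnostic(hail_risk_table, "nope", hail_pop)


class TestConservationProperty:
    @given(
        st.lists(
            st.tuples(
                st.floats(min_value=0.01, max_value=1.0),
                st.integers(min_value=1, max_value=50),
            ),
            min_size=2,
            max_size=6,
        ),
        priors,
    )
    def test_population_weighted_posterior_equals_prior(self, raw, prior):
        # build an exhaustive factor whose population proportions sum to 1
        pop_weights = [w for w, _ in raw]
        total_w = sum(pop_weights)
        pop_props = [w / total_w for w in pop_weights]
        counts = [c for _, c in raw]
        n = sum(counts)
        case_props = [c / n for c in counts]
        weighted = sum(
            posterior_risk(cp, pp, prior) * pp
            for cp, pp in zip(case_props, pop_props)
        )
        assert weighted == pytest.approx(prior, rel=1e-9)
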