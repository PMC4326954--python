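import math

import numpy as np
import pytest

from agemarkers.data_model import Sex, merge_lifespan, records_to_frame
from agemarkers.errors import CollinearityError, InsufficientDataError
from agemarkers.prognostic import (
    Direction,
    build_profile,
    correlate_lifespan,
    cox_multivariate,
    cox_univariate,
    summarize_direction,
)
from agemarkers.synthetic import FeatureSpec, generate_cohort

from .conftest import make_merged
from .helpers import grid_search_cox, make_config


class TestCorrelateLifespan:
    def test_identity_feature(self):
        lifespans = [20.0, 24.0, 28.0, 32.0]
        merged = make_merged(lifespans, lifespans)
        cell = correlate_lifespan(merged, "x", Sex.female, 6.0)
        assert cell.pearson_r == pytest.approx(1.0)
        assert cell.relevant
        assert cell.n == 4

    def test_p_gate_blocks_weak_small_n(self):
        # |r| above r_min but p far above alpha at n=5 -> not relevant
        rng = np.random.default_rng(5)
        for _ in range(50):
            lifespans = list(rng.normal(26, 5, size=5))
            values = list(rng.normal(size=5))
            cell = correlate_lifespan(make_merged(values, lifespans), "x",
                                      Sex.female, 6.0)
            if 0.2 <= abs(cell.pearson_r) <= 0.5:
                assert cell.p_value > 0.05
                assert not cell.relevant
                return
        pytest.fail("no suitable draw found")

    def test_brute_force_oracle(self):
        values = [3.1, 2.4, 5.0, 4.2, 3.3, 2.8]
        lifespans = [22.0, 19.0, 31.0, 27.0, 24.0, 20.5]
        cell = correlate_lifespan(make_merged(values, lifespans), "x",
                                  Sex.female, 6.0)
        x, y = np.array(values), np.array(lifespans)
        expected = (np.mean((x - x.mean()) * (y - y.mean()))
                    / (x.std() * y.std()))
        assert cell.pearson_r == pytest.approx(expected, abs=1e-12)

    def test_constant_feature_degenerate(self):
        cell = correlate_lifespan(
            make_merged([1.0, 1.0, 1.0], [20.0, 25.0, 30.0]), "x",
            Sex.female, 6.0)
        assert cell.degenerate
        assert not cell.relevant
        assert math.isnan(cell.pearson_r)

    def test_too_few_pairs_degenerate(self):
        cell = correlate_lifespan(make_merged([1.0, 2.0], [20.0, 25.0]), "x",
                                  Sex.female, 6.0)
        assert cell.degenerate and not cell.relevant

    def test_relevance_monotone_in_thresholds(self):
        rng = np.random.default_rng(9)
        lifespans = list(rng.normal(26, 5, size=30))
        values = [0.12 * le + float(rng.normal(0, 1)) for le in lifespans]
        merged = make_merged(values, lifespans)
        loose = correlate_lifespan(merged, "x", Sex.female, 6.0, r_min=0.2)
        strict = correlate_lifespan(merged, "x", Sex.female, 6.0, r_min=0.9)
        assert 0.2 <= abs(loose.pearson_r) < 0.9
        assert loose.relevant and not strict.relevant
        tight_alpha = correlate_lifespan(merged, "x", Sex.female, 6.0,
                                         alpha=1e-12)
        assert not tight_alpha.relevant


class TestProfiles:
    def test_direction_summaries(self):
        from agemarkers.prognostic import PrognosticCell

        def cell(r, relevant=True, age=6.0):
            return PrognosticCell(feature="x", sex=Sex.female, age_group=age,
                                  pearson_r=r, p_value=0.001, n=50,
                                  relevant=relevant)

        assert summarize_direction([cell(0.4), cell(0.3)])[0] is Direction.long
        assert summarize_direction([cell(-0.4)])[0] is Direction.short
        assert summarize_direction([cell(0.4), cell(-0.4)])[0] is Direction.switch
        assert summarize_direction([cell(0.4, relevant=False)])[0] is Direction.none

    def test_build_profile_ages(self):
        cohort = generate_cohort(make_config(0))
        merged = merge_lifespan(cohort.records, cohort.lifespans)
        df = records_to_frame(merged.records)
        prof = build_profile(df, "f_pro", Sex.female, [6.0, 12.0, 18.0, 24.0])
        assert set(prof.cells) == {6.0, 12.0, 18.0, 24.0}
        assert prof.direction_summary is Direction.long


class TestCoxUnivariate:
    def test_null_feature(self):
        cohort = generate_cohort(make_config(
            3, features=(FeatureSpec(name="x"),)))
        merged = merge_lifespan(cohort.records, cohort.lifespans)
        res = cox_univariate(merged.records, "x", Sex.female, 6.0)
        assert abs(res.coefficient) < 0.15
        assert res.p_value > 0.05

    def test_sign_concordance_with_correlation(self):
        cohort = generate_cohort(make_config(4))
        merged = merge_lifespan(cohort.records, cohort.lifespans)
        df = records_to_frame(merged.records)
        for feature, sign in [("f_pro", 1), ("f_anti", -1)]:
            cell = correlate_lifespan(df, feature, Sex.female, 6.0)
            res = cox_univariate(df, feature, Sex.female, 6.0)
            assert np.sign(cell.pearson_r) == sign
            assert np.sign(res.display_sign) == sign
            # positive correlation -> hazard decrease -> negative coefficient
            assert np.sign(res.coefficient) == -sign

    def test_grid_search_oracle_five_observations(self):
        values = [0.5, -1.2, 0.3, 2.0, -0.7]
        lifespans = [10.0, 25.0, 18.0, 7.0, 30.0]  # tie-free
        merged = make_merged(values, lifespans)
        res = cox_univariate(merged, "x", Sex.female, 6.0)
        x = np.asarray(values)
        z = (x - x.mean()) / x.std(ddof=1)
        expected = grid_search_cox(z, np.asarray(lifespans))
        assert res.coefficient == pytest.approx(expected, abs=1e-4)

    def test_breslow_equals_efron_tie_free(self):
        values = [0.5, -1.2, 0.3, 2.0, -0.7, 1.1]
        lifespans = [10.0, 25.0, 18.0, 7.0, 30.0, 14.0]
        merged = make_merged(values, lifespans)
        efron = cox_univariate(merged, "x", Sex.female, 6.0, ties="efron")
        breslow = cox_univariate(merged, "x", Sex.female, 6.0, ties="breslow")
        assert breslow.coefficient == pytest.approx(efron.coefficient, abs=1e-3)

    def test_monotone_time_transform_invariance(self):
        values = [0.5, -1.2, 0.3, 2.0, -0.7, 1.1, 0.9, -0.2]
        lifespans = [10.0, 25.0, 18.0, 7.0, 30.0, 14.0, 21.0, 27.0]
        base = cox_univariate(make_merged(values, lifespans), "x",
                              Sex.female, 6.0)
        squared = cox_univariate(
            make_merged(values, [t * t for t in lifespans]), "x",
            Sex.female, 6.0)
        assert squared.coefficient == pytest.approx(base.coefficient, abs=1e-6)

    def test_complete_separation_flagged_and_capped(self):
        lifespans = [10.0, 15.0, 20.0, 25.0, 30.0]
        res = cox_univariate(make_merged(list(lifespans), lifespans), "x",
                             Sex.female, 6.0)
        assert res.separation
        assert res.coefficient < 0  # high value -> long life -> hazard down
        assert abs(res.coefficient) == 20.0

    def test_display_sign_inverts(self):
        values = [0.5, -1.2, 0.3, 2.0, -0.7]
        lifespans = [10.0, 25.0, 18.0, 7.0, 30.0]
        res = cox_univariate(make_merged(values, lifespans), "x",
                             Sex.female, 6.0)
        assert res.display_sign == -res.coefficient

    def test_insufficient_data(self):
        with pytest.raises(InsufficientDataError):
            cox_univariate(make_merged([1.0, 2.0], [20.0, 25.0]), "x",
                           Sex.female, 6.0)


class TestCoxMultivariate:
    @staticmethod
    def two_feature_merged(seed=8):
        cohort = generate_cohort(make_config(seed, features=(
            FeatureSpec(name="a", prognostic_r={6: 0.45}),
            FeatureSpec(name="b", prognostic_r={6: -0.45}),
        )))
        return merge_lifespan(cohort.records, cohort.lifespans).records

    def test_single_feature_reduces_to_univariate(self):
        merged = self.two_feature_merged()
        uni = cox_univariate(merged, "a", Sex.female, 6.0)
        (multi,) = cox_multivariate(merged, ["a"], Sex.female, 6.0)
        assert multi.coefficient == pytest.approx(uni.coefficient, abs=1e-8)

    def test_independent_predictors_near_univariate(self):
        merged = self.two_feature_merged()
        multi = {r.feature: r for r in
                 cox_multivariate(merged, ["a", "b"], Sex.female, 6.0)}
        for f in ("a", "b"):
            uni = cox_univariate(merged, f, Sex.female, 6.0)
            assert abs(multi[f].coefficient - uni.coefficient) <= 2 * uni.se

    def test_duplicated_feature_collinearity(self):
        merged = self.two_feature_merged()
        records = [
            m.__class__(animal_id=m.animal_id, strain=m.strain, sex=m.sex,
                        age_months=m.age_months,
                        values={**m.values, "a2": m.values["a"]},
                        life_expectancy=m.life_expectancy)
            for m in merged
        ]
        with pytest.raises(CollinearityError):
            cox_multivariate(records, ["a", "a2"], Sex.female, 6.0)

    def test_duplicate_name_rejected(self):
        with pytest.raises(CollinearityError):
            cox_multivariate(self.two_feature_merged(), ["a", "a"],
                             Sex.female, 6.0)

    def test_too_few_complete_cases(self):
        from agemarkers.data_model import MergedRecord

        merged = [
            MergedRecord(animal_id=f"a{i}", strain=f"S{i}", sex=Sex.female,
                         age_months=6.0, values={"x": float(i), "y": float(-i)},
                         life_expectancy=20.0 + i)
            for i in range(3)
        ]
        with pytest.raises(InsufficientDataError):
            cox_multivariate(merged, ["x", "y"], Sex.female, 6.0)

    def test_reports_strain_count(self):
        merged = self.two_feature_merged()
        (res,) = cox_multivariate(merged, ["a"], Sex.female, 6.0)
        assert res.n_strains == 30
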