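import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import special

from intelligrowth.thresholds import (
    build_threshold_table,
    ppv,
    prevalence_from_counts,
    round_half_point,
    sensitivity_at_threshold,
    specificity_at_threshold,
    table_to_frame,
    threshold_at_sensitivity,
    threshold_at_specificity,
    write_table,
)
from intelligrowth.betareg import model_quantile

from conftest import constant_model

# Published worked examples: (sensitivity, specificity, prevalence) -> PPV
PUBLISHED_PPV_TRIPLES = [
    (0.900, 0.511, 0.677, 0.794),
    (0.900, 0.786, 0.677, 0.898),
    (0.899, 0.817, 0.677, 0.911),
    (0.901, 0.676, 0.677, 0.854),
    (0.903, 0.576, 0.677, 0.817),
    (0.900, 0.609, 0.677, 0.828),
]


class TestPPV:
    @pytest.mark.parametrize("sens,spec,prev,expected", PUBLISHED_PPV_TRIPLES)
    def test_reproduces_published_values(self, sens, spec, prev, expected):
        assert round(ppv(sens, spec, prev), 3) == expected

    def test_perfect_test_gives_unit_ppv(self):
        assert ppv(1.0, 1.0, 0.3) == 1.0

    def test_undefined_when_no_positive_calls(self):
        with pytest.raises(ZeroDivisionError):
            ppv(0.0, 1.0, 0.5)

    @settings(max_examples=200, derandomize=True)
    @given(
        sens=st.floats(0.05, 0.99),
        spec=st.floats(0.05, 0.99),
        prev=st.floats(0.05, 0.95),
        bump=st.floats(0.001, 0.04),
    )
    def test_monotone_in_prevalence_and_specificity(self, sens, spec, prev, bump):
        base = ppv(sens, spec, prev)
        assert ppv(sens, spec, min(prev + bump, 0.999)) >= base
        assert ppv(sens, min(spec + bump, 0.999), prev) >= base


class TestPrevalence:
    def test_published_group_sizes(self):
        assert round(prevalence_from_counts(44, 21), 3) == 0.677

    def test_trivial_cases(self):
        assert prevalence_from_counts(1, 1) == 0.5
        assert prevalence_from_counts(0, 5) == 0.0

    def test_empty_sample_rejected(self):
        with pytest.raises(ZeroDivisionError):
            prevalence_from_counts(0, 0)


class TestFixedLevelThresholds:
    def test_uniform_reference_closed_form(self):
        ref = constant_model(0.5, 2.0)
        assert threshold_at_specificity(ref, 60, 0.90) == pytest.approx(0.10,
                                                                        abs=1e-12)

    def test_median_of_symmetric_reference(self):
        ref = constant_model(0.5, 10.0)
        assert threshold_at_specificity(ref, 60, 0.50) == pytest.approx(0.5,
                                                                        abs=1e-9)
        assert threshold_at_sensitivity(ref, 60, 0.50) == pytest.approx(0.5,
                                                                        abs=1e-9)

    def test_beta22_against_grid_inversion_oracle(self):
        """Numeric inversion of the Beta(2,2) cdf 3y^2 - 2y^3 at 0.10."""
        ref = constant_model(0.5, 4.0)
        grid = np.arange(0.5e-5, 1.0, 1e-5)
        cdf = 3 * grid ** 2 - 2 * grid ** 3
        oracle = grid[np.searchsorted(cdf, 0.10)]
        assert threshold_at_specificity(ref, 60, 0.90) == pytest.approx(
            oracle, abs=2e-5
        )

    def test_uniform_case_sensitivity_quantile(self):
        case = constant_model(0.5, 2.0)
        assert threshold_at_sensitivity(case, 60, 0.90) == pytest.approx(0.90,
                                                                         abs=1e-12)

    def test_sensitivity_threshold_is_case_quantile(self, smi_model):
        t = threshold_at_sensitivity(smi_model, 48, 0.90)
        assert t == model_quantile(smi_model, 48, 0.90)

    def test_specificity_roundtrip(self, td_model):
        for age in (36, 60, 96):
            t = threshold_at_specificity(td_model, age, 0.90)
            assert specificity_at_threshold(td_model, age, t) == pytest.approx(
                0.90, abs=1e-8
            )
            t2 = threshold_at_sensitivity(td_model, age, 0.90)
            assert sensitivity_at_threshold(td_model, age, t2) == pytest.approx(
                0.90, abs=1e-8
            )

    def test_operating_characteristic_limits(self):
        case = constant_model(0.5, 2.0)
        assert sensitivity_at_threshold(case, 60, 0.999) > 0.99
        assert sensitivity_at_threshold(case, 60, 0.3) == pytest.approx(0.3,
                                                                        abs=1e-12)
        ref = constant_model(0.5, 10.0)
        med = model_quantile(ref, 60, 0.5)
        assert specificity_at_threshold(ref, 60, med) == pytest.approx(0.5,
                                                                       abs=1e-9)


class TestThresholdTable:
    def test_identical_models_fixed_specificity(self):
        m = constant_model(0.6, 8.0)
        rows = build_threshold_table(m, m, mode="fix_specificity", level=0.90)
        assert len(rows) == 6
        for row in rows:
            assert row.sensitivity == pytest.approx(0.10, abs=1e-8)

    def test_rows_compose_atomic_operations(self, td_model, nsmi_model):
        rows = build_threshold_table(td_model, nsmi_model, mode="fix_specificity")
        for row in rows:
            age = row.age_years * 12
            t = threshold_at_specificity(td_model, age, 0.90)
            assert row.threshold == t
            assert row.sensitivity == sensitivity_at_threshold(nsmi_model, age, t)

    def test_known_quantile_map_between_groups(self):
        """With ref ~ U(0,1) and case ~ Beta(1,2), F_case = 1 - (1-t)^2,
        so the fixed-specificity threshold t = 0.10 yields sensitivity
        0.19 at every age."""
        ref, case = constant_model(0.5, 2.0), constant_model(1 / 3, 3.0)
        rows = build_threshold_table(ref, case, mode="fix_specificity", level=0.90)
        for row in rows:
            assert row.threshold == pytest.approx(0.10, abs=1e-12)
            assert row.sensitivity == pytest.approx(0.19, abs=1e-12)

    def test_ppv_filled_from_prevalence(self):
        ref, case = constant_model(0.7, 8.0), constant_model(0.4, 8.0)
        rows = build_threshold_table(
            ref, case, mode="fix_sensitivity", prevalence=0.677
        )
        for row in rows:
            assert row.sensitivity == pytest.approx(0.90, abs=1e-9)
            assert row.ppv == pytest.approx(
                ppv(row.sensitivity, row.specificity, 0.677), abs=1e-12
            )

    def test_rounding_dialect(self):
        assert round_half_point(0.3119) == 0.310
        assert round_half_point(0.3127) == 0.315
        rows = build_threshold_table(
            constant_model(0.6, 8.0), constant_model(0.4, 8.0))
        for row in rows:
            assert (row.threshold_rounded * 200) == pytest.approx(
                round(row.threshold_rounded * 200)
            )

    def test_written_table_mirrors_columns(self, tmp_path, td_model, nsmi_model):
        import pandas as pd

        rows = build_threshold_table(td_model, nsmi_model)
        path = tmp_path / "table.csv"
        write_table(rows, path)
        df = pd.read_csv(path)
        assert list(df.age_years) == [3, 4, 5, 6, 7, 8]
        frame = table_to_frame(rows)
        assert list(frame.columns)[:5] == [
            "age_years", "threshold", "threshold_rounded", "sensitivity",
            "specificity",
        ]
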