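import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings as hyp_settings, strategies as st

from labri.prep import (
    AntibodyCutoffs,
    SubgroupKey,
    apply_exclusions,
    classify_antibody,
    classify_antibody_frame,
    quantile,
    stratify_subgroups,
    tukey_filter,
)
from labri.synthetic import default_config, generate_cohort

from conftest import make_frame, make_record

CUTOFFS = AntibodyCutoffs.defaults()


class TestApplyExclusions:
    def fixture_10(self):
        rows = [
            make_record(subject_id="P1", pregnant=True),
            make_record(subject_id="P2", pregnant=True),
            make_record(subject_id="I1", inpatient=True),
            make_record(subject_id="A1", age=55.0),
            make_record(subject_id="M1", tsh=np.nan),
            make_record(subject_id="K1"),
            make_record(subject_id="K2"),
            make_record(subject_id="K3"),
            make_record(subject_id="K4"),
            make_record(subject_id="K5"),
        ]
        return make_frame(rows)

    def test_hand_count(self):
        retained, report = apply_exclusions(self.fixture_10())
        assert len(retained) == 5
        assert set(retained["subject_id"]) == {"K1", "K2", "K3", "K4", "K5"}
        assert report.excluded_pregnant == 2
        assert report.excluded_inpatient == 1
        assert report.excluded_age == 1
        assert report.excluded_missing_hormones == 1

    def test_empty_input(self):
        retained, report = apply_exclusions(make_frame([]))
        assert len(retained) == 0
        assert report.n_input == 0
        assert report.excluded_age == 0

    @pytest.mark.parametrize("age,kept", [(18.0, True), (50.0, True), (17.9, False), (50.1, False)])
    def test_age_boundaries_inclusive(self, age, kept):
        retained, _ = apply_exclusions(make_frame([make_record(age=age)]))
        assert (len(retained) == 1) is kept

    def test_overlapping_criteria_counted_twice(self):
        df = make_frame([make_record(pregnant=True, inpatient=True)])
        retained, report = apply_exclusions(df)
        assert len(retained) == 0
        assert report.excluded_pregnant == 1
        assert report.excluded_inpatient == 1

    def test_idempotent(self):
        once, _ = apply_exclusions(self.fixture_10())
        twice, report = apply_exclusions(once)
        pd.testing.assert_frame_equal(once, twice)
        assert report.n_retained == report.n_input

    def test_bad_age_window(self):
        with pytest.raises(ValueError):
            apply_exclusions(make_frame([]), age_min=50, age_max=18)


class TestClassifyAntibody:
    def test_abbott_tpo_above_cutoff(self):
        rec = make_record(analyzer="Abbott", tpo_ab=6.0, tg_ab=1.0)
        assert classify_antibody(rec, CUTOFFS) == "pos"

    def test_roche_both_below(self):
        rec = make_record(analyzer="Roche", tg_ab=50.0, tpo_ab=20.0)
        assert classify_antibody(rec, CUTOFFS) == "neg"

    def test_both_missing_indeterminate(self):
        rec = make_record(tg_ab=np.nan, tpo_ab=np.nan)
        assert classify_antibody(rec, CUTOFFS) == "indeterminate"

    def test_one_missing_other_low_indeterminate(self):
        rec = make_record(analyzer="Abbott", tg_ab=np.nan, tpo_ab=1.0)
        assert classify_antibody(rec, CUTOFFS) == "indeterminate"

    def test_one_missing_other_high_pos(self):
        rec = make_record(analyzer="Abbott", tg_ab=np.nan, tpo_ab=100.0)
        assert classify_antibody(rec, CUTOFFS) == "pos"

    def test_at_cutoff_is_negative(self):
        rec = make_record(analyzer="Abbott", tg_ab=4.11, tpo_ab=5.61)
        assert classify_antibody(rec, CUTOFFS) == "neg"

    def test_unknown_analyzer(self):
        rec = make_record(analyzer="Ortho")
        with pytest.raises(KeyError):
            classify_antibody(rec, CUTOFFS)

    @given(
        tg=st.floats(min_value=0.1, max_value=1000.0),
        bump=st.floats(min_value=0.0, max_value=1000.0),
    )
    @hyp_settings(max_examples=50, deadline=None)
    def test_monotone_in_antibody_level(self, tg, bump):
        lo = classify_antibody(make_record(analyzer="Roche", tg_ab=tg, tpo_ab=1.0), CUTOFFS)
        hi = classify_antibody(make_record(analyzer="Roche", tg_ab=tg + bump, tpo_ab=1.0), CUTOFFS)
        assert not (lo == "pos" and hi == "neg")

    def test_frame_agrees_with_scalar(self):
        cfg = default_config(n=300, seed=8)
        df = generate_cohort(cfg)
        vec = classify_antibody_frame(df, CUTOFFS)
        for idx in df.index[:50]:
            assert vec[idx] == classify_antibody(df.loc[idx], CUTOFFS)

    def test_cutoffs_require_all_analyzers(self):
        with pytest.raises(ValueError):
            AntibodyCutoffs({"Abbott": (4.11, 5.61)})


class TestStratify:
    def test_counting_example(self):
        rows = [
            make_record(subject_id="a", sex="M", tg_ab=1.0, tpo_ab=1.0),
            make_record(subject_id="b", sex="M", tpo_ab=100.0),
            make_record(subject_id="c", sex="F", tg_ab=1.0, tpo_ab=1.0),
            make_record(subject_id="d", sex="F", tpo_ab=100.0),
        ]
        cells = stratify_subgroups(make_frame(rows), CUTOFFS)
        assert len(cells[SubgroupKey("Abbott", "M+F", "all", "TSH")]) == 4
        assert len(cells[SubgroupKey("Abbott", "M", "neg", "TSH")]) == 1

    def test_no_positive_records(self):
        rows = [make_record(subject_id=str(i), tg_ab=1.0, tpo_ab=1.0) for i in range(6)]
        cells = stratify_subgroups(make_frame(rows), CUTOFFS)
        assert len(cells[SubgroupKey("Abbott", "F", "pos", "TSH")]) == 0
        np.testing.assert_array_equal(
            cells[SubgroupKey("Abbott", "F", "all", "TSH")],
            cells[SubgroupKey("Abbott", "F", "neg", "TSH")],
        )

    def test_conservation(self):
        cfg = default_config(n=4000, seed=21)
        df, _ = apply_exclusions(generate_cohort(cfg))
        ab = classify_antibody_frame(df, CUTOFFS)
        cells = stratify_subgroups(df, CUTOFFS)
        for analyzer in cfg.analyzers:
            mask = df["analyzer"] == analyzer
            n_ind = int((ab[mask] == "indeterminate").sum())
            elementary = sum(
                len(cells[SubgroupKey(analyzer, sex, stratum, "TSH")])
                for sex in ("M", "F")
                for stratum in ("neg", "pos")
            )
            assert elementary + n_ind == int(mask.sum())
            assert len(cells[SubgroupKey(analyzer, "M+F", "all", "TSH")]) == int(mask.sum())


class TestQuantile:
    def test_exact_order_statistic(self):
        assert quantile([1, 2, 3, 4, 5], 0.25) == 2.0

    def test_midpoint(self):
        assert quantile([1, 2, 3, 4], 0.5) == 2.5

    def test_two_point_interpolation(self):
        assert quantile([10, 20], 0.75) == 17.5

    def test_empty_error(self):
        with pytest.raises(ValueError):
            quantile([], 0.5)

    def test_p_out_of_range(self):
        with pytest.raises(ValueError):
            quantile([1, 2], 1.5)

    @given(
        values=st.lists(st.floats(min_value=-1e6, max_value=1e6), min_size=1, max_size=50),
        p=st.floats(min_value=0.0, max_value=1.0),
    )
    @hyp_settings(max_examples=100, deadline=None)
    def test_matches_numpy_linear(self, values, p):
        ours = quantile(values, p)
        ref = float(np.quantile(np.asarray(values), p, method="linear"))
        assert ours == pytest.approx(ref, rel=1e-12, abs=1e-9)


class TestTukeyFilter:
    def test_all_retained(self):
        kept, frac = tukey_filter([1, 2, 3, 4, 5])
        assert list(kept) == [1, 2, 3, 4, 5]
        assert frac == 0.0

    def test_outlier_removed(self):
        kept, frac = tukey_filter([1, 2, 3, 4, 100])
        assert list(kept) == [1, 2, 3, 4]
        assert frac == pytest.approx(0.2)

    def test_normal_removal_rate(self):
        # theoretical outside-fence mass for a normal is ~0.70%
        rng = np.random.default_rng(17)
        _, frac = tukey_filter(rng.standard_normal(10_000))
        assert frac == pytest.approx(0.007, abs=0.004)

    def test_warning_above_five_percent(self):
        values = np.concatenate([np.zeros(90) + np.arange(90) * 1e-3, np.full(10, 1e6)])
        with pytest.warns(UserWarning, match="> 5%"):
            _, frac = tukey_filter(values)
        assert frac == pytest.approx(0.10)

    def test_too_few_values(self):
        with pytest.raises(ValueError):
            tukey_filter([1, 2, 3])

    @given(st.lists(st.floats(min_value=-1e3, max_value=1e3), min_size=4, max_size=60))
    @hyp_settings(max_examples=60, deadline=None)
    def test_subset_and_order_invariance(self, values):
        arr = np.asarray(values)
        kept, _ = tukey_filter(arr)
        assert set(kept).issubset(set(arr))
        kept_rev, frac_rev = tukey_filter(arr[::-1])
        assert sorted(kept_rev) == sorted(kept)
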