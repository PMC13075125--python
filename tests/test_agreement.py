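import numpy as np
import pandas as pd
import pytest

import gaitmark as gm
from gaitmark.errors import (
    AlignmentError,
    DegenerateStatisticError,
    UndefinedCorrelationError,
    ValidationError,
)

from _oracles import icc_a1_pingouin, spearman_rank_then_pearson, wilcoxon_enumeration_p


def _sample(ref, est, name="p"):
    return gm.PairedSample(name, np.asarray(ref, float), np.asarray(est, float))


class TestMAE:
    def test_identical_vectors_give_zero(self):
        assert gm.mae(_sample([1, 2, 3], [1, 2, 3])) == 0.0

    def test_hand_example(self):
        assert gm.mae(_sample([10, 20, 30], [12, 17, 30])) == pytest.approx(5 / 3)

    def test_symmetric_in_systems(self, rng):
        a, b = rng.normal(size=20), rng.normal(size=20)
        assert gm.mae(_sample(a, b)) == gm.mae(_sample(b, a))


class TestBlandAltman:
    def test_hand_computation(self):
        ba = gm.bland_altman(_sample([0, 0, 0], [1, 2, 3]))
        assert ba.bias == pytest.approx(2.0)
        assert ba.sd_diff == pytest.approx(1.0)
        assert (ba.loa_low, ba.loa_high) == pytest.approx((0.04, 3.96))
        assert (ba.ci_low, ba.ci_high) == pytest.approx(
            (2 - 1.96 / np.sqrt(3), 2 + 1.96 / np.sqrt(3))
        )

    def test_internal_identities(self, rng):
        for _ in range(20):
            n = int(rng.integers(3, 40))
            ba = gm.bland_altman(_sample(rng.normal(size=n), rng.normal(size=n)))
            assert ba.loa_low == pytest.approx(ba.bias - 1.96 * ba.sd_diff, abs=1e-12)
            assert ba.loa_high == pytest.approx(ba.bias + 1.96 * ba.sd_diff, abs=1e-12)
            assert ba.ci_high - ba.bias == pytest.approx(ba.bias - ba.ci_low, abs=1e-12)
            assert ba.loa_low <= ba.bias <= ba.loa_high

    def test_equal_differences_collapse_loa(self):
        ba = gm.bland_altman(_sample([1, 2, 3], [4, 5, 6]))
        assert ba.sd_diff == 0.0
        assert ba.loa_low == ba.loa_high == ba.bias == 3.0

    def test_ci_width_shrinks_as_sqrt_n(self, rng):
        d = rng.normal(size=400)
        small = gm.bland_altman(_sample(np.zeros(100), d[:100]))
        large = gm.bland_altman(_sample(np.zeros(400), d))
        ratio = (small.ci_high - small.ci_low) / (large.ci_high - large.ci_low)
        # widths scale as sd/sqrt(n); with the same underlying population
        # quadrupling n halves the width up to sampling error in sd
        expected = 2.0 * small.sd_diff / large.sd_diff
        assert ratio == pytest.approx(expected, rel=1e-12)

    def test_direction_flips_sign_only(self, rng):
        s = _sample(rng.normal(size=15), rng.normal(size=15))
        fwd = gm.bland_altman(s, "est_minus_ref")
        rev = gm.bland_altman(s, "ref_minus_est")
        assert rev.bias == pytest.approx(-fwd.bias)
        assert rev.sd_diff == pytest.approx(fwd.sd_diff)


def test_ci_from_limits_reconstructs_published_bounds():
    """bias 0.66, upper LoA 5.76, n=27 -> bias CI (-0.32, 1.64)."""
    lo, hi = gm.ci_from_limits(0.66, 5.76, 27)
    assert round(lo, 2) == -0.32
    assert round(hi, 2) == 1.64


class TestSpearman:
    def test_monotone_pairs(self):
        assert gm.spearman_rho(_sample([1, 2, 3, 4], [10, 20, 25, 40])) == 1.0
        assert gm.spearman_rho(_sample([1, 2, 3, 4], [8, 6, 4, 2])) == -1.0

    def test_ties_match_rank_then_pearson_oracle(self, rng):
        for _ in range(50):
            n = int(rng.integers(4, 15))
            a = rng.integers(0, 5, size=n).astype(float)  # heavy ties
            b = rng.integers(0, 5, size=n).astype(float)
            if np.ptp(a) == 0 or np.ptp(b) == 0:
                continue
            mine = gm.spearman_rho(_sample(a, b))
            assert mine == pytest.approx(spearman_rank_then_pearson(a, b), abs=1e-12)

    def test_zero_rank_variance_rejected(self):
        with pytest.raises(UndefinedCorrelationError):
            gm.spearman_rho(_sample([5, 5, 5], [1, 2, 3]))


class TestICC:
    def test_identical_columns_give_one(self):
        assert gm.icc(_sample([1, 2, 3, 4], [1, 2, 3, 4])) == pytest.approx(1.0)

    def test_fixed_matrix_matches_anova_oracle(self):
        Y = np.array([[9, 2], [6, 1], [8, 4], [7, 1], [10, 5], [6, 2]], float)
        assert gm.icc_from_matrix(Y) == pytest.approx(icc_a1_pingouin(Y), abs=1e-10)

    def test_random_matrices_match_anova_oracle(self, rng):
        for _ in range(50):
            n = int(rng.integers(4, 11))
            Y = rng.normal(size=(n, 2)) * rng.uniform(0.5, 20)
            assert gm.icc_from_matrix(Y) == pytest.approx(icc_a1_pingouin(Y), abs=1e-10)

    def test_absolute_agreement_penalizes_constant_offset(self, rng):
        """Shifting one column drops ICC(2,1) below the consistency form."""
        base = rng.normal(size=12) * 5
        Y = np.column_stack([base, base + 10.0])
        icc_abs = gm.icc_from_matrix(Y)
        # consistency-form oracle: two-way mixed, interaction-free
        n, k = Y.shape
        grand = Y.mean()
        msr = k * np.sum((Y.mean(1) - grand) ** 2) / (n - 1)
        msc = n * np.sum((Y.mean(0) - grand) ** 2) / (k - 1)
        sse = np.sum((Y - grand) ** 2) - msr * (n - 1) - msc * (k - 1)
        mse = sse / ((n - 1) * (k - 1))
        icc_consistency = (msr - mse) / (msr + (k - 1) * mse)
        assert icc_abs < icc_consistency

    def test_zero_variance_rejected(self):
        with pytest.raises(DegenerateStatisticError):
            gm.icc_from_matrix(np.full((5, 2), 3.0))


class TestPairedLocationTest:
    def test_extreme_wilcoxon_p_is_two_over_two_to_n(self):
        d = np.array([0.7, 1.3, 2.1, 2.9, 3.6, 4.4])
        assert gm.wilcoxon_signed_rank(d) == pytest.approx(2 / 2**6)

    def test_antisymmetric_differences_give_p_one_under_t(self):
        ref = np.zeros(6)
        est = np.array([-3.0, 3.0, -1.0, 1.0, -2.0, 2.0])
        p, used = gm.paired_location_test(_sample(ref, est))
        assert used == "paired_t"
        assert p == pytest.approx(1.0)

    def test_exact_wilcoxon_matches_enumeration_for_random_sign_patterns(self, rng):
        mags = np.array([0.5, 1.1, 1.8, 2.6, 3.5, 4.5, 5.6, 6.8])
        for _ in range(30):
            signs = rng.choice([-1.0, 1.0], size=8)
            d = mags * signs
            assert gm.wilcoxon_signed_rank(d) == pytest.approx(
                wilcoxon_enumeration_p(d), abs=1e-12
            )

    def test_all_zero_differences_degenerate(self):
        with pytest.raises(DegenerateStatisticError):
            gm.paired_location_test(_sample([1, 2, 3, 4], [1, 2, 3, 4]))

    def test_skewed_differences_take_wilcoxon_branch(self, rng):
        ref = np.zeros(20)
        est = rng.exponential(2.0, size=20) ** 3  # heavily non-normal
        p, used = gm.paired_location_test(_sample(ref, est))
        assert used == "wilcoxon"
        assert 0 < p <= 1


@pytest.mark.parametrize(
    "value, band",
    [
        (0.916, "excellent"), (0.932, "excellent"),
        (0.798, "good"), (0.862, "good"), (0.9, "good"),
        (0.75, "moderate"), (0.5, "moderate"), (0.564, "moderate"),
        (0.499, "poor"), (0.478, "poor"), (-0.3, "poor"),
        (1.0, "excellent"), (0.0, "poor"),
    ],
)
def test_classify_band(value, band):
    assert gm.classify_band(value) == band


def test_classify_band_rejects_out_of_range():
    with pytest.raises(ValidationError):
        gm.classify_band(1.2)


class TestCompareSystems:
    @pytest.fixture()
    def cohort(self):
        return gm.make_cohort(27, noise=gm.NoiseModel(angle_offset=3.0, seed=11))

    def test_identical_systems(self):
        ref, _ = gm.make_cohort(10, noise=gm.NoiseModel(seed=3))
        report = gm.compare_systems(ref, ref.copy())
        for row in report.rows:
            assert row.ba.bias == 0.0
            assert row.mae_deg == 0.0
            assert row.icc == pytest.approx(1.0)
            assert row.test_used == "degenerate"
            assert np.isnan(row.p_value)

    def test_constant_offset_appears_as_bias_everywhere(self):
        ref, _ = gm.make_cohort(12, noise=gm.NoiseModel(seed=4))
        est = ref.copy()
        est["value_deg"] += 3.0
        report = gm.compare_systems(ref, est)
        for row in report.rows:
            assert row.ba.bias == pytest.approx(3.0, abs=1e-9)
            assert row.mae_deg == pytest.approx(3.0, abs=1e-9)

    def test_report_matches_independent_formulas(self, cohort):
        """Every reported field reproduces a directly scripted computation."""
        ref, est = cohort
        report = gm.compare_systems(ref, est)
        assert len(report.rows) == 12  # 2 joints x 2 sides x 3 parameters
        for row in report.rows:
            mask = lambda df: df[
                (df.joint == row.joint) & (df.side == row.side)
                & (df.parameter == row.parameter)
            ].sort_values("subject")["value_deg"].to_numpy()
            r, e = mask(ref), mask(est)
            d = e - r
            assert row.ba.bias == pytest.approx(d.mean(), abs=1e-10)
            assert row.ba.sd_diff == pytest.approx(d.std(ddof=1), abs=1e-10)
            assert row.mae_deg == pytest.approx(np.abs(d).mean(), abs=1e-10)
            assert row.ref_mean == pytest.approx(r.mean(), abs=1e-10)
            assert row.est_sd == pytest.approx(e.std(ddof=1), abs=1e-10)
            assert row.icc == pytest.approx(
                icc_a1_pingouin(np.column_stack([r, e])), abs=1e-10
            )
            assert row.rho == pytest.approx(spearman_rank_then_pearson(r, e), abs=1e-10)

    def test_subject_mismatch_raises_alignment_error(self, cohort):
        ref, est = cohort
        with pytest.raises(AlignmentError, match="S01"):
            gm.compare_systems(ref[ref.subject != "S01"], est)

    def test_report_frames_and_plot_data(self, cohort):
        ref, est = cohort
        report = gm.compare_systems(ref, est)
        table = report.to_frame()
        ba = report.ba_frame()
        assert set(table.columns) >= {"parameter", "p_value", "rho", "icc", "mae_deg"}
        assert set(ba.columns) >= {"bias", "bias_ci_low", "loa_high", "n"}
        assert (ba.n == 27).all()
        # plot data: one point per subject per parameter
        assert len(report.plot_data) == 27 * 12
        sub = report.plot_data.query(
            "joint == 'knee' and side == 'right' and parameter == 'flexion_max'"
        )
        merged = ref.merge(est, on=["subject", "joint", "side", "parameter"],
                           suffixes=("_r", "_e"))
        m = merged.query("joint == 'knee' and side == 'right' and parameter == 'flexion_max'")
        assert np.allclose(
            sorted(sub["difference"]), sorted(m.value_deg_e - m.value_deg_r)
        )

    def test_formatted_rounds_half_up(self, cohort):
        ref, est = cohort
        out = gm.compare_systems(ref, est).formatted(2)
        assert all(abs(v * 100 - round(v * 100)) < 1e-9 for v in out["mae_deg"])
        assert gm.agreement.round_half_up(0.125, 2) == 0.13
        assert gm.agreement.round_half_up(-0.125, 2) == -0.13
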