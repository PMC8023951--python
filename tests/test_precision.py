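"""Precision statistics, normality screening, and dose conversion."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ctmigrate import (
    DoubleExamStudy,
    MigrationResult,
    RigidTransform,
    decompose,
    effective_dose,
    ks_normality,
    precision_value,
    summarize_study,
    t_critical,
)
from ctmigrate.errors import (
    DegenerateSampleError,
    InsufficientDataError,
)


# --------------------------------------------------------------------- #
# precision_value
# --------------------------------------------------------------------- #
def test_all_zero_differences_give_zero_precision():
    assert precision_value([0.0] * 5) == 0.0


def test_worked_five_sample_example_matches_hand_computation():
    """diffs (0.1, -0.1, 0.2, -0.2, 0.0): SD = 0.15811, t(4) = 2.7764,
    precision = 0.43898 (hand oracle)."""
    d = [0.1, -0.1, 0.2, -0.2, 0.0]
    sd = np.sqrt(np.sum(np.square(d)) / 4)  # mean is exactly zero
    assert sd == pytest.approx(0.158114, abs=1e-6)
    assert t_critical(5) == pytest.approx(2.776445, abs=1e-6)
    assert precision_value(d, 0.95) == pytest.approx(sd * t_critical(5),
                                                     abs=1e-9)
    assert precision_value(d, 0.95) == pytest.approx(0.43898, abs=1e-4)


def test_large_sample_limit_reaches_normal_quantile():
    """With n -> inf the precision converges to 1.96 sigma."""
    rng = np.random.default_rng(0)
    sigma = 0.25
    d = rng.normal(0, sigma, 100_000)
    assert precision_value(d) == pytest.approx(1.959964 * sigma, rel=0.01)


def test_single_measurement_insufficient():
    with pytest.raises(InsufficientDataError):
        precision_value([0.1])


def test_about_zero_variant_uses_rms():
    d = np.array([0.3, 0.3, 0.3, 0.3])  # nonzero mean
    sd_zero = np.sqrt(np.sum(d ** 2) / 3)
    assert precision_value(d, about_mean=False) == pytest.approx(
        sd_zero * t_critical(4))
    assert precision_value(d, about_mean=True) == 0.0


@settings(deadline=None, max_examples=40)
@given(st.floats(0.01, 100), st.integers(0, 2 ** 16))
def test_precision_is_scale_equivariant(scale, seed):
    rng = np.random.default_rng(seed)
    d = rng.normal(0, 1, 8)
    assert precision_value(d * scale) == pytest.approx(
        scale * precision_value(d), rel=1e-9)


def test_t_critical_decreases_toward_normal_quantile():
    values = [t_critical(n) for n in (3, 5, 10, 50, 1000)]
    assert all(a > b for a, b in zip(values, values[1:]))
    assert values[-1] == pytest.approx(1.96, abs=0.01)
    assert all(v > 1.959 for v in values)


def test_coverage_of_plus_minus_precision_is_95_percent():
    """±precision from n double measurements covers a fresh measurement
    ~95% of the time (the defining property of the precision value)."""
    rng = np.random.default_rng(12345)
    n, reps, sigma = 8, 10_000, 0.2
    samples = rng.normal(0, sigma, (reps, n))
    fresh = rng.normal(0, sigma, reps)
    prec = samples.std(axis=1, ddof=1) * t_critical(n)
    coverage = float(np.mean(np.abs(fresh) <= prec))
    assert coverage == pytest.approx(0.95, abs=0.02)


# --------------------------------------------------------------------- #
# normality screening
# --------------------------------------------------------------------- #
def test_normal_samples_rarely_rejected():
    rng = np.random.default_rng(7)
    accepted = 0
    for rep in range(50):
        x = rng.standard_normal(500)
        _, p = ks_normality(x, n_sims=400, seed=rep)
        accepted += p > 0.05
    assert accepted >= 45  # >= 90% of repetitions


def test_uniform_samples_rejected():
    rng = np.random.default_rng(8)
    _, p = ks_normality(rng.uniform(0, 1, 500), n_sims=400, seed=0)
    assert p < 0.05


def test_constant_sample_degenerate():
    with pytest.raises(DegenerateSampleError):
        ks_normality([1.0, 1.0, 1.0, 1.0])


def test_tiny_sample_insufficient():
    with pytest.raises(InsufficientDataError):
        ks_normality([0.1, 0.2, 0.3])


# --------------------------------------------------------------------- #
# study summaries
# --------------------------------------------------------------------- #
def _result(rng=None, zero=False):
    if zero:
        return decompose(RigidTransform.identity())
    T = RigidTransform.from_axis_angle(
        rng.normal(size=3), rng.normal(0, 0.1),
        translation=rng.normal(0, 0.05, 3))
    return decompose(T)


def test_zero_study_has_zero_precisions():
    study = DoubleExamStudy([_result(zero=True) for _ in range(5)],
                            label="zeros")
    report = summarize_study(study)
    for m in ("tx", "ty", "tz", "tt", "rx", "ry", "rz"):
        assert report.precision(m) == 0.0
        assert report.table.loc[m, "t_critical"] == pytest.approx(
            2.776445, abs=1e-6)


def test_summary_invariant_under_patient_permutation():
    rng = np.random.default_rng(5)
    results = [_result(rng) for _ in range(9)]
    r1 = summarize_study(DoubleExamStudy(list(results)))
    rng2 = np.random.default_rng(99)
    shuffled = list(results)
    rng2.shuffle(shuffled)
    r2 = summarize_study(DoubleExamStudy(shuffled))
    assert np.allclose(r1.table["precision"], r2.table["precision"])
    assert np.allclose(r1.table["ks_statistic"], r2.table["ks_statistic"],
                       equal_nan=True)


def test_tt_precision_computed_on_per_exam_tt_values():
    rng = np.random.default_rng(6)
    results = [_result(rng) for _ in range(8)]
    study = DoubleExamStudy(results)
    report = summarize_study(study)
    tt = np.array([r.total_translation for r in results])
    assert report.precision("tt") == pytest.approx(
        np.std(tt, ddof=1) * t_critical(8))


def test_study_round_trip_through_directory(tmp_path):
    rng = np.random.default_rng(7)
    results = [_result(rng) for _ in range(4)]
    for i, r in enumerate(results):
        r.save(tmp_path / f"p{i:02d}.json")
    study = DoubleExamStudy.from_dir(tmp_path, label="disk")
    assert len(study) == 4
    assert np.allclose(study.values("tt"),
                       [r.total_translation for r in results])


def test_study_needs_two_exams():
    with pytest.raises(InsufficientDataError):
        DoubleExamStudy([_result(zero=True)])


# --------------------------------------------------------------------- #
# dose
# --------------------------------------------------------------------- #
def test_dose_worked_examples():
    assert effective_dose(0.0, 0.015).effective_dose == 0.0
    assert effective_dose(100.0, 0.015).effective_dose == pytest.approx(1.5)
    assert effective_dose(153.3, 0.015).effective_dose == pytest.approx(2.2995)


@settings(deadline=None, max_examples=60)
@given(st.floats(0, 1e4), st.floats(1e-4, 1.0))
def test_dose_is_exact_product_with_units(dlp, k):
    rec = effective_dose(dlp, k)
    assert rec.effective_dose == dlp * k
    d = rec.to_dict()
    assert d["dlp_mGycm"] == dlp and d["k_mSv_per_mGycm"] == k


def test_negative_dose_inputs_rejected():
    with pytest.raises(ValueError):
        effective_dose(-1.0, 0.015)
    with pytest.raises(ValueError):
        effective_dose(100.0, 0.0)
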