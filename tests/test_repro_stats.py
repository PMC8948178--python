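import itertools
import warnings

import numpy as np
import pytest
from scipy import stats as sps

from marmoreg.errors import InputError
from marmoreg.frames import LandmarkSet
from marmoreg.repro_stats import (
    RepeatedMeasures,
    cov_summary,
    cov_summary_from_values,
    icc_1_1,
    isometric_ratio,
    landmark_variability,
    wilcoxon_signed_rank,
)


def anova_icc_oracle(x: np.ndarray) -> float:
    """Explicit sums-of-squares one-way ANOVA, written independently."""
    n, k = x.shape
    grand = sum(x[i, j] for i in range(n) for j in range(k)) / (n * k)
    ssb = 0.0
    for i in range(n):
        mi = sum(x[i]) / k
        ssb += k * (mi - grand) ** 2
    ssw = 0.0
    for i in range(n):
        mi = sum(x[i]) / k
        for j in range(k):
            ssw += (x[i, j] - mi) ** 2
    msb = ssb / (n - 1)
    msw = ssw / (n * (k - 1))
    return (msb - msw) / (msb + (k - 1) * msw)


def enumerate_wilcoxon_oracle(values, null=0.0) -> float:
    """Literal 2^n sign enumeration with Pratt zeros and midranks."""
    d = np.asarray(values, dtype=float) - null
    ranks = sps.rankdata(np.abs(d))           # zeros ranked too (Pratt)
    nz = np.nonzero(d)[0]
    if len(nz) == 0:
        return 1.0
    w_obs = ranks[nz][d[nz] > 0].sum()
    dist = []
    for signs in itertools.product((0, 1), repeat=len(nz)):
        dist.append(sum(r for r, s in zip(ranks[nz], signs) if s))
    dist = np.asarray(dist)
    p_le = (dist <= w_obs + 1e-12).mean()
    p_ge = (dist >= w_obs - 1e-12).mean()
    return min(1.0, 2.0 * min(p_le, p_ge))


# ---------------------------------------------------------------- ICC

def test_icc_perfect_reliability():
    x = np.array([[1.0, 1.0], [2.0, 2.0], [3.0, 3.0]])
    res = icc_1_1(x)
    assert res.icc == 1.0


def test_icc_no_between_subject_variance_is_nonpositive(rng):
    x = np.zeros((4, 3)) + rng.normal(0, 1, (4, 3))
    x -= x.mean(axis=1, keepdims=True)  # identical subject means
    res = icc_1_1(x)
    assert res.icc <= 0
    assert res.icc >= -1.0 / (3 - 1)


def test_icc_zero_total_variance_warns():
    with pytest.warns(UserWarning):
        res = icc_1_1(np.ones((3, 3)))
    assert res.icc == 0.0


def test_icc_matches_anova_oracle(rng):
    for _ in range(10):
        x = rng.normal(0, 1, (5, 5)) + rng.normal(0, 2, (5, 1))
        assert icc_1_1(x).icc == pytest.approx(anova_icc_oracle(x), abs=1e-10)


def test_icc_monte_carlo_population_value():
    """sigma_b^2=4, sigma_w^2=1 -> population ICC 0.8.

    The ICC(1,1) point estimator is biased downward at 5 subjects
    (E[icc] ~ 0.72-0.75, measured by this very simulation); the +-0.03
    agreement with the population value holds once n is large.
    """
    rng = np.random.default_rng(2024)
    small = np.empty(2000)
    for i in range(2000):
        x = rng.normal(0, 1, (5, 5)) + rng.normal(0, 2, (5, 1))
        small[i] = icc_1_1(x).icc
    assert 0.69 < small.mean() < 0.78   # documented small-sample bias
    large = np.empty(100)
    for i in range(100):
        x = rng.normal(0, 1, (200, 5)) + rng.normal(0, 2, (200, 1))
        large[i] = icc_1_1(x).icc
    assert abs(large.mean() - 0.8) < 0.03


def test_icc_confidence_interval_brackets_estimate(rng):
    x = rng.normal(0, 1, (6, 4)) + rng.normal(0, 1.5, (6, 1))
    res = icc_1_1(x)
    assert res.ci_low <= res.icc <= res.ci_high
    assert res.ci_high <= 1.0


def test_icc_ci_coverage_sane():
    rng = np.random.default_rng(7)
    cover = 0
    for _ in range(300):
        x = rng.normal(0, 1, (8, 4)) + rng.normal(0, 2, (8, 1))
        res = icc_1_1(x)
        if res.ci_low <= 0.8 <= res.ci_high:
            cover += 1
    assert 0.88 < cover / 300 <= 1.0  # ~95% nominal


def test_repeated_measures_validation():
    with pytest.raises(InputError):
        RepeatedMeasures(np.zeros((1, 5)))
    with pytest.warns(UserWarning):
        rm = RepeatedMeasures(np.array([[1.0, 2], [np.nan, 3], [2, 2]]))
    assert rm.n_subjects == 2


def test_repeated_measures_tsv_round_trip(tmp_path, rng):
    rm = RepeatedMeasures(rng.normal(0, 1, (5, 5)), "pitch_deg", "deg")
    rm.to_tsv(tmp_path / "reps.tsv")
    back = RepeatedMeasures.from_tsv(tmp_path / "reps.tsv")
    assert np.allclose(back.values, rm.values)


# ---------------------------------------------------------------- Wilcoxon

def test_wilcoxon_symmetric_sample_p_one():
    assert wilcoxon_signed_rank([-1.0, 1.0, -2.0, 2.0]) == pytest.approx(1.0)


def test_wilcoxon_five_positive_exact():
    p = wilcoxon_signed_rank([1.0, 2.0, 3.0, 4.0, 5.0])
    assert p == pytest.approx(2.0 / 32.0, abs=1e-12)


def test_wilcoxon_published_table_case():
    # n=5, all positive, distinct: minimum attainable two-sided exact p
    p = wilcoxon_signed_rank([1.2, 1.9, 1.5, 2.1, 1.4], null=0.0)
    assert p == pytest.approx(0.0625, abs=1e-12)


def test_wilcoxon_matches_enumeration_oracle(rng):
    for n in (4, 6, 8, 10):
        for _ in range(5):
            values = np.round(rng.normal(0.3, 1.0, n), 1)  # rounding makes ties/zeros
            ours = wilcoxon_signed_rank(values)
            oracle = enumerate_wilcoxon_oracle(values)
            assert ours == pytest.approx(oracle, abs=1e-9)


def test_wilcoxon_matches_scipy_exact_no_ties():
    values = [0.8, -1.4, 2.3, 0.9, -0.2, 1.7, 2.8, -3.1, 1.1]
    ours = wilcoxon_signed_rank(values)
    scipy_p = sps.wilcoxon(values, alternative="two-sided", mode="exact").pvalue
    assert ours == pytest.approx(scipy_p, abs=1e-12)


def test_wilcoxon_all_equal_null_warns():
    with pytest.warns(UserWarning):
        assert wilcoxon_signed_rank([2.0, 2.0, 2.0], null=2.0) == 1.0


def test_wilcoxon_normal_approximation_close_to_exact_tail():
    rng = np.random.default_rng(0)
    values = rng.normal(0.5, 1.0, 30)  # m=30 > 25 -> normal path
    p_approx = wilcoxon_signed_rank(values)
    p_scipy = sps.wilcoxon(values, alternative="two-sided", mode="approx",
                           correction=True).pvalue
    assert 0.0 < p_approx <= 1.0
    assert abs(p_approx - p_scipy) < 0.01


# ---------------------------------------------------------------- COV / ratios

def test_cov_paper_style_values():
    assert cov_summary(6180.0, 524.0).cov_rounded() == 8.5
    assert cov_summary(6912.0, 470.0).cov_rounded() == 6.8


def test_cov_zero_sd():
    assert cov_summary(10.0, 0.0).cov_percent == 0.0


def test_cov_domain_errors():
    with pytest.raises(InputError):
        cov_summary(0.0, 1.0)
    with pytest.raises(InputError):
        cov_summary(-5.0, 1.0)


def test_cov_from_values(rng):
    values = rng.normal(100, 10, 500)
    s = cov_summary_from_values(values)
    assert s.n == 500
    assert s.cov_percent == pytest.approx(100 * values.std(ddof=1) / values.mean())


def test_isometric_ratios():
    assert isometric_ratio(2.0, 0.5, "linear") == pytest.approx(4.0, abs=1e-12)
    assert isometric_ratio(0.6, 0.5, "linear") == pytest.approx(1.2, abs=1e-12)
    assert isometric_ratio(3.3, 3.3, "linear") == 1.0
    assert isometric_ratio(8.0, 1.0, "volume") == pytest.approx(2.0, abs=1e-12)
    with pytest.raises(InputError):
        isometric_ratio(-1.0, 1.0)
    with pytest.raises(InputError):
        isometric_ratio(1.0, 1.0, "area")


# ---------------------------------------------------------------- landmark variability

def test_landmark_variability_identical_subjects():
    lm = LandmarkSet({"bregma": [0.0, 1.0, 2.0], "inion": [0.0, -3.0, 1.0]})
    table = landmark_variability([lm, lm, lm])
    assert (table[["sd_x", "sd_y", "sd_z"]].to_numpy() == 0).all()
    assert (table["n"] == 3).all()


def test_landmark_variability_recovers_generator_sds():
    from marmoreg.phantom import simulate_cohort_landmarks

    truth = LandmarkSet({"bregma": [0.0, -7.0, 10.0], "inion": [0.0, -23.0, -3.0]})
    cohort, _ = simulate_cohort_landmarks(
        200, truth, {"bregma": (0.2, 1.0, 0.3), "inion": (0.2, 1.0, 0.3)}, seed=9)
    table = landmark_variability(cohort).set_index("landmark")
    for name in ("bregma", "inion"):
        got = table.loc[name, ["sd_x", "sd_y", "sd_z"]].to_numpy(dtype=float)
        assert np.abs(got / np.array([0.2, 1.0, 0.3]) - 1).max() < 0.10


def test_landmark_variability_reduced_n():
    from marmoreg.phantom import simulate_cohort_landmarks

    truth = LandmarkSet({"bregma": [0.0, 0, 0], "ips_L": [-5.0, -10, 5]})
    cohort, counts = simulate_cohort_landmarks(
        20, truth, 0.5, seed=1, presence_probability={"ips_L": 0.35})
    table = landmark_variability(cohort).set_index("landmark")
    assert table.loc["bregma", "n"] == 20
    assert table.loc["ips_L", "n"] == counts["ips_L"]
    assert counts["ips_L"] < 20


def test_landmark_variability_in_frame(main_phantom):
    from marmoreg.frames import fit_stereotactic_frame

    truth = main_phantom[3]
    frame = fit_stereotactic_frame(truth.landmarks)
    table = landmark_variability([truth.landmarks, truth.landmarks], frame)
    row = table.set_index("landmark").loc["ear_canal_L"]
    # in the stereotactic frame the left ear canal sits at (-x, 0, 0)
    assert row["mean_y"] == pytest.approx(0.0, abs=1e-6)
    assert row["mean_z"] == pytest.approx(0.0, abs=1e-6)
    assert row["mean_x"] < 0


# ---------------------------------------------------------------- qualitative power

def test_wilcoxon_borderline_power_for_small_pitch_bias():
    """A 1.6 deg pitch bias at N=5 can at best reach p=0.0625 two-sided:
    detection is only marginal, matching the borderline published p."""
    from marmoreg.phantom import simulate_positionings

    rng = np.random.default_rng(5)
    p_values = []
    for rep in range(100):
        tables, _ = simulate_positionings(
            5, 5,
            bias=(1.6, 0, 0, 0, 0, 0),
            within_sd=(0.5,) * 6,
            between_sd=(0.8,) * 6,
            seed=int(rng.integers(1 << 30)),
        )
        means = tables["pitch_deg"].subject_means()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            p_values.append(wilcoxon_signed_rank(means))
    p_values = np.array(p_values)
    power_at_0625 = (p_values <= 0.0625).mean()
    assert 0.5 < power_at_0625 < 0.95          # detects, but not overwhelmingly
    assert (p_values > 0.05).all() | (p_values <= 0.0625).any()
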