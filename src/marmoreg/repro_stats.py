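"""Bias and reproducibility statistics for repeated positionings and
cohort landmark variability.

Implements ICC(1,1) from a one-way random-effects ANOVA with the classic
F-based 95% confidence interval, an exact Wilcoxon signed-rank test
(Pratt handling of zeros, midranks for ties), coefficient-of-variation
summaries, isometric scale ratios, and per-landmark variability tables.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InputError
from .frames import FrameDefinition, LandmarkSet

__all__ = [
    "RepeatedMeasures",
    "ICCResult",
    "VariabilitySummary",
    "icc_1_1",
    "wilcoxon_signed_rank",
    "cov_summary",
    "cov_summary_from_values",
    "isometric_ratio",
    "landmark_variability",
]


@dataclass
class RepeatedMeasures:
    """A subjects x repetitions matrix of one scalar parameter."""

    values: np.ndarray
    parameter: str = ""
    units: str = ""

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2:
            raise InputError("RepeatedMeasures needs a 2D subjects x repetitions array")
        if np.isnan(values).any():
            keep = ~np.isnan(values).any(axis=1)
            warnings.warn(
                f"{(~keep).sum()} subject(s) with missing cells excluded listwise")
            values = values[keep]
        if values.shape[0] < 2 or values.shape[1] < 2:
            raise InputError(
                f"need >= 2 subjects and >= 2 repetitions, got {values.shape}")
        self.values = values

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_reps(self) -> int:
        return self.values.shape[1]

    def subject_means(self) -> np.ndarray:
        return self.values.mean(axis=1)

    def to_tsv(self, path) -> None:
        pd.DataFrame(
            self.values,
            index=[f"subject{i + 1}" for i in range(self.n_subjects)],
            columns=[f"rep{j + 1}" for j in range(self.n_reps)],
        ).to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path, parameter: str = "", units: str = "") -> "RepeatedMeasures":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(df.to_numpy(dtype=float), parameter, units)


@dataclass(frozen=True)
class ICCResult:
    icc: float
    ci_low: float
    ci_high: float
    ms_between: float
    ms_within: float
    n_subjects: int
    n_reps: int


def icc_1_1(rm: "RepeatedMeasures | np.ndarray", alpha: float = 0.05) -> ICCResult:
    """One-way random-effects intraclass correlation ICC(1,1).

    ICC = (MSB - MSW) / (MSB + (k-1) MSW) with the F-based two-sided
    confidence interval (Shrout & Fleiss form):
    ``FL = F / F_{1-a/2}(n-1, n(k-1))``, ``FU = F * F_{1-a/2}(n(k-1), n-1)``,
    and bounds ``(F* - 1) / (F* + k - 1)``.
    """
    if not isinstance(rm, RepeatedMeasures):
        rm = RepeatedMeasures(rm)
    x = rm.values
    n, k = x.shape
    grand = x.mean()
    means = x.mean(axis=1)
    ssb = k * np.sum((means - grand) ** 2)
    ssw = np.sum((x - means[:, None]) ** 2)
    msb = ssb / (n - 1)
    msw = ssw / (n * (k - 1))

    if msb == 0 and msw == 0:
        warnings.warn("zero total variance; ICC undefined, returning 0")
        return ICCResult(0.0, 0.0, 0.0, 0.0, 0.0, n, k)
    if msw == 0:
        return ICCResult(1.0, 1.0, 1.0, msb, 0.0, n, k)

    icc = (msb - msw) / (msb + (k - 1) * msw)
    f = msb / msw
    fl = f / stats.f.ppf(1 - alpha / 2, n - 1, n * (k - 1))
    fu = f * stats.f.ppf(1 - alpha / 2, n * (k - 1), n - 1)
    ci_low = (fl - 1) / (fl + k - 1)
    ci_high = (fu - 1) / (fu + k - 1)
    return ICCResult(float(icc), float(ci_low), float(ci_high),
                     float(msb), float(msw), n, k)


def _signed_rank_statistic(diffs: np.ndarray) -> tuple:
    """Pratt zeros + midranks.  Returns (W+, doubled ranks of nonzero diffs,
    signs), with ranks doubled so midranks stay integral."""
    absd = np.abs(diffs)
    order_ranks = stats.rankdata(absd)          # zeros included in ranking (Pratt)
    nonzero = absd > 0
    ranks2 = np.rint(2 * order_ranks[nonzero]).astype(int)
    signs = np.sign(diffs[nonzero]).astype(int)
    w_plus2 = int(ranks2[signs > 0].sum())
    return w_plus2, ranks2, signs


def wilcoxon_signed_rank(values: Sequence[float], null: float = 0.0) -> float:
    """Exact two-sided Wilcoxon signed-rank p-value against a point null.

    Zeros are handled by the Pratt method (ranked, then discarded from the
    signing) and ties by midranks.  For up to 25 informative observations
    the null distribution of W+ is computed exactly (equivalent to
    enumerating all 2^m sign patterns); beyond that a tie-corrected normal
    approximation with continuity correction is used.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 1 or len(values) == 0:
        raise InputError("wilcoxon_signed_rank needs a non-empty 1D sample")
    diffs = values - null
    w_plus2, ranks2, signs = _signed_rank_statistic(diffs)
    m = len(ranks2)
    if m == 0:
        warnings.warn("all values equal the null; p = 1")
        return 1.0

    if m <= 25:
        # exact distribution of 2*W+ by convolving (1 + x^r)/2 per rank
        total = int(ranks2.sum())
        dist = np.zeros(total + 1)
        dist[0] = 1.0
        for r in ranks2:
            shifted = np.zeros_like(dist)
            shifted[r:] = dist[: total + 1 - r]
            dist = 0.5 * (dist + shifted)
        p_le = dist[: w_plus2 + 1].sum()
        p_ge = dist[w_plus2:].sum()
        return float(min(1.0, 2.0 * min(p_le, p_ge)))

    # normal approximation (on doubled ranks), with tie/zero-aware moments
    mean = ranks2.sum() / 2.0
    var = np.sum(ranks2.astype(float) ** 2) / 4.0
    if var == 0:
        return 1.0
    z = (w_plus2 - mean - 0.5 * np.sign(w_plus2 - mean)) / np.sqrt(var)
    return float(min(1.0, 2.0 * stats.norm.sf(abs(z))))


@dataclass(frozen=True)
class VariabilitySummary:
    mean: float
    sd: float
    cov_percent: float
    n: Optional[int] = None

    def cov_rounded(self, decimals: int = 1) -> float:
        return round(self.cov_percent, decimals)


def cov_summary(mean: float, sd: float, n: Optional[int] = None) -> VariabilitySummary:
    """Coefficient of variation, 100·SD/mean (percent)."""
    if mean <= 0:
        raise InputError(f"COV undefined for non-positive mean ({mean})")
    if sd < 0:
        raise InputError("SD must be non-negative")
    return VariabilitySummary(float(mean), float(sd), 100.0 * sd / mean, n)


def cov_summary_from_values(values: Sequence[float]) -> VariabilitySummary:
    values = np.asarray(values, dtype=float)
    if len(values) < 2:
        raise InputError("need >= 2 values for a COV summary")
    return cov_summary(float(values.mean()), float(values.std(ddof=1)), n=len(values))


def isometric_ratio(value_a: float, value_b: float, kind: str = "linear") -> float:
    """Scale ratio of a relative to b: ``a/b`` for linear measures,
    ``(a/b)^(1/3)`` for volumes (isometric scaling)."""
    if value_a <= 0 or value_b <= 0:
        raise InputError("isometric_ratio requires positive inputs")
    if kind == "linear":
        return float(value_a / value_b)
    if kind == "volume":
        return float((value_a / value_b) ** (1.0 / 3.0))
    raise InputError(f"unknown ratio kind {kind!r}; use 'linear' or 'volume'")


def landmark_variability(
    cohort: Sequence[LandmarkSet],
    frame: Optional[FrameDefinition] = None,
) -> pd.DataFrame:
    """Per-landmark, per-axis mean and SD across a cohort.

    Landmarks are transformed into *frame* (if given) before averaging.
    Landmarks absent in some subjects are reported with the reduced n.
    Columns: landmark, n, mean_x/y/z, sd_x/y/z.
    """
    cohort = list(cohort)
    if len(cohort) < 2:
        raise InputError("need >= 2 subjects for landmark variability")
    if frame is not None:
        cohort = [lm.transformed(frame.to_frame) for lm in cohort]

    names = []
    for lm in cohort:
        for n in lm.names:
            if n not in names:
                names.append(n)
    rows = []
    for name in names:
        coords = np.array([lm[name] for lm in cohort if name in lm])
        n = len(coords)
        mean = coords.mean(axis=0)
        sd = coords.std(axis=0, ddof=1) if n > 1 else np.full(3, np.nan)
        rows.append({
            "landmark": name, "n": n,
            "mean_x": mean[0], "mean_y": mean[1], "mean_z": mean[2],
            "sd_x": sd[0], "sd_y": sd[1], "sd_z": sd[2],
        })
    return pd.DataFrame(rows)
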