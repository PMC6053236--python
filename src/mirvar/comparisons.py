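"""Protocol, material and platform comparison statistics.

Student t-tests for the centrifugation-protocol and order-of-draw
checks, Spearman rank correlation for cross-material and cross-platform
agreement, and the paired-means sample-size rule used to size the
centrifugation comparison.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateVarianceError

#: Qualitative correlation labels (presentation convention of this
#: package, not a standard): |rho| < 0.3 none, 0.3-0.7 intermediate,
#: > 0.7 good.
CORRELATION_LABELS = ((0.3, "none"), (0.7, "intermediate"), (1.01, "good"))


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    n1: int
    n2: int
    test_kind: str  # student_t_two_sample | student_t_paired


@dataclass(frozen=True)
class CorrelationResult:
    rho: float
    p_value: float
    n: int
    label: str


@dataclass(frozen=True)
class SampleSizeSpec:
    """Design parameters of the paired-means power calculation."""

    relative_difference: float = 0.10  # detectable difference, fraction of mean
    relative_sd: float = 0.20          # SD as fraction of mean
    pair_correlation: float = 0.85
    alpha: float = 0.05                # two-sided
    power: float = 0.8

    def effect_size(self) -> float:
        """Paired effect size d = diff / (SD * sqrt(2(1 - rho)))."""
        if not 0 < self.power < 1:
            raise ValueError("power must be in (0, 1)")
        if self.pair_correlation >= 1:
            raise ValueError("pair correlation must be < 1")
        sd_diff = self.relative_sd * math.sqrt(2.0 * (1.0 - self.pair_correlation))
        if sd_diff == 0 or self.relative_difference == 0:
            raise ValueError("degenerate design: zero difference or SD")
        return abs(self.relative_difference) / sd_diff


def _student_t(x: np.ndarray, y: np.ndarray, paired: bool) -> TestResult:
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each group needs at least 2 values")
    kind = "student_t_paired" if paired else "student_t_two_sample"
    if paired:
        if len(x) != len(y):
            raise ValueError("paired test needs equal group sizes")
        d = x - y
        if np.ptp(d) == 0.0:
            if d[0] == 0.0:
                return TestResult(0.0, 1.0, len(x), len(y), kind)
            raise DegenerateVarianceError("constant nonzero paired differences")
        res = stats.ttest_rel(x, y)
    else:
        if np.ptp(x) == 0.0 and np.ptp(y) == 0.0:
            if x[0] == y[0]:
                # Identical constant groups: no evidence of a difference.
                return TestResult(0.0, 1.0, len(x), len(y), kind)
            raise DegenerateVarianceError(
                "zero within-group variance with differing means"
            )
        res = stats.ttest_ind(x, y, equal_var=True)
    return TestResult(
        float(res.statistic), float(res.pvalue), len(x), len(y), kind
    )


def compare_protocols(
    levels: pd.DataFrame, pairing: str = "unpaired"
) -> pd.DataFrame:
    """Dual vs prolonged single centrifugation, per assay x strategy.

    ``unpaired`` (default) is the equal-variance two-sample Student t;
    ``paired_by_adjacent_tube`` pairs each dual tube with the next tube
    drawn (draw order 1-2, 3-4, ...), honouring the single-venipuncture
    design. Expects a normalized-level table with a ``protocol`` column.
    """
    if pairing not in ("unpaired", "paired_by_adjacent_tube"):
        raise ValueError(f"unknown pairing {pairing!r}")
    rows = []
    for (assay, strategy), grp in levels.groupby(["assay", "strategy"], sort=True):
        dual = grp[grp["protocol"] == "dual"]
        single = grp[grp["protocol"] == "single"]
        if dual.empty or single.empty:
            raise ValueError(f"{assay}/{strategy}: a protocol group is empty")
        if pairing == "paired_by_adjacent_tube":
            d = dual.sort_values("draw_order")["level"].to_numpy(float)
            s = single.sort_values("draw_order")["level"].to_numpy(float)
            if len(d) != len(s):
                raise ValueError("paired mode needs equal protocol groups")
            result = _student_t(d, s, paired=True)
        else:
            result = _student_t(
                dual["level"].to_numpy(float),
                single["level"].to_numpy(float),
                paired=False,
            )
        rows.append(
            {
                "assay": assay,
                "strategy": strategy,
                "statistic": result.statistic,
                "p_value": result.p_value,
                "n_dual": result.n1,
                "n_single": result.n2,
                "test_kind": result.test_kind,
            }
        )
    return pd.DataFrame(rows)


def order_of_draw_test(levels: pd.DataFrame) -> pd.DataFrame:
    """First 10 vs last 10 tubes drawn, per assay x strategy.

    The middle 10 tubes are excluded. Raises
    :class:`DegenerateVarianceError` on constant data with differing
    group means (and returns p = 1 for identical constant groups, where
    there is trivially no order effect).
    """
    if levels["draw_order"].isna().any():
        raise ValueError("order_of_draw_test requires draw_order on every row")
    out = []
    for (assay, strategy), grp in levels.groupby(["assay", "strategy"], sort=True):
        grp = grp.sort_values("draw_order")
        vals = grp["level"].to_numpy(float)
        n = len(grp)
        k = n // 3  # first/last third: 10 tubes each in the 30-tube design
        first = vals[:k]
        last = vals[n - k:]
        result = _student_t(first, last, paired=False)
        out.append(
            {
                "assay": assay,
                "strategy": strategy,
                "statistic": result.statistic,
                "p_value": result.p_value,
                "n_first": len(first),
                "n_last": len(last),
            }
        )
    return pd.DataFrame(out)


def _spearman_exact_p(x: np.ndarray, y: np.ndarray, rho_obs: float) -> float:
    """Two-sided exact permutation p for Spearman rho at small n:
    fraction of all n! orderings of y whose |rho| >= |rho_obs|."""
    n = len(x)
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    count = 0
    total = 0
    target = abs(rho_obs) - 1e-12
    for perm in itertools.permutations(range(n)):
        r = np.corrcoef(rx, ry[list(perm)])[0, 1]
        if abs(r) >= target:
            count += 1
        total += 1
    return count / total


def correlate(
    levels_x: Sequence[float] | pd.Series,
    levels_y: Sequence[float] | pd.Series,
    exact_max_n: int = 8,
) -> CorrelationResult:
    """Spearman rank correlation of two matched-by-sample level vectors.

    Average ranks for ties; two-sided p from the t-approximation on
    n - 2 df, replaced by the exhaustive permutation distribution when
    n <= ``exact_max_n``.
    """
    x = np.asarray(levels_x, float)
    y = np.asarray(levels_y, float)
    if len(x) != len(y):
        raise ValueError("correlate needs matched vectors of equal length")
    n = len(x)
    if n < 5:
        raise ValueError("correlate needs at least 5 matched pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateVarianceError("zero variance in a correlation input")
    rho = float(stats.spearmanr(x, y).statistic)
    if n <= exact_max_n:
        p = _spearman_exact_p(x, y, rho)
    elif abs(rho) >= 1.0:
        p = 0.0
    else:
        t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
        p = float(2.0 * stats.t.sf(abs(t), n - 2))
    label = next(lab for cut, lab in CORRELATION_LABELS if abs(rho) < cut)
    return CorrelationResult(rho=rho, p_value=min(p, 1.0), n=n, label=label)


def correlate_tables(
    levels_x: pd.DataFrame, levels_y: pd.DataFrame, on: str = "subject_id"
) -> pd.DataFrame:
    """Per assay x strategy Spearman correlation of two level tables
    matched by subject (e.g. PPP vs standard plasma, qPCR vs ddPCR)."""
    rows = []
    keys = ["assay", "strategy"]
    merged = levels_x.merge(
        levels_y, on=keys + [on], suffixes=("_x", "_y"), how="inner"
    )
    for (assay, strategy), grp in merged.groupby(keys, sort=True):
        try:
            res = correlate(grp["level_x"], grp["level_y"])
            row = {"rho": res.rho, "p_value": res.p_value, "n": res.n,
                   "label": res.label}
        except DegenerateVarianceError:
            # constant levels (e.g. a zero-variance simulation): ranks
            # carry no information, the coefficient is undefined
            row = {"rho": float("nan"), "p_value": float("nan"),
                   "n": len(grp), "label": "undefined"}
        rows.append({"assay": assay, "strategy": strategy, **row})
    return pd.DataFrame(rows)


def paired_sample_size(spec: SampleSizeSpec = SampleSizeSpec()) -> int:
    """Samples per group for the paired-means design.

    Solves ``n = (t_{1-a/2, n-1} + t_{power, n-1})^2 / d^2`` to a fixed
    point by damped iteration on a continuous n (df floored at 1), then
    rounds up; never returns less than 2. At the study's parameters
    (10% difference, 20% SD, rho 0.85, alpha 0.05, power 0.8) this gives
    n = 12 per protocol.
    """
    d = spec.effect_size()
    n = 4.0
    for _ in range(500):
        df = max(n - 1.0, 1.0)
        t_alpha = stats.t.ppf(1.0 - spec.alpha / 2.0, df)
        t_beta = stats.t.ppf(spec.power, df)
        n_new = (t_alpha + t_beta) ** 2 / d**2
        if abs(n_new - n) < 1e-10:
            n = n_new
            break
        n = 0.5 * n + 0.5 * n_new
    return max(2, math.ceil(n - 1e-9))
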