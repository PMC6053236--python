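"""Repeatability, precision and preanalytical variance attribution.

The pooled-sample design yields, per assay x platform x strategy, k runs
each contributing a duplicate pair of final normalized levels (the two
RT replicates, each already averaged over its PCR wells). From those:

* repeatability (intra-assay CV): pooled within-run duplicate SD
  (Dahlberg form ``sqrt(sum d_i^2 / 2k)``) over the grand mean;
* precision (inter-assay CV): CV of the k run means (default), or of
  all 2k individual values (``inter_from='all_values'``) — the study
  text does not pin down which of the two readings was used, so both
  are exposed.

The attribution statistic compares the whole-procedure CV (plasma
preparation + purification + RT-qPCR, from the centrifugation
experiment) with the RT-qPCR-only repeatability CV:
``fraction = 100 * (CV_total - CV_rep) / CV_total`` with ``CV_total``
the mean of the dual- and single-centrifugation CVs.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import DegenerateVarianceError

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class PrecisionEstimate:
    assay: str
    platform: str
    strategy: str
    grand_mean: float
    sd_total: float
    cv_inter: float  # percent
    cv_intra: float  # percent
    n_runs: int


@dataclass(frozen=True)
class AttributionResult:
    assay: str
    strategy: str
    cv_total: float               # percent, mean of per-protocol CVs
    cv_rt_qpcr: float             # percent, qPCR repeatability
    fraction_preanalytical: float  # percent, not rounded


def cv(values: Sequence[float]) -> float:
    """Coefficient of variation ``(SD / mean) * 100`` with the sample SD
    (n-1 denominator)."""
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise ValueError("cv needs at least 2 values")
    mean = arr.mean()
    if mean <= 0:
        raise ValueError("cv undefined for non-positive mean")
    return float(arr.std(ddof=1) / mean * 100.0)


def fold_difference(delta_ct: float) -> float:
    """Fold change implied by a Ct difference: ``2^|dCt|`` (8 cycles ->
    256-fold, 2 cycles -> 4-fold)."""
    return 2.0 ** abs(delta_ct)


def round_half_up(x: float, decimals: int = 0) -> float:
    """Presentation rounding: round half away from zero at the printed
    precision (1 d.p. for CVs, integers for attribution percentages)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def precision_from_duplicates(
    levels: pd.DataFrame, inter_from: str = "run_means"
) -> list[PrecisionEstimate]:
    """Estimate intra- and inter-assay CVs from the nested duplicate
    design.

    ``levels`` is a normalized-level table (one row per run x RT
    replicate) as produced by :func:`mirvar.quantification.normalize_table`
    on the precision experiment. Runs missing one member of the pair are
    dropped with a warning; fewer than 3 complete runs is an error.
    """
    if inter_from not in ("run_means", "all_values"):
        raise ValueError("inter_from must be 'run_means' or 'all_values'")
    required = {"assay", "platform", "strategy", "run_day", "rt_replicate", "level"}
    missing = required - set(levels.columns)
    if missing:
        raise ValueError(f"levels table lacks columns: {sorted(missing)}")

    out = []
    for (assay, platform, strategy), grp in levels.groupby(
        ["assay", "platform", "strategy"], sort=True
    ):
        pairs = []
        for run, run_grp in grp.groupby("run_day"):
            vals = run_grp.sort_values("rt_replicate")["level"].to_numpy(float)
            if len(vals) != 2:
                log.warning(
                    "run %s of %s/%s/%s has %d replicate level(s), "
                    "expected 2; dropped",
                    run, assay, platform, strategy, len(vals),
                )
                continue
            pairs.append(vals)
        if len(pairs) < 3:
            raise ValueError(
                f"{assay}/{platform}/{strategy}: only {len(pairs)} complete "
                "run(s); need >= 3"
            )
        arr = np.array(pairs)  # shape (k, 2)
        k = arr.shape[0]
        grand_mean = float(arr.mean())
        diffs = arr[:, 0] - arr[:, 1]
        within_sd = math.sqrt(float(np.sum(diffs**2)) / (2 * k))
        cv_intra = within_sd / grand_mean * 100.0
        if inter_from == "run_means":
            cv_inter = cv(arr.mean(axis=1))
        else:
            cv_inter = cv(arr.ravel())
        out.append(
            PrecisionEstimate(
                assay=assay,
                platform=platform,
                strategy=strategy,
                grand_mean=grand_mean,
                sd_total=float(arr.std(ddof=1)),
                cv_inter=cv_inter,
                cv_intra=cv_intra,
                n_runs=k,
            )
        )
    return out


def attribute_preanalytical(
    cv_single: float,
    cv_dual: float,
    cv_repeatability: float,
    assay: str = "",
    strategy: str = "",
) -> AttributionResult:
    """Fraction of whole-procedure intra-assay variation assigned to the
    centrifugation + purification steps.

    ``cv_total`` is the mean of the per-protocol whole-procedure CVs;
    the fraction is ``100 * (cv_total - cv_repeatability) / cv_total``.
    A repeatability above the whole-procedure CV yields a negative
    fraction, reported as-is with a warning (never clamped).
    """
    for name, val in (
        ("cv_single", cv_single), ("cv_dual", cv_dual),
        ("cv_repeatability", cv_repeatability),
    ):
        if val <= 0:
            raise ValueError(f"{name} must be positive")
    cv_total = (cv_single + cv_dual) / 2.0
    fraction = 100.0 * (cv_total - cv_repeatability) / cv_total
    if fraction < 0:
        log.warning(
            "repeatability CV %.2f exceeds whole-procedure CV %.2f: "
            "attribution fraction is negative", cv_repeatability, cv_total,
        )
    return AttributionResult(
        assay=assay,
        strategy=strategy,
        cv_total=cv_total,
        cv_rt_qpcr=cv_repeatability,
        fraction_preanalytical=fraction,
    )


def protocol_cvs(levels: pd.DataFrame) -> pd.DataFrame:
    """Per assay x strategy x protocol mean and CV of normalized levels
    from the centrifugation experiment (the whole-procedure CVs)."""
    rows = []
    for (assay, strategy, protocol), grp in levels.groupby(
        ["assay", "strategy", "protocol"], sort=True
    ):
        vals = grp["level"].to_numpy(float)
        if len(vals) < 2:
            raise DegenerateVarianceError(
                f"{assay}/{strategy}/{protocol}: fewer than 2 samples"
            )
        rows.append(
            {
                "assay": assay,
                "strategy": strategy,
                "protocol": protocol,
                "n": len(vals),
                "mean": float(np.mean(vals)),
                "cv": cv(vals),
            }
        )
    return pd.DataFrame(rows)
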