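"""Raw wells -> per-sample normalized relative levels.

qPCR/TLDA: replicate Cts are averaged first, then normalized as
``level = 2^(-dCt)`` with ``dCt = Ct_target - Ct_ref`` where the
reference is the spike-in (cel-miR-39), the endogenous miR-16, or the
arithmetic mean of both Cts (which makes the combined level the exact
geometric mean of the two single-reference levels).

ddPCR: each well's droplet count is inverted through the Poisson
occupancy model ``lambda = -ln(1 - k/n)``, converted to copies/uL, the
duplicate wells averaged, and the target concentration divided by the
reference concentration (geometric mean of both for the combined
strategy).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .errors import MissingLevelError, SaturationError, ValidationError
from .io_plates import (
    CtMeasurement,
    DropletCount,
    Measurement,
    measurements_to_frame,
)

STRATEGIES = ("spike", "endogenous", "combined")
SPIKE = "cel-miR-39"
ENDOGENOUS_REF = "miR-16"

#: Reference assays consumed by each normalization strategy.
STRATEGY_REFS = {
    "spike": (SPIKE,),
    "endogenous": (ENDOGENOUS_REF,),
    "combined": (SPIKE, ENDOGENOUS_REF),
}


@dataclass(frozen=True)
class NormalizedLevel:
    """A per-sample relative abundance under one reference strategy."""

    sample_id: str
    assay: str
    platform: str
    strategy: str
    level: float
    delta_ct: float | None = None  # qPCR/TLDA only
    n_wells_used: int = 0

    def __post_init__(self):
        if self.level <= 0:
            raise ValidationError("normalized level must be positive")
        if self.strategy not in STRATEGIES:
            raise ValidationError(f"unknown strategy {self.strategy!r}")


@dataclass(frozen=True)
class ConcentrationEstimate:
    """Absolute ddPCR concentration from pooled-well droplet counts."""

    sample_id: str
    assay: str
    copies_per_microlitre: float
    lam: float
    saturated: bool = False


def aggregate_replicates(wells: Sequence[Measurement]) -> tuple[float, int]:
    """Average replicate wells of one sample x assay x platform.

    qPCR/TLDA: arithmetic mean of the determined Cts (undetermined wells
    are excluded). ddPCR: mean of the per-well concentration estimates.
    Returns ``(mean readout, n wells used)``.
    """
    wells = list(wells)
    if not wells:
        raise ValueError("aggregate_replicates needs at least one well")
    first = wells[0]
    if isinstance(first, CtMeasurement):
        cts = [w.ct for w in wells if w.ct is not None]
        if not cts:
            raise MissingLevelError(
                first.meta.sample_id, first.assay, first.platform
            )
        return sum(cts) / len(cts), len(cts)
    concs = [estimate_concentration(w).copies_per_microlitre for w in wells]
    return sum(concs) / len(concs), len(concs)


def normalize_qpcr(
    ct_target: float,
    ct_refs: float | Sequence[float],
    strategy: str,
    sample_id: str = "",
    assay: str = "",
    platform: str = "qPCR",
    n_wells_used: int = 0,
) -> NormalizedLevel:
    """Relative level ``2^(-dCt)`` against one or two reference Cts.

    The combined strategy uses the arithmetic mean of the two reference
    Cts, which equals the geometric mean of the two single-reference
    levels on the linear scale.
    """
    refs = [ct_refs] if isinstance(ct_refs, (int, float)) else list(ct_refs)
    expected = len(STRATEGY_REFS[strategy]) if strategy in STRATEGY_REFS else None
    if expected is None:
        raise ValidationError(f"unknown strategy {strategy!r}")
    if len(refs) != expected:
        raise ValidationError(
            f"strategy {strategy!r} needs {expected} reference Ct(s), "
            f"got {len(refs)}"
        )
    r = sum(refs) / len(refs)
    delta_ct = ct_target - r
    return NormalizedLevel(
        sample_id=sample_id,
        assay=assay,
        platform=platform,
        strategy=strategy,
        level=2.0 ** (-delta_ct),
        delta_ct=delta_ct,
        n_wells_used=n_wells_used,
    )


def estimate_concentration(counts: DropletCount) -> ConcentrationEstimate:
    """Invert the Poisson occupancy model for one ddPCR well.

    ``lambda = -ln(1 - k/n)`` mean copies per droplet;
    ``copies/uL = lambda / droplet volume (uL)``. All droplets positive
    means the occupancy model cannot be inverted (saturation).
    """
    k, n = counts.positives, counts.total_droplets
    if k == n:
        raise SaturationError(
            f"sample {counts.meta.sample_id!r} assay {counts.assay!r}: "
            f"all {n} droplets positive; concentration not estimable"
        )
    lam = -math.log1p(-k / n)
    vol_ul = counts.droplet_volume_nl * 1e-3
    return ConcentrationEstimate(
        sample_id=counts.meta.sample_id,
        assay=counts.assay,
        copies_per_microlitre=lam / vol_ul,
        lam=lam,
        saturated=False,
    )


def normalize_ddpcr(
    conc_target: float,
    conc_refs: float | Sequence[float],
    strategy: str,
    sample_id: str = "",
    assay: str = "",
    n_wells_used: int = 0,
) -> NormalizedLevel:
    """Concentration ratio against one reference or the geometric mean
    of two."""
    refs = [conc_refs] if isinstance(conc_refs, (int, float)) else list(conc_refs)
    expected = len(STRATEGY_REFS[strategy]) if strategy in STRATEGY_REFS else None
    if expected is None:
        raise ValidationError(f"unknown strategy {strategy!r}")
    if len(refs) != expected:
        raise ValidationError(
            f"strategy {strategy!r} needs {expected} reference "
            f"concentration(s), got {len(refs)}"
        )
    if any(r <= 0 for r in refs):
        raise ValidationError("reference concentration must be positive")
    ref = refs[0] if len(refs) == 1 else math.sqrt(refs[0] * refs[1])
    return NormalizedLevel(
        sample_id=sample_id,
        assay=assay,
        platform="ddPCR",
        strategy=strategy,
        level=conc_target / ref,
        n_wells_used=n_wells_used,
    )


def _target_assays(strategy: str, assays: Iterable[str]) -> list[str]:
    """Assays that can be normalized under a strategy: references are
    never normalized to themselves (miR-16 has no miR-16-normalized
    level; the spike has none at all)."""
    refs = set(STRATEGY_REFS[strategy])
    return [a for a in assays if a not in refs and a != SPIKE]


def normalize_table(
    records: Sequence[Measurement],
    strategy: str,
    group_extra: Sequence[str] = (),
) -> pd.DataFrame:
    """Normalize a whole measurement collection into a tidy level table.

    Wells are grouped per sample x platform x (run_day, rt_replicate)
    x assay, replicate wells averaged, then each target assay normalized
    against the strategy's reference assay(s) measured in the same
    group. Samples whose reference is missing or unusable are dropped.

    Returns columns: sample_id, subject_id, material, protocol,
    draw_order, run_day, rt_replicate, platform, assay, strategy,
    delta_ct, level, n_wells_used.
    """
    if strategy not in STRATEGIES:
        raise ValidationError(f"unknown strategy {strategy!r}")
    frame = measurements_to_frame(records)
    keys = [
        "experiment_id", "sample_id", "subject_id", "material", "protocol",
        "draw_order", "run_day", "rt_replicate", "platform",
    ]
    by_group: dict[tuple, dict[str, list[Measurement]]] = {}
    meta_rows: dict[tuple, dict] = {}
    for rec, (_, row) in zip(records, frame.iterrows()):
        key = tuple(row[k] if not pd.isna(row[k]) else None for k in keys)
        by_group.setdefault(key, {}).setdefault(rec.assay, []).append(rec)
        meta_rows[key] = {k: v for k, v in zip(keys, key)}

    out_rows = []
    for key, assays in by_group.items():
        platform = meta_rows[key]["platform"]
        means: dict[str, tuple[float, int]] = {}
        for assay, wells in assays.items():
            try:
                means[assay] = aggregate_replicates(wells)
            except (MissingLevelError, SaturationError):
                continue
        ref_names = STRATEGY_REFS[strategy]
        if any(r not in means for r in ref_names):
            continue
        refs = [means[r][0] for r in ref_names]
        for assay in _target_assays(strategy, assays):
            if assay not in means:
                continue
            value, n_used = means[assay]
            if platform == "ddPCR":
                lev = normalize_ddpcr(
                    value, refs if len(refs) > 1 else refs[0], strategy,
                    sample_id=meta_rows[key]["sample_id"], assay=assay,
                    n_wells_used=n_used,
                )
            else:
                lev = normalize_qpcr(
                    value, refs if len(refs) > 1 else refs[0], strategy,
                    sample_id=meta_rows[key]["sample_id"], assay=assay,
                    platform=platform, n_wells_used=n_used,
                )
            row = dict(meta_rows[key])
            row.update(
                assay=assay,
                strategy=strategy,
                delta_ct=lev.delta_ct,
                level=lev.level,
                n_wells_used=lev.n_wells_used,
            )
            out_rows.append(row)
    return pd.DataFrame(
        out_rows,
        columns=keys + ["assay", "strategy", "delta_ct", "level", "n_wells_used"],
    )
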