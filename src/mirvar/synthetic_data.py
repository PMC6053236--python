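"""Synthetic measurement tables with a hierarchical variance structure.

The generator emulates the four-experiment study design of a plasma
microRNA quality-control study: a 30-tube centrifugation comparison from
one donor, a 50-patient cohort measured in platelet-poor plasma (PPP)
and standard plasma across platforms, and a pooled-sample precision
experiment of 15 runs x duplicate reverse transcription x duplicate PCR.

Noise model (cycles, i.e. log2 scale), for a well of assay ``g`` on
aliquot ``a``, run ``r``, reverse-transcription reaction ``t``::

    ct = mu_ct[g] - log2(level) - e_a + prep_{a,g} + day_{r,g}
         + rt_{t,g} [+ preamp_{s,g}] [+ pipette_a, spike only] + eps_well

``e_a`` is the RNA-extraction efficiency of the aliquot, shared by every
assay including the spike-in, so it cancels under any reference
normalization. ``prep_{a,g}`` is the per-assay residue of plasma
preparation + purification (column losses differ between microRNAs), so
it does *not* cancel and is what the attribution statistic recovers.
``level`` carries the linear-domain biology: per-subject true abundance
plus platelet/hemolysis contamination terms in standard plasma.

ddPCR wells map the same multiplicative level to a concentration and
draw droplet counts from the Poisson occupancy model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from .errors import ValidationError
from .io_plates import (
    ASSAYS,
    DEFAULT_DROPLET_VOLUME_NL,
    CtMeasurement,
    DropletCount,
    Measurement,
    SampleMeta,
)

SPIKE = "cel-miR-39"
ENDOGENOUS_REF = "miR-16"
TLDA_ASSAYS = ("miR-92a", "miR-16", "cel-miR-39")  # no miR-126 primer on card


def _default_mu_ct() -> dict[str, float]:
    # Baselines consistent with the reported fold spacings in PPP:
    # miR-16 ~8 Ct below miR-126 (256-fold), ~3.4 Ct below miR-92a,
    # cel-miR-39 ~1.8 Ct below miR-126 (~4-fold).
    return {
        "cel-miR-39": 24.0,
        "miR-92a": 20.7,
        "miR-126": 25.8,
        "miR-16": 17.3,
    }


def _default_platelet_load() -> dict[str, float]:
    # Linear copies (relative units) per unit residual-platelet index;
    # all three endogenous microRNAs are platelet-expressed.
    return {"miR-92a": 1.5, "miR-126": 1.5, "miR-16": 2.0, "cel-miR-39": 0.0}


@dataclass
class SyntheticConfig:
    """All variance components, effect terms and design sizes.

    SDs are in cycles (log2 units). Setting every SD and load to zero
    (and ``droplet_sampling`` off) makes the generator a deterministic
    function of ``mu_ct``.
    """

    mu_ct: dict[str, float] = field(default_factory=_default_mu_ct)
    sigma_extraction: float = 0.4   # aliquot recovery, shared across assays
    sigma_day: float = 0.15         # between-run, per run x assay
    sigma_prep: float = 0.15        # centrifugation+purification, per aliquot x assay
    sigma_rt: float = 0.06          # per RT reaction x assay
    sigma_pcr: float = 0.07         # per well
    sigma_spike_pipette: float = 0.12  # spike dispensing, per aliquot
    sigma_preamp: float = 2.0       # TLDA pre-amplification, per sample x assay
    platelet_load: dict[str, float] = field(default_factory=_default_platelet_load)
    hemolysis_load: float = 0.5     # miR-16 only, linear copies per unit index
    biological_sd: float = 0.8      # SD of log2 true level across subjects
    n_tubes: int = 30
    n_patients: int = 50
    n_runs: int = 15
    droplets_per_well: int = 16000
    droplet_volume_nl: float = DEFAULT_DROPLET_VOLUME_NL
    ddpcr_spike_concentration: float = 35.0  # copies/uL for cel-miR-39
    droplet_sampling: bool = True
    seed: int = 0

    def __post_init__(self):
        for name in (
            "sigma_extraction", "sigma_day", "sigma_prep", "sigma_rt",
            "sigma_pcr", "sigma_spike_pipette", "sigma_preamp",
            "biological_sd", "hemolysis_load",
        ):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        for assay in ASSAYS:
            if assay not in self.mu_ct:
                raise ValidationError(f"mu_ct missing assay {assay!r}")
            if self.platelet_load.get(assay, 0.0) < 0:
                raise ValidationError("platelet_load values must be >= 0")
        if min(self.n_tubes, self.n_patients, self.n_runs) < 1:
            raise ValidationError("design sizes must be >= 1")
        if self.droplets_per_well < 1 or self.droplet_volume_nl <= 0:
            raise ValidationError("droplet parameters must be positive")

    # -- presets ---------------------------------------------------------

    @classmethod
    def preset(cls, name: str, seed: int = 0) -> "SyntheticConfig":
        """Named configurations: ``study`` (calibrated defaults) and
        ``zero_noise`` (every variance component and load zero)."""
        if name == "study":
            return cls(seed=seed)
        if name == "zero_noise":
            return cls(
                sigma_extraction=0.0, sigma_day=0.0, sigma_prep=0.0,
                sigma_rt=0.0, sigma_pcr=0.0, sigma_spike_pipette=0.0,
                sigma_preamp=0.0, biological_sd=0.0, hemolysis_load=0.0,
                platelet_load={a: 0.0 for a in ASSAYS},
                droplet_sampling=False, seed=seed,
            )
        raise ValueError(f"unknown preset {name!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SyntheticConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    def concentration_scale(self) -> dict[str, float]:
        """Baseline ddPCR concentration (copies/uL) per assay, anchored
        at the spike-in and spaced by the Ct baselines."""
        mu_spike = self.mu_ct[SPIKE]
        return {
            g: self.ddpcr_spike_concentration * 2.0 ** (mu_spike - self.mu_ct[g])
            for g in ASSAYS
        }


# -- droplet forward model ----------------------------------------------


def generate_droplets(
    concentration: float,
    n_droplets: int,
    droplet_volume_nl: float,
    rng: np.random.Generator,
    meta: SampleMeta,
    assay: str,
    sampling: bool = True,
) -> DropletCount:
    """Draw a droplet count from the Poisson occupancy forward model.

    lambda = concentration x droplet volume (in uL); each droplet is
    positive independently with probability ``1 - exp(-lambda)``, so
    ``k ~ Binomial(n, 1 - exp(-lambda))``. With ``sampling=False`` the
    expected count is returned (rounded), making the output
    deterministic.
    """
    if concentration < 0:
        raise ValidationError("concentration must be >= 0")
    lam = concentration * droplet_volume_nl * 1e-3  # nL -> uL
    p = -math.expm1(-lam)
    if sampling:
        k = int(rng.binomial(n_droplets, p))
    else:
        k = int(round(n_droplets * p))
    return DropletCount(
        meta=meta,
        assay=assay,
        positives=k,
        total_droplets=n_droplets,
        droplet_volume_nl=droplet_volume_nl,
    )


# -- internal helpers ----------------------------------------------------


def _noise(rng: np.random.Generator, sd: float) -> float:
    # Draw unconditionally so the RNG stream (and thus every other draw)
    # is identical whether or not a component is switched off.
    x = rng.normal()
    return sd * x


def _assay_noise(rng: np.random.Generator, sd: float, assays) -> dict[str, float]:
    return {g: _noise(rng, sd) for g in assays}


def _ct_from(
    cfg: SyntheticConfig, assay: str, level: float, shift: float,
    rng: np.random.Generator,
) -> float | None:
    """Map a linear level + accumulated cycle shift to a well Ct."""
    ct = cfg.mu_ct[assay] - math.log2(level) + shift + _noise(rng, cfg.sigma_pcr)
    from .io_plates import CYCLE_MAX

    if ct > CYCLE_MAX or ct <= 0:
        return None  # below detection within the thermal program
    return ct


def _conc_from(
    cfg: SyntheticConfig, assay: str, level: float, shift: float,
    rng: np.random.Generator,
) -> float:
    base = cfg.concentration_scale()[assay]
    eps = _noise(rng, cfg.sigma_pcr)
    return base * level * 2.0 ** (-(shift + eps))


# -- experiment generators ----------------------------------------------


def generate_centrifugation_experiment(
    config: SyntheticConfig, seed: int | None = None
) -> list[Measurement]:
    """Thirty single-donor PPP tubes, alternating centrifugation protocol.

    Odd draw order -> dual centrifugation, even -> prolonged single.
    Each tube yields one purified aliquot, one RT reaction and duplicate
    qPCR wells per assay. Both protocols share the same true level: the
    generator encodes the study's null of protocol equivalence, so any
    protocol difference found downstream is noise.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    records: list[Measurement] = []
    for tube in range(1, config.n_tubes + 1):
        protocol = "dual" if tube % 2 == 1 else "single"
        e_a = _noise(rng, config.sigma_extraction)
        prep = _assay_noise(rng, config.sigma_prep, ASSAYS)
        pipette = _noise(rng, config.sigma_spike_pipette)
        rt = _assay_noise(rng, config.sigma_rt, ASSAYS)
        for assay in ASSAYS:
            shift_base = -e_a + prep[assay] + rt[assay]
            if assay == SPIKE:
                shift_base += pipette
            for well in (1, 2):
                meta = SampleMeta(
                    sample_id=f"tube{tube:02d}",
                    subject_id="volunteer",
                    material="PPP",
                    protocol=protocol,
                    experiment_id="centrifugation",
                    draw_order=tube,
                    run_day=1,
                    rt_replicate=1,
                    pcr_replicate=well,
                )
                records.append(
                    CtMeasurement(
                        meta=meta, assay=assay, platform="qPCR",
                        ct=_ct_from(config, assay, 1.0, shift_base, rng),
                    )
                )
    return records


def generate_patient_cohort(
    config: SyntheticConfig, seed: int | None = None
) -> list[Measurement]:
    """Fifty patients measured in PPP and standard plasma.

    Per subject: a true log2 level per assay (SD ``biological_sd``), a
    residual-platelet index ``c_s ~ Exp(1)`` and a hemolysis index
    ``h_s ~ Exp(1)``. Standard plasma adds ``c_s * platelet_load[assay]``
    linear copies to each platelet-expressed assay and
    ``h_s * hemolysis_load`` to miR-16, degrading the PPP vs standard
    correlation most strongly under spike-in normalization. PPP aliquots
    are additionally measured by ddPCR (same RT reaction as qPCR, as the
    assay workflow shares the cDNA) and on TLDA (separate RT plus a
    per-assay pre-amplification term).
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    records: list[Measurement] = []
    for s in range(1, config.n_patients + 1):
        subject = f"patient{s:02d}"
        bio = {g: 2.0 ** _noise(rng, config.biological_sd) for g in ASSAYS}
        bio[SPIKE] = 1.0  # spike amount independent of biology
        c_s = rng.exponential(1.0)
        h_s = rng.exponential(1.0)
        for material in ("PPP", "standard_plasma"):
            level = dict(bio)
            if material == "standard_plasma":
                for g in ASSAYS:
                    level[g] = level[g] + c_s * config.platelet_load.get(g, 0.0)
                level[ENDOGENOUS_REF] += h_s * config.hemolysis_load
            sample_id = f"{subject}-{'ppp' if material == 'PPP' else 'std'}"
            e_a = _noise(rng, config.sigma_extraction)
            prep = _assay_noise(rng, config.sigma_prep, ASSAYS)
            pipette = _noise(rng, config.sigma_spike_pipette)
            rt = _assay_noise(rng, config.sigma_rt, ASSAYS)

            def shift(g, extra=0.0):
                s_ = -e_a + prep[g] + rt[g] + extra
                if g == SPIKE:
                    s_ += pipette
                return s_

            # qPCR single assays, duplicate wells (both materials)
            for assay in ASSAYS:
                for well in (1, 2):
                    meta = SampleMeta(
                        sample_id=sample_id, subject_id=subject,
                        material=material, protocol="dual"
                        if material == "PPP" else "none",
                        experiment_id="cohort", run_day=1,
                        rt_replicate=1, pcr_replicate=well,
                    )
                    records.append(
                        CtMeasurement(
                            meta=meta, assay=assay, platform="qPCR",
                            ct=_ct_from(config, assay, level[assay],
                                        shift(assay), rng),
                        )
                    )
            if material != "PPP":
                continue
            # ddPCR on the PPP cDNA, duplicate wells
            for assay in ASSAYS:
                for well in (1, 2):
                    meta = SampleMeta(
                        sample_id=sample_id, subject_id=subject,
                        material=material, protocol="dual",
                        experiment_id="cohort", run_day=1,
                        rt_replicate=1, pcr_replicate=well,
                    )
                    conc = _conc_from(config, assay, level[assay],
                                      shift(assay), rng)
                    records.append(
                        generate_droplets(
                            conc, config.droplets_per_well,
                            config.droplet_volume_nl, rng, meta, assay,
                            sampling=config.droplet_sampling,
                        )
                    )
            # TLDA: separate RT, pre-amplification noise, no miR-126 primer
            rt_tlda = _assay_noise(rng, config.sigma_rt, TLDA_ASSAYS)
            preamp = _assay_noise(rng, config.sigma_preamp, TLDA_ASSAYS)
            for assay in TLDA_ASSAYS:
                extra = rt_tlda[assay] - rt[assay] + preamp[assay]
                for well in (1, 2):
                    meta = SampleMeta(
                        sample_id=sample_id, subject_id=subject,
                        material=material, protocol="dual",
                        experiment_id="cohort", run_day=1,
                        rt_replicate=1, pcr_replicate=well,
                    )
                    records.append(
                        CtMeasurement(
                            meta=meta, assay=assay, platform="TLDA",
                            ct=_ct_from(config, assay, level[assay],
                                        shift(assay, extra), rng),
                        )
                    )
    return records


def generate_precision_experiment(
    config: SyntheticConfig,
    platform: str = "both",
    seed: int | None = None,
) -> list[Measurement]:
    """Pooled-sample precision design: ``n_runs`` runs on different days,
    each with duplicate RT reactions and duplicate wells per assay per
    platform. qPCR and ddPCR wells of a run share the RT reactions (one
    cDNA synthesis feeds both instruments). The pool is one aliquot, so
    extraction/preparation terms are common to every well and cancel.
    """
    if platform not in ("qPCR", "ddPCR", "both"):
        raise ValueError(f"platform must be qPCR, ddPCR or both, got {platform!r}")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    platforms = ("qPCR", "ddPCR") if platform == "both" else (platform,)
    records: list[Measurement] = []
    for run in range(1, config.n_runs + 1):
        day = _assay_noise(rng, config.sigma_day, ASSAYS)
        for rt_rep in (1, 2):
            rt = _assay_noise(rng, config.sigma_rt, ASSAYS)
            for assay in ASSAYS:
                shift = day[assay] + rt[assay]
                for well in (1, 2):
                    meta = SampleMeta(
                        sample_id="pool",
                        subject_id="pool",
                        material="pool",
                        protocol="none",
                        experiment_id="precision",
                        run_day=run,
                        rt_replicate=rt_rep,
                        pcr_replicate=well,
                    )
                    if "qPCR" in platforms:
                        records.append(
                            CtMeasurement(
                                meta=meta, assay=assay, platform="qPCR",
                                ct=_ct_from(config, assay, 1.0, shift, rng),
                            )
                        )
                    if "ddPCR" in platforms:
                        conc = _conc_from(config, assay, 1.0, shift, rng)
                        records.append(
                            generate_droplets(
                                conc, config.droplets_per_well,
                                config.droplet_volume_nl, rng, meta, assay,
                                sampling=config.droplet_sampling,
                            )
                        )
    return records
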