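"""Generator invariants: determinism, design arithmetic, closed-form CVs."""

import math

import numpy as np
import pytest

from mirvar.errors import ValidationError
from mirvar.io_plates import CtMeasurement, measurements_to_frame
from mirvar.precision_stats import precision_from_duplicates, protocol_cvs
from mirvar.quantification import normalize_table
from mirvar.synthetic_data import (
    SyntheticConfig,
    generate_centrifugation_experiment,
    generate_droplets,
    generate_patient_cohort,
    generate_precision_experiment,
)

from conftest import make_meta

L2 = math.log(2.0) ** 2


def lognormal_cv(sigma_tot_sq: float) -> float:
    """Percent CV of 2^X for X ~ N(., sigma_tot_sq) (cycles^2)."""
    return 100.0 * math.sqrt(math.exp(L2 * sigma_tot_sq) - 1.0)


class TestZeroVarianceFixedPoint:
    def test_centrifugation_cts_equal_mu(self, zero_config):
        records = generate_centrifugation_experiment(zero_config)
        assert len(records) == 30 * 4 * 2
        for rec in records:
            assert rec.ct == zero_config.mu_ct[rec.assay]

    def test_precision_wells_identical(self, zero_config):
        records = generate_precision_experiment(zero_config, platform="qPCR")
        by_assay = {}
        for rec in records:
            by_assay.setdefault(rec.assay, set()).add(rec.ct)
        for cts in by_assay.values():
            assert len(cts) == 1

    def test_ddpcr_counts_deterministic(self, zero_config):
        a = generate_precision_experiment(zero_config, platform="ddPCR")
        b = generate_precision_experiment(zero_config, platform="ddPCR")
        assert a == b
        counts = {r.positives for r in a if r.assay == "miR-126"}
        assert len(counts) == 1


class TestDeterminism:
    @pytest.mark.parametrize(
        "generator", [generate_centrifugation_experiment,
                      generate_patient_cohort,
                      generate_precision_experiment],
    )
    def test_same_seed_same_table(self, study_config, generator):
        assert generator(study_config) == generator(study_config)

    def test_different_seed_differs(self, study_config):
        a = generate_centrifugation_experiment(study_config, seed=1)
        b = generate_centrifugation_experiment(study_config, seed=2)
        assert a != b


class TestDesignArithmetic:
    def test_centrifugation_protocol_by_draw_parity(self, study_config):
        records = generate_centrifugation_experiment(study_config)
        for rec in records:
            expect = "dual" if rec.meta.draw_order % 2 == 1 else "single"
            assert rec.meta.protocol == expect
        frame = measurements_to_frame(records)
        assert frame["sample_id"].nunique() == 30

    def test_precision_sixty_wells_per_assay_platform(self, study_config):
        records = generate_precision_experiment(study_config, platform="both")
        frame = measurements_to_frame(records)
        counts = frame.groupby(["platform", "assay"]).size()
        assert (counts == 15 * 2 * 2).all()

    def test_cohort_covers_materials_and_platforms(self, study_config):
        frame = measurements_to_frame(generate_patient_cohort(study_config))
        assert frame["subject_id"].nunique() == 50
        ppp = frame[frame["material"] == "PPP"]
        assert set(ppp["platform"]) == {"qPCR", "ddPCR", "TLDA"}
        std = frame[frame["material"] == "standard_plasma"]
        assert set(std["platform"]) == {"qPCR"}
        assert "miR-126" not in set(frame[frame["platform"] == "TLDA"]["assay"])


class TestDroplets:
    def test_zero_concentration_always_empty(self, rng):
        for _ in range(20):
            rec = generate_droplets(0.0, 16000, 0.85, rng,
                                    make_meta(), "miR-92a")
            assert rec.positives == 0

    def test_binomial_mean_at_lambda_ln2(self, rng):
        # lambda = ln 2 -> p(positive) = 1/2 -> E[k] = n/2
        conc = math.log(2.0) / 0.00085
        n = 20000
        ks = [generate_droplets(conc, n, 0.85, rng, make_meta(), "miR-92a").positives
              for _ in range(30)]
        sd = math.sqrt(n * 0.25)
        assert abs(np.mean(ks) - n / 2) < 5 * sd / math.sqrt(len(ks))

    def test_huge_lambda_saturates(self, rng):
        rec = generate_droplets(25.0 / 0.00085, 20000, 0.85, rng,
                                make_meta(), "miR-16")
        assert rec.positives == rec.total_droplets

    def test_negative_concentration_rejected(self, rng):
        with pytest.raises(ValidationError):
            generate_droplets(-1.0, 16000, 0.85, rng, make_meta(), "miR-92a")


class TestClosedFormOracles:
    def test_centrifugation_cv_matches_lognormal_closed_form(self):
        # prep and per-well noise only; duplicate wells halve the pcr term,
        # target and reference each contribute one prep draw.
        cfg = SyntheticConfig(
            sigma_prep=0.25, sigma_pcr=0.05, sigma_day=0.0, sigma_rt=0.0,
            sigma_extraction=0.0, sigma_spike_pipette=0.0,
            n_tubes=2000, seed=11,
        )
        levels = normalize_table(
            generate_centrifugation_experiment(cfg), "spike")
        cvs = protocol_cvs(levels)
        expected = lognormal_cv(2 * 0.25**2 + 0.05**2)
        for cv_obs in cvs["cv"]:
            assert cv_obs == pytest.approx(expected, rel=0.10)

    def test_precision_cvs_match_lognormal_closed_form(self):
        cfg = SyntheticConfig(
            sigma_day=0.30, sigma_rt=0.10, sigma_pcr=0.07,
            sigma_extraction=0.0, sigma_prep=0.0, sigma_spike_pipette=0.0,
            n_runs=400, seed=7,
        )
        levels = normalize_table(
            generate_precision_experiment(cfg, platform="qPCR"), "spike")
        sa2 = 2 * 0.30**2          # run effect, target + reference
        sb2 = 2 * 0.10**2 + 0.07**2  # RT + well-averaged PCR noise
        intra = 100 * math.sqrt(math.exp(L2 * sa2) * (math.exp(L2 * sb2) - 1))
        inter = 100 * math.sqrt(
            math.exp(L2 * sa2) * (math.exp(L2 * sb2) + 1) / 2 - 1)
        for est in precision_from_duplicates(levels):
            assert est.cv_intra == pytest.approx(intra, rel=0.10)
            assert est.cv_inter == pytest.approx(inter, rel=0.10)


class TestComponentOrdering:
    """Dominant variance components surface in the matching estimate."""

    def test_day_dominant_drives_inter_over_intra(self):
        cfg = SyntheticConfig(sigma_day=0.5, sigma_rt=0.02, sigma_pcr=0.02,
                              n_runs=60, seed=3)
        levels = normalize_table(
            generate_precision_experiment(cfg, platform="qPCR"), "spike")
        for est in precision_from_duplicates(levels):
            assert est.cv_inter > 2 * est.cv_intra

    def test_rt_dominant_drives_intra_toward_inter(self):
        cfg = SyntheticConfig(sigma_day=0.0, sigma_rt=0.4, sigma_pcr=0.02,
                              n_runs=200, seed=3)
        levels = normalize_table(
            generate_precision_experiment(cfg, platform="qPCR"), "spike")
        for est in precision_from_duplicates(levels):
            # with no run effect the run-mean CV is the duplicate-mean CV:
            # cv_inter ~ cv_intra / sqrt(2)
            assert est.cv_inter == pytest.approx(
                est.cv_intra / math.sqrt(2), rel=0.25)


class TestCohortEmulation:
    def test_no_contamination_no_noise_gives_identical_rankings(self):
        cfg = SyntheticConfig.preset("zero_noise", seed=4)
        cfg.biological_sd = 0.8  # biology without technical noise
        levels = normalize_table(generate_patient_cohort(cfg), "spike")
        qpcr = levels[levels["platform"] == "qPCR"]
        ppp = qpcr[qpcr["material"] == "PPP"].set_index(["subject_id", "assay"])
        std = qpcr[qpcr["material"] == "standard_plasma"].set_index(
            ["subject_id", "assay"])
        joined = ppp.join(std, lsuffix="_p", rsuffix="_s")
        assert np.allclose(joined["level_p"], joined["level_s"])

    def test_large_platelet_load_destroys_spike_correlation(self):
        # Monte-Carlo over 50 seeds: contamination much larger than biology
        from mirvar.comparisons import correlate

        rhos = []
        for seed in range(50):
            cfg = SyntheticConfig(
                platelet_load={"miR-92a": 25.0, "miR-126": 25.0,
                               "miR-16": 25.0, "cel-miR-39": 0.0},
                seed=seed,
            )
            levels = normalize_table(generate_patient_cohort(cfg), "spike")
            qpcr = levels[(levels["platform"] == "qPCR")
                          & (levels["assay"] == "miR-92a")]
            ppp = qpcr[qpcr["material"] == "PPP"].sort_values("subject_id")
            std = qpcr[qpcr["material"] == "standard_plasma"].sort_values(
                "subject_id")
            rhos.append(correlate(ppp["level"], std["level"]).rho)
        assert np.mean(rhos) < 0.3


def test_validation_rejects_negative_sd():
    with pytest.raises(ValidationError):
        SyntheticConfig(sigma_prep=-0.1)


def test_yaml_roundtrip(tmp_path, study_config):
    path = tmp_path / "cfg.yaml"
    study_config.to_yaml(path)
    assert SyntheticConfig.from_yaml(path) == study_config
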