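# mirvar

Quantifying circulating microRNAs in plasma is notoriously hard to
reproduce: the measured level of a microRNA depends not only on biology
but on how the plasma was centrifuged, how the RNA was purified, which
reference the data were normalized to, and which PCR platform ran the
assay. `mirvar` implements the statistical machinery of a
quality-control study of exactly these factors — for laboratory
scientists and biostatisticians who need to quantify how much of their
assay variation is preanalytical, and to size studies accordingly.

The package covers four assays (miR-92a, miR-126, miR-16 and the
C. elegans spike-in cel-miR-39), three platforms (single TaqMan qPCR,
TaqMan Low Density Arrays, droplet digital PCR) and three normalization
strategies (spike-in, endogenous miR-16, or both combined).

## The statistics at its core

* **Relative quantification (qPCR/TLDA).** Replicate Ct values are
  averaged, then `ΔCt = Ct_target − Ct_ref` and `level = 2^(−ΔCt)`.
  With the combined strategy the reference Ct is the arithmetic mean of
  the spike-in and miR-16 Cts, making the level the exact geometric
  mean of the two single-reference levels.
* **ddPCR concentration.** Each well's positive-droplet count inverts
  the Poisson occupancy model `λ = −ln(1 − k/n)`,
  `copies/µL = λ / V_droplet`; duplicate wells are averaged on the
  concentration scale and normalized as a ratio (geometric-mean
  reference for the combined strategy). `k = n` is flagged as
  saturation, not a number.
* **Precision and repeatability.** From k runs × duplicate RT
  reactions: intra-assay CV = pooled within-run duplicate SD (Dahlberg,
  `sqrt(Σd²/2k)`) over the grand mean; inter-assay CV = CV of the run
  means (`CV = SD/mean × 100`, sample SD). The alternative reading —
  CV of all 2k values — is available as `inter_from="all_values"`.
* **Preanalytical attribution.**
  `fraction = 100 (CV_total − CV_RT-qPCR) / CV_total`, where `CV_total`
  is the mean of the whole-procedure CVs under the two centrifugation
  protocols and `CV_RT-qPCR` is the qPCR repeatability.
* **Comparisons.** Student t-tests (unpaired equal-variance by default,
  paired-by-adjacent-tube optional) for protocol and order-of-draw
  effects; Spearman rho (exact permutation p for n ≤ 8, t-approximation
  above) for cross-material/platform agreement; and the iterative
  paired-means sample-size rule
  `n = (t_{1−α/2,n−1} + t_{power,n−1})² / d²` with
  `d = Δ/(SD·sqrt(2(1−ρ)))`.

A synthetic-data generator (`mirvar.synthetic_data`) emulates the
hierarchical variance structure of all four experiments — 30
single-donor tubes alternating dual/prolonged-single centrifugation, a
50-patient cohort in platelet-poor and standard plasma, and a
15-run × duplicate-RT × duplicate-PCR pooled-sample precision design —
so every stage is testable without any download.

## Worked example

```sh
python analysis/01_simulate.py --seed 1     # write synthetic plate tables
python analysis/05_attribution.py --seed 1  # variance attribution
```

prints, for the simulated study conditions:

```
  assay   strategy  cv_total  cv_rt_qpcr  fraction_preanalytical  fraction_rounded
 miR-16      spike    17.705       6.311                  64.353              64.0
miR-92a      spike    14.479       7.098                  50.976              51.0
...
paired sample size (10% difference, 20% SD, rho 0.85, alpha 0.05, power 0.8): 12 per protocol
8 Ct-values -> 256-fold level difference; 2 Ct-values -> 4-fold
```

Reading: under spike-in normalization, roughly half to four-fifths of
the whole-procedure intra-assay variation in the simulation is
attributable to centrifugation + purification rather than to the
RT-qPCR measurement itself; detecting a 10% protocol difference at
these noise levels needs 12 tubes per protocol; and miR-16 sits ~8 Ct
(256-fold) above miR-126, which is why it is a questionable reference
for low-abundance targets. The other drivers
(`02_centrifugation.py`, `03_agreement.py`, `04_precision.py`) produce
the protocol-comparison, agreement and precision tables the same way,
all under `results/`. The same pipelines are available as a CLI
(`mirvar simulate|normalize|precision|attribute|compare|report`).

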