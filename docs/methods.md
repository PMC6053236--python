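# Methods

## Measurement model

All technical noise lives on the cycle (log2) scale, matching PCR's
exponential chemistry. For a well of assay *g* on plasma aliquot *a*,
run *r*, reverse-transcription (RT) reaction *t*:

```
Ct = mu_ct[g] − log2(level) − e_a + prep_{a,g} + day_{r,g} + rt_{t,g}
     [+ preamp_{s,g}]  [+ pipette_a]  + eps_well
```

* `mu_ct[g]` — baseline Ct of the assay in platelet-poor plasma (PPP).
  Defaults (cel-miR-39 24.0, miR-92a 20.7, miR-126 25.8, miR-16 17.3
  cycles) reproduce the relative spacings of the four assays: miR-16
  ≈ 8 Ct below miR-126 (256-fold), 3–4 Ct below miR-92a, and the spike
  ≈ 2 Ct below miR-126.
* `e_a ~ N(0, sigma_extraction²)` — RNA-extraction efficiency of the
  aliquot, **shared by every assay including the spike-in** (the spike
  is added before purification). It therefore cancels under any
  reference normalization; its default (0.4 cycles) only matters for
  unnormalized Cts.
* `prep_{a,g} ~ N(0, sigma_prep²)` — per-aliquot **and per-assay**
  residue of centrifugation + purification (recovery differs between
  microRNAs). Because it is assay-specific it survives normalization
  and is the component the attribution statistic measures. Default
  0.15 cycles.
* `day_{r,g} ~ N(0, sigma_day²)` — between-run effect, per assay
  (default 0.15); `rt_{t,g} ~ N(0, sigma_rt²)` — per RT reaction and
  assay (0.06); `eps_well ~ N(0, sigma_pcr²)` — per well (0.07).
* `pipette_a ~ N(0, sigma_spike_pipette²)` — spike-dispensing error,
  spike assay only (0.12). This is why spike-normalized CVs run higher
  than endogenous-normalized ones in the single-donor experiment.
* `preamp_{s,g} ~ N(0, sigma_preamp²)` — TLDA pre-amplification, per
  sample × assay (default 2.0 cycles — large enough that single-assay
  vs TLDA rank correlation collapses below ~0.3, the qualitative
  behaviour the design emulates). The TLDA card carries no miR-126
  primer.

Linear-domain biology and contamination enter through `level`: each
cohort subject has true level `2^N(0, biological_sd²)` per assay
(default SD 0.8 log2 units); standard plasma adds
`c_s × platelet_load[g]` copies (residual-platelet index
`c_s ~ Exp(1)` shared across assays of a subject; loads 1.5–2.0) and
miR-16 additionally `h_s × hemolysis_load` (hemolysis). Contamination
shared between target and miR-16 partially cancels under endogenous
normalization — which is exactly why cross-material agreement survives
endogenous normalization better than spike normalization.

ddPCR maps the same multiplicative level to a concentration anchored at
35 copies/µL for the spike (droplet occupancies ≈ 0.01–3 across the
assays) and draws `k ~ Binomial(n, 1 − e^{−λ})` per well with
n = 16 000 droplets of 0.85 nL. With `droplet_sampling: false`
(zero-noise preset) the expected count is used instead, making the
whole generator a deterministic function of `mu_ct` — the fixed-point
invariant the tests rely on.

Component values are illustrative calibrations, not estimates: the
underlying study publishes only composite CVs, so the preset was chosen
once, via the closed-form lognormal CV mapping below, to land the
simulated summary CVs within roughly a factor of 1.5 of the published
magnitudes. The data publish no separation of sigma_day from
sigma_rt; that split in the preset is a design choice.

## Closed-form oracles

If a ΔCt carries run-level variance `s_a²` and within-run variance
`s_b²` (cycles²), the normalized level `2^(−ΔCt)` is lognormal with
log-scale SDs `ln2 · s`. Writing `L² = (ln 2)²`:

* whole-procedure CV: `sqrt(exp(L²(s_a²+s_b²)) − 1)`
* Dahlberg intra-assay CV: `sqrt(exp(L² s_a²)(exp(L² s_b²) − 1))`
* inter-assay CV of duplicate run means:
  `sqrt(exp(L² s_a²)(exp(L² s_b²) + 1)/2 − 1)`

For the spike strategy in the precision design,
`s_a² = 2 sigma_day²` and `s_b² = 2 sigma_rt² + sigma_pcr²` (duplicate
wells halve the PCR term; target and reference each contribute once).
The parameter-recovery tests check the estimators against these forms
at 400 simulated runs within ±10% relative; 400 runs keeps the
Monte-Carlo error of a CV estimate near 3–4%, comfortably inside that
band.

## Estimators and numerical choices

* **Replicate handling.** Cts are averaged before normalization (not
  levels after), following the stated order of operations of the
  protocol being modeled; ddPCR wells are converted to concentrations
  first and then averaged. Undetermined wells (no signal in 40 cycles,
  encoded explicitly, never as a sentinel) are excluded from the mean;
  a sample whose wells are all undetermined raises a missing-level
  error carrying the sample/assay identity.
* **Intra vs inter CV.** The published description does not pin down
  how the duplicate design was split into the two CVs. Default here:
  intra = Dahlberg pooled duplicate SD over the grand mean; inter = CV
  of run means. The alternative inter-assay reading (CV of all 2k
  values) is exposed as `inter_from="all_values"` because reanalyses of
  similar designs differ on this point. The pooled-CV bound
  (intra ≤ CV of all values) holds whenever a between-run component is
  present; it can invert for artificial inputs whose run means are
  exactly equal.
* **References are never self-normalized**: miR-16 has no
  endogenous- or combined-normalized level, the spike none at all.
* **Degenerate inputs.** Identical constant groups give t = 0, p = 1
  (no evidence of a difference); constant groups with different means
  raise a degenerate-variance error rather than fabricating an
  infinite statistic. Group constancy is detected by zero range, not
  by a variance threshold. Correlation on constant vectors is reported
  as undefined in table outputs.
* **Spearman p.** Exact enumeration of all n! rank orderings for
  n ≤ 8; the t-approximation on n − 2 df above (the study's n is 50).
* **Sample size.** Damped fixed-point iteration of
  `n = (t_{1−α/2,n−1} + t_{β,n−1})²/d²` on a continuous n with df
  floored at 1, then rounded up, floored at 2. At the study parameters
  the fixed point is 11.47 → 12 per group; for very large effects the
  iteration settles at 2–4 (small-sample t inflation keeps it off 1).
* **Presentation rounding** is half-up at the printed precision (one
  decimal for CVs, integers for attribution percentages) and applied
  only at presentation; all stored values are unrounded.

## What the generator does and does not emulate

It reproduces the *variance structure* (nesting, which components
cancel under which normalization, platform sharing of RT reactions)
and the qualitative agreement patterns (good qPCR–ddPCR correlation,
no single-vs-TLDA correlation, spike-normalized cross-material
agreement worst). It does not model amplification curves, per-cycle
efficiencies, droplet rain/threshold ambiguity, run-to-run droplet
count variation, non-Gaussian preanalytical shocks, or real platelet
biology; passing tests therefore demonstrate correctness of the
estimators under the assumed lognormal hierarchy, not the field
accuracy of any particular CV value. Reproducing the published
precision tables verbatim would require the study's raw measurement
workbook, which this repository does not ship; the attribution
percentages and sample size are recomputed from the published summary
CVs and design parameters, which are inputs of those statistics.

## Problem sizes

Default analyses use the study's design sizes (30 tubes, 50 patients,
15 runs). Oracle-based tests enlarge only what the check needs (2000
tubes / 400 runs for parameter recovery; 200-seed sweeps for
Monte-Carlo means), sizes chosen so the statistical tolerance, not the
runtime, is the binding constraint.
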