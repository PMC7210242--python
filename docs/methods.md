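# Methods

This note documents the models, parameters, numerical choices and known
limitations of the `fluoromargin` pipeline. It states no empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## The clinical procedure being modeled

A patient undergoing breast-conserving lumpectomy receives 1 mg/kg of a
PEGylated, protease-activatable far-red fluorescent agent intravenously
before surgery. Cathepsins concentrated in and around tumor cleave the
agent, producing fluorescence that rises with time since injection and
extends beyond the anatomical tumor border. After the main specimen (and,
later, comprehensive shaved cavity margins) are removed, the surgeon scans
the cavity walls with a hand-held probe imaging a 2.6-cm-diameter circular
field. Analysis software initializes on a short cavity scan to measure the
patient's normal-tissue fluorescence baseline, then classifies each field
against a patient-specific threshold and paints suprathreshold regions red.
Device readings are later adjudicated against histopathology of the tissue
excised at each site.

The pipeline has six stages: simulate → qc → calibrate → detect →
adjudicate → evaluate. All randomness flows from a single seed.

## Synthetic image model

Each field of view is a square raster (default 256×256 px) with the circular
field inscribed; out-of-field pixels are carried as NaN — *invalid, not
zero* — so they can never bias baseline or summary statistics. The pixel
model is

S(x) = A(t) · c · B_p · [1 + (R − 1) K(x)] · (1 + ε(x))

- **A(t) = t / (t + t_half)** — saturating activation in the
  injection-to-imaging interval. t_half defaults to 5 min so that
  A(101 min) ≥ 0.95: the clinically established 101-minute lower bound sits
  on the plateau, and eligible imaging times (101–402 min) differ by at most
  a few percent in amplitude. Only the empirical lower bound is known, so
  the curve is phenomenological, not pharmacokinetic.
- **c ∈ (0, 1]** — probe–tissue contact factor. Technically adequate scans
  draw c ~ U(0.85, 1); with probability `contact_failure_rate` (default
  0.05) a scan is a contact failure, c ~ U(0.45, 0.84).
- **B_p** — latent per-patient baseline, lognormal with mean 100 AFU and
  CV 0.2. Absolute fluorescence units are arbitrary by necessity (no
  absolute scale is published); everything downstream is
  scale-equivariant, which the test suite verifies.
- **R** — tumor:normal signal ratio of the specimen. Per-histology-subtype
  means (IDC/ILC/mixed/DCIS at weights 0.55/0.11/0.07/0.27) are drawn
  N(3.9, 0.07), putting ≈95% of subtype means inside the published
  3.78–4.11 range; individual specimens scatter around their subtype mean
  with lognormal CV 0.10.
- **K(x)** — tumor indicator extended by a halo: K = max(indicator,
  Gaussian-blur(indicator, σ = 6 px)). The max keeps K ≡ 1 inside the tumor
  (so the in-tumor peak is exactly R·c·A·B_p) while the blur makes signal
  decay smoothly *outside* the recorded truth mask, emulating the protease
  cloud around tumor. The truth mask is recorded before the halo. The blur
  kernel is truncated at 4σ; because the separable kernel has square
  support, region-labelling code that needs halo-free normal tissue uses a
  guard distance of 4σ√2 + 2 px.
- **ε(x)** — independent multiplicative lognormal noise, mean 1, CV 0.10.

**Benign hotspots** model the false-positive source (benign tissue with
elevated protease activity). A tumor-free surface carries a hotspot with
probability 0.75: a small (0.08–0.16 cm radius) halo-free focus. Hotspot
intensity is a two-component mixture: a *moderate* component (ratio
lognormal, mean 2.8, CV 0.22) sitting just below/inside the tumor intensity
range, and with probability 0.25 a *bright* component (mean 5.5) that
exceeds any plausible threshold. The two components play different roles:
the moderate shelf determines where the ROC-optimal coefficient lands,
while the bright foci put a floor on the false-positive rate at every
operating point. A single unimodal hotspot population cannot reproduce the
published asymmetric operating point (sensitivity 84%, specificity 73%):
maximizing Youden's J on overlapping unimodal classes drives sensitivity
and specificity toward equality. The mixture parameters (rate 0.75,
moderate mean 2.8, bright fraction 0.25, together with the contact floor
0.85) were calibrated once so that the pooled held-out operating point of
the default cohort matches the published one, and then frozen; the
end-to-end surrogate test checks this at ±10 percentage points.

**Cohort structure.** Default 40 patients × 6 orientations × 2 stages
(intermediate = after main-specimen removal, final = after comprehensive
shaves) = 480 surfaces, near the published 570 surfaces/40 patients; one
field per surface by default (several fields per margin are supported and
are OR-combined). Tumor prevalence per surface is 0.03 (≈ the published
17/570). Each patient also receives two tumor-free initialization-scan
fields at full contact for baseline estimation. Patient-level exclusion
flags (too-short interval 0.044, missed dose 0.022, hematoma/necrosis
0.022, data loss 0.022) are drawn at the frequencies implied by the
published 45-patient accounting.

**Transected specimens.** T:N estimation uses dedicated ex-vivo images: a
central tumor disk (0.30–0.55 cm radius), full contact, with the tumor
region labeled by the truth mask and the normal region everything beyond
the halo guard band. With noise off the per-specimen ratio equals the drawn
R to machine precision (tested); with defaults the mean over 50 specimens
is computed by `scripts/acceptance.py`.

## QC and eligibility

Patient level, applied first and in roster order with one reason per
patient (priority: short_interval, dose_failure, hematoma_necrosis,
data_lost): imaging must start ≥ 101 min after injection. No upper bound is
enforced — 402 min is the longest interval observed clinically and is
acceptable, so `max_interval_min` is informational only.

Image level: the contact score is the in-vivo mean in-field signal divided
by the matched ex-vivo specimen signal (the summary statistic is not
specified clinically; the mean is used here). Scores ≤ 0.84 mark poor
contact and exclude the image; the comparison carries a 1e-9 relative
tolerance so that ratios like 8.4/10.0 land on the inclusive side of the
cutoff. The cutoff's clinical provenance (ROC-derived or empirical) is not
stated; it is treated as a fixed constant. Filtering is idempotent and
monotone in the cutoff (tested).

## Calibration

- **Baseline:** median of valid in-field pixels pooled over the patient's
  initialization scans — the median resists benign hotspots, which would
  bias a mean upward.
- **ROC samples:** one per margin surface — the maximum baseline-normalized
  pixel after 3×3 median smoothing over the surface's fields, labeled by
  ground-truth tumor presence. (Whether the clinical ROC used pixels,
  images or margins is not published; the per-surface unit matches the
  per-margin reporting of results.)
- **Candidates:** the sorted unique sample values; rule `value >
  coefficient`, strict.
- **Operating point:** maximum Youden's J, ties to the smaller coefficient
  (higher sensitivity). J is symmetric and standard for "optimized both
  sensitivity and specificity"; the coefficient is config-exposed so other
  operating points are selectable.
- **Thresholds:** threshold_p = coefficient × baseline_p.
- **Degenerate input:** a single-class training set cannot produce a ROC;
  the pipeline then falls back to a configured default coefficient (2.0)
  and the report shows the undefined rate as "n/a".
- **Evaluation modes:** resubstitution (the pooled fit reapplied to the
  same cohort, mirroring the clinical retrospective procedure) and
  leave-one-patient-out (each patient classified with a coefficient fitted
  on the others), both labeled in reports. Held-out estimates are the
  honest ones for generalization claims.

The ROC/Youden path is verified against an exhaustive brute-force
confusion-matrix scan and, as an area, against
`sklearn.metrics.roc_auc_score`.

## Detection

3×3 median smoothing (out-of-field pixels filled with the in-field median
before filtering so rim pixels are not dragged down, then restored to NaN);
strict `>` at the threshold; 8-connected components; positive iff some
component has ≥ 9 px (a noise-speckle guard ≈ 0.01% of the field). The
clinical device's smoothing/area rules are not published — both are
config-exposed declared assumptions. The red overlay is lossless: red
pixels correspond exactly to the retained suprathreshold mask (grayscale is
quantized to 0–254 so pure red is unambiguous).

## Adjudication

Invasive carcinoma (IDC, ILC, mixed): margin positive iff tumor on ink.
Pure DCIS: positive iff < 2 mm from ink, strictly (2.0 mm is negative).
Mixed findings evaluate each component under its own rule and OR them.
"Surface contains tumor" (tumor anywhere in the tissue excised at the
site — the sense in which a margin with tumor > 2 mm from ink still counts
as tumor-containing) is kept distinct from "margin status" (the
on-ink/<2-mm rule); sensitivity/specificity use the former via the shave
whenever a shave exists, else margin status of the main-specimen surface.

Outcome logic for positive final margins: tissue excised intraoperatively
at the signal site → spared reoperation; device-positive but not excised →
reoperation required; device-negative with benign re-excision → correctly
predicted clear. A device-negative site with tumor at re-excision has no
defined outcome and raises an error.

Printed distance classes in the fixture tables are encoded by class
representatives (0.5 mm for "< 1 mm", 1.0 mm for "< 2 mm", 3.0 mm for
"> 2 mm"); each representative classifies identically to every member of
its class under the margin rules, so no information relevant to status is
lost.

## Evaluation and reporting

Rates use exact rational arithmetic before rounding; zero-denominator rates
surface as "n/a", never 0 or 1. Confusion counts are conserved
(TP+FP+TN+FN = adjudicated surfaces, tested). The printed-table checker
reports the published pooled sensitivity (84% = 14/17) alongside the two
values recomputable from the printed tables themselves (10/13
shave-adjudicated, 12/17 surface-status), which do not fully reconcile with
it or with the statement that all three sub-threshold tumor images were
intermediate; the discrepancy is reported, not resolved.

## Problem sizes

Defaults were chosen to keep the full pipeline interactive on one CPU:
256×256 fields, 480 surfaces per cohort (≈7 s per cohort end-to-end). The
end-to-end surrogate test pools 16 seeded replicate cohorts (≈170 tumor
surfaces) so the Monte-Carlo error of the held-out sensitivity estimate is
well inside the ±10-point acceptance band. The acceptance script's T:N
computation uses 50 transected specimens, matching a plausible per-study
specimen count.

## What passing tests do and do not show

The generator reproduces the *statistical structure* the analysis assumes:
baseline variation, T:N ratios in the published range, halo bleed,
activation timing, contact attenuation, benign false-positive sources,
pixel noise, and the published exclusion frequencies. It does not model
optics (PSF, illumination falloff), tissue texture or autofluorescence
spatial structure, 3-D cavity geometry, probe motion, pathology sampling
error (only a few 5-µm sections are examined per specimen), or per-subtype
signal differences beyond small mean shifts. Passing the end-to-end
surrogate therefore shows that the calibration/detection/adjudication
machinery recovers the intended operating point under the modeled
conditions — not that the system would achieve those numbers on real
tissue. The desk-scale checks (fixture tables, eligibility accounting,
outcome logic) are exact reproductions of published arithmetic and carry no
simulation caveat.

## Known limitations

- Confidence intervals ignore patient-level clustering (as in the published
  report); future work.
- The resubstitution mode inherits the optimism of tuning and evaluating on
  the same cohort; leave-one-patient-out is provided and used for the
  surrogate check.
- The contact score's summary statistic and the clinical device's exact
  spatial processing are assumptions, declared and config-exposed.
- Only the refined pooled calibration procedure is implemented; the
  earlier per-study iteration it replaced is out of scope.
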