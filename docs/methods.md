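# Methods

## The measurement being modelled

A scintigraphic reflux study follows swallowed Tc-99m DTPA with a gamma
camera: an upright dynamic acquisition (2 min, 15 s frames, 64×64),
a supine acquisition (30 min, 30 s frames), and — after an oral Tc-99m
colloid dose at the end of supine imaging — a delayed 256×256 static
image two hours later to look for pulmonary aspiration of refluxate.
Regions of interest over the pharynx, the three oesophageal thirds and
the stomach, with a lateral-chest background region, yield
time-activity curves (TACs); curves are graded declining/flat/rising,
and the delayed image is read with a line profile through the lung hila
against a 2× background threshold.

## Tracer-kinetics model

The simulator uses six compartments: stomach, lower/mid/upper
oesophagus, pharynx, lungs, plus an absorbing "emptied" pool for
activity that has left the stomach into the bowel. No kinetic model is
published for this technique; this one was chosen as the simplest
mechanism that makes every downstream observable (curve grade,
pharyngeal contamination, lung uptake) an *emergent* function of
physiologically named parameters, so that each analysis stage can be
validated against ground truth.

Assumptions and dynamics:

- The bolus reaches the stomach within the first frame. A residual
  fraction (`residual_fraction`, default 0.04 of the administered
  activity, split 30/30/20/20 over pharynx/upper/mid/lower) stays above
  the stomach after the water flush and clears like refluxate. This
  residual is what makes a healthy study's pharyngeal curve *declining*
  (grade 1) rather than empty-flat; set it to zero to model a perfectly
  cleared pharynx.
- Gastric emptying is first-order with half-time `gastric_half_time`
  (default 25.2 min, the half-clearance time the technique's worked
  example reports; per-patient values are lognormal around it).
- Reflux events form a Poisson process with posture-specific rates
  (events/min). Each event instantaneously carries `reflux_fraction`
  (default ≈0.08) of current gastric activity up to the patient's
  `max_reflux_height`; traversed compartments share the bolus equally
  except the topmost, which receives double weight (the refluxate comes
  to rest at its maximum height).
- Oesophageal and pharyngeal activity returns directly to the stomach
  first-order at `clearance_rate` (1/min). Ineffective oesophageal
  motility (IOM) is modelled as a low clearance rate: defaults 0.35 /
  0.20 / 0.10 / 0.04 min⁻¹ for normal/mild/moderate/severe grades
  (half-times 2–17 min, spanning normal transit to severe stasis).
- During pharyngeal events, `aspiration_fraction` of the pharyngeal
  deposit transfers irreversibly to the lungs. Aspiration therefore
  *requires* pharyngeal reach, which the parameter validation enforces.
- The colloid dose re-labels the stomach with fresh activity at 32 min;
  it obeys the same kinetics, so late upright reflux can still deliver
  colloid to the lungs before the delayed image. The 2-hour delay is
  measured from the colloid dose.
- Physical decay (Tc-99m half-life 6.0067 h) is applied at sampling
  time; the internal state is decay-free, which makes conservation
  exact: compartments + emptied pool = administered activity to
  better than 1e-6 at every sampled time.

Between events the dynamics are linear and are advanced in closed form
(matrix exponential of the two-rate system written out explicitly, with
the k_empty = k_clear degenerate case handled by its limit), so there is
no integration error; the emptied pool is recovered by conservation.

## Image formation

The anatomy is a fixed schematic on the 64×64 matrix (scaled ×4 at
256×256): pharynx at the top, oesophageal thirds stacked in the midline,
stomach lower-left, two lung fields flanking the mediastinum with
12×4-pixel hilar strips, and a lateral-chest background region. Zone
coordinates are part of the documented format (`render.ZONES_64`), so
ROI placement needs no registration. Expected pixel counts are
compartment activity × frame duration × sensitivity, spread uniformly
over the zone, plus a uniform body-background term; realized counts are
Poisson. Lung zones receive counts only from the lungs compartment, 70%
concentrated in the hilar strips (aspirated activity collects in the
main airways).

Count-rate constants were fixed by first-principles Poisson arithmetic
before any end-to-end testing, to give realistic frame statistics:
sensitivity 25 counts·s⁻¹·MBq⁻¹ (a stomach containing 50 MBq yields
≈57 counts/pixel in a 15 s upright frame) and body background
0.1 counts·px⁻¹·s⁻¹ at 64×64 (scaled by pixel area on other matrices).
The delayed static image integrates 600 s. With these values the
pharynx/background ratio of a clean study stays below 1.5 in ≥95% of
realizations, while ≈0.1 MBq in the airways — the detectability floor
reported for the salivagram-type technique — approaches the 2×
threshold.

## Cohort generation

Defaults reproduce the reference cohort: 250 patients (72 GORD,
178 LPR, 62% female, ages 20–85 centred on 60), aspiration probability
10/72 (GORD) and 58/178 (LPR), severe IOM 17%/35%, normal motility
49%/27% (mild/moderate split the remainder equally), 24-h pH categories
25/78/147 (normal/weakly acidic/abnormal), and LOS pressure lognormal
with location ln(2.3) and scale 1.42 — giving mean 6.3 and median
2.3 mmHg exactly; the implied SD (≈16 mmHg) overshoots the reported
8.4 mmHg, an accepted limitation of the two-parameter fit.

Couplings use a Gaussian copula per patient. A latent motility severity
drives the IOM grade through per-class cutpoints; the aspiration
indicator is thresholded on a latent correlated with it, with the
tetrachoric correlation solved numerically so the *realized* Pearson phi
between severe IOM and aspiration matches the configured targets (0.54
LPR, 0.21 GORD). A reflux-intensity latent (correlation 0.6 with
motility severity) drives event rates, which makes rising pharyngeal
curves correlate with IOM (observed r ≈ 0.3–0.45, bracketing the
reported 0.29 supine / 0.38 upright). Proximal and distal acid
exposures are bivariate lognormal with the latent correlation solved in
closed form so their Pearson correlation is 0.32; the proximal exposure
also loads weakly (0.25) on the aspiration latent, so proximal — but
not distal — acid exposure is a marginal predictor of aspiration, as
observed clinically. The 24-h pH category is drawn directly from the
configured probabilities (the categorization rule behind the published
25/78/147 split is not specified); each patient also carries a
representative episode nadir pH consistent with the category under the
episode rule (acid < 4 ≤ weakly acid < 7 ≤ non-acid).

Aspirators are forced to pharyngeal reflux height with
`aspiration_fraction` ~ U(0.08, 0.25) and a supine event-rate floor of
0.2/min — aspiration is the end result of recurrent pharyngeal reflux,
and without recurrent events there would be nothing to aspirate.

Randomness: one master seed; patient *i* uses
`SeedSequence(entropy=(seed, i))` spawned into three child streams
(covariates, kinetics, rendering), so cohorts are extensible without
reshuffling and every stage is independently reproducible.

## Analysis conventions

- **TAC extraction**: per frame, (mean organ counts/px − mean background
  counts/px) / frame duration, decay-corrected to the segment start
  (≤6% over 30 min, applied for bit-exact reproducibility); times are
  frame mid-points; pixel convention row-major, origin top-left,
  half-open frame intervals.
- **Grading**: least-squares line of value vs time (minutes);
  z = slope/SE; grade 3 if z > z_crit, 1 if z < −z_crit, else 2, with
  z_crit = 2.0 configurable. The criterion is deliberately noise-aware:
  a curve is called rising only when the trend clears its own standard
  error. Upright and supine segments are graded separately. On long
  curves the false-call rate on truly flat data approaches the normal
  rate 2Φ(−z_crit) ≈ 4.6%; on short segments it follows the heavier
  t-tail (≈9% for the 8-frame upright segment) — a property of the
  z-approximation, which is why calibration checks use long curves.
- **Half-clearance**: nonlinear fit of A·exp(−kt) to the stomach TAC
  (log-linear start values); ln 2/k in minutes; an infinite sentinel
  when the fitted rate is non-positive ("not reached"). Note that in
  heavy refluxers the apparent half-clearance is shorter than the
  intrinsic emptying half-time because reflux events also drain the
  stomach.
- **Aspiration**: profile row = the row inside the hilar band
  maximizing band-summed lung counts (exported in the call for audit);
  the profile averages a 9-row band (≈2 cm at 256×256) — wide enough
  that single-pixel Poisson spikes cannot cross the threshold, narrow
  enough to stay inside the hilar strips; threshold "> 2× background"
  is read strictly, so a ratio of exactly 2.0 is negative.
- **Fisher two-sided p**: sum of hypergeometric probabilities ≤ the
  observed table's, with the standard 1+1e-7 relative tie guard. This
  convention is stated explicitly because other two-sided definitions
  exist; it is validated against exact rational enumeration on every
  table with total ≤ 12.
- **ROC**: rank (Mann-Whitney) AUC with ties ½, equal to the
  trapezoidal area under the empirical curve; Hanley–McNeil SE; ordinal
  markers (curve grade 1–3, IOM 1–4) enter as their ordinal scores.
  ANOVA, Wilcoxon and t-tests are not implemented: no benchmark result
  depends on them. No multiple-testing correction is applied (each test
  read at 0.05), matching the benchmarking convention; the report
  footer says so.

## What the simulator does and does not emulate

It emulates the cohort marginals, the configured covariate couplings,
Poisson counting statistics at realistic count rates, and the causal
chain reflux → pharyngeal contamination → aspiration. It does **not**
model scatter, attenuation, collimator response, patient motion,
anatomical variability, swallow artefacts, or pH-probe physics; the IOM
grade is a simulated covariate, not derived from pressure traces.
Passing tests therefore demonstrate that the analysis chain recovers
known ground truth under ideal acquisition geometry with faithful
counting noise — not that it would perform identically on patient
images, where ROI placement and motion dominate.

For the same reason the simulated predictive values should be read
qualitatively. The declining supine pharyngeal curve reaches NPV ≈ 95%
for aspiration (reported: 97–98%); the PPV of a rising curve is much
lower here (≈60%) than the reported 98–100%, because the generator
deliberately includes vigorous non-aspirating refluxers. End-to-end
validation targets the NPV and the ROC ordering, not the PPV.

## Problem sizes and numerical tolerances

Validation runs use: 200–250-patient cohorts (10 seeds for operating
points), 200 seeds for aspiration-rate calibration, 1000 renderings for
the Poisson-mean check, 2000 replicates of 200-point curves for the
grade type-I calibration, 5 rendered studies for half-time recovery
(within 10% of 25.2 min), and exhaustive oracle sweeps (all 2×2 tables
with total ≤ 12 at 1e-12; brute-force AUC at 1e-12; closed-form
slope/SE at 1e-10). Conservation is checked at 1e-6 in MBq.
The ground-truth definition used for end-to-end grade recovery is the
sign of the least-squares trend of the *noise-free* pharyngeal activity
from the same kinetics realization — the cleanest statement of "what
was actually rising" — against which the imaged grade-3 call reaches
≥85% balanced accuracy on default cohorts.

## Known limitations

- The schematic anatomy makes ROI placement trivial; there is no
  registration or segmentation machinery, by design.
- LOS pressure SD exceeds the reported value (see above); LOS pressure
  is uncoupled from the kinetics (the clinical data show it
  discriminates poorly).
- Upright grading rests on 8 frames and is correspondingly noisy; the
  supine curve is the primary marker.
- DICOM support covers multi-frame NM pixel data and frame timing only,
  not full NM metadata.
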