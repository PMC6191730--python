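# refluxscint

Simulation and analysis of scintigraphic gastro-oesophageal reflux
studies, for nuclear-medicine and oesophageal-physiology researchers who
want a fully ground-truthed testbed for the technique.

Gastro-oesophageal reflux disease (GORD) and its extra-oesophageal form,
laryngopharyngeal reflux (LPR), are usually worked up with 24-hour pH
monitoring and manometry — tests that are blind to what matters most in
severe disease: refluxate reaching the pharynx and being aspirated into
the lungs. A scintigraphic reflux study images this directly: the
patient swallows 40–60 MBq of Tc-99m DTPA, dynamic gamma-camera imaging
follows (upright, 8 × 15 s frames on a 64×64 matrix, then supine,
60 × 30 s frames), and a delayed 256×256 static image after an oral
Tc-99m colloid dose looks for lung aspiration two hours later.

The package implements the full analysis chain and a physics-based
simulator to validate it:

- **simulation** — a six-compartment tracer-kinetics model (stomach,
  oesophageal thirds, pharynx, lungs) with first-order gastric emptying,
  Poisson-process reflux events, first-order oesophageal clearance and
  irreversible pulmonary aspiration, rendered into Poisson-noise count
  images on a schematic anatomy; cohort generation with configurable
  clinical marginals and Gaussian-copula covariate couplings;
- **time-activity curves** — background- and decay-corrected ROI curves,
  graded 1 (declining) / 2 (flat) / 3 (rising) by the z-statistic of the
  least-squares slope (`z = slope/SE`, |z| > 2 by default), gastric
  half-clearance by exponential fit, pharynx-to-background ratios;
- **aspiration detection** — a transverse line profile through the hilar
  band of the delayed image, positive when peak lung count density
  exceeds 2× body background (strict inequality);
- **statistics** — exact two-sided Fisher tests (sum-of-small-p
  convention), sensitivity/specificity/PPV/NPV, Pearson correlation, and
  ROC analysis with rank-based AUC (ties ½) and Hanley–McNeil standard
  errors, assembled into an auditable cohort benchmark report.

## Worked example

```bash
python examples/benchmark_cohort.py
```

simulates a 120-patient cohort (35 GORD / 85 LPR), analyses every image,
and prints:

```
aspiration by class [[27, 58], [3, 32]]: Fisher exact p = 0.009729
supine pharyngeal curve: NPV of a declining curve = 94.0% (n=67), PPV of a rising curve = 51.5%
ROC AUC for predicting aspiration:
  iom_grade              AUC = 0.808  (p = 1.8e-09)
  grade_pharynx_supine   AUC = 0.791  (p = 3.16e-08)
  proximal_acid_pct      AUC = 0.679  (p = 0.00264)
  ...
  distal_acid_pct        AUC = 0.551  (p = 0.404)
  los_pressure           AUC = 0.417  (p = 0.155)
```

Reading the numbers: aspiration is significantly more common in the LPR
group (27/85) than the GORD group (3/35); a declining supine pharyngeal
curve virtually rules out aspiration (high NPV); and the scintigraphic
curve grade and the motility grade discriminate aspirators far better
than distal acid exposure or sphincter pressure — the core clinical
argument for the technique.

Other examples: `simulate_cohort.py` (cohort marginals and couplings),
`grade_curves.py` (TAC extraction and grading for one patient),
`detect_aspiration.py` (line-profile detection).

A thin CLI wraps the same functions:

```bash
refluxscint run --out results --seed 1            # full pipeline
refluxscint simulate --out sim --seed 1 --n-studies 5
refluxscint tac --study sim/P0000 --out tac_out
refluxscint aspiration --image sim/P0000 --out calls.csv
refluxscint bench --results results/results.csv --out bench_out
```

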