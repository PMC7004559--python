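# chronopk

Pump-to-patient transport modelling, chronomodulated infusion design and
semi-physiological pharmacokinetics for hepatic-artery chronotherapy.

## The problem

Chronomodulated chemotherapy delivers drugs on programmed, quasi-sinusoidal
schedules timed to circadian rhythms, via a multi-channel portable pump into
the hepatic artery. The infusion line between pump and catheter tip holds a
dead volume (1.84 ml in the clinical set-up modelled here), which distorts
the delivered profile in two ways that matter for anyone analysing plasma
PK from such trials:

* a **fill delay** — no drug reaches the patient until the pumped volume has
  displaced the tube content, which takes from ~51 min (irinotecan) to over
  3 h (oxaliplatin) depending on the programmed flow rate;
* a **rinse spike** — when the pump stops, a tube-volume's worth of drug is
  left in the line and is expelled as a bolus by the subsequent 30-min
  glucose flush (up to ~10.7% of the oxaliplatin dose).

`chronopk` models the line as a 1-D advection equation

```
∂u/∂t = −V(t) ∂u/∂x,    u(0,t) = S(t) / (sa·V(t)),    d(t) = sa·V(t)·u(t, L)
```

solved both exactly (method of characteristics, via cumulative-volume
bookkeeping) and by an upwind finite-difference scheme as a numerical
cross-check. On top of that it provides:

* a **corrected-program designer** — bolus (fills the tube, ends at the
  clinical start) + truncated sinusoid (cut when the drug bag empties) +
  rate-matched glucose rinse — that makes the delivered profile equal the
  clinical intent with no delay and no spike;
* **semi-physiological Liver/Blood/Organs PK models** for irinotecan/SN38
  (Michaelis–Menten bio-activation, Km = 59.2 µM fixed), oxaliplatin
  (free/bound platinum, renal clearance of free Pt) and 5-fluorouracil
  (linear three-compartment), driven by the delivered profile into the
  Liver and individualised by Vauthey/Nadler-style compartment volumes;
* **estimation**: 10%-proportional-error weighted least squares minimised by
  CMA-ES in log-parameter space, clearance-route penalty constraints, Sobol
  sensitivity screening and likelihood-profile identifiability;
* **cohort analysis**: nearly unbiased CV `(1 + 1/(4n))·σ/μ·100`, fuzzy
  c-means clustering (m = 2) with the Fukuyama–Sugeno validity index, and
  metric MDS projection with distance-fidelity reporting;
* a **synthetic cohort generator** emulating the trial design (11 patients,
  7 men / 4 women, the per-drug post-infusion sampling grids, log-normal
  parameter variation, 10% proportional assay noise).

## Worked example

```
$ chronopk simulate-pump --drug LOHP --out profile.csv
fill delay: 183 min
flush spike: 10.71% of dose
```

Oxaliplatin (28 mg/m² at 3 mg/ml, 11.5 h sinusoid, BSA 1.84 m²) is pumped so
slowly that the 1.84 ml line takes just over three hours to fill, and 10.71%
of the dose is still in the line when the pump stops — delivered later as a
spike by the glucose flush. The corrected program removes both artefacts:

```
$ chronopk optimize-profile --drug LOHP --out corrected.yaml
bolus 0.9 min at 125.0 ml/h; drug channel cut at t = 8.446 h
$ chronopk simulate-pump --config corrected.yaml --out corrected_profile.csv
fill delay: 1 min
flush spike: 0.00% of dose
```

(The 1-min "delay" is the bolus itself, which ends exactly at the intended
clinical start; the delivered profile then follows the intended sinusoid
with zero onset shift and an L¹ mismatch below 0.01% of the dose.)

The same library functions drive the full pipeline in Python:

```python
from chronopk import build_trial_schedule, solve_transport_characteristics, fill_delay

program = build_trial_schedule("CPT11", reference_bsa=1.84)
profile = solve_transport_characteristics(program)
print(fill_delay(profile))   # -> 51 (minutes)
```

and `chronopk synth` / `fit` / `cluster` generate a synthetic cohort, fit
each virtual patient (pooled R² ≈ 0.94–0.98 at 10% noise) and cluster the
fitted parameter vectors.

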