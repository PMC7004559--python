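# Methods

## Pump-to-patient transport

The infusion line is modelled as pure 1-D advection of an incompressible
fluid: `∂u/∂t = −V(t) ∂u/∂x` with inlet boundary `u(0,t) = S(t)/(sa·V(t))`
and outlet delivery `d(t) = sa·V(t)·u(t,L)`. No diffusion or Taylor
dispersion is included, and between program segments the flow is zero and
the field is frozen. Because the fluid is incompressible the outlet depends
only on the tube's total dead volume; the default tube is the clinical
1.84 ml line. (The clinical set-up is two sections of different diameter;
the simplified single tube of length 2340 mm uses the radius that preserves
the 1.84 ml volume, ≈0.5 mm.)

**Exact solver.** The characteristics solution is implemented in Lagrangian
volume coordinates: the parcel exiting at time `t` entered when the
cumulative pumped volume was `W(t) − V_tube`, so
`d(t) = Q(t)·c(W(t) − V_tube)` where `c(w)` is the (piecewise-constant)
inlet concentration indexed by cumulative volume and `Q = sa·V` the pump
rate. `W` is accumulated analytically per segment (the sin² arch has a
closed-form integral), the tube-fill time is found by root-bracketing on
`W(t) = V_tube` (xtol 1e-12 h), and the cumulative outlet mass is the exact
piecewise-linear mass-vs-volume relation, so mass conservation holds to
machine precision. Delays are reported to the nearest minute, the clinical
granularity.

**Finite-difference cross-check.** A first-order upwind scheme (backward in
space, explicit in time, CFL factor 0.9, default dx = L/1000) solves the
same PDE on the physical grid. It is used only to corroborate the exact
solver; tests verify that its L¹ error against the characteristics solution
shrinks under grid refinement and that mass is conserved to <0.1% at
dx = L/2000.

**Trial schedules.** The drug arch is `peak·sin²(πt/T)` — chosen because
its mean is half its peak, which reproduces the published peak rates from
dose, stock concentration and duration (e.g. irinotecan:
2·180/(3.33·6) = 18.02 ml/m²/h) — followed by a 30-min glucose rinse of the
same shape. Per-m² rates are scaled by a reference body surface area of
1.84 m² (configurable per patient); this value reproduces the published
fill delays and spike fractions. The printed 5-FU peak (3.4 ml/m²/h)
slightly exceeds the value implied by its nominal 933 mg/m² dose (3.245);
the printed peak is used as the programmed pump input and the nominal dose
as the denominator of dose-fraction metrics.

## Corrected infusion programs

Three parts, with stock concentrations untouched (drug-stability
constraint): (1) a bolus at the channel maximum rate (default 125 ml/h),
sized to exactly the tube volume and scheduled to end at the intended
clinical start, so the line is primed with drug at t₀; (2) the intended
sinusoid, truncated at the root `t_cut` of "cumulative arch volume = bag
volume − tube volume" (bisection, 1e-9 ml); (3) a glucose rinse continuing
the arch's volumetric rate to the intended end, which expels the residual
tube drug at exactly the intended rate. The legacy 30-min rinse peak may be
appended unchanged; by then the line holds only glucose, so it delivers no
drug. By construction the delivered mass-rate equals the intended curve
exactly; the simulation-based test tolerance (L¹ < 1% of dose, onset shift
0 min) absorbs only output-grid quadrature.

## Compartment volumes

Liver: the BSA-based Vauthey total-liver-volume regression,
`TLV(ml) = −794.41 + 1267.28·BSA`. Blood: Nadler's sex-specific formula
from height and weight. Organs: total body volume minus liver and blood,
with total body volume taken as weight over a whole-body density of
1.04 kg/L — a deliberate, config-overridable stand-in for a nomogram-based
body-volume method; all three formulas accept overrides. BSA defaults to
Du Bois. Non-physiologic inputs (any volume ≤ 0) raise.

## PK models

All models track amounts (mg) in Liver, Blood, Organs; the delivered
profile enters the Liver (hepatic-artery infusion). Transport across each
tissue–Blood interface is `p·V_tissue·(C_tissue − C_blood)` with one
permeability `p` (1/h) per drug per interface: the flux vanishes exactly
when concentrations match (tested), and the coefficient scales with the
tissue volume, the simplest reading of volume-proportional passive
transport. Clearances are first-order on amounts; cleared mass leaves the
system (no enterohepatic recirculation) and is tracked in auxiliary
cumulative states together with the cumulative input, so mass balance is an
internal identity of each integration (verified to 1e-6 relative).
Circadian modulation of parameters is deliberately absent.

* **Irinotecan/SN38** (6 states + bookkeeping): Michaelis–Menten conversion
  in Liver and Organs only (`Vmax·C/(Km+C)`, Km fixed at 59.2 µM ≈
  34.7 mg/L via the parent molar mass 586.68 g/mol), none in Blood
  (carboxylesterases absent there). SN38 amounts are in mg of SN38 with the
  conversion scaled by 392.40/586.68 for mole consistency. SN38 is given
  Blood↔Liver and Blood↔Organs transport — without it plasma SN38 would be
  identically zero since conversion does not occur in Blood — and is
  cleared hepatically (deactivation to its glucuronide) and in Organs at
  twice the hepatic rate (fixed ratio, from the ~4%:~9% literature split).
* **Oxaliplatin** (6 states): free and protein-bound platinum per
  compartment; only free Pt crosses walls; binding `k_on` and unbinding
  `k_off` in every compartment (unbinding reflects protein turnover); the
  only elimination is renal clearance of free blood Pt. Parent drug and its
  platinum metabolites are lumped into one species. `Pt_total` =
  free + bound in Blood.
* **5-fluorouracil** (3 states): linear, hepatic and renal clearance, no
  protein binding, no Organs clearance.

Integration uses LSODA with rtol 1e-8 (1e-6 inside optimization loops),
atol 1e-10 and max step 0.05 h so the 30-min flush spike is never stepped
over. States are clipped at zero on output; a state below −1e-6 mg signals
integration failure, which the fitting layer converts to an infinite cost.

## Estimation

Cost: `Σ ((pred−obs)/(0.1·max(obs, LLOQ)))²` — the 10% proportional assay
error, floored at a configurable LLOQ (default 1e-3 mg/L) so baseline zeros
carry finite weight — plus quadratic penalties
`w·(route_fraction − target)²` on clearance-route mass-balance targets.
Penalties rather than hard constraints keep the problem derivative-free.
Each constraint carries its own evaluation horizon because the literature
targets refer to different times: the oxaliplatin tissue-bound fractions
(84% Organs / 12% Liver) are end-of-infusion quantities while the 54% renal
fraction is a post-treatment cumulative — and, summed, the three exceed
100%, so they cannot bind simultaneously at one time point; they act as
soft pulls. (With renal clearance the only elimination route, the
asymptotic renal fraction is trivially 100%, hence the default 24 h
horizon.)

Minimization runs in log10-parameter space (bounds default to ±2 decades
around the generator means) with an in-package CMA-ES — standard
(µ/µ_w, λ) formulation with cumulative step-size adaptation and rank-one
plus rank-µ covariance updates, population `4+⌊3 ln n⌋`, all randomness
through one seeded generator, hence bit-reproducible fits. A soft quadratic
barrier discourages leaving the box. Starting point: the geometric midpoint
of the bounds.

Identifiability is probed in the two-step pattern the models were built
around: a global Sobol variance decomposition of the cost over the
parameter box (Saltelli-type sampling through `scipy.stats.sobol_indices`,
log-uniform by default; total-order index < 0.01 flags a parameter as
non-identifiable) as a cheap necessary condition, then likelihood profiles
(re-optimizing all other parameters at each grid value; excursion below
3.84 — the 95% χ²₁ threshold — flags practical non-identifiability, and the
threshold crossing defines the confidence interval). Under 10% noise on the
trial grids this reduction leaves, e.g., oxaliplatin's `k_off` unpinned
(it relaxes slowly relative to the 17.25 h observation window), so the
noisy recovery study fixes it and fits (k_LB, k_on, Cl_B).

Flush-time realignment: a blood draw scheduled at the rinse start is moved
to the rinse peak (+15 min) when its concentration exceeds the preceding
point's (the spike evidently occurred before the draw); otherwise left
unchanged. Adjustments are returned as a per-patient log.

## Cohort variability and clustering

The nearly unbiased CV `(1 + 1/(4n))·σ/μ·100` (sample σ) summarises
inter-patient spread per parameter; drug-level variability is the mean over
parameters. Fuzzy c-means (fuzzifier m = 2, matching the squared
memberships of the printed objective) is run with 20 seeded restarts per
candidate count, keeping the best objective; a point coinciding with a
centroid receives crisp membership. The cluster count minimises the
Fukuyama–Sugeno index (computed with `x_i`, the conventional form) over
[2, n−1], ties toward the smaller count. Crisp labels (max membership)
define the per-cluster CV reassessment; singleton clusters are skipped.

Columns are scaled to unit variance before clustering by default (raw PK
rate constants span orders of magnitude and would otherwise let one
parameter dominate the Euclidean metric); raw-scale and log-scale modes are
provided. For log-normally distributed parameters the log transform is the
appropriate one — it gives fold-change-separated groups equal spread —
and the two-subpopulation validation uses it.

A caveat established during validation: with a well-converged FCM, V_FS
decreases with c on crisply separable data (the separation term grows as
centroids spread), so an argmin over [2, n−1] recovers a planted count only
when groups are compact enough that splitting one forces near-coincident
centroids, whose fuzzy memberships worsen the index. The synthetic
two-subpopulation check therefore uses fold-change 5 between group means
with 10% within-group CV; under those conditions the selector returns 2 and
the within-cluster mean CV drops to ~10% against ~50% population-wide. On
real cohorts the index should be read as an elbow diagnostic as much as an
argmin.

The 2-D view is metric MDS (scikit-learn, seeded); fidelity is the Pearson
correlation between original and embedded pairwise distances (>0.98 on the
clustered synthetic cohorts, matching the regime where the projection is
trustworthy).

## Synthetic cohorts

The generator emulates the trial design: 11 patients (7 men, 4 women),
anthropometrics uniform over 1.55–1.88 m and 52–95 kg, per-drug post-HAI
sampling grids {0, 2, 3, 4, 6, 8.25, 31.75} h (irinotecan),
{0, 3, 6, 9, 11.5, 17.25} h (oxaliplatin), {0, 3, 5.75, 9, 11.5} h (5-FU;
the "approximately 3 h" draw fixed at 3.0), log-normal inter-patient
parameter variation (exact-mean parameterisation; default CV 50%), and a
10% proportional measurement error, multiplicative-normal truncated at zero
(log-normal mode available). Optional subpopulations assign group-specific
means. One seed fixes anthropometrics, parameters, noise, fits and clusters
end to end.

Default parameter means are order-of-magnitude physiologic values chosen
once so that simulated profiles show the qualitative clinical features
(rapid irinotecan rise; free-Pt spike at the flush shifting t_max; fast
5-FU decay with a late flush bump) and the clearance-route fractions sit
near the literature targets; they are placeholders by construction — the
real per-patient values were never published — so passing recovery tests
demonstrates that the pipeline estimates what generated the data, not that
these values describe any patient. Problem sizes in the test suite (single
patients for recovery, 20 replicates for the noisy study, 20 random
programs for solver agreement) were chosen as the smallest that make the
statistical assertions stable.

## Known limitations

* The advection model ignores diffusion, dispersion and pump mechanical
  error; it predicts sharp delivery onsets that a real line would smear.
* The Organs compartment is a lumped remainder; its clearance parameters
  are weakly identifiable from plasma data alone (the Sobol screen flags
  them), which is why route-fraction constraints are needed.
* The oxaliplatin literature constraints are mutually inconsistent as
  simultaneous mass fractions; they are treated as soft penalties with
  per-constraint horizons.
* Fitted-parameter clustering inherits estimation noise that the
  true-parameter validation cohorts do not have; V_FS-based count selection
  is reliable only for compact, well-separated groups (above).
* Circadian modulation of PK parameters, mixed-effects population
  estimation and covariate association are out of scope.
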