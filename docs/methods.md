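# Methods

## The kinetic model

`coagsim` ships the Hockin–Mann model of the tissue-factor (extrinsic)
coagulation pathway: 34 species and 43 irreversible mass-action steps
(reversible bindings written as forward/backward pairs; two of the
complex-decay steps share one constant, giving the model's 42 distinct
rate constants). The network covers initiation (TF·VIIa formation and
factor X/IX activation), amplification (intrinsic tenase IXa·VIIIa and
prothrombinase Xa·Va, with meizothrombin as the intermediate of
prothrombin activation), and the stoichiometric inhibitors TFPI and
antithrombin-III. There is no synthesis or degradation, so the system is
closed: the total of each core protein over its free and complexed forms
is a conservation law. The network file makes those moiety sets explicit
and `load_network` verifies, reaction by reaction, that each moiety's
weighted stoichiometry change is zero. One bookkeeping convention: the
VIIIa split into its A2 subunit and the rest is counted by assigning the
VIII moiety unit to the `VIIIa1-L` fragment.

Concentrations are in nM, time in seconds; second-order constants from
the literature (M⁻¹s⁻¹) are stored divided by 10⁹.

## The virtual PT assay

The prothrombin-time assay is simulated by setting tissue factor to
5 nM (the reagent bolus; the network's own trace default is overridden),
starting all other species from the individual's plasma levels, and
integrating until the thrombin readout reaches 20 nM. The PT is the
first crossing time.

* Readout: free IIa by default. Meizothrombin is catalytically active
  and some conventions count it at weight 1.2; `AssayConditions(readout=
  "IIa+1.2mIIa")` selects that variant. The default is the literal
  reading of "activated factor II".
* Integrator: LSODA via `scipy.integrate.solve_ivp` with the analytic
  mass-action Jacobian, `rtol = 1e-8`, `atol = 1e-12` nM (species span
  ~6 orders of magnitude, from 0.1 nM VIIa to 3.4 µM ATIII). The
  threshold crossing is a terminal event located by root-finding on the
  solver interpolant; `prothrombin_time` additionally extracts crossings
  from stored trajectories by linear interpolation. A fixed first step
  (1 µs) makes the step sequence — and hence the located event time —
  independent of the integration horizon, so results are bit-for-bit
  deterministic and horizon-invariant.
* Degenerate inputs: a readout already at threshold gives PT = 0; never
  crossing within `t_max_s` (default 1000 s) returns the
  `CLOT_NOT_REACHED` sentinel (`inf`), a legal outcome so pathological
  random draws cannot abort a cohort. Pre-clamp dips below −10⁻⁹ nM
  abort the run as integrator failure; smaller noise is clamped to zero
  on output.
* Cross-check: a deliberately naive fixed-step RK4 integrator
  (`simulate_clotting_fixed_step`, dt = 1 ms) reproduces the adaptive
  solver's PT to well under 0.5% on random profiles; with the default
  levels both give PT = 27.34 s.

## The synthetic population

The generator emulates interindividual variability of coagulation-protein
expression in healthy adults. Each of II, V, VII, VIII, IX, X, XI,
ATIII and TFPI gets an independent multiplier `1 + (cv/100)·z`,
`z ~ N(0,1)`, applied to the kinetic model's default mean; the CVs
(11.95% for II up to 35.16% for TFPI) are medians of published
population measurements. Choices the data did not fix:

* Truncation: "truncated Gaussian" without stated bounds. We truncate
  at zero by rejection-resampling — negative concentrations are
  unphysical, and at these CVs rejection is rare enough that the mean
  bias stays under 0.5% and the realised CV within ~1% of nominal.
  Symmetric bounds (e.g. ±2σ) would additionally trim the tails; see
  Limitations.
* VII/VIIa: the same gene product at a fixed ~1% activation ratio, so
  both share one multiplier.
* Factor XI: the extrinsic network contains no XI species. XI is
  accepted in the population spec (nominal mean 1.0), carried as an
  inert annotation with a warning, and has no kinetic effect.
* Cohort size: default 1000 per intensity, which puts the Monte Carlo
  standard error of the INR sd near 0.01 untreated.

Anticoagulant treatment is modelled as a uniform proportional reduction
of II, VII (and VIIa), IX and X to a fraction of baseline — the steady
state warfarin produces — applied per individual, so it scales the mean
and the spread of those levels together. No pharmacokinetics, genetics
or synthesis dynamics are modelled.

What passing tests on this generator do *not* show about real data:
real factor levels are weakly correlated (shared hepatic synthesis and
vitamin-K status), assay noise is absent, and intraindividual drift is
ignored; the independence assumption follows the population model being
reimplemented.

## Cohort analysis

The mean normal prothrombin time (MNPT) is the arithmetic mean of the
untreated arm's finite PTs; it is then a fixed scalar for every treated
arm of the same cohort. INR = PT / MNPT, a plain ratio without the
reagent-specific ISI exponent — so the untreated mean INR is 1 by
construction. Non-clotting individuals propagate an infinite INR,
excluded from moments and quartiles and counted in diagnostics; outliers
follow the 1.5×IQR boxplot convention. Correlations are Pearson R of
*baseline* (pretreatment) levels against INR, per intensity, so the
treated-arm table asks how the original variability shows through under
treatment; zero-variance levels give an undefined (NaN) R.

## The titration (dose-surrogate) experiment

The fraction of vitamin-K-factor levels remaining is the single lever
this model gives treatment, so the "dose search" titrates that fraction
per individual: bisection over [0.05, 1] until the INR is within 0.01 of
the target (2.5 by default), at most 40 iterations. INR is monotone
decreasing in the fraction, so the root is unique; endpoints within
tolerance are returned directly, and a non-bracketing individual is
flagged, never dropped. Bisection was chosen over Newton steps because
each INR evaluation is a full ODE solve and derivatives are not cheaply
available.

The paired series are labelled by content: `full_variability` (sampled
profiles) and `fixed_baseline` (every individual at the cohort-mean
levels). With no pharmacokinetic layer in this package the
fixed-baseline series is degenerate — the simulation is deterministic,
so the search runs once and its value is replicated, making that
series' variance exactly zero (bounded in general only by the search
tolerance). The contrast therefore isolates the variance contributed by
baseline protein levels alone, and the correlation table identifies its
carriers (VII and X negative — more procoagulant, deeper reduction
required; TFPI positive).

## Problem sizes

Cohort analyses default to n = 1000 individuals; the full five-intensity
grid at that size is ~5000 stiff solves (a few minutes on one core).
The test suite shares one such cohort across its end-to-end checks, runs
the titration experiment at n = 150 (the experiment costs ~16 solves per
individual), and uses n = 50 000 draws for generator statistics (no ODE
involved). The RK4 cross-check uses five random individuals.

## Known limitations

* The treated-arm INR distribution is right-skewed: joint low draws of
  VII and X under zero-truncated Gaussians produce a heavy tail (a few
  INR > 5 per 1000 at 20% intensity), so the sample sd at strong
  treatment runs above robust spread measures (IQR/1.349 ≈ 0.44 here).
  Bounded truncation would trim this tail; the zero-truncation rule was
  fixed a priori as the physically minimal assumption.
* TFPI's association with the treated INR is real but modest in this
  network (|R| ≈ 0.16 at n = 1000), statistically inseparable from
  factor V's residual association at that sample size.
* Only the extrinsic pathway is modelled: no contact pathway, protein C
  system, platelet surfaces, or rate-constant fitting.
* The mg/day warfarin dose scale, its pharmacokinetic variance floor and
  genetics are out of scope; dose-level claims are reproduced as
  sign/ranking properties of the reduction-fraction surrogate only.
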