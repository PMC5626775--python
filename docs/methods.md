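# Methods

## The model

`beigeflux` models whole-cell oxygen consumption (OCR) of cultured adipocytes
during extracellular-flux (Seahorse-type) assays with a deliberately small,
fit-for-purpose ODE system.  Detailed oxidative-phosphorylation models resolve
individual respiratory complexes and membrane potential in millivolts; they
are over-parametrized for whole-cell OCR traces and omit the pathways that
matter here (UCP1, lipolysis).  This model keeps exactly the mechanisms the
data can constrain.

Two state variables:

* `dp` — proton motive force Δp across the inner mitochondrial membrane
  (arbitrary units; only OCR is observed, so Δp has no absolute scale),
* `ffa` — intracellular free fatty acid level (arbitrary units).

Fluxes (OCR units, pmol O₂/min per 10⁴ cells):

```
v_etc  = m_mito · k_etc · (1 + s_ffa·ffa) · (1 − e_rot_aa) / (1 + dp/K_dp)
v_atp  = m_mito · k_atp · dp · (1 − e_oligo)
A_ucp1 = u_ucp1 · (a0 + a_ffa·ffa + a_ra·e_atra)
G      = m_mito · (L_basal + L_ucp1·A_ucp1
                   + L_alt·u_alt·ffaⁿ/(K_altⁿ + ffaⁿ) + L_dnp·e_dnp)

c_dp · dp'  = v_etc − v_atp − G·dp
ffa'        = f_ffa·(k_ffa0 + (k_lip·e_iso + k_palm·e_palm)·(1 − e_bsa))
              − k_clr·ffa
OCR         = v_etc + ocr_nonmito
```

The electron transport chain (ETC) pumps protons in proportion to oxygen
consumption and is inhibited hyperbolically by the back-pressure of Δp —
the simplest saturating form that yields a finite maximum capacity under a
chemical uncoupler.  Δp is dissipated by the ATP synthase and by four leak
conductances: basal, UCP1-mediated (activated basally, by FFA, and directly
by all-*trans* retinoic acid), an FFA-gated alternative uncoupler (Hill gate,
default exponent 2 — the threshold-like FFA dependence seen in BMP4-treated
cells), and the protonophore 2,4-DNP.

Each assay drug enters with a first-order onset `e_a(t) = 1 − exp(−(t−t_inj)/
tau_drug)` (default τ = 1 min), reflecting mixing and response lag and keeping
the right-hand side continuous.  Because the onsets do not feed back on the
states, they are evaluated in closed form and the integrated system stays
two-dimensional.  Cyclosporine A (permeability-transition-pore inhibitor) is
accepted as a protocol agent but has no model effect: PTP inhibition does not
change the final model's behaviour, so the pore is not represented.

BSA scavenging multiplies the stimulated FFA supply (lipolysis and exogenous
palmitate) by `(1 − e_bsa)` while the basal supply persists.  A consequence:
under BSA the model's Rosi cells show *no* Iso response at all, whereas real
Rosi cells retain a partial response; the model errs on the side of the
mechanism it is built to test (FFA-dependence of BMP4 uncoupling) and is not
calibrated to the Rosi/BSA arm.

### Condition parameters

Treatment differences are carried by exactly four per-condition "beige"
modifiers: relative UCP1 protein level `u_ucp1` (control ≡ 0), mitochondrial
content `m_mito` (control ≡ 1), FFA content `f_ffa` (control ≡ 1), and
alternative-uncoupler level `u_alt` (control ≡ 0).  All kinetic parameters —
the "basic mitochondrial functions" — are shared across conditions.  The
shared set has 20 members, all free in the default fit configuration.

### Default parameter values

Defaults were chosen so the control condition reproduces typical human
adipocyte stress-test numbers (basal ≈ 60, post-oligomycin ≈ 22, DNP
maximum ≈ 140, non-mitochondrial 10 pmol O₂/min per 10⁴ cells), with Δp
resting at 2·K_dp so that uncoupling has ~3-fold ETC headroom.  Two leak
conductances were then calibrated numerically, once, against the effect
pattern the generator must emulate (`scratch` calibration, frozen into the
defaults): `L_ucp1 = 622.949` so that direct isoproterenol stimulation
doubles total OCR in the Rosi condition (phase-mean ratio exactly 2.0), and
`L_alt = 15.788` so that Iso doubles uncoupled OCR in the BMP4 condition.
The retinoic-acid activation coefficient `a_ra = 2.1` puts the Rosi RA
response in the same range as its Iso response.  FFA kinetics
(`k_clr = 0.3 min⁻¹`) equilibrate within a measurement phase; the traces'
kinetic time scales are a package convention, since the emulated study shows
its timings only graphically.

## Protocols and summary metrics

Protocols follow plate-assay conventions: measurements every 7 min, injections
3 min after the last measurement of the preceding phase, 3 measurements per
phase with 6 in the final stimulation phase of the discrimination-relevant
designs.  The catalog covers the mito stress test (P1), oligomycin→Iso and its
vehicle arm (P2/P2v), oligomycin→all-*trans*-RA (P3), the reversed-order
validation design Iso→oligomycin (P4), BSA-scavenged and CsA-pre-treated
variants (P5/P7), oligomycin→palmitate-BSA (P6), and a direct-Iso protocol
without oligomycin (P0) used for the fold-change readout.

Stress-test summaries aggregate each phase by its mean after dropping the
first post-injection measurement (mixing artifact), subtract the post-rot/AA
phase (non-mitochondrial OCR), and report basal, ATP turnover, leak,
maximum capacity, spare capacity and cRCR = max capacity / leak.  When leak
≤ 0 the cRCR is reported as undefined rather than raising.

## Fitting and rejection

Agreement is the weighted sum of squared residuals
`Σ ((y_data − y_sim)/σ)²` over all fitted points of all experiments fitted
simultaneously.  A hypothesis is rejected when its best fit exceeds the χ²
quantile at significance α = 0.05 with degrees of freedom equal to the number
of fitted points (the convention of the rejection framework this follows; a
points-minus-parameters convention would only tighten the bound and is
configurable through `alpha`/`chi2_threshold`).

Weights use `σ = max(SEM, 0.5 OCR units, 2.2% of the measurement)`.  The
relative floor matters: SEMs estimated from ~5 replicate wells are themselves
noisy (the standardized residual is t-distributed, not normal), and taking
them at face value makes even the true model's cost exceed the χ² bound on
occasion.  The 2.2% floor is the typical well-to-well SEM of the noise model
(5%/√5) and encodes a minimum plate-assay technical variability.

Optimization is multi-start trust-region least squares (`scipy`
`least_squares`, TRF) in log₁₀ parameter space.  Shared parameters get bounds
of ±6 decades around the defaults (exceptions: Hill exponent in [1, 4], drug
onset τ in [0.2, 5] min).  Condition modifiers get biological plausibility
bounds: content scales within a few-fold of control (`m_mito` ∈ [0.2, 5],
`f_ffa` ∈ [0.5, 3] — measured mitochondrial-protein and lipid differences
between these treatments are of that order), expression-like levels
(`u_ucp1`, `u_alt`) within [10⁻², 10²].  These bounds are load-bearing for
hypothesis discrimination: with unbounded per-condition FFA content, a
no-uncoupler model can mimic an uncoupling response through the shared
substrate-drive term alone, which is exactly the degeneracy the bounds
exclude.  The first start is the package default parameter vector; the
remaining starts are Latin-hypercube samples within ±1 decade of it.  Stage-B
refits also warm-start from the stage-A optimum.  Fits are deterministic
given `(config, seed)`.

Integration inside fitting uses rtol 10⁻⁶/atol 10⁻⁸ (residuals are
noise-dominated far above that); standalone simulation defaults to
rtol 10⁻⁸/atol 10⁻¹⁰ with a stiff-capable solver (LSODA; any scipy
`solve_ivp` method can be requested for cross-checks).

## Hypotheses

* **H1**: BMP4 cells have `u_ucp1 = u_alt = 0`.
* **H2**: BMP4 `u_ucp1 = θ · δ · u_ucp1(rosi)` with θ ∈ (0, 1] fitted and
  δ = 0.1 by default — "below the detection limit" has no printed number, so
  the bound is declared as a configurable fraction of the fitted Rosi level
  and reported with the results.  `u_alt = 0`.
* **H3**: BMP4 `u_ucp1 = 0`, `u_alt` free.

All three fix control modifiers at reference and give Rosi a free UCP1 level
with `u_alt = 0` (Rosi uncoupling is attributed to UCP1).  Stage A comprises
the dynamic OCR data: stress tests and oligomycin→Iso(±vehicle) for all
conditions, plus the Rosi RA experiment — the latter pins `a_ra` so that
stage-A ensembles make a meaningful prediction for the discriminating
experiment.  Stage B adds the BMP4 RA experiment.  Rejection is monotone
across stages by construction.  Whether to refit all parameters at stage B or
freeze the shared kinetics is genuinely open; the default refits everything
(`freeze_shared_at_stage_b` reserved for the alternative).

## Ensembles and prediction bands

The acceptable ensemble is a feasibility envelope, not a posterior: any
parameter vector whose re-evaluated cost stays under the threshold is a
member, and the best fit always is.  Sampling is a random walk over the
acceptable region seeded at the optimum (global Gaussian jitter alternating
with single-axis excursions, every proposal re-checked against the
threshold).  Prediction bands are the pointwise min/max of the members'
simulations; band overlap (each band widened by one data SEM) decides
discriminability — with the default cutoff 0, two designs are discriminable
when their bands are disjoint at some post-injection time point.  Validation
coverage counts data means inside the band ± 1 SEM; the default pass cutoff
is 0.9.  Both cutoffs are configuration values; the emulated analysis used
visual overlap.

## Synthetic data

The generator simulates per-well traces as the noiseless model trajectory
plus independent Gaussian noise, sd = max(0.5, 5%·|OCR|), 5 wells per
condition, and reports the well mean and estimated SEM.  Defaults were chosen
to be visually consistent with typical published error bars; no noise
magnitudes are printed in the emulated study.  What the generator does *not*
emulate: instrument drift, plate-edge effects, background wells, correlated
noise between adjacent measurements, and the partial Rosi response under BSA
noted above.  Passing tests therefore demonstrate the *machinery* —
identifiability of the hypothesis structure under honest noise — not
robustness to instrument artifacts.

The H2 counterfactual world (`default_truth("H2")`) sets the BMP4 UCP1 level
to 0.0143 (calibrated so its oligomycin→Iso response matches the H3 world's
exactly); it is indistinguishable from H3 on stage-A data by construction and
separable only through the RA experiment.

## Numerical and degenerate-input choices

* Steady states: FFA from the supply/clearance balance in closed form; Δp by
  bracketed root finding (the balance is strictly decreasing in Δp).  A
  configuration with no proton sink at all (no ATP synthase activity and zero
  leak) has no finite steady state and raises a solver error with residual.
* Zero-noise traces carry SEM 0; the fit-time uncertainty floor makes them
  fittable (the container accepts SEM ≥ 0; strict positivity is enforced only
  where χ² weights are formed without a floor).
* Equal-cost optima: all are kept in the ensemble; "best" is the first found
  under the seeded start order.
* A rejected fit yields an empty, flagged ensemble; an ensemble smaller than
  `ensemble_min_members` is flagged, not fatal.

## Problem sizes

The reference analysis fits 9 experiments / 108 points at stage A and 10/120
at stage B, with 26–27 free parameters per fit and 3 starts; the staged
workflow, including both ensembles and held-out validation, completes in
about three minutes on one core.  These sizes are the package's desk-scale
reference configuration; every piece scales to more experiments or starts
through `RunConfig`.

## Known limitations

* Δp and FFA are in arbitrary units; parameters tied to them (e.g. `K_alt`,
  `c_dp`) are identifiable only up to that scaling.
* The χ²-with-df-=-n convention is anti-conservative when SEMs are taken from
  few replicates; the relative uncertainty floor mitigates but does not
  remove this.
* The discrimination verdict depends on the modifier plausibility bounds (see
  above); with unbounded condition modifiers, H2 degenerates into an
  unfalsifiable "arbitrarily active trace UCP1" model.
* The BSA arm of the Rosi condition is qualitatively wrong by design (see
  model section); only BMP4 BSA behaviour is part of the calibration
  contract.
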