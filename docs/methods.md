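# Methods

## The kinetic model

`tsp1apop` implements a deterministic kinetic model of TSP1-induced
apoptosis signaling in endothelial cells. Thrombospondin-1 (TSP1) binds the
CD36 receptor (K_d = 0.23 uM, k_off = 1.2e-2 /min, hence
k_on = 5.22e-2 /uM/min), the ternary TSP1:CD36:p59fyn complex activates the
Src-family kinase p59fyn, activated p59fyn phosphorylates p38MAPK, and
phosphorylated p38 (pp38) acts along two arms:

1. a **direct arm** in the cytosol, where pp38 promotes maturation of
   procaspase-8 to caspase-8;
2. a **transcriptional arm**, where pp38 translocates into the nucleus
   (rate `K_trsp`), activates the resident nuclear NF-κB pool, and the
   activated factor drives FasL transcription with Michaelis–Menten
   kinetics `V = Vmax_FasL * NFkB_p / (Km_FasL + NFkB_p)`. Secreted FasL
   ligates Fas (K_d = 0.4 nM), the DISC assembles with FADD, and
   DISC-bound procaspase-8 matures to caspase-8. DISC also binds c-FLIP to
   form p43-FLIP, which activates IKK; IKK phosphorylates IκB and releases
   cytosolic NF-κB, closing the positive feedback onto FasL production.

Caspase-8 activates procaspase-3 through an enzyme–substrate complex;
caspase-3 feeds back onto procaspase-8 (weakly), is sequestered and
destroyed by XIAP (the complex degrades, consuming both partners), and
cleaves PARP into cPARP, the apoptosis readout. Procaspase-8 and
procaspase-3 are synthesized at `V = F*DISC + Ksyn_all`; other turnover
species carry basal synthesis at `Ksyn_all = 1e-4 uM/min` and first-order
degradation (default `1e-3 /min`, species-specific overrides chosen so the
resting state balances exactly).

The model has 53 species in two well-mixed compartments, cytosol
(relative volume 1) and nucleus (relative volume 0.1432). State variables
are concentrations in their own compartment; a flux J crossing the
membrane enters the destination compartment scaled by the volume ratio, so
mass (concentration x volume) is conserved in transport. Sixteen species
have nonzero resting concentrations; CD36 and Fas levels derive from
measured receptor counts (24,372 and 7,860 receptors/cell at 1 pL, i.e.
4.05e-2 and 1.31e-2 uM). Receptors are internalized when ligated and
re-inserted, with the bound ligand degraded, so the total CD36 and Fas
pools are conserved exactly by stoichiometry.

### Parameter provenance

Every bundled table row carries a `provenance` tag. Quantities printed in
the source literature (`paper`) are the two receptor affinities, the
universal dissociation rate, the basal synthesis and default degradation
rates, the compartment ratio, the receptor counts, the gamma shape factor
and the apoptosis threshold. Everything else (`reconstructed` / `fitted`)
was set by hand so that the assembled network reproduces the documented
system behavior: a resting steady state without TSP1; a sigmoidal,
switch-like cPARP trajectory under stimulation; near dose-independence of
the 24-h response between 0.1 and 100 nM TSP1; insensitivity of cPARP to
ten-fold receptor-level changes; strong sensitivity to XIAP and PARP; and
the ordering of the population-level intervention strategies (XIAP
knock-down > doxorubicin > baseline > faster translocation). This mirrors
the role the original calibration played; the baseline set should be read
as one self-consistent working point, not as measured constants.

### Design choices in the reconstruction

- **Stable pools.** XIAP, PARP, p59fyn and p38MAPK carry no basal
  synthesis/degradation; over the 24-h horizon they are treated as
  redistribution-only pools. The choice matters for the doxorubicin
  perturbation (`Ksyn_all` x10): with these species also synthesized, the
  inhibitor capacity (XIAP) and substrate pool (PARP) inflate in lock-step
  with the pro-apoptotic supply and the strategy's documented enhancement
  inverts or explodes. With stable pools, cPARP is proportional to the
  sampled initial PARP, which is also what the fate-prediction result
  (PARP AUC ~ 0.95) implies.
- **One-shot phosphorylation pulse.** Phosphatase-bound pp38 is removed
  rather than recycled to p38. The p38 pool is therefore converted once,
  early, and the pp38 exposure equals pool/removal -- which makes the
  response nearly dose-flat (the pulse saturates at low TSP1) while
  staying sensitive to phosphatase inhibition (slower removal) and to the
  translocation rate (faster nuclear drain of the cytosolic effector).
- **NF-κB bookkeeping.** Resting NF-κB sits in the cytosolic IκB complex
  plus a small stable nuclear pool; free cytosolic NF-κB appears only when
  IKK signaling releases it and is avidly recaptured by IκB. FasL
  transcription saturates in activated NF-κB, so the transcriptional arm
  is robust to moderate changes in NF-κB trafficking.
- **Caspase-activity observable.** Fluorogenic caspase-3 assays integrate
  cleaved substrate, so the "caspase-3 activity" observable is modeled as
  accumulated cleavage (an assay background plus cPARP, fold-change over
  the background) rather than the instantaneous caspase-3 concentration.
  The cumulative readout also preserves the direction of the
  p38-inhibition comparison at 300 min, which an instantaneous readout
  inverts transiently through peak-timing shifts. In this reconstruction
  the FasL arm contributes mostly after the first few hours, so the
  300-min inhibition margin is small (fractions of a percent) though
  strictly negative.

## Population model

Cell-to-cell variability is extrinsic only: all cells share one parameter
set, and each of the 16 nonzero initial concentrations is drawn
independently from Gamma(a = 5.5, b = mean/5.5), so the distribution mean
equals the baseline and the CV is 1/sqrt(5.5) ~ 0.43. One master seed
spawns per-cell substreams, so enlarging a population extends it without
reshuffling earlier cells. A cell is apoptotic when its cPARP at the 24-h
endpoint reaches 1.05 uM; the time-to-threshold T_t is the interpolated
first crossing, reported for apoptotic cells. The 1.05 uM value is the
published calibration (the cPARP level at which a population under
low-dose doxorubicin plus 10 nM TSP1 is 50% apoptotic); re-running that
calibration on the reconstructed model returns a threshold within ~10% of
it.

Endpoint (not ever-crossed) classification is used because the published
population histograms classify cells by concentration at each time point;
with cPARP treated as a terminal product the two rules coincide.

## Perturbation strategies

Seven built-in edits (applied to copies; originals untouched): XIAP x0.5
(IC), DXR = Fas IC x3 + `Ksyn_all` x10, Ptase = `K_on_dephos` and
`K_dephos` x0.1, Kp = the three phosphorylation rate constants (p59fyn,
p38MAPK, IκB) x10, pro3 IC x3, Fas IC x3, `Ktrsp` x10, plus the
p38-inhibition scenario (`k_phos_nfkb` = 0) used for hold-out validation.
The "percent more cells" comparison is relative change of the apoptotic
fraction by default (an absolute-difference mode exists); strategy
comparisons use one-way ANOVA against baseline on max-cPARP (all cells)
and T_t (apoptotic cells), without multiplicity correction, with a
Holm-corrected alternative available through `statsmodels` if needed.

## eFAST

The extended Fourier Amplitude Sensitivity Test assigns each input a
driving frequency along the search curve
x(s) = 0.5 + arcsin(sin(w s + phi))/pi, maps the curve into each input's
range (log-uniformly over 0.1x-10x baseline by default, because the range
is multiplicative), and reads the first-order index from spectral power at
the driving frequency and its first M harmonics; the total-order index is
one minus the power at the complementary low frequencies. Defaults:
M = 4, 5 resample phase shifts, 513 points per curve. 513 (not the more
common 257) is used because complementary-frequency coverage at 257
produces closed low-order Lissajous curves that misestimate interaction
variance; at 513 the estimator reproduces the analytic Ishigami and
Sobol-g indices within 0.05, which is the package's oracle requirement. A
dummy input is always carried through the analysis; inputs are called
influential when their total-order index beats the dummy's in a one-sided
Welch test over resamples.

## Parameter estimation

The objective is the weighted sum of squared residuals between simulated
and observed fold changes of five observables (TSP1:CD36:p59fyn complex,
activated p59fyn, activated p38 over 30-60 min at 10 nM; caspase-3
activity over 300 min at 5 nM and 720 min at 0.388 nM). Immunoblot
observables carry the control-band background as an additive offset so
fold change is exactly 1 at t = 0. Fitting uses bounded
trust-region-reflective least squares in log10 parameter space (kinetic
constants span decades and box bounds stay boxes), from log-uniform random
starts plus one warm start at the incumbent values -- the warm start makes
the step-wise refinement provably monotone. The step-wise pipeline
alternates an eFAST screen of the candidate parameters (WSSR as the
output, dummy-referenced) with refitting of the influential set, updating
the baselines each iteration; the 12 lowest-WSSR parameter sets form the
reported ensemble. Per-series weights default to 1.

## ROC analysis

Nineteen per-cell predictors (16 sampled initial concentrations,
[XIAP]/[PARP], [PARP]/[XIAP], |[PARP]-[XIAP]|) are scored against the
simulated fate by single-feature AUC. The curve and AUC come from the
standard trapezoidal sweep (scikit-learn backend), which equals the
Mann-Whitney U probability with ties counted one half; the test suite
verifies this against exhaustive pair counting. Predictors are
auto-oriented (AUC = max(A, 1-A), flip recorded) because XIAP predicts
apoptosis with *low* values. Confidence intervals default to a stratified
bootstrap (2000 resamples, percentile), with the Hanley-McNeil closed form
as an alternative; the p-value against AUC = 0.5 is the two-sided
Mann-Whitney test. Fate-group comparisons of initial concentrations use
the two-sided Wilcoxon rank-sum by default (Welch-t optional).

## Synthetic data

The training measurements exist only as digitized figures, so the package
generates stand-ins: the bundled model is simulated under each
observable's protocol, sampled on the study-shaped grids (0-30 min for the
complex and pp59, 0-60 min for pp38, 0-300/0-720 min for caspase
activity), converted to fold change, and multiplied by lognormal noise
exp(N(0, cv)) -- densitometry noise is proportional, hence multiplicative;
default CV 0.15. The fate-population fixture draws (PARP, XIAP) from the
population gammas and assigns labels by a median split of |PARP-XIAP|
plus calibrated Gaussian label noise, with the noise scale bisected until
the feature's AUC on the sample equals the requested target. Three toy
networks (reversible binding, synthesis/degradation, linear cascade) have
closed-form references and anchor the integration accuracy tests at 1e-8.

## Numerical choices

- Stiff integration: LSODA (BDF fallback) at rtol 1e-6, atol 1e-9 uM;
  halving tolerances moves 24-h cPARP by < 0.1%.
- The right-hand side is generated source code specialized to the
  reaction list (`model.rhs().__rhs_source__` shows it); parameter values
  are passed as a vector so perturbations never recompile.
- Negative concentrations are clipped to zero inside rate evaluation
  only, never in the state; trajectories stay above about -1e-8 uM.
- Transport fluxes are computed in the source compartment's concentration
  units and scaled by the volume ratio on the destination side.
- Quantile-based threshold calibration uses the interpolated empirical
  quantile.

## Problem sizes

Tests and the acceptance script scale the study down to keep runs short:
populations of 120-300 cells instead of 2000 (binomial error ~2-3
percentage points instead of ~1.1), eFAST screens of 65 points/curve
inside the fitting pipeline, 6-8 optimizer starts instead of 100, and
two step-wise iterations instead of four. All full-scale settings remain
the defaults of the corresponding functions. Dose-monotonicity checks use
common random numbers (the same sampled cells at every dose), which makes
the comparison deterministic at small n.

## Limitations

- The bundled reaction list is a reconstruction; rate constants and
  initial concentrations not printed in the source literature are a
  self-consistent working point, and headline percentages computed from
  them are reproduction-quality, not measured values.
- The population model captures extrinsic noise only; reaction-rate
  (intrinsic) fluctuations and cell-cell signaling are out of scope.
- The intrinsic (mitochondrial) apoptosis pathway is not represented;
  cPARP is the single terminal readout.
- The FasL arm activates late in this parameterization, so early
  differences under p38 inhibition are directionally correct but small.
- Synthetic training data share the generating model's structure; recovery
  tests demonstrate estimator correctness, not identifiability of the real
  biology from real blots.
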