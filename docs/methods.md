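# Methods

## Reaction schemes and simulation

Binding mechanisms are expressed as elementary mass-action reactions with
unit stoichiometry between named species: free receptor RNA (`R`, or an
inactive/active pair `Ri`/`Ra` for conformational selection), free ligand
(`L`), an intermediate encounter complex (`I`) and the final complex (`B`).
Each reaction contributes ±k·∏[reactants] to the participating species'
derivatives; no cooperativity or higher-order stoichiometry is modelled.
Ligand depletion is always explicit — the receptor is only 2–10× below the
ligand in the reference design, so pseudo-first-order algebra is an
approximation, not the model.

Units are fixed package-wide to µM and seconds, with bimolecular rates in
µM⁻¹s⁻¹, so published rate tables can be used without conversion.

Integration uses LSODA with rtol 1e-8 and atol 1e-10 µM.  The preset rate
sets span 0.06 s⁻¹ to 23 s⁻¹ plus bimolecular terms up to ~200 s⁻¹ at 20 µM
ligand, which is mildly stiff.  Round-off negatives above −1e-9 µM are
clamped to zero (logged at debug level); anything below that aborts with an
error.  Mass conservation (total ligand, total receptor) holds to < 1e-6 µM
along every simulated trajectory and is enforced by tests.

For the conformational-selection scheme the ligand-free receptor pool is
pre-equilibrated between the inactive and active state at t = 0
(`Ra/Rtot = k_pre/(k_pre + k_unpre)`), reflecting that the RNA is folded and
equilibrated before mixing.  Its rate symbols are namespaced
(`k_pre`, `k_unpre`, `k_on`, `k_off`) internally because the conventional
labels k₁/k₋₁/k₂/k₋₂ collide between the preformation and binding steps;
reports map them back to the conventional labels.

Closed-form results used as oracles: the one-step pseudo-first-order course
B(t) = B_eq(1 − e^(−k_obs t)) with k_obs = k₁L₀ + k₋₁ and
B_eq = R₀L₀/(L₀ + k₋₁/k₁); the apparent equilibrium dissociation constant
K_D = k₋₁/k₁ (one step) and (k₋₁/k₁)·(k₋₂/(k₂+k₋₂)) (two reversible steps).
Mechanisms ending in an irreversible step have K_D = 0; the
conformational-selection scheme has no closed form here because the overall
constant depends on the inactive fraction, and the function says so rather
than guessing.  Note the closed form assumes constant ligand: against a full
simulation it deviates by ~0.16% of R₀ at R₀ = 0.01·L₀ (linearly worse at
higher ratios), which is the tolerance scale the oracle tests use.

## Fluorescence observable and preprocessing

The measured signal is the ligand's emission.  The raw model signal is
([L] + Σ response·[complex])/L₀ plus a baseline, with the free-ligand
response fixed at 1 and complex responses in [0, 1].  By default both
complexes are fully quenched (response 0); responses can instead be fixed at
intermediate values or freed as fit parameters.  They are off by default to
avoid over-parametrization — with both complexes dark the signal is simply
the free-ligand fraction.

One identifiability consequence is worth spelling out: for the
two-irreversible-step scheme (model 3) the final step I → B never feeds back
into free ligand, so with both complexes dark k₂ does not affect the signal
at all and cannot be fitted.  Recovering model-3 rates requires an
observable that distinguishes I from B (e.g. a partially quenched
intermediate).

Measured (and synthetic) traces are preprocessed by: averaging the repeated
shots pointwise, subtracting the baseline estimated as the mean of the final
5% of points, and rescaling so that signal(0) = 1 — every trace then decays
from 1 toward 0.  The transform is exactly invariant under affine maps
a·x + b (a > 0) of the raw signal.  A linear drift across the last decile
exceeding 2% of the normalized amplitude flags the trace as possibly not
equilibrated.  Model predictions are passed through the same transform, so
model and data live on the same scale.  The stopped-flow dead time defaults
to 0 and can be set to truncate the first d_t seconds of every trace.

## k_obs / k_on analysis

Mono-exponential fits (offset + amplitude·e^(−k_obs·t), full trace, initial
rate guess ln2 / t_half) give one k_obs per ligand concentration; ordinary
least squares of k_obs against [L] gives k_on (slope) and an apparent
off-rate (intercept).  Points with a leave-one-out studentized residual
above 3 — the plateau of k_obs at high ligand excess — are excluded from the
slope and reported.  The scatter estimate in that statistic is floored at
1e-9 of the data scale so numerically exact data do not produce spurious
outliers.

## Global fitting

A global fit shares the scheme's rate constants across all traces of a
concentration series and minimizes the summed squared residuals.  Rates are
optimized as log10 values within bounds (default [1e-3, 1e3] in natural
units), which makes positivity structural and conditions the search across
scales.  The best of N multi-starts (default 20) drawn log-uniformly from a
recorded seed is polished without the exploration iteration cap.  Standard
errors are sqrt(diag(RSS/(n−p)·(JᵀJ)⁻¹)) with the Jacobian taken with
respect to the natural parameters at the optimum.  Parameters at a bound are
flagged in the result, not silently reported.

One nuisance is handled explicitly: the normalization anchors each measured
trace on its own noisy first point and baseline window, which perturbs the
trace's overall scale by O(σ) in a correlated way that plain least squares
cannot represent.  A multiplicative amplitude scale per trace is therefore
profiled out in closed form during fitting (default on).  Without it,
replicate studies here showed the strongly correlated rate pairs of two-step
schemes biased beyond 3 standard errors; with it, recovery z-scores sit
within ±2.6 across replicate noise seeds.  The scales are counted in the
free-parameter number and in the covariance, and are reported.

Model discrimination uses the least-squares information criteria
AIC = n·ln(RSS/n) + 2p and BIC = n·ln(RSS/n) + p·ln n (constant terms cancel
in Δ values), with p = free rates + free observable parameters + profiled
scales; small-sample AICc is available behind a flag.  ΔAIC/ΔBIC are
relative to the best model in the comparison; models within |ΔAIC| < 2 of
the best are reported as indistinguishable rather than crowning one.  For
n > e² ≈ 7.4 points the BIC penalizes each parameter more severely than the
AIC.

## TCSPC decay fitting

Histogram counts are modelled as bg + Σ aᵢ·e^(−t/τᵢ), optionally convolved
with an instrument response (a measured IRF on the same grid, or a Gaussian
of configurable FWHM, default 0.5 ns for the pulsed-LED regime).  Without an
IRF the fit is a tail fit from the histogram peak channel; the window ends
where the smoothed counts fall to the background/single-photon level,
because empty channels carry no information and would dilute the chi-square.
The objective is the Poisson-weighted χ² = Σ(obs−model)²/max(obs, 1); the
max guard handles empty channels.  Amplitudes are constrained non-negative
and reported as percent of their sum (summing to 100), with standard errors
propagated through the normalization; lifetimes are bounded to [0.05, 50] ns
(sub-channel lifetimes are unresolvable without a measured IRF); components
are reported sorted by ascending lifetime.  Reduced χ² = χ²/(n_channels −
n_free); on purely Poisson data it sits near 1.  Lifetimes closer than 1%,
amplitudes below their standard error and lifetimes at the fit bounds are
flagged.

The component count is chosen sequentially: n+1 components are accepted over
n when the reduced χ² improves by more than 5% and every amplitude exceeds
3× its standard error; the decision trail is attached to the result.  The
amplitude-weighted mean lifetime is ⟨τ⟩ = Σ(Aᵢ/100)·τᵢ.

## Equilibrium titrations

The response fitted by default is the quench fraction (F₀−F)/F₀, which rises
with binding and reproduces the increasing modified Hill form
B_max·xʰ/(K_Dʰ+xʰ) directly; raw emission-ratio curves (F/F₀, decreasing)
are converted on the fly.  Initial guesses are B_max = max response, K_D =
concentration at half-max, h = 1.  Probe depletion is ignored exactly as the
isotherm ignores it (the 50 nM probe is not negligible against K_D ≈ 13 nM);
an exact 1:1 quadratic depletion model is available behind a flag for
sensitivity checks but is deliberately not the default, so that fitted K_D
values mean the same thing as conventionally reported apparent constants.
The Hill slope can be floated (default) or fixed per fit.  Flat responses
return an explicit no-binding failure; curves that do not bracket
half-saturation are flagged wide-SE.  Mg²⁺-dependence profiles collect
per-level K_D fits into a table, flag non-binding levels, and report the
fold change across binding levels.

## Synthetic data

The generators emulate the statistical structure the fitters assume, with
all randomness drawn from explicit seeds (no global state, bit-identical
regeneration):

* **Stopped flow** — deterministic kinetics through the observable and the
  normalization contract, then independent Gaussian noise per shot (σ is the
  per-shot noise on the normalized scale, default 0.01 — the instrument's
  gain keeps raw amplitudes comparable across a series), shot averaging
  (default 25, matching the 20–30 shots averaged per concentration in the
  reference design), then the standard preprocessing.  The reference design
  is 2 µM RNA with 4, 8, 12, 16, 20 µM ligand, 2 s windows at 200 points.
  The window and point count are deliberately modest; they cover ~5× the
  slowest observed equilibration and give fit precision comparable to the
  published uncertainties.
* **TCSPC** — expected counts from the multi-exponential model (2048
  channels of 25 ps), scaled to the requested total counts and
  Poisson-sampled per channel.
* **Titrations** — Hill responses plus Gaussian noise; reference grids are
  12 log-spaced points, 1–500 nM RNA or 0.05–10 mM Mg²⁺ (the Mg²⁺ midpoint
  0.8 mM sits between the two lowest measured levels, where the published
  data locate the folding transition).

What the generators do **not** emulate: mixing artifacts and dead-time
distortion, detector nonlinearity, TCSPC pile-up, RF pickup, drift between
shots, and heteroscedastic noise.  Passing recovery tests therefore
demonstrates the correctness and calibration of the estimators under the
assumed noise model, not robustness to instrument pathology.

A small diagnostic, `equilibration_time`, reports when a normalized trace
first stays within 5% of its plateau — the 5% band mimics the by-eye
judgement of when a displayed trace "has reached equilibrium".  Driven with
the best-model presets it reproduces the observed ordering of equilibration
at 2 ligand equivalents: the non-regulating aptamer A fastest, the
riboswitch RS intermediate, the precursor preRS slowest.

## Known limitations

* Uniform least-squares weighting throughout the stopped-flow pipeline (the
  traces are normalized; no heteroscedastic weighting).
* Standard errors are linearized (Wald); strongly correlated rate pairs in
  two-step schemes can be non-Gaussian at low information, where the printed
  uncertainty understates the tail risk.
* The Neyman form of the Poisson χ² is mildly biased for channels with very
  few counts; at the ≥1e5 total counts the fitters are designed for, the
  effect on lifetimes is well below the reported uncertainties.
* No stochastic (Gillespie) kinetics, no diffusion limitation, no
  temperature dependence, no global lifetime analysis across histograms.
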