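# aptakinetics

Kinetic and equilibrium analysis of aptamer–ligand binding, built around the
question of what distinguishes an RNA aptamer that merely *binds* its ligand
from one that can act as a synthetic riboswitch.  The package analyses the
three fluorescence experiments that answer it for ciprofloxacin (CFX)-binding
aptamers — the ligand's intrinsic fluorescence is quenched on binding, which
makes CFX its own reporter:

* **Stopped-flow kinetics** — time-resolved emission traces after rapidly
  mixing RNA with excess ligand, one trace per ligand concentration.  The
  package preprocesses (averages, baseline-corrects, normalizes) the traces,
  extracts observed rates *k*_obs by mono-exponential fitting and the
  apparent association rate *k*_on from the slope of *k*_obs vs [L], and
  fits full mass-action mechanisms globally across the whole concentration
  series, discriminating candidate mechanisms by AIC/BIC.
* **TCSPC fluorescence decays** — photon-counting histograms of the free and
  complexed ligand, fitted with 1–3 exponential components under Poisson
  weighting; complex formation shows up as a dominant sub-nanosecond quench
  lifetime τ_q.
* **Equilibrium titrations** — quench fraction vs RNA (or Mg²⁺)
  concentration at a fixed 50 nM probe, fitted with the modified Hill
  isotherm *B*_max·*x*ʰ/(*K*_D&#8203;ʰ + *x*ʰ) for the apparent dissociation
  constant and Hill slope.

## Binding mechanisms

Five mass-action schemes are built in (`model1` … `model5`), covering the
standard one- and two-step hypotheses:

| id | scheme | interpretation |
|----|--------|----------------|
| 1 | R + L ⇌ B | one-step reversible binding |
| 2 | Rᵢ ⇌ Rₐ, Rₐ + L ⇌ B | conformational selection |
| 3 | R + L → I → B | two irreversible steps |
| 4 | R + L ⇌ I ⇌ B | reversible induced fit |
| 5 | R + L ⇌ I → B | induced fit, irreversible final step |

ODE systems are derived mechanically from the schemes by mass action (units:
µM, s; bimolecular rates in µM⁻¹s⁻¹) and integrated with a stiff-capable
solver.  Global fits share the rate constants across all traces of a series,
use multi-start log-uniform initialisation, and report standard errors from
the linearized covariance at the optimum.

Because no instrument data ship with the package, a first-class synthetic
data module generates all three experiment types with the matching
statistical structure (per-shot Gaussian noise and shot averaging for
stopped flow, Poisson channel counts for TCSPC), with published rate and
lifetime sets for the three aptamer candidates (**A**, **preRS**, **RS**)
available as named presets.

## Worked example

Simulate the riboswitch (RS) stopped-flow series under the induced-fit
mechanism with an irreversible final step, then let the fits decide which
mechanism the data support:

```python
import aptakinetics as ak
from aptakinetics.io import render_rate_table

series = ak.gen_stopped_flow_preset(
    "RS-model5", noise=ak.NoiseSpec(sigma=0.005, seed=1))
fits = [ak.global_fit(m, series, ak.GlobalFitOptions(n_starts=8, seed=2))
        for m in ("model1", "model4", "model5")]
print(render_rate_table(fits, ak.compare_models(fits)))
```

```
label	scheme	k1	k-1	k2	k-2	RMSD	dAIC	dBIC
RS-model5	model1	6.95±0.03	0.00±0.05	—	—	0.003207	2144	2139
RS-model5	model4	7.60±0.01	2.64±0.08	20.7±0.5	0.0±0.1	0.001097	2	7
RS-model5	model5	7.60±0.01	2.64±0.08	20.7±0.5	—	0.001097	0	0
```

The generating mechanism wins both criteria (ΔAIC = ΔBIC = 0), the
reversible two-step alternative collapses onto it (its fitted k₋₂ hits
zero and costs one wasted parameter), and the one-step model is rejected
outright.  The recovered rates match the generating truth
(k₁ = 7.62 µM⁻¹s⁻¹, k₋₁ = 2.9 s⁻¹, k₂ = 23 s⁻¹) to within a few standard
errors — k₂ is the hardest because it rides on the fast early transient.

An equilibrium titration is one line each way:

```python
curve = ak.gen_titration(13.0, 1.0, 1.0, ak.TitrationDesign.paper_rna(),
                         ak.NoiseSpec(sigma=0.01, seed=3))
fit = ak.fit_hill(curve)
print(f"K_D = {fit.kd:.1f} ± {fit.kd_se:.1f} nM, h = {fit.h:.2f} ± {fit.h_se:.2f}")
# K_D = 13.8 ± 0.7 nM, h = 0.98 ± 0.04
```

A command-line interface wraps the same pipeline
(`aptakinetics simulate|fit-stopflow|kobs|fit-decay|fit-titration|compare|report`);
every run writes a machine-readable echo of its configuration next to the
results.

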