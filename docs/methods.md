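# Methods

## The kinetic model

`strandsep` models DNA methylation by CcrM-family methyltransferases as a
four-step mass-action mechanism

```
E + S  <=>  FS  <=>  GS^I  <=>  GSp  <=>  E + Sp
      k1/k1r    k2/k2r     k3/k3r    k4/k4r
```

E is free enzyme (the catalytically functional unit), S unmethylated duplex
DNA carrying one recognition site, FS the initial bound complex, GS^I the
strand-separated intermediate, GSp enzyme-bound methylated product, and Sp
released product. Two equilibria summarize the early steps: K1 = k1/k1r
(binding, 1/uM) and K2 = k2/k2r (stability of the strand-separated state,
dimensionless).

Assumptions baked into the model:

* **The cofactor is not a species.** All experiments the model targets are
  run at saturating SAM, so methyl-donor binding is absorbed into k3.
* **The functional unit is "E".** Oligomer assembly is not modelled. For
  multi-turnover burst analysis the caller supplies the concentration of
  active units explicitly (half the monomer concentration for an obligate
  dimer); everywhere else concentrations are used as mixed.
* **No second strand-separated intermediate.** The four-step scheme is the
  minimal model that supports all three observables.
* Units are fixed: uM, seconds, 1/s, and 1/(uM*s) for the bimolecular
  constants k1 and k4r.

Default locks mirror how such data are analysed in practice: k1 is held at
100 1/(uM*s) (binding is treated as rapid equilibrium; transient data do
not define the association rate) with k1r floating to determine K1; k3r is
held at 0 (methyl transfer irreversible); k4r at 1e-6 1/(uM*s) as a
minimal value. Product release k4 is resolvable only when chemistry is
fast (wild type); for slow-chemistry variants it is locked at the
wild-type value 1.63 1/s.

## Simulation

The ODE system is integrated with LSODA and an analytic Jacobian at
rtol = 1e-8, atol = 1e-12 uM. The stiff path matters: legitimate
parameter sets span 1e-6 to 1e2. Conservation of the enzyme and DNA
totals is monitored and holds to better than 1e-6 relative at these
tolerances (property-tested on random rate sets log-uniform in
[1e-3, 1e2]).

Burst analysis fits an ordinary least-squares line to the final 50% of a
multi-turnover product trace and reports its t = 0 intercept as the burst
amplitude. The late phase is accepted as linear only if the slope over
the last quartile agrees with the last-half slope within 1%; substrate
depletion otherwise inflates the intercept, so windows should be chosen
to keep depletion below a few percent.

## Observables and dead time

* PydC fluorescence: `a1 * (S + FS + e*GS^I + f*GSp + h*Sp)`
* Trp fluorescence: `a3 * (E + k*FS + m*GS^I + n*GSp)`
* Radiochemical product: `GSp + Sp + bkg2` (uM)

Fluorescence units are arbitrary; absolute scale lives entirely in a1/a3
and optional per-trace factors. Stopped-flow traces are blind for the
first 2.5 ms after mixing; the model is evaluated at observed time plus
dead time, so the first recorded point corresponds to that reaction age.
No inner-filter, photobleaching or instrument-response corrections are
applied.

## Synthetic data

The raw experimental traces behind the published parameter sets are not
deposited in machine-readable form, so the generator reproduces the three
designs: a Trp series (0.5 uM enzyme vs 2.5/5/7.5/10 uM DNA), a PydC
series (1.0 uM DNA vs 2.5/5/7.5/10 uM enzyme) over 2 s, and a
single-turnover methylation course (0.1 uM DNA, 0.25 uM enzyme).
Fluorescence traces use 500 log-spaced points on [0, 2] s (resolving both
the ~20 1/s and ~0.2 1/s phases); the methylation course uses 12
log-spaced points over an auto-scaled window of 5/k3. Noise is Gaussian:
homoscedastic per fluorescence trace with SD = 1% of the trace amplitude,
and 5% CV (SD proportional to signal) for the radiochemical points; three
replicates are averaged (fluorescence) or averaged with a per-point SD
column (radio). Generation is deterministic per seed, with independent
substreams per experiment class.

The coefficient truths (e = 3, f = 2, h = 1.5; k = 0.8, m = n = 0.6;
a1 = a3 = 1) are package choices giving phase amplitudes with the
qualitative shape of the real experiments (PydC rise dominated by GS^I,
Trp quench on binding); they are config-exposed and never claimed as
measured values. The generator does not emulate photophysics, membrane
or scintillation-counting statistics, baseline drift, or the true
instrument-to-instrument replicate variability — passing recovery tests
therefore demonstrate identifiability under the stated noise model, not
robustness to every real-world artifact.

## Global fitting

The fit minimizes the weighted SSR over all traces simultaneously with
trust-region-reflective least squares. Choices that matter:

* **Parameterization.** Positive parameters (rate constants, a1, a3) are
  optimized in log space, enforcing positivity without penalties; the
  per-species fluorescence factors are linear with a [0, 1e3] box. A
  linear parameterization is available and reaches the same optimum on
  clean data (tested).
* **Weighting.** Per-trace sigma is taken from the replicate SD column
  where present (radio) and otherwise estimated as the residual RMS of a
  Savitzky-Golay detrend, floored at 1e-3 of the trace amplitude. Each
  point then contributes (model - data)/sigma.
* **Finite differences.** The Jacobian step is set to 1e-4 (relative),
  well above the 1e-8 integration noise floor; the default machine-epsilon
  step produces garbage derivatives against an ODE solver and was the
  single largest practical pitfall in development.
* **Caching.** Species trajectories are cached per rate-constant vector,
  so Jacobian columns for the (linear) observable coefficients cost no
  ODE solves.
* **Seeding.** Following standard practice, exponential pre-fits seed the
  rates: the fast PydC phase approximates k2 + k2r; the radiochemical
  observed rate approximates k3 times the substrate occupancy, and is
  divided by the occupancy implied by the template binding constants.
  The coefficients are then seeded by solving their linear subproblem
  exactly at the seeded rates.
* **Multistart.** Default 8 starts: the seed itself plus starts with
  every floating rate perturbed by a random factor up to 3, coefficients
  re-seeded linearly at the perturbed rates. Seeded and reproducible.
* **Convergence.** ftol = 1e-10, xtol = 1e-12. Integration failures at a
  proposed point return a flat penalty vector so the optimizer backs away
  instead of aborting.

Per-trace fluorescence scale factors exist (bounded [0.8, 1.25]) but
default to locked at 1: with the shared output scales a1/a3 floating,
per-trace factors are an exact gauge freedom (only the products are
identified), and replicate-averaged synthetic traces carry no drift for
them to absorb. Floating them is appropriate when a1/a3 are locked, or
when fitting real concentration series with visible amplitude drift; this
mode is tested.

## Confidence intervals

One-dimensional profile likelihood: the target parameter is clamped on a
grid walking outward from the best fit (21 log-spaced points per side
spanning a factor of 4, warm-starting each re-optimization from its
neighbor), all other floats re-optimized, and the 95% bound placed where
the re-optimized SSR crosses

```
SSR_crit = SSR_min * (1 + F(0.95; 1, N-P) / (N-P))
```

the standard F-based threshold for one parameter (N points, P floats).
Crossings are refined by bisection to 0.5% of the parameter value; a side
that never crosses within the grid is flagged open. The generic profiling
core is validated against the closed-form interval of a linear regression
with known sigma, and interval coverage is checked empirically on seeded
synthetic datasets.

## Steady-state constants

With rapid-equilibrium binding, the King-Altman reduction of the scheme
gives

```
D       = k2*(k3 + k3r + k4) + k2r*(k3r + k4) + k3*k4
kcat    = k2*k3*k4 / D
Km      = [k1r*(k2r*k3r + k2r*k4 + k3*k4) + k2*k3*k4] / (k1*D)
kcat/Km = k1*k2*k3*k4 / [k1r*(k2r*k3r + k2r*k4 + k3*k4) + k2*k3*k4]
```

The k2r*(k3r + k4) grouping in D is required for internal consistency:
with it, kcat/Km equals kcat divided by Km identically when k3r = 0
(asserted at machine precision on random parameter sets). The closed
forms are additionally cross-checked against simulated initial-velocity
Michaelis-Menten curves (enzyme at 1% of the lowest substrate
concentration, velocities from the linear phase at ~2% depletion,
hyperbolic fit over 0.1-10 x Km); agreement is within 2% for every
bundled parameter set, tested at 5%.

## Problem sizes in the test suite

The acceptance-level recovery study runs one fit at the full design (500
points per fluorescence trace, seed 1) and a ten-seed study at 150 points
per trace with single-start fits and a compact k2 profile (6 points per
side spanning x1.3, bisection-refined). These sizes are the package's
chosen desk-scale study; they preserve the designs, noise model and
estimator exactly and change only sampling density and replication count
of the study itself.

## Known limitations

* The published per-parameter confidence ranges cannot be reproduced
  numerically without the original raw traces; the package matches them
  in format and validates its intervals by simulation coverage instead.
* K1 (via k1r) is informed mostly by amplitude ratios across the
  concentration series, not by a resolved binding phase (binding largely
  completes within the dead time at these concentrations); expect wider
  intervals on k1r than on k2/k2r/k3.
* k4 is identifiable only when chemistry is fast relative to release;
  fits of slow-chemistry variants should lock it.
* Equilibrium DNA-binding (anisotropy-style) measurements are out of
  scope and cannot be folded into the global fit.
* Single-turnover "observed rates" are occupancy-scaled: at 0.25 uM
  enzyme the effective binding is sub-saturating, so the apparent product
  formation rate sits well below k3. The pre-fit seeding corrects for
  this explicitly.
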