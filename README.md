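# strandsep

Global transient-kinetic analysis of enzymatic DNA strand separation.

CcrM-family DNA N6-adenine methyltransferases (recognition site
5'GANTC3') methylate their target by locally melting the duplex: the
enzyme binds DNA, separates the strands around the recognition site,
transfers a methyl group from SAM, and releases product. `strandsep`
is for enzymologists who measure this chemistry by stopped-flow
fluorescence and radiochemical single-turnover assays and want to turn
those traces into microscopic rate constants. It implements the full
pipeline: simulation of the four-step mass-action scheme

```
E + S  <=>  FS  <=>  GS^I  <=>  GSp  <=>  E + Sp
      k1/k1r    k2/k2r     k3/k3r    k4/k4r
```

observable models for tryptophan fluorescence (enzyme conformation,
`a3*(E + k*FS + m*GS^I + n*GSp)`), pyrrolocytosine fluorescence (strand
separation, `a1*(S + FS + e*GS^I + f*GSp + h*Sp)`) and radiochemical
product (`GSp + Sp + bkg2`), with the 2.5 ms stopped-flow dead-time
convention; simultaneous weighted least-squares fitting of all
experiments with locked/floating parameters; profile-likelihood 95%
intervals; steady-state constants (kcat, Km, kcat/Km) in closed form
from the microscopic rates; a seeded synthetic-data generator matching
the published experimental designs; and a small CLI
(`strandsep synth|prefit|fit|profile|steadystate|report`).

See `docs/methods.md` for the model, its assumptions, and every
numerical choice.

## Worked example

Fit a synthetic wild-type dataset (three experiment classes, nine
traces) and derive everything downstream:

```python
import strandsep as ss

wt = ss.reference_rate_constants("WT")
p = ss.steady_state_params(wt)
# kcat = 0.147 1/s, Km = 1.1 uM, kcat/Km = 0.133 1/(uM s)

ds = ss.generate_full_dataset(ss.SyntheticConfig(rates="WT", seed=1))
template = wt.replace(k1r=300.0, k2=10.0, k2r=5.0, k3=0.1, k4=1.0)
guess = ss.initial_rate_guess(ds.traces, template)          # exponential pre-fits
model = ss.GlobalKineticModel(ds.traces, guess,
                              ss.linear_coefficient_seed(ds.traces, guess))
res = model.fit(multistart=2, seed=1)
print(res.summary())
prof = res.profile("k2")
print(ss.ci_table([prof]).loc[0, "formatted"])
```

prints (abridged):

```
Global kinetic fit
================================================
traces: 9   points: 4012   floating: 13
weighted SSR: 4201.4   unweighted SSR: 0.0907995
------------------------------------------------
rate constants (1/s; k1, k4r in 1/(uM*s)):
  k1   = 100          [locked]
  k1r  = 525.278      [fitted]
  k2   = 23.1211      [fitted]
  k2r  = 6.72601      [fitted]
  k3   = 0.212144     [fitted]
  k3r  = 0            [locked]
  k4   = 1.6378       [fitted]
  k4r  = 1e-06        [locked]
  K1 = 0.1904 1/uM   K2 = 3.438
...
23.1 (22.9–23.3)
```

The dataset was generated from k2 = 23.2, k2r = 6.7, k3 = 0.21 and
k4 = 1.63 with 1% fluorescence / 5% radiochemical noise: the global fit
recovers each floating rate constant to better than 1%, and the
profile-likelihood interval for the strand-separation rate k2 brackets
the generating value. The weighted SSR (~4200 for 4012 points) sits at
the value expected when residuals match the noise model. From the fitted
constants, `res.steady_state()` gives the turnover parameters and
`ss.equilibrium_constants(res.rates)["K2"]` the stability of the
strand-separated intermediate (3.44 here; a destabilized variant drops
well below 1).

The same pipeline from the shell:

```sh
strandsep synth --fixture WT --seed 1 --out data/
strandsep fit --config fit.yaml --out result.json
strandsep profile --config fit.yaml --fit result.json --param k2 --out k2.csv
```

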