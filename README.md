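# cdgsensor

Quantitative analysis for genetically encoded c-di-GMP biosensors of the
cdGreen/cdGreen2 family — circularly permuted GFP sensors whose fluorescence
reports binding of the bacterial second messenger bis-(3′-5′)-cyclic dimeric
GMP. The package is aimed at biochemists and microbiologists who calibrate
such sensors in vitro, use them to assay c-di-GMP-metabolizing enzymes, or
track c-di-GMP in single dividing cells.

It implements, as a tested library:

- **Equilibrium calibration** — the four-parameter variable-slope isotherm
  `S(c) = Bottom + (Top − Bottom)/(1 + (K_d/c)^h)` with a signed Hill slope
  (rising 497-nm and falling 405-nm excitation channels), per-channel and
  ratiometric fits with asymptotic 95% CIs, fold-change (dynamic range)
  estimation, and two-segment breakpoint fits of stoichiometric titrations.
- **Binding kinetics** — one-phase exponential dissociation-by-dilution fits
  (`t_{1/2} = ln 2 / k_off`), global pseudo-first-order association fits with
  `k_obs(L) = k_on L + k_off` and shared amplitude, and the rate-constant
  arithmetic `k_on = k_off / K_d`.
- **Stepwise four-site ITC model** — the ladder
  `P ⇌ P·L ⇌ P·L₂ ⇌ P·L₃ ⇌ P·L₄` as two classes of two equivalent sites with
  statistical-factor constraints `K₂ = K₁/4`, `K₄ = K₃/4`, `ΔH₂ = ΔH₁`,
  `ΔH₄ = ΔH₃`: binding-polynomial speciation, exact free-ligand mass
  balance, displacement-corrected thermogram simulation, nonlinear fitting
  with a protein-concentration correction factor, jackknife standard errors,
  and microscopic site constants `K_D = 1/(0.5 K_macro)`.
- **Sensor-coupled enzyme assays** — saturated-control plate normalization,
  shared-asymptote 4PL-in-time progression fits, and the specific-activity
  formulas `K_d/(EC₅₀·[DGC])` (diguanylate cyclases) and
  `([cdG]₀ − K_d)/(EC₅₀·[PDE])` (phosphodiesterases), plus hyperbolic GTP
  dose-response fits for GTP-activated enzymes.
- **Lineage quality control** — sister-cell pairing and trimming, the three
  exclusion filters (minimum track length; frame-to-frame length jumps;
  division length consistency) with species presets, high/low c-di-GMP
  classification by lifetime-mean intensity, and minimum-anchored trace
  overlays.
- **Seeded synthetic data** for every input above, so every stage is
  testable end-to-end without instrument data.

## Worked example

`examples/dose_response_calibration.py` generates a 12-point c-di-GMP
titration of the fast-off sensor variant with 2% multiplicative noise and
fits the isotherm:

```
fitted Kd    : 1.269 µM  (95% CI 1.239-1.301 µM)
Hill slope   : 1.82
fold change  : 8.3
residual sd  : 0.0120 (relative units)
```

The K_d is the ligand concentration at half-maximal fluorescence, the Hill
slope reflects the cooperative assembly of the intercalated c-di-GMP dimer,
and the fold change is the sensor's usable dynamic range in that channel.
The other scripts in `examples/` walk through the kinetics
(`binding_kinetics.py`), the ITC model (`itc_four_site.py`), the enzyme
assay pipeline (`enzyme_activity.py`) and lineage screening
(`lineage_qc.py`) the same way; each prints the quantities it computes and a
one-line interpretation.

CSV/YAML ingestion for all table dialects (dose-response, kinetic traces,
thermograms + protocols, plates, track tables) lives in `cdgsensor.io`.

## Layout

```
src/cdgsensor/    isotherm, kinetics, itc, assay, lineage, simulate, io
examples/         one narrative script per capability
tests/            unit, property and end-to-end recovery tests
docs/methods.md   models, assumptions, numerical choices, limitations
```
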