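# Methods

This note documents the models implemented in `cdgsensor`, their
assumptions, the defaults of the synthetic-data generators, and the
numerical choices that matter when reproducing or extending the analyses.

## Equilibrium isotherm (module `isotherm`)

The sensor readout at one excitation wavelength is modeled as a
four-parameter logistic in ligand concentration `c`:

    S(c) = bottom + (top − bottom) / (1 + (kd/c)^hill)

A single *signed* Hill slope covers both channel polarities: the 497-nm
channel rises with c-di-GMP (`hill > 0`), the 405-nm channel falls
(`hill < 0`). Two identities are used repeatedly as internal checks:
`S(kd) = (top + bottom)/2` for any slope, and the zero-concentration value is
the analytic limit (`bottom` for positive slopes, `top` for negative) — zero
doses are never log-transformed away or dropped. The parameterization is
degenerate under `(bottom, top, hill) → (top, bottom, −hill)`; fits are
canonicalized to `top ≥ bottom` so the slope sign always carries the
direction.

Fitting is weighted least squares with relative (1/|signal|) weights by
default, matching the multiplicative noise of fluorescence plate readers;
`weights="none"` gives ordinary least squares. Initialization is a
deterministic multi-start: five log-spaced `kd` seeds across the measured
concentration range crossed with slope seeds {−3, −1, 1, 3}. Confidence
intervals are asymptotic (Jacobian-based, t-distribution); `kd` is fitted as
`log10(kd)` and its CI is transformed back, so it is asymmetric and always
positive. Repeated measurements of a well are treated as replicates, not
averaged, so they contribute to the residual degrees of freedom. The
ratiometric channel is constructed as the per-concentration mean of the
497-nm signal divided by the mean of the 405-nm signal *before* fitting;
dividing noisy singletons and then averaging is noticeably less stable.

Stoichiometric titrations (sensor far above `kd`, signal linear in bound
ligand until the sites fill) are fitted with a continuous two-segment linear
model; the hinge is profiled on a 256-point grid and polished with a bounded
scalar minimization, and the model must beat a single line in an F-test at
α = 0.05 or a no-breakpoint error is raised.

## Binding kinetics (module `kinetics`)

Dissociation by dilution follows `S(t) = span·exp(−k_off t) + plateau`. The
plateau is fitted, not fixed: dilution leaves a small residual occupancy and
instrument offset that a fixed zero plateau would fold into `k_off`. The
half-life is defined as `ln 2 / k_off`, never fitted separately. Relative
weighting is the default here too; with 1% multiplicative noise it keeps the
asymptotic 95% CI near nominal coverage (the suite checks ≥ 90/100
replicates cover the true rate). A matched protein-only baseline trace can
be subtracted pointwise (linear interpolation onto the sample grid) to
remove the transient dilution artifact seen with some sensor preparations.

Association under pseudo-first-order conditions (ligand ≫ sensor) is fitted
globally across ligand concentrations with shared `k_on`, `k_off` and
amplitude:

    S(t; L) = s_max · L/(L + k_off/k_on) · (1 − exp(−(k_on L + k_off) t))

The occupancy plateau deliberately uses the single-step form (Hill slope 1)
even though the *equilibrium* readout has a Hill slope near 2: the kinetic
scheme fitted here is a single bimolecular step, and the cooperative shape
of the equilibrium curve is a property of the readout, not of the relaxation
rate. The kinetic `Kd = k_off/k_on` is a derived quantity. A single ligand
concentration cannot separate `k_on` from `k_off`; in that case only
`k_obs` is returned, with a warning. The ~10 s dilution/mixing dead time of
the plate assay is not modeled (traces are assumed to start at the first
reading); at the rates involved this shifts amplitudes, not rates.

## Four-site ITC model (module `itc`)

Binding of c-di-GMP to the sensor is described by the stepwise ladder
`P ⇌ P·L ⇌ P·L₂ ⇌ P·L₃ ⇌ P·L₄`, organised as two classes of two equivalent
sites. Free parameters are the first macroscopic association constant and
enthalpy of each class (`K1`, `K3`, `dH1`, `dH3`) plus a multiplicative
protein-concentration correction `f`; the statistical factors for two
equivalent sites fix `K2 = K1/4`, `K4 = K3/4`, and the within-class
enthalpies are shared. Microscopic (site) constants follow from
`K_micro = K_macro/2`. Note that the stepwise ladder with these constraints
is exactly the two-equivalent-site polynomial `(1 + sx)²` per class
(`s = K1/2`) and factorizes into two independent pairs only when the classes
are well separated (`K1 ≫ K3`); it is *not* algebraically identical to a
four-equivalent-site model when `K1 = K3`. The tests therefore check the
exact pair reduction (second class negligible) and the single-phase collapse
of the thermogram when the classes coincide.

Speciation uses the binding polynomial `Z(x) = 1 + Σ β_i x^i`
(`β_i = Π_{j≤i} K_j`); free ligand is recovered from the scalar mass balance
`L_tot = x + P_tot·n̄(x)`, which is strictly monotone, by a bracketed root
solve on `[0, L_tot]` to relative tolerance ~1e−12 (scipy's Brent method; a
property test checks mass conservation to 1e−8 relative against an
independent polynomial-root solution).

Thermogram simulation uses exact stepwise displacement dilution — each
injection of `dV` into the cell of volume `V0` scales existing totals by
`1 − dV/V0` and adds `dV·c_syr/V0` of ligand — and the standard trapezoidal
displacement correction
`q_i = Q_i − Q_{i−1} + (dV_i/V0)(Q_i + Q_{i−1})/2`, normalized per mole of
injectant. The cell volume defaults to the nominal 200 µl of an iTC200-class
instrument and is configurable. The first small (0.4 µl) priming injection
is included by default; `exclude_first=True` drops it, matching the common
practice of discarding it.

Fitting operates on per-mole-of-injectant normalized heats (raw-µcal input
is converted through the protocol by `cdgsensor.io`), with the ligand-into-
buffer blank subtracted injection-by-injection when provided. The `K`s are
fitted on a log10 scale from a small deterministic multi-start. Jackknife
standard errors come from leave-one-injection-out refits (started from the
full-fit solution) and the standard `(n−1)/n` variance formula, computed in
the fitted log-`K` parameterization: at the high c-values of the
high-affinity class, leaving out the single transition injection can leave
`K1` bounded only from below, and the log scale keeps such replicates from
producing meaningless linear SEs (linear-scale SEs are also reported via the
delta method). This weak per-experiment identifiability of `K1` is real:
recovery of `K1` is therefore assessed on the median across simulated
experiments, while `dH1`, `dH3`, `K3` and `f` are well determined per
experiment.

## Enzyme assays (module `assay`)

The forward model shared with the generator is zero-order turnover at the
enzyme's specific rate `ρ = rate·[E]` (µM/s): diguanylate cyclases produce
c-di-GMP up to `[GTP]₀/2` (two GTP per c-di-GMP), phosphodiesterases degrade
it to zero. The sensor (present at ~0.3 µM) is treated as an instantaneous
equilibrium reporter: its relaxation (`k_off ≈ 0.5 min⁻¹`) is fast against
hour-scale progression curves, and the ≤ 0.6 µM of ligand it sequesters is
negligible against the 12–250 µM substrate pools. Under this model the
normalized signal is the sensor isotherm evaluated along `cdG(t)`, so the
half-maximal time falls exactly where `cdG` crosses the sensor `K_d`
(midpoint identity, any Hill slope), which makes the activity formulas

    DGC: a = K_d/(EC50·[DGC])      PDE: a = ([cdG]₀ − K_d)/(EC50·[PDE])

exact for linear turnover; the suite asserts recovery of the true rate
within a 2% fit-model tolerance on noiseless simulations. The PDE formula is
undefined when the starting substrate does not exceed the sensor `K_d`; that
is rejected as an invalid design rather than returning a negative rate.

Plate normalization divides every well by the time-averaged mean of the
saturating-c-di-GMP control wells; it is gain-invariant and idempotent.
Progression curves are fitted with the same signed-slope 4PL reparameterized
in time, with *all* parameters shared across replicate curves ("shared value
for all data sets"); the curve direction (rising DGC / falling PDE) is
auto-detected and overridable. A fitted EC50 outside the observation window
raises a censored-EC50 error carrying the usable bound instead of reporting
an extrapolated number. GTP activation is summarized by fitting specific
activity against GTP with `v = v_max·G/(K + G)`; fitting 1/EC50 instead
gives the same `K` up to scale and is supported by passing those values.
The 405-nm channel of the assay can be ingested but is unused by default —
the activity formulas are defined on the 497-nm channel.

## Lineage screening (module `lineage`)

Sister pairing uses the parent links of the tracking output; each parent's
two children are trimmed to the shorter sister's frame count (frames are
kept verbatim, never interpolated), and the mother's length "just before
division" is her last recorded frame. Three filters then exclude unreliable
pairs: (i) trimmed length below a species minimum (12 frames for
*C. crescentus* at 5-min framing, 8 for *P. aeruginosa*); (ii) any
frame-to-frame relative length change — denominator: the earlier frame —
below −8% or above +8% (*C. crescentus*) / +12% (*P. aeruginosa*); (iii)
summed sister birth lengths deviating from the mother's final length by
< −6% or > +20%. The minimum-frames rule is evaluated on the *trimmed* pair.
Rejected pairs carry every violated rule, so filtering is idempotent,
order-independent and monotone in the thresholds. Classification labels the
sister with the greater lifetime-mean FITC intensity c-di-GMP-high; exact
ties break lexicographically by cell id with a warning. Intensities are
assumed background-corrected upstream. Overlay alignment anchors each track
at its intensity minimum (earliest frame on ties) and summarizes across
tracks with a per-time-point t-distribution confidence band (95% default).

## Synthetic data (module `simulate`)

All generators are pure functions of (specification, seed) and their
zero-noise output satisfies the corresponding forward model to machine
precision. Defaults encode the study designs used throughout the tests:
12-point log-spaced dose grids with 2 replicates and 2% multiplicative
Gaussian noise; dissociation traces sampled every 10 s for 20 min at 1%
noise; the 1 × 0.4 µl + 19 × 1.8 µl / 25 µM / 1000 µM ITC protocol with
additive per-injection noise of sd 0.15 kcal/mol (the plausible instrument
scale; the recovery tests sweep it) and a −0.10 kcal/mol constant dilution
heat in sample and blank; 16-h plate courses sampled every minute at 2%
noise. The PDE used for the GTP dose series runs at 2.4 × 10⁻³ s⁻¹ at
saturating GTP — chosen once so that all eight EC50s across the 0.5–50 µM
dose range fall well inside the 16-h window.

Lineages are full binary trees: exponential length growth doubling over one
interdivision time (default 75 min, 5-min frames), Beta-distributed division
splits around 0.5 (concentration 200), and an asymmetric intensity program —
one random daughter per division dips from 1000 to 300 arbitrary units for a
20-min trough with ~2-min logistic edges (the trough shape is a modeling
choice; only its depth and duration are meaningful). Injected tracking
errors are single-frame multiplicative length glitches of 15–25% at a
per-frame probability, sized to always trip the jump filter so that
retention has a closed-form expectation used in the tests.

What the generators do *not* emulate: pixel-level imaging, photobleaching
and phototoxicity, sensor maturation, autofluorescence background,
instrument drift, or non-zero-order enzyme kinetics (for PDEs in particular,
pseudo-first-order conditions are genuinely not met near substrate
exhaustion — the zero-order window around the sensor transition is what the
activity formulas rely on). Passing recovery tests therefore demonstrate
correctness of the estimators under the stated noise models, not robustness
to every artifact of real instruments.

## Problem sizes and determinism

The recovery studies use 50 replicate datasets for dose-response and
dissociation, 30 simulated titrations for ITC, and 8-dose plates for the
GTP pipeline — enough for stable medians while keeping the whole suite and
the acceptance script in the minutes range on one core. All randomness
flows through explicit integer seeds; `scripts/acceptance.py` derives
per-replicate seeds from its `--seed` argument, so runs are exactly
reproducible.
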