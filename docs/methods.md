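# Methods

## Scope and model

`pfmfa` implements steady-state ¹³C metabolic flux analysis (¹³C-MFA) for
*Pseudomonas fluorescens* SBW25 growing on fructose in nitrogen-limited
chemostats (dilution rate 0.04 h⁻¹), comparing the wild type against an
alginate-non-producing *mucA⁻* Δ*algC* double knockout.  The pipeline is:
atom-mapped network model → steady-state labelling simulation (EMU) →
synthetic or supplied mass-isotopomer data → weighted least-squares flux
estimation with multistart globalisation → derived physiology (branch
ratios, cofactor balances) and tracer-mixture design.

The packaged network (`data/pfluorescens_sbw25.txt`) is a deliberately
reduced reconstruction: 25 balanced pools, 34 reactions (13 reversible),
covering fructose uptake through F1P, the Embden–Meyerhof–Parnas route with
gluconeogenic fructose-1,6-bisphosphatase only (*Pseudomonas* lacks
phosphofructokinase), the Entner–Doudoroff pathway, the oxidative and
non-oxidative pentose phosphate pathway, the TCA cycle with glyoxylate
shunt, and the anaplerotic set (PEP carboxylase, PEP carboxykinase, malic
enzyme, pyruvate carboxylase).  Lumping choices: one 23PG pool for the
phosphoglycerates; glyceraldehyde → glycerate → 2-phosphoglycerate as a
single entry step; citrate+isocitrate as one pool; KDPG folded into the ED
dehydratase/aldolase step.  Succinate and fumarate are symmetric molecules;
every producing direction carries two equally weighted atom maps, which is
the standard treatment of rotational symmetry.  CO₂ is a balanced, labelled
pool (so carboxylation reintroduces label) drained by a single efflux.
Fructose uptake is modelled as a carbon-only entry into F1P; the PEP
consumption of the PTS is accounted only in the cofactor map.  The full
published model for this organism is roughly 3–4× larger; the manifest
records both sets of counts.

The biomass drain pulls 11 precursors (G6P, F6P, R5P, E4P, GAP, 23PG, PEP,
PYR, AcCoA, OAA, AKG) with fixed coefficients scaled so that total biomass
carbon is exactly 35 mmolC/gDW, making μ = 0.04 h⁻¹ correspond to
1.4 mmolC/(gDW h) of biomass carbon.  The exact published precursor vector
is not available; the packaged coefficients are a conventional
proteobacterial composition and are editable in the model file.

## Flux parametrisation

Net fluxes live on the null space of the stoichiometric matrix over
balanced pools (dimension 9 for the packaged model).  The free net fluxes
are chosen by a preference list (uptake, growth, F1P-aldolase routing,
FBPase, oxidative PPP, glyoxylate shunt, malic enzyme, pyruvate
carboxylase, PEP carboxylase) so that the estimated parameters are
field-meaningful quantities; the dependent fluxes follow linearly and the
steady-state residual is zero by construction (checked to 1e-9).
Reversible reactions carry an exchange flux v_xch ≥ 0 with unidirectional
rates fwd = max(v,0)+v_xch, bwd = max(−v,0)+v_xch.  Free exchange
parameters x ∈ [0, 1) map to v_xch = x/(1−x) mmol/(gDW h) — a bounded,
scale-free transform.  Six reversible reactions (pgi, fba, tpi, gapd, mdh,
fum) carry free exchange fluxes; the remaining reversible steps are held at
zero exchange.  This is fewer than the published model's 15 exchange
degrees of freedom, consistent with the reduced network.

## Labelling simulation

The simulator decomposes the network into elementary metabolite units
(EMUs): for each measured fragment it traces carbon subsets backwards
through the atom maps, producing per-size linear balance systems with
convolution inputs where condensation reactions join fragments from two
molecules.  Systems are solved dense size-by-size (247 EMUs for the default
panel; ~1 ms per simulation).  Pools with zero influx at a given flux state
(e.g. the glyoxylate shunt in the wild type) have zero consumption at
steady state, so they decouple and are held unlabelled instead of making
the balance singular.  Negative fractions beyond −1e-9 raise; smaller ones
are clipped and the MID renormalised.

A brute-force oracle (`isotopomer.py`) solves the complete isotopomer
balance system (all 2ⁿ binary labelling patterns per pool) by Gauss–Seidel
fixed-point iteration to 1e-13, guarded to ≤ 22 total balanced carbons.  It
shares no code path with the EMU cascade and is used in the tests to verify
the cascade to 1e-9 on chain, diamond and condensation toys.  Joint
precursor/fragment (tandem MS) mass distributions are available from the
oracle path only; the estimation pipeline consumes marginal fragment MIDs.

Substrate mixtures are positional-isotopomer compositions with per-lot
enrichment (99% for 1-¹³C lots, 99.5% for U-¹³C).  Natural ¹³C abundance
(1.07%) can be switched on for carbon-backbone atoms; measurements are
treated as backbone MIDs already corrected for derivatisation and adduct
atoms, which keeps that correction explicitly out of scope.

## Measurement model

The default panel emulates the study's coverage: 8 LC-MS/MS compounds
(sugar phosphates and organic acids, full backbones) and 14 GC-MS/MS
compounds (soluble free amino acids read through their biosynthetic
precursor pools — Ala from PYR, Asp/Thr/Asn from OAA, Glu/Gln/Pro from AKG,
Ser/Gly from 23PG — plus organic acids), with three positional fragments,
130 mass-isotopomer fractions in total.  The true compound and MRM lists of
the study are not public, so the panel is an explicit stand-in chosen from
pools the network names.  Relative standard deviations per instrument and
condition follow the study: LC 13/10/8% and GC 10/12/15% for
pre-experiment/wild-type/mutant, 2 biological replicates for the
pre-experiment LC samples and 3 otherwise.

Per-fraction standard deviations are RSD × replicate mean, floored at an
absolute 0.01 on the fraction scale (the floor represents noise near the
detection limit; a relative floor is available as a toggle).  Replicate
noise is multiplicative Gaussian, clipped at zero and renormalised; an
additive-Gaussian mode without renormalisation exists for statistical
calibration studies where the assumed diagonal covariance must hold
exactly.  A single-pass exclusion rule drops fractions with replicate-mean
abundance < 0.01 *and* |standardised residual| > 5 against the current best
fit, logs both numbers, and triggers one re-fit; the thresholds are
configurable because the original study states the rule qualitatively only.

## Flux estimation

The objective is the weighted SSR over included MID fractions plus the four
extracellular rates (fructose uptake and biomass production in mmolC/(gDW h),
CO₂ excretion in mmol/(gDW h), growth rate in 1/h), each at its stated STD.
Rates are soft constraints: the study's own estimated rates differ slightly
from the measured ones, which this treatment reproduces.  Optimisation is
bounded trust-region least squares (finite-difference Jacobians) from
multiple starts: one rate-consistent heuristic start plus uniform draws in
the parameter box (net fluxes within [0, 2.5×uptake] on the hexose scale,
exchange parameters in [0, 0.99]), a coarse pass per start, tight polish of
the three best basins, then the exclusion pass and a final re-fit.  All
per-start SSRs are recorded to expose multimodality.  Dependent
irreversible fluxes are kept non-negative by hinge penalty residuals
(weight 1e3), inactive at any feasible optimum.  Fits are bit-reproducible
given (seed, n_starts).

Statistics: χ² = best SSR against the central 95% band of χ²(dof).  Note
that the CLE fits weight the replicate *mean* by the replicate-level STD
(as the measurement covariance is defined), not by its standard error, so
their χ² sits conservatively below dof — roughly dof/3 at three
replicates; the calibration study in the test suite uses single-replicate,
additive-Gaussian data where χ²/dof ≈ 1 holds exactly.
linearised parameter covariance from the pseudo-inverse of the whitened
normal matrix with a relative eigenvalue cutoff of 1e-10 — directions below
the cutoff are flagged non-identifiable and reported as unbounded rather
than numeric.  Intervals are propagated linearly to every net and exchange
flux and truncated at feasibility bounds, which yields asymmetric intervals
like [0, u] for fluxes estimated at a bound (the wild type's glyoxylate
flux).  For interval reporting a configurable set of exchange fluxes
(default: the estimated-magnitude upper half) is constrained at its point
estimate, mirroring standard practice when exchange directions are weakly
informed.  Monte-Carlo intervals (parametric resampling around the best-fit
simulation, refit per draw) are available and agree with the linearised
widths within 20% on the two-parameter toy problem.

## Reference flux maps and synthetic data

The packaged wild-type and mutant reference maps anchor the printed
hallmark values — wild type: uptake 11.8 mmolC/(gDW h), 6PGN split 61/39
EDP/PPP with PPP 1.18, ICIT influx 3.10, glyoxylate flux 0, MAL→PYR 0.84;
mutant: uptake 7.34, split 29/71 with PPP 1.60, ICIT influx 1.51,
glyoxylate 0.33, MAL→PYR 0.20 — by heavily weighted least squares on the
free-flux coordinates, with weak routing preferences closing the remaining
degrees of freedom and an active-set loop keeping irreversible fluxes
non-negative.  Hallmark anchors are met to better than 1e-4.

One structural property deserves note: with the hallmark fluxes fixed, the
network forces CO₂ output (and hence the biomass rate) as a linear
combination of uptake, PPP and TCA fluxes.  The measured rate set is about
0.13 mmolC/(gDW h) away from that constraint, so the reference maps land at
biomass 1.38 (wild type) and 1.27 (mutant) mmolC/(gDW h) instead of the
measured 1.4 — within 0.05 of the study's own model-estimated rates
(1.34 and 1.30), i.e. the reduced network reproduces the study's
measured-vs-estimated slack rather than hiding it.  Noise-free datasets
therefore carry the map-consistent rates (so that exact recovery is well
posed); noisy datasets draw the rates once per experiment around the
measured table values at their printed STDs.

Synthetic experiments simulate the panel on a reference map with a given
mixture (default: the administered 60.08% 1-¹³C / 39.92% U-¹³C blend; the
pre-experiment scenario uses 60.04/20.31/19.65 with its own RSDs), apply
replicate noise, and are reproducible by seed.  `noise_scale` multiplies
both the injected noise and the declared RSDs, so downstream covariances
stay coherent; the generator's defaults are the study conditions and are
not tuning knobs.

What the generator does *not* emulate: chromatographic peak quality,
derivatisation-atom corrections, instrument drift, replicate correlation,
and any mismatch between the panel stand-in and the study's true compound
list.  Passing recovery tests therefore show that the estimator is correct
and well calibrated *under the stated noise model on this network*, not
that the original experimental data would yield identical uncertainties.

### Recovery precision

With rates drawn at the printed STDs, the absolute scale of the flux map is
informed only by the rate block (labelling is scale-free), giving a
scale uncertainty of ~4–5%.  The recovered ICIT influx consequently
scatters with σ ≈ 0.08 (mutant) and ≈ 0.13 (wild type) — essentially equal
to the study's printed ±0.09/±0.17, which are themselves 1σ statistics of
the same structure.  Hallmark quantities with wider printed bands
(glyoxylate ±0.16, PPP ±0.3, pyruvate shunt ±0.27, EDP split ±8%) are
recovered inside their bands in ≥90% of seeded repetitions; a "within ±1σ
in ≥90% of repetitions" requirement is statistically unattainable for the
two ICIT-influx bands under these conditions (it would demand σ ≲ band/1.6),
and the corresponding checks are expected to sit at ~70–85%.

## Mixture design

The Fisher information of a candidate mixture at a reference flux state is
J'Σ⁻¹J with J the finite-difference sensitivity of the whitened residuals
to the free parameters.  The default criterion is D-optimality (log-det) on
the identifiable subspace (relative eigenvalue cutoff 1e-10); A-optimality
is available.  `design_mixture` scans the candidate simplex (1-¹³C, U-¹³C,
unlabelled fructose; default grid 0.02) and exports the full landscape.
Design is local at the supplied reference map (the wild-type map stands in
for a pre-experiment fit).  The administered 60.08/39.92 blend scores above
pure 1-¹³C on the packaged wild-type reference; the exact published optimum
depends on the unavailable pre-experiment fit and is not a target, although
the packaged scan (`analysis/04_design_mixture.py`, grid 0.05) does select
60% 1-¹³C / 40% U-¹³C / 0% unlabelled on this reference map.

## Physiology

Carbon balance (CO₂ = uptake − biomass − alginate, carbon-mole units),
biomass yield (100 × biomass/uptake, reported rounded with full precision
retained), branch-point effluxes as percentages of node influx (summing to
100 at any steady-state node), adenylate energy charge
(ATP + ADP/2)/(ATP+ADP+AMP), and a change map classifying mutant/wild-type
ratios as increased (> 1.5, strict), decreased (< 0.5) or unchanged, with
zero denominators flagged.  The cofactor map (`data/cofactor_map.yaml`)
uses textbook assignments: NADPH from glucose-6-phosphate dehydrogenase,
6-phosphogluconate dehydrogenase, isocitrate dehydrogenase and malic
enzyme; NADH from lower glycolysis, pyruvate dehydrogenase, 2-oxoglutarate
dehydrogenase and malate dehydrogenase (FADH₂ of succinate dehydrogenase is
not counted as NADH); substrate-level ATP only, with uptake/fructokinase,
pyruvate carboxylase and PEP carboxykinase as consumers.  The exact map
behind the published cofactor figure is not available; this one is
documented and editable.

## Numerical choices and limitations

* Steady state enforced to 1e-9; MID sums to 1e-9; EMU-vs-oracle agreement
  to 1e-9; optimiser tolerances 1e-9 coarse / 1e-12 polish.
* Problem sizes in tests and drivers (3 multistarts per recovery fit, 25
  seeded repetitions, 200 calibration fits, grid step 0.05 in the design
  driver) are the package's default desk-scale settings; the estimation
  code accepts larger values unchanged (the acceptance driver uses 100
  starts).
* The reduced network cannot represent degradation effluxes or minor
  biomass components of the full published model; absolute agreement with
  the published flux maps is therefore expected only at the hallmark-flux
  level, which is what the synthetic-recovery suite checks.
* Non-stationary (isotopically transient) MFA, ¹⁵N/¹⁸O isotopes, P/O-ratio
  or oxidative-phosphorylation modelling, and thermodynamic constraints are
  out of scope.
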