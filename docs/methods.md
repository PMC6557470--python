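# Methods

`lactoflux` implements steady-state ¹³C metabolic flux analysis (¹³C-MFA) for
proliferating breast cell lines grown under control and high extracellular
lactate conditions, together with a synthetic-data generator that emulates the
underlying study design so the full pipeline can be exercised and validated
without access to raw instrument data.

## Model and assumptions

Cells are assumed to be in metabolic and isotopic steady state during the
24–48 h window after a media exchange: fluxes `v` satisfy `S v = 0` over all
balanced intracellular metabolites, and intracellular mass isotopomer
distributions (MIDs) are time-invariant. CO₂ is an unbalanced, unlabeled pool
(no labeled-CO₂ refixation); oxygen and cofactor (NADH/NADPH/ATP) balances are
excluded. Only citrate and acetyl-CoA are compartmented (mitochondrial vs
cytosolic); all other pools are lumped.

The default network (`network.default_breast_network`, 38 reactions) covers
glycolysis, the oxidative and non-oxidative pentose phosphate pathway, the TCA
cycle with reversible isocitrate dehydrogenase (IDH), pyruvate carboxylase and
malic enzyme anaplerosis/cataplerosis, glutaminolysis, alanine and aspartate
transaminases, the citrate shuttle with ATP-citrate lyase, fatty-acid
synthesis from cytosolic acetyl-CoA, lumped essential-amino-acid uptake, and
two biomass drains. A dilution-exchange reaction (v38) mixes intracellular and
extracellular lactate without net carbon transfer. Atom maps use
reaction-local lowercase letters; rotationally symmetric molecules (succinate,
fumarate) carry two equally weighted map variants. Amino acids whose carbon
cannot reach any measured fragment are lumped without atom maps — a standard
model reduction.

## Extracellular rates

For exponential growth `X(t) = X₂₄·e^{μ(t−24)}` the biomass-specific rate of a
metabolite measured at 24 h and 48 h after media exchange is

    q = 10⁹ · μ (C₄₈ − C₂₄) / (X₂₄ (e^{μt} − 1)),   t = 24 h,

in nmol/10⁶ cells·h (negative = consumption). The μ→0 limit is handled
explicitly. Glutamine additionally degrades chemically at k = 0.0019 h⁻¹; the
cellular rate is the exact solution of `dC/dt = −kC − qX(t)/10⁹`:

    q_gln = 10⁹ (μ+k) (C₄₈ − C₂₄ e^{−kt}) / (X₂₄ (e^{μt} − e^{−kt})),

which reduces to the plain expression at k = 0 and is verified against
numerical ODE integration in the tests. Rate standard deviations are
propagated by Monte-Carlo simulation (default 10⁶ iterations) over independent
Gaussian draws of μ, (C₄₈−C₂₄), and X₂₄, with μ and X₂₄ truncated positive by
resampling. The concentration difference is treated as a single Gaussian
variable with SD = √(SE₂₄² + SE₄₈²).

Because replicate counts are small (3–6), per-group SD estimates are
heavy-tailed. The pipeline therefore assumes proportional measurement noise
and estimates one coefficient of variation pooled over all concentration
replicate groups (≈ 40–70 degrees of freedom), with an absolute floor of
0.02 mM for near-zero concentrations. Growth rate and its SE come from
log-linear regression over all count replicates.

## MID processing

Raw GC-MS single-ion distributions are corrected for the natural isotope
abundance of every atom in the detected ion except the backbone carbons whose
labeling is being estimated. The correction matrix is banded: each column is
the same mass-shift distribution (convolution of per-atom IUPAC 2021
abundances for C, H, N, O, Si, S, P) shifted by the backbone mass. Correction
solves a non-negative least-squares inversion and renormalizes to unit sum;
SDs propagate through the unconstrained linear map. On noise-free data the
correction inverts the convolution to < 10⁻⁸ (property-tested).

Replicates are corrected individually, then pooled to a mean with per-mass
sample SDs (n−1). The measurement error entering the fit is the pooled
standard error with a 0.6 mol% floor. Because MID noise is homoscedastic
across the masses and fragments of one labeling experiment, the SD estimate is
pooled experiment-wide before dividing by √n — per-mass estimates from
triplicates follow a t(2) law whose inverse-square weighting is undefined in
expectation. The floor is applied per mass.

## EMU simulation

Measured fragments are traced backward through the atom maps to the minimal
set of elementary metabolite units (EMUs). EMUs are grouped by size; each size
block is one linear system whose right-hand side collects tracer-substrate
EMUs and convolutions of smaller EMUs (condensation reactions). Reversible
reactions contribute forward flux net+exchange and backward flux exchange
(net<0 handled symmetrically); dilution exchanges carry equal flux both ways;
symmetric-molecule variants split the flux. Pools with zero total flux at a
given flux vector (closed branches) are pinned to unlabeled so blocks stay
nonsingular. Blocks are solved densely (the default network yields ~170 EMUs,
largest block well under 10³ entries; one full simulation ≈ 1 ms). EMU
ordering is lexicographic, so simulations are bit-reproducible.

Tracer substrates are mixtures: enrichment-weighted labeled species plus a
remainder that is strictly unlabeled by default (natural abundance is handled
on the measurement side; a natural-abundance remainder is available). The
default panel is 95% [1,2-¹³C] glucose, 95% [U-¹³C] glutamine, and 50%
[U-¹³C] lactate.

A brute-force solver (`emu.brute_force_isotopomer`) integrates the complete
2ⁿ isotopomer balance by fixed-point iteration for networks of ≤ 16 total
backbone carbons and serves as the independent correctness oracle; EMU and
brute-force MIDs agree to < 10⁻¹⁰ across randomized flux vectors on five toy
topologies (reversible steps, condensation, symmetric scrambling, a cycle, a
dilution exchange).

## Flux estimation

Net fluxes are parameterized as `v = v₀ + Nβ` where N is an orthonormal basis
of the affine space defined by steady state, zero net dilution-exchange flux,
and biomass drains fixed from the growth rate (`v_bio = μ × 470 pg/cell`,
giving drains in nmol/10⁶ cells·h through precursor coefficients in mmol/g
dry weight). Exchange fluxes of LDH, IDH, GDH/AT, and the lactate dilution are
fitted on a bounded scale `e = 50·u/(1−u)`, `u ∈ [0, 0.995]`; other reversible
reactions simulate at zero exchange (their bidirectionality is not informed by
the measured fragments at this design).

The objective is the variance-weighted SSRes over all parallel tracer
experiments (each simulated with its own tracer, one shared flux vector) plus
the extracellular rate residuals. Lactate-tracer MIDs are excluded from the
objective by default and kept for qualitative comparison. Irreversibility is
enforced by hinge penalty residuals (weight 10), inactive at any feasible
optimum and asserted after the fit. Optimization is multi-start trust-region
least squares (default 20 restarts; the first start anchors β to the measured
extracellular rates, the rest perturb it randomly); the best feasible solution
wins, deterministically for a given seed.

Goodness of fit compares SSRes to a two-sided chi-square interval with
dof = (number of fitted values: every mass fraction plus every extracellular
rate) − (free net dimensions + fitted exchanges). Confidence intervals profile
the objective — re-optimizing all other parameters with the target flux pinned
by an extra linear constraint — until SSRes crosses SSRes_min + χ²₁₋α(1),
with geometric march plus bisection; a direction that never crosses within
±3000 nmol/10⁶ cells·h is reported open. `profile_covers` tests membership of
a single value with one constrained refit, which is how the recovery study
evaluates coverage without tracing full intervals.

## Synthetic data generator

The generator emulates the study design: three virtual cell lines at
μ = 0.017/0.018/0.021 h⁻¹ in control (5 mM glucose, 3 mM glutamine) and
high-lactate (+10 mM for the MCF10A-like line, +20 mM otherwise) media;
parallel tracers with the lactate tracer only in high-lactate scenarios; six
replicates for counts/glucose/lactate, triplicates for amino acids and MIDs;
sampling at 0/24/48 h with a seeding density of 10⁵ cells/mL at the media
exchange (chosen so 5 mM glucose is not depleted within 48 h at the largest
anchored uptake rates).

Ground-truth flux vectors honor the measured extracellular rates (the shipped
reference table) as equality anchors and draw the remaining freedom as a
weighted-L1-parsimonious LP solution mixed with a small random convex
combination of LP vertices (mixing weight λ ∈ [0.02, 0.10]). The L1 weights
discourage futile pyruvate-carboxylase/malic-enzyme cycling and excess
oxidative PPP, so the backbone reflects the glycolysis-dominant, oxidative-TCA
phenotype of proliferating breast lines. Exchange truths: LDH 50, GDH/AT 200
(keeps α-ketoglutarate/glutamate > 70% labeled from [U-¹³C] glutamine, as
observed in such cultures), IDH 5 (control) vs 60 (high lactate; sized
against that condition's large oxidative TCA flux so M5 citrate rises above
the control level — the reductive-carboxylation phenotype), lactate dilution
5 vs 150 (intracellular lactate M3 ≈ 10% from the 50% tracer).

Concentration trajectories invert the rate equation exactly (closed forms,
including glutamine degradation), so noise-free round trips recover the truth
to 10⁻⁶ relative. Noise: multiplicative CV 5% on counts and concentrations
(0.02 mM absolute floor); MIDs receive independent additive Gaussian noise of
1.04 mol% per replicate mass — √3 × the 0.6 mol% floor, so the pooled
triplicate's standard error equals the floor the fit assumes. Noisy MIDs are
*not* renormalized to unit sum: renormalization correlates the per-mass
errors and breaks the independent-Gaussian error model behind the
variance-weighted SSRes, destroying chi-square calibration; trace masses may
therefore go slightly negative, as integrator noise does. By default MID
tables are emitted on the corrected (backbone) scale; setting
`convolve_natural_abundance=True` emits raw-scale ions and exercises the
correction stage (validated separately by round-trip tests, since the
non-negative correction carries a small truncation bias at structurally-zero
masses).

All randomness descends from a single scenario seed; bundles regenerate
bit-identically.

### What the generator does not emulate

Lag phases, media exchanges mid-experiment, isotopic non-steady-state
transients, labeled-CO₂ refixation (hence no M1-dominated TCA labeling from
the lactate tracer), fragment-specific error structure, inter-replicate
biological drift, and chromatographic artifacts. Passing recovery tests
demonstrates the estimator is correct and calibrated under its own
assumptions at realistic scales — not that those assumptions hold for any
particular instrument or cell line.

## Pipeline and reporting

`pipeline.run_pipeline` chains rate computation → MID processing → fitting →
reporting for every scenario in a bundle, then compares control vs
high-lactate fits per cell line on the key flux panel (oxidative PPP, PDH,
CS, PC, GDH/AT, malic enzyme, IDH exchange). Between-condition significance is
flagged by non-overlap of the two 95% profile CIs — a conservative proxy for
a p ≤ 0.05 test, used because the underlying inter-condition test is a design
choice, not a derived quantity. Reports are pure functions of (inputs,
options, seed) and serialize to deterministic JSON.

## Numerical choices and defaults

| Quantity | Default | Notes |
| --- | --- | --- |
| glutamine degradation k | 0.0019 h⁻¹ | first-order, media chemistry |
| dry mass | 470 pg/cell | converts μ to biomass drains |
| MID error floor | 0.6 mol% | per mass, on the pooled SE |
| Monte-Carlo iterations | 10⁶ | rate SDs |
| restarts | 20 (fits), 2 (recovery studies) | multi-start LS |
| exchange scale s | 50 | `e = s·u/(1−u)` |
| α | 0.05 | chi-square test and CIs |
| EMU/brute-force agreement | 10⁻¹⁰ | oracle tolerance |
| steady-state tolerance | 10⁻⁶ relative | simulation precondition |

The recovery study in the acceptance tests runs 100 replicate synthetic
studies of one control scenario (two tracers, 12 fitted parameters, 54
residual degrees of freedom) with 2 restarts per fit and single-refit
coverage checks for the seven key fluxes; at these sizes it completes in
roughly five minutes on one CPU.

## Known limitations

- The default network is a reconstruction: atom transitions follow canonical
  biochemistry and the published pathway list, not a verbatim supplementary
  table; the network file format makes substituting an exact table trivial.
- Biomass precursor coefficients are literature-style defaults (protein
  ~0.7 g/g with ~6.4 mmol amino acids/g DW split across mapped pools and the
  lumped essential feed; 0.35 mmol/g each G6P and pentose-5-phosphate; lipid
  as 0.27 mmol/g palmitate-equivalents plus 0.13 mmol/g glycerol backbone).
  They are config inputs carried in the network file, not constants.
- Exchange fluxes other than the four fitted ones are fixed at zero; labeling
  effects of fast near-equilibrium exchanges (e.g., fumarase) are absorbed by
  the symmetric atom maps but not independently estimated.
- The lactate dilution exchange is weakly identified without lactate-tracer
  MIDs in the objective (by design); its CI is wide or open.
- Profile CIs assume a unimodal profile along each flux; the bisection will
  bracket the first crossing only.
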