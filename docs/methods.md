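# Methods

`znfbind` quantifies how the tandem C2H2 zinc-finger (ZnF) domain of the
recombination-hotspot-positioning protein PRDM9 binds its DNA target site.
It covers four connected analyses: rate-constant estimation from biosensor
traces, equilibrium affinity from gel-shift (EMSA) titrations, mechanistic
simulation of hot/cold DNA competition, and finger-resolved target-site
dissection via chimera/truncation panel design. A seeded synthetic-data
layer emulates each experimental design so every stage is testable without
instrument or gel data.

## Two-state kinetic model

All kinetics assume a reversible bimolecular reaction

    P + D  <->  PD,    d[PD]/dt = k_on [P][D] - k_off [PD]

with `k_on` in M⁻¹ s⁻¹ and `k_off` in s⁻¹. On a sensor surface with the
protein in large excess over immobilized DNA, the approach to steady state
is a single exponential with the pseudo-first-order observed rate

    k_obs = c · k_on + k_off,

where `c` is the protein concentration. Derived quantities are

    K_D = k_off / k_on                         (equilibrium dissociation constant)
    t_1/2(off) = ln 2 / k_off                  (complex half-life)
    t_1/2 = ln 2 / (c · k_on + k_off)          (equilibration halftime)

with the K_D standard error by Gaussian propagation,
`ΔK_D = sqrt((Δk_off/k_on)² + (k_off Δk_on / k_on²)²)`. `k_off = 0`
(an irreversible control) is representable; `dissociation_halftime` then
returns an infinite-halftime sentinel (`math.inf`) rather than raising, so
simulators can pass such controls through.

Units are strict: molar and seconds internally; interfaces and reports use
nanomolar and hours where those are the conventional scales (all such
fields are suffixed `_nM` / `_hours`).

## Trace normalization and global fitting

Association traces are normalized so that the mean of a configurable start
window (default: first 3 samples) is 100%; the paired dissociation trace is
scaled by the same factor, keeping both phases on one scale. Rates are
invariant to this scaling (the fits carry free offsets and amplitudes), so
normalization is presentation, not inference.

Fitting uses shared-parameter ("global") unweighted least squares
(Levenberg–Marquardt via lmfit):

- **Dissociation** (`DissociationModel`): `y = y0_i + A_i exp(-(t-x0_i)/τ)`
  with one shared τ across the replicate sensor-spot traces and free
  `y0_i, A_i` per trace (spot-to-spot amplitude variation); `k_off = 1/τ`,
  with the standard error mapped by the delta method. `individual` mode
  fits each trace separately and reports the across-trace mean and SD.
- **Association** (`AssociationModel`): `y = y0_i + A_i exp(-(t-x0_i)(c_i k_on + k_off))`
  with one shared `k_on` over all concentrations. `k_off` is fixed to the
  dissociation-fit value by default — it is concentration independent and
  measured separately on the long dissociation phase — but can be floated
  when at least two distinct concentrations are present (otherwise the pair
  is not identifiable and construction raises).

Numerical choices: `x0` is frozen at each trace's first sample time by
default (optionally fitted); bounds `k_on ∈ (0, 1e9]` M⁻¹s⁻¹,
`k_off ∈ [0, 1]` s⁻¹, `τ ∈ (0, 1e9]` s; starting points are deterministic
and derivative free — successive differences of a sampled exponential decay
log-linearly in time regardless of the unknown offset, which yields a rate
guess robust to unresolved plateaus; per-trace rate guesses regressed on
concentration seed `(k_on, k_off)`. Two starting variants are tried and the
fit with the lower residual RMS is kept. Optimizer tolerances are 1e-12,
tight enough that noiseless simulate→fit round trips recover the generating
parameters to better than 1e-6 relative.

## Equilibrium titrations (EMSA)

A lane's fraction bound is `100 · shifted / (shifted + free)` from the two
band intensities. A titration of protein concentration `R` against a fixed
labeled-DNA concentration `L` is fitted with the solution (depletion)
isotherm — the physically valid root of the mass-action quadratic:

    C = (S - sqrt(S² - 4RL)) / 2,   S = R + L + K_D,
    fraction bound = 100 · C / L

evaluated in the cancellation-free form `C = 2RL/(S + sqrt(S² - 4RL))`.
This reduces to the trace-ligand isotherm `100·R/(R+K_D)` as `L → 0`
(exactly 50% at `R = K_D`) and to `C = min(R, L)` at `K_D = 0`. Depletion
matters here: at 3 nM labeled DNA and K_D ≈ 25 nM, the fraction bound at
`R = K_D` is ≈48.5%, not 50%.

The single free parameter is fitted as `log10 K_D` (bounded [-16, -1]) by
unweighted least squares on the mean fraction per concentration, with
replicate SDs carried for reporting; a 1/SD² weighting is available as an
option. The K_D standard error comes from the fit covariance via the delta
method. The starting point is the log-interpolated 50% crossing of the mean
curve. Points below 10% or above 90% bound are kept in the fit but flagged:
affinity differences are poorly resolved outside the 30–70% band.
Fitting requires ≥4 distinct concentrations spanning ≥1 decade, and rejects
all-zero / all-saturated series as unidentifiable.

## Competition series and their comparison

Competition experiments express the shifted-band intensity relative to a
no-competitor reference lane (=100%) across a ladder of cold:hot excess
ratios. Two series on the same ratio grid are compared with a stratified
bootstrap: the statistic is the mean over ratios of the difference of
replicate means; the null distribution pools replicates within each ratio
and resamples two groups of the original sizes with replacement; the
two-sided p-value uses the (+1)/(n+1) correction and is deterministic under
a fixed seed. A resampling test was chosen over a parametric
generalized-least-squares trend model deliberately: it needs no variance or
autocorrelation model for few-replicate gel data, at the cost of modest
power. P-values are checked to be (super-)uniform under the null.

## Competition ODE model

`CompetitionModel` integrates the mass-action network for any number of
ligands sharing one protein pool:

    d[PD_i]/dt = k_on,i [P][D_i] - k_off,i [PD_i]

parameterized by the complex concentrations only; free protein and free DNA
follow from conservation, so mass balance holds to solver precision by
construction. Dosing events (instantaneous additions of protein or ligand,
no volume change — dilutions are assumed folded into stated concentrations)
re-initialize the totals between integration segments. The integrator is
LSODA (stiff-capable, adaptive) at rtol 1e-9; the long-time limit is
cross-checked against an independent algebraic solver
(`equilibrium_occupancy`) that brackets the root of the strictly monotone
free-protein balance `P + Σ P L_i/(K_i + P) = P_total` to machine precision.

The gel-visible observable is the labeled (biotinylated, "hot") complex as
a percentage of the labeled total. With protein in excess of total DNA and
`k_off` in the measured 1.1–2.2 × 10⁻⁵ s⁻¹ range, a 1 h pre-formed hot
complex loses under 1 percentage point of its level over a 14 h cold chase
— the quantitative form of "the complex hardly changes". Rate constants for
short cold competitors are per-ligand inputs, not a built-in length law:
affinity ratios should be scanned, not asserted.

## Finger→triplet map and panel design

Each sequence-specific C2H2 finger reads 3 nt. For the 12-finger array
(finger 0 separate and non-contacting; finger 1 degenerate CH2-type,
non-specific; fingers 2–11 specific) the 31-nt target site is tiled by the
closed form

    finger k  ->  site positions [3k-4, 3k-2]   (k = 2..11, 1-based inclusive)

so finger 2 reads nt 2–4 and finger 11 reads nt 29–31; finger 1 straddles
the upstream boundary (positions −1..1). The offset of this tiling is not
stated anywhere as a number; it is the unique 3-nt tiling consistent with
the full set of chimera finger annotations, and the test suite verifies all
12 exhaustively against a brute-force per-position membership count.

Chimeras keep a 1-based interval of the site on an otherwise unspecific
donor duplex (flanks always donor-derived); truncations shorten the
reference duplex (75/39/34/31 bp and two 28-bp variants removing 3 nt from
either site end, which delete finger 2's or finger 11's triplet). Expected
binding is classified from the contact score (1 per fully retained finger
triplet, 0.5 per partially retained one — the 0.5 is independent of whether
1 or 2 nt remain, the simplest rule consistent with the panel):
score ≥ 8 comparable, ≥ 5 reduced, < 5 strongly reduced. These cutoffs are
the unique half-integer thresholds reproducing the observed three-way
classification of all 12 panel chimeras; the half-site designs (nt 1–16 and
16–31) each retain exactly five full fingers and classify as reduced,
i.e. five consecutive fingers over 15–16 nt still confer specific binding.

Coordinates are 1-based inclusive on the stored strand throughout the
design API; conversion to 0-based happens only at FASTA boundaries. The
packaged site/donor sequences are seeded synthetic stand-ins with the
correct geometry (31-nt site centered in a 75-bp duplex, donor sharing no
k-mer ≥ 8 with the site); real sequences can be supplied as FASTA.

## Synthetic data layer

Generators are pure functions of (parameters, seed) via
`numpy.random.default_rng`:

- **Traces**: ladder 78/156/312/625/1250 nM, 2 h association, 15 h
  dissociation at 625 nM in triplicate. Sampling interval defaults to 60 s
  for both phases (the instrument's raw sampling is far denser; 1-min
  points are a conservative aggregation). The saturating response drop
  defaults to 40% of the normalized scale, scaled per concentration by the
  equilibrium occupancy `c/(c+K_D)`; spot amplitudes get log-normal jitter
  (CV 0.1 by default); noise is additive i.i.d. Gaussian, default SD 1.5
  response-percent.
- **Titrations**: 14 log-spaced points over 0.16–4300 nM against 3 nM
  labeled DNA, 3 replicates, additive Gaussian noise (default SD 3
  percentage points) clipped to [0, 100] with clipping flagged per
  replicate.
- **Competition gels**: the ODE endpoint at each cold:hot ratio converted
  to shifted/free band intensities at a configured scale with additive
  noise, plus the no-competitor reference lane.

What the generators do *not* emulate — and hence what passing recovery
tests do not demonstrate about real data: baseline drift, heteroscedastic
or photon-counting noise, mass-transport limitation on the sensor,
lysate-composition effects (e.g. nonspecific competitor partitioning, which
shifted apparent `k_on` several-fold between buffer conditions in the
motivating experiments), membrane-blotting saturation artifacts, and gel
smearing. Condition labels are metadata only.

## Problem sizes and tolerances used in the shipped checks

Round-trip identities are asserted at 1e-6 relative (noiseless), ODE
terminal state vs. algebraic equilibrium at 0.1%, mass conservation at 1e-8
relative. Stochastic recovery uses 25 seeded trace replicates at 2% noise
(median relative rate error ≤ 10%) and 50 seeded titrations at 3-point
noise (K_D within 25% of truth in ≥ 90% of replicates); these sizes keep
the full suite in a few seconds while leaving the binomial/median margins
comfortable.

## Known limitations

- Single-site, single-step binding only: no cooperativity, no
  conformational-change (two-step) kinetics, no multimer models, although
  the longer-DNA preference in the motivating data hints at more than a
  1:1 story.
- The bootstrap series comparison tests a mean shift, not trend shape.
- The depletion isotherm assumes one binding site per duplex and no
  nonspecific partitioning.
- Fit standard errors are asymptotic (covariance-based); for few traces
  the `individual` dissociation mode's across-spot SD is the more honest
  spread estimate.
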