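# znfbind

Kinetic and equilibrium analysis of zinc-finger-domain/DNA binding.

PRDM9 positions meiotic recombination hotspots by binding DNA through a
long tandem array of C2H2 zinc fingers. Characterizing that interaction
quantitatively takes four connected analyses, and this package implements
all of them as a tested library with a thin CLI:

- **Rate constants from biosensor traces** (`znfbind.tracefit`): global
  exponential fits of normalized dynamic-response traces. Association at
  protein concentration *c* decays with the pseudo-first-order rate
  *k*obs = *c·k*on + *k*off (one shared *k*on across the concentration
  ladder); the long dissociation phase decays with *k*off alone (one shared
  time constant across replicate sensor spots). Derived quantities:
  *K*D = *k*off/*k*on, *t*½(off) = ln2/*k*off, with Gaussian error
  propagation.
- **Equilibrium affinity from EMSA titrations** (`znfbind.emsa`): fraction
  bound from band intensities, fitted with the solution binding isotherm
  including ligand depletion — the physically valid root of the mass-action
  quadratic *C*² − (*R*+*L*+*K*D)*C* + *RL* = 0 — plus a stratified
  bootstrap for comparing competition series.
- **Mechanistic competition simulation** (`znfbind.competition`): mass-action
  ODEs for hot (labeled) and cold DNA sharing one protein pool under a
  dosing schedule, with an independent algebraic equilibrium solver as the
  long-time oracle. Quantifies why an hours-long complex half-life means a
  pre-formed labeled complex barely exchanges during an overnight chase.
- **Finger-resolved target mapping** (`znfbind.znf`): the closed-form
  finger→nucleotide-triplet tiling of the 31-nt target site
  (finger *k* ↦ positions 3*k*−4…3*k*−2), chimera and truncation panel
  design, and a contact-score classification of expected binding.

A seeded synthetic-data layer (`znfbind.synthetic`) emulates each
experimental design — trace ladders, titrations, competition gels, target
and donor sequences — so every analysis stage round-trips against known
ground truth.

## Worked example

Simulate a noisy biosensor run at the default 78–1250 nM ladder with known
rates, re-fit it, then fit a simulated equilibrium titration:

```python
from znfbind import RateConstants
from znfbind.binding import NM
from znfbind.synthetic import (TraceDesign, TitrationDesign,
                               simulate_switchsense, simulate_titration)
from znfbind.tracefit import (fit_dissociation, fit_association_global,
                              summarize_kinetics)
from znfbind.emsa import fit_titration

rates = RateConstants(k_on=725.0, k_off=1.1e-5)   # truth: K_D ≈ 15.2 nM
traces = simulate_switchsense(rates, TraceDesign(noise_sd=1.5, seed=7))
dissoc = fit_dissociation([t for t in traces if t.phase == "dissociation"])
assoc = fit_association_global([t for t in traces if t.phase == "association"],
                               k_off=dissoc.k_off)
print(summarize_kinetics(assoc, dissoc))

fit = fit_titration(simulate_titration(25 * NM, TitrationDesign(seed=7)).series)
print(fit.summary())
```

Output:

```
k_on  = 713.3 +/- 18 M^-1 s^-1
k_off = 1.032e-05 +/- 8.1e-07 s^-1
K_D   = 14.47 +/- 1.2 nM
t_1/2(off) = 18.65 h

Titration isotherm fit
  K_D = 28.26 +/- 0.76 nM
  residual RMS: 1.14 percentage points
  flagged (<10.0% or >90.0% bound): 8 of 14 points
  converged: True
```

At 1.5% trace noise the fitted constants land within a few percent of the
generating values (k_on 713 vs 725, k_off 1.03 vs 1.10 × 10⁻⁵ s⁻¹), giving
K_D ≈ 14.5 nM and an ≈19 h complex half-life; the titration recovers
28.3 nM against a generating 25 nM at 3-percentage-point gel noise. The
"flagged" count marks titration points outside the 10–90% bound window,
where affinity differences are poorly resolved.

The same pipeline is scriptable from the shell:

```sh
znfbind simulate-traces --kon 725 --koff 1.1e-5 --seed 7 --out traces.csv
znfbind fit-kinetics --traces traces.csv --out fit.json
znfbind report --kon 1908 --dkon 130 --koff 1.4e-5 --dkoff 0.1e-5
znfbind design-chimeras --out chimeras.fasta
```

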