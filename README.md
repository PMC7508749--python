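# wobblefit

Analysis of short-lived Watson–Crick-like states of wobble G·T mismatches
in DNA from off-resonance **R1ρ relaxation dispersion**, together with the
sugar-backbone geometry survey that characterizes the wobble conformation
in crystal structures.

Wobble G·T mismatches transiently ionize or tautomerize into Watson–Crick-
like species with populations of ~0.05–8% and lifetimes of microseconds to
milliseconds — invisible to conventional structure determination but
readable from the dependence of the rotating-frame relaxation rate R1ρ on
spin-lock power ω₁ and offset Ω. This package implements the full
estimation chain:

* **Bloch–McConnell simulation** of 2- and 3-state exchange (star and
  triangular topologies) under an off-resonance spin lock, with matched
  eigenvalue and decay-fit routes for R1ρ;
* **reduction** of peak-intensity decays to R1ρ ± σ by mono-exponential
  fitting with a seeded Monte-Carlo error scheme;
* **dispersion fitting** — individual and global (populations and exchange
  rates shared across nuclei, R1/R2/Δω per nucleus), fixed parameters for
  pinned processes such as Hoogsteen blowback, multi-start optimization,
  Monte-Carlo parameter uncertainties, AIC/BIC topology selection, and the
  Henderson–Hasselbalch pKa of the anionic state:
  χ² = Σ((R1ρ,meas − R1ρ,calc)/σ)², AIC = χ² + 2k, BIC = χ² + k·ln N,
  pKa = pH − log₁₀(p/(1−p));
* **structure survey** — backbone/glycosidic torsions, sugar pseudorotation
  (P, ν_max), the BI/BII classifier (ε−ζ wrapped to [0°, 360°); BII iff in
  [20°, 200°]), C1′–C1′ distances, a Watson–Crick-flanked wobble-mismatch
  filter over DSSR-style annotation tables, and Kabsch superposition onto
  an idealized base-pair triplet;
* **synthetic data** — a generator implementing the acquisition-design
  rules (delays to ~70% signal loss, capped at 60 ms for ¹³C and 120 ms
  for ¹⁵N) so that every stage is testable end to end without the
  unpublished experimental intensities.

See `docs/methods.md` for the model conventions, numerical choices and
known limitations.

## Layout

The analyses are numbered drivers over the library:

```
analysis/01_design_and_simulate.py    delay design + synthetic RD tables
analysis/02_reduce_decays.py          intensities -> R1rho +/- sigma
analysis/03_fit_two_state.py          two-state tautomer-exchange fit
analysis/04_global_star_blowback.py   global star fit, fixed blowback
analysis/05_high_ph_topology_and_pka.py  AIC/BIC topology choice + pKa
analysis/06_structure_survey.py       idealized-duplex geometry survey
src/wobblefit/                        the library all steps import
```

Each driver writes its tables under `results/`. A thin CLI mirrors the
pipeline: `wobblefit synth | reduce | fit | global-fit | mc |
model-select | design | survey` (see `wobblefit --help`).

## Worked example

```python
from wobblefit.experiments import high_ph_recovery
from wobblefit.fitting import pka_from_population

rep = high_ph_recovery(seed=1)           # generate -> reduce -> fit -> MC
print(f"anion population {rep.fit.params['p_c']:.3%}, "
      f"tautomer population {rep.fit.params['p_b']:.4%}")
print(f"pKa = {pka_from_population(rep.fit.params['p_c'], 8.8):.2f}")
print("poorly determined:", rep.poorly_determined)
```

prints

```
anion population 7.637%, tautomer population 0.0437%
pKa = 9.88
poorly determined: ['dw_ab:T5-C4p']
```

i.e. the fit recovers the generating anion population (8.019%) and
tautomer population (0.075%) within their Monte-Carlo uncertainties, the
implied mismatch ionization pKa is ≈9.9, and the tautomer Δω of the sugar
¹³C probe — whose tiny population and fast exchange contribute almost no
dispersion — is flagged as undetermined by the data.

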