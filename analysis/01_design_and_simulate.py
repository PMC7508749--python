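#!/usr/bin/env python
"""Lay out the acquisition designs and simulate raw dispersion data.

Prints the delay grids implied by the ~70% signal-loss rule and the
nucleus-specific duration caps, then simulates peak-intensity decays for
the three study regimes (two-state tautomer exchange, star topology with
Hoogsteen blowback, high-pH wobble/tautomer/anion exchange) and writes the
raw RD tables under results/.
"""

from pathlib import Path

from wobblefit import io as wio
from wobblefit.synth import (AcquisitionDesign, design_delays, generate_dataset,
                             truth_high_ph_star, truth_star_blowback,
                             truth_two_state_tautomer)

OUT = Path(__file__).resolve().parent.parent / "results"
OUT.mkdir(exist_ok=True)
SEED = 1

print("Delay design (8 delays to ~70% loss, capped at 60/120 ms):")
for kind, rate in (("13C", 20.0), ("13C", 100.0), ("15N", 10.0)):
    d = AcquisitionDesign(nucleus_kind=kind, n_delays=8)
    delays = design_delays(rate, d)
    print(f"  {kind} R1rho={rate:5.1f}/s -> t_max {delays[-1]*1e3:6.1f} ms")

for name, truth in (("two_state_tautomer", truth_two_state_tautomer(SEED)),
                    ("star_blowback", truth_star_blowback(SEED)),
                    ("high_ph_star", truth_high_ph_star(SEED))):
    decays = {}
    for k, (nid, ch) in enumerate(truth.channels.items()):
        design = AcquisitionDesign(nucleus_kind=ch.nucleus_kind,
                                   noise_sd=0.02, seed=SEED + 1000 * k)
        decays[(name, nid)] = generate_dataset(truth, design, nid)
    path = OUT / f"raw_{name}.csv"
    wio.write_decays_csv(path, decays, truth.channels)
    n_rows = sum(len(s.delays) for sl in decays.values() for s in sl)
    print(f"wrote {path.name}: {len(decays)} nuclei, {n_rows} intensity rows")
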