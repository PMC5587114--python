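"""Simulate a cage of 3 rats for 24 h and summarize its circadian structure.

The generator produces per-animal positions (bounded correlated random walk
with rest bouts), postures, tag poses and subcutaneous temperature on a
0.1 s grid. Rats are nocturnal: with the default dark:light activity ratio
of 1.4, step counts in the dark phase should exceed the light phase by
about 40%, and temperature runs about 0.5 degC higher in the dark.
"""

import numpy as np

import hcasim as h

cfg = h.SimConfig(duration_s=86400.0, seed=1)
truth = h.simulate_cohort(cfg)

dark_steps, light_steps = truth.step_counts_by_phase()
dark = truth.dark
print(f"simulated {cfg.n_animals} rats for 24 h ({len(truth.t)} samples each)")
for a, aid in enumerate(truth.animal_ids):
    ratio = dark_steps[a] / light_steps[a]
    t_light = truth.temp[a, ~dark].mean()
    t_dark = truth.temp[a, dark].mean()
    print(f"  {aid}: {dark_steps[a] + light_steps[a]:6d} steps, "
          f"dark:light step ratio {ratio:.2f}, "
          f"temp light {t_light:.2f} / dark {t_dark:.2f} degC")
print("-> ratios scatter around the configured 1.4; the dark-phase")
print("   temperature elevation is the configured 0.5 degC plus AR(1) noise.")
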