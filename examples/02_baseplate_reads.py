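"""Run the 12-antenna baseplate reader over a simulated session.

The reader polls the coils sequentially (75 ms activation, 1080 ms cycle,
so at most one read per tag per cycle = 0.93 Hz). Coupling follows the
exact field of a circular coil projected on the tag axis; a tag must stay
above the detection threshold for the 60 ms charge time, and only the
strongest tag on an activation is reported. With the shipped calibration a
ventral-midline cage of 3 rats reads at about 0.74 Hz per tag; the
shielding upgrade (a coupling gain) raises that.
"""

import hcasim as h
from hcasim.baseplate import read_rates

cfg = h.SimConfig(duration_s=4 * 3600.0, seed=2)
truth = h.simulate_cohort(cfg)
array = h.AntennaArray()

print(f"theoretical ceiling: {h.max_read_frequency(array):.3f} Hz per tag")
for upgraded in (False, True):
    model = h.CouplingModel(upgraded=upgraded)
    reads = h.simulate_readstream(truth, array, model, seed=3)
    rates = read_rates(reads, cfg.duration_s, truth.animal_ids)
    tag = "post-upgrade" if upgraded else "pre-upgrade "
    print(f"{tag}: {len(reads):6d} reads over 4 h; per-tag rates "
          + ", ".join(f"{r:.3f}" for r in rates) + " Hz")
print("-> pre-upgrade rates sit near the 0.74 Hz calibration point;")
print("   the upgrade gain recovers part of the gap to the 0.93 Hz ceiling")
print("   (the rest is tag-collision drop-out between cage mates).")
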