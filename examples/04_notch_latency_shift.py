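"""Show that a spectral notch at a neuron's CF delays its first spike.

The full population is stimulated with the three echo mimics (flat,
16-us notch, 32-us notch).  Neurons tuned to a notch frequency see a
~28 dB lower effective level there and, through amplitude-latency trading
(1/3 ms/dB), respond ~9-10 ms later -- while their spike counts barely
change.
"""

import numpy as np

from notchcode import (
    build_fm_protocol,
    build_tone_protocol,
    latency_shift_report,
    sample_population,
    simulate_dataset,
    tuning_table,
)

pop = sample_population(122, seed=1)
fm_ds = simulate_dataset(pop, build_fm_protocol(seed=12), seed=22)
tone_ds = simulate_dataset(pop, build_tone_protocol(seed=11), seed=21)
tuning = tuning_table(tone_ds)

table, report = latency_shift_report(fm_ds, tone_ds, pop, tuning)
for g, rep in report["groups"].items():
    fsl = rep["delta_fsl_ms"]["means"]
    cnt = rep["delta_count"]["means"]
    own = "Notch30" if g == 30.0 else "Notch45"
    print(f"CF group {g:g} kHz ({rep['n_neurons']} neurons):")
    print(f"  FSL shift re CF tone: FM {fsl['FM']:+.1f} ms, "
          f"{own} {fsl[own]:+.1f} ms "
          f"(notch adds {fsl[own] - fsl['FM']:+.1f} ms; "
          f"ANOVA significant: {rep['delta_fsl_ms']['significant']})")
    print(f"  spike-count change:   FM {cnt['FM']:+.2f}, {own} {cnt[own]:+.2f} "
          f"(significant: {rep['delta_count']['significant']})")
# The notch-at-CF condition lengthens latency significantly without a
# significant rate change: timing, not rate, carries the notch signature.
# Group medians understate the per-neuron effect because the comb notch is
# only ~2 kHz wide while CF groups span 5 kHz; neurons whose CF sits right
# at the notch frequency shift by ~9-10 ms (trading x ~28 dB attenuation).
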