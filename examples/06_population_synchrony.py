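"""Population spike synchrony with and without spectral notches.

A flat sweep activates the tonotopic sheet in a smooth high-to-low-CF
sequence, so neurons with similar CFs fire near-simultaneously.  A notch
delays the notch-tuned neurons into temporal register with lower-CF,
later-firing neurons: the pairwise SPIKE-synchronization index between
those groups rises, which is the proposed population-level signature of
object shape.
"""

import numpy as np

from notchcode import (
    build_fm_protocol,
    cf_group,
    group_sync_by_cf,
    sample_population,
    simulate_dataset,
    sync_matrix,
)

pop = sample_population(122, seed=1)
ds = simulate_dataset(pop, build_fm_protocol(seed=12), seed=22)
labels = {n.id: cf_group(n.cf_khz) for n in pop}

blocks = {}
for sid in ("FM", "Notch30", "Notch45"):
    blocks[sid] = group_sync_by_cf(sync_matrix(ds, sid, pop), labels)

flat = blocks["FM"]
groups = list(flat.index)
within = np.nanmean([flat.loc[g, g] for g in groups])
between = np.nanmean([flat.loc[gi, gj] for gi in groups for gj in groups if gi != gj])
print(f"flat dFM: mean within-CF-group sync {within:.3f} "
      f"vs between-group {between:.3f}")

for sid, g, partners in (("Notch30", 30.0, [20.0]), ("Notch45", 45.0, [20.0, 25.0])):
    for p in partners:
        print(f"{sid}: sync({g:g} kHz x {p:g} kHz) = {blocks[sid].loc[g, p]:.3f} "
              f"(flat: {flat.loc[g, p]:.3f})")
# Each notch raises the synchrony between its notch-CF group and the
# low-CF groups its delay pushes those neurons toward.
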