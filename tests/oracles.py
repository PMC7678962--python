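"""Independent brute-force oracles, written directly from the published
definitions with explicit loops; deliberately share no code with the
package implementations they check."""

import math


def brute_spike_sync(a, b, fallback_ms=5.0):
    """Spike-synchronization index by literal application of the adaptive
    coincidence definition: spike i of one train is coincident when its
    distance to the nearest spike j of the other train is below half the
    minimum of the local inter-spike intervals around i and j."""
    a, b = [float(x) for x in a], [float(x) for x in b]
    if not a or not b:
        return 0.0

    def local_isi(train, i):
        if len(train) == 1:
            return None
        cands = []
        if i > 0:
            cands.append(train[i] - train[i - 1])
        if i < len(train) - 1:
            cands.append(train[i + 1] - train[i])
        return min(cands)

    coincident = 0
    for x, y in ((a, b), (b, a)):
        for i, ti in enumerate(x):
            j = min(range(len(y)), key=lambda k: abs(y[k] - ti))
            lx, ly = local_isi(x, i), local_isi(y, j)
            if lx is None and ly is None:
                tau = 0.5 * fallback_ms
            elif lx is None:
                tau = 0.5 * ly
            elif ly is None:
                tau = 0.5 * lx
            else:
                tau = 0.5 * min(lx, ly)
            if abs(ti - y[j]) < tau:
                coincident += 1
    return coincident / (len(a) + len(b))


def brute_mi_bits(pairs):
    """I(R;S) by direct summation over an iterable of (stimulus, response)
    trial pairs: sum_{s,r} P(s,r) log2 [P(s,r) / (P(s) P(r))]."""
    pairs = list(pairs)
    n = len(pairs)
    p_sr, p_s, p_r = {}, {}, {}
    for s, r in pairs:
        p_sr[(s, r)] = p_sr.get((s, r), 0) + 1 / n
        p_s[s] = p_s.get(s, 0) + 1 / n
        p_r[r] = p_r.get(r, 0) + 1 / n
    total = 0.0
    for (s, r), p in p_sr.items():
        total += p * math.log2(p / (p_s[s] * p_r[r]))
    return total
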