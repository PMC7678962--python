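"""Synthesize the echo-mimic stimulus set and measure its spectral notches.

A downward FM sweep (70->20 kHz in 10 ms) is summed with a delayed copy of
itself, mimicking the echo from an object with two reflecting surfaces
(glints).  The delay imposes a comb filter with zeros at (2k+1)/(2*tau);
the notch frequency therefore encodes the glint separation.
"""

from notchcode import (
    add_delayed_copy,
    comb_zero_khz,
    delay_to_range,
    notch_metrics,
    synthesize_dfm,
)

sweep = synthesize_dfm(70, 20, 10, level_db=80)
print(f"flat dFM: {len(sweep.samples)} samples at {sweep.rate_hz:g} Hz, "
      f"RMS level {sweep.level_db_spl} dB SPL")

for delay_us in (16, 32):
    echo = add_delayed_copy(sweep, delay_us)
    spec = notch_metrics(echo)
    print(
        f"delay {delay_us:>2} us -> glint separation {delay_to_range(delay_us):.2f} mm, "
        f"notch measured at {spec.measured_notch_khz:.3f} kHz "
        f"(first in-band comb zero {comb_zero_khz(delay_us, 0 if delay_us == 16 else 1):.3f} kHz), "
        f"depth {spec.depth_db:.1f} dB"
    )

flat = notch_metrics(sweep)
print(f"flat dFM in-band ripple: {flat.depth_db:.2f} dB "
      f"(below the {10:.0f}-dB notch-detection threshold: {not flat.is_notch})")
# The notch frequencies sit at the comb zeros; their depths exceed 30 dB,
# which is what makes them behaviorally relevant interference cues.
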