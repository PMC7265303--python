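"""Ring-oscillator dynamics and period estimation.

Simulates the 3-node cyclic-repression circuit for 200 h, estimates the
limit-cycle period from successive reporter maxima (first 20 h
discarded), verifies the ≈⅓-period phase offsets between the three
reporters, and shows the open-ring control does not oscillate.  Also
regenerates the 10-min-interval synthetic time-lapse table.
"""

import json
from pathlib import Path

from crisprikit.synthetic_data import NoiseModel, gen_timelapse
from crisprikit.workflows import oscillator_run

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)

closed = oscillator_run()
s = closed["summary"]
print(f"closed ring: sustained={s.sustained}, period={s.period:.2f} h, "
      f"dispersion={s.period_dispersion:.2e}")
print("phase offsets (h): "
      + ", ".join(f"{k}={v:.2f}" for k, v in s.phase_offsets.items())
      + f"  (T/3 = {s.period/3:.2f})")

opened = oscillator_run(open_ring=True)
print(f"open-ring control: sustained={opened['summary'].sustained}")

lapse = gen_timelapse(closed["timeseries"],
                      channels=["reporter1", "reporter2", "reporter3"],
                      noise=NoiseModel(cv=0.05, seed=6))
lapse.to_csv(OUT / "oscillator_timelapse.csv", index=False)

(OUT / "oscillator.json").write_text(json.dumps({
    "period_h": s.period,
    "period_dispersion": s.period_dispersion,
    "sustained": s.sustained,
    "phase_offsets_h": s.phase_offsets,
    "open_ring_sustained": opened["summary"].sustained,
}, indent=2))
print(f"wrote {OUT/'oscillator_timelapse.csv'} (10-min frames, 5% CV noise)")
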