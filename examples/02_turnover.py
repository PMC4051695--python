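"""Quantify a pulse-chase experiment: onset, peak, half-life, Z/body ratio.

Simulates a 28 h pulse of GFP-tagged sarcomeric actin (signal rising from
20 h, peaking at 95 h, decaying with a 72 h half-life) and a cytoplasmic
eGFP control that plateaus, then summarises both with the turnover
pipeline.
"""

from sarcotrack import synthetic as syn, turnover as to

grid = list(range(0, 170, 5))  # hours post induction

act = syn.gen_pulse_chase(
    syn.TurnoverKinetics(lag=20, rise_end=95, decay_halflife=72, body_fraction=0.4),
    grid, n_sarcomeres_per_tp=40, noise_sd=4.0, seed=1, label="Act88F_GFP",
)
egfp = syn.gen_pulse_chase(
    syn.TurnoverKinetics(lag=15, rise_end=95, body_fraction=0.95, decays=False),
    grid, n_sarcomeres_per_tp=40, noise_sd=4.0, seed=2, label="eGFP",
)

for series in (act, egfp):
    s = to.summarize_turnover(series)
    hl = f"{s.halflife:.0f} h" if s.halflife else "none (no decay)"
    print(f"{series.label}: onset {s.onset:.0f} h, peak {s.peak_time:.0f} h, "
          f"half-life {hl}, Z/body ratio at peak {s.ratio_mean[19]:.2f}")

print("The tagged actin is enriched at the Z-disc (ratio well above 1) and "
      "decays after the chase; the eGFP control stays diffuse and elevated.")
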