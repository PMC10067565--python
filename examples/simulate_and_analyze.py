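"""Simulate an injured lung in supine and quantify its ventilation.

Builds the documented early-ARDS lung model, lets it settle at PEEP 10,
renders one minute of EIT frames at 50 Hz, and runs the ventilation-side
analysis: breath detection, tidal impedance variation (dZ) per region,
the ventilation distribution, estimated regional tidal volumes, and
regional compliance.
"""

from eitpose import breaths, io, sim

cfg = sim.SimConfig(seed=20, injury_severity=1.0)
roi = io.default_roi_mask()
vent = sim.VentSettings(tidal_volume=350.0, respiratory_rate=30.0, peep=10.0)

model = sim.build_lung_model(cfg, roi)
sim.initialize_state(model, vent, sim.SUPINE, cfg, peak_pressure=40.0)
state = sim.step_state(model, vent, sim.SUPINE, cfg, n_breaths=450)

seq = sim.render_frames(
    [sim.Segment(model, vent, sim.SUPINE, 60.0)], cfg,
    metadata={"subject": "example-pig"},
)
print(f"rendered {seq.n_frames} frames ({seq.duration:.0f} s at "
      f"{seq.frame_rate:.0f} Hz), {model.n_units} lung units, "
      f"{int((~model.is_open).sum())} collapsed")

summary = breaths.epoch_ventilation_summary(seq, roi, vent.respiratory_rate)
dist_h = summary["distribution_half"]
dist_q = summary["distribution_quadrant"]
print(f"\n{summary['n_breaths']} breaths analyzed")
print("ventilation distribution (% of total):")
print(f"  ventral {dist_h['ventral']:5.1f}   dorsal {dist_h['dorsal']:5.1f}")
for q in io.QUADRANT_LABELS:
    print(f"  {q:12s} {dist_q[q]:5.1f}")

vtr = breaths.regional_tidal_volume(dist_h, vent.tidal_volume)
cz = breaths.regional_compliance(vtr, state.driving_pressure)
print(f"\ndriving pressure {state.driving_pressure:.1f} cmH2O, "
      f"respiratory-system compliance "
      f"{vent.tidal_volume / state.driving_pressure:.1f} mL/cmH2O")
print(f"regional V_T (mL): ventral {vtr['ventral']:.0f}, dorsal {vtr['dorsal']:.0f}")
print(f"regional compliance C_Z (mL/cmH2O): ventral {cz['ventral']:.1f}, "
      f"dorsal {cz['dorsal']:.1f}")
print("\nA dorsal share well below 50 % with low dorsal C_Z is the supine "
      "signature of dependent collapse in this injury model.")
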