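"""Simulate one transfected HEK 293 cultivation and look at its structure.

Generates a 9-day run (4-day growth, 1:1 dilution + glucose replenishment
at transfection on day 3.7, 5-day production phase) with a 201-channel
PTR-MS matrix, offline analytics and a biased permittivity trace.
"""

from vocsense import SimulationConfig, simulate_run

run, truth = simulate_run(SimulationConfig.transfected(seed=1), run_id="demo")

print(f"scans: {run.voc.n_scans} at 0.005 day (~7 min) intervals, "
      f"{len(run.voc.channels)} m/z channels")
print(f"offline samples: {run.offline.time.size} (twice daily)")
print(f"peak viable cell density: {truth.vcd_true.max():.2f} x 1e6 cells/mL")
print(f"glucose depletion instants (days): "
      f"{[round(t, 3) for t in truth.depletion_times]}")
print(f"transfection at day {truth.transfection_time}: VCD halves by dilution, "
      f"glucose is replenished")
print(f"planted biomass channels: m/z {sorted(truth.informative_channels)}, "
      f"depletion burst channel: m/z {truth.burst_channel}")

# The first depletion occurs shortly before transfection (the culture runs
# out of glucose at the end of the growth phase), the second one during the
# production phase -- the pattern the m/z 45 indicator is built to flag.
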