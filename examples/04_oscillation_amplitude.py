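"""Measure apical-area oscillation amplitude with the Hilbert envelope.

A cohort of cells oscillates at 5% relative amplitude (period 120 s)
around jittered baselines with random phases; the analytic-signal
pipeline reads the amplitude back as a percentage of the local mean
area.
"""

from epiratchet.oscillation import cell_oscillation_amplitudes
from epiratchet.synth import synth_area_series

areas = synth_area_series(n_cells=100, n_frames=1200, amplitude_pct=5.0,
                          period_s=120.0, seed=1)
table = cell_oscillation_amplitudes(areas, frame_interval=1.0)
print(f"cells analysed: {len(table)}")
print(f"mean amplitude: {table.mean_amplitude_pct.mean():.2f}% "
      f"(imposed 5.00%)")
print(f"per-cell spread: {table.mean_amplitude_pct.std():.2f} points")
# The Savitzky-Golay prefilter attenuates the 120 s component slightly,
# so the recovered mean sits just under the imposed 5%.
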