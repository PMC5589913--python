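"""Detect discrete contraction steps in interface-length trajectories.

Compares a progressive ("control") cohort, whose interfaces take only
negative steps, with a reversing ("ratchet_off") cohort whose steps
alternate sign — the signature of a broken ratchet: same stepping
activity, no net contraction.
"""

import numpy as np

from epiratchet.msd import Trajectory, detect_steps, rolling_gamma, step_metrics
from epiratchet.synth import synth_step_lengths

for mode in ("control", "ratchet_off"):
    lengths, truth = synth_step_lengths(mode=mode, n=25, seed=6)
    annotations = {}
    for i in range(25):
        traj = Trajectory(lengths[i], 1.0, source_id=str(i))
        annotations[str(i)] = detect_steps(traj, rolling_gamma(traj))
    m = step_metrics(annotations)
    print(f"{mode:>12}: {m.frequency_per_min.mean():.3f} steps/min, "
          f"mean duration {np.nanmean(m.mean_duration_s):.1f} s, "
          f"net displacement {m.net_displacement.mean():+.2f} um")
# Step frequency and duration agree between the regimes; the net
# stepped displacement is strongly negative only for the control
# cohort (about -4 um for 4 steps of -1 um each).
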