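"""Signal-processing chain on a simulated day: magnitude -> band-pass ->
windowed MAD -> active/idle.

Prints the active/idle split and the displacement interpretation of the
0.02 m/s^2 threshold.
"""

import numpy as np

from rehabsense import CohortConfig, analyze_stream, displacement_from_acceleration
from rehabsense.cohort import make_protocol_schedule, simulate_accelerometer

config = CohortConfig(n_community=1, n_hospital=0, seed=7)
rng = np.random.default_rng(11)
schedule = make_protocol_schedule(config, "community", rng)
stream = simulate_accelerometer(schedule, config, np.random.default_rng(12))

windows = analyze_stream(stream)  # 10 s windows, 1 s overlap, 160 samples each
active = windows.motion_state == "active"
print(f"windows analysed:     {len(windows)} (160 samples each)")
print(f"active windows:       {active.mean() * 100:.1f} % (MAD >= 0.02 m/s^2)")
print(f"median active MAD:    {np.median(windows.mad_ms2[active]):.3f} m/s^2")
print(f"median idle MAD:      {np.median(windows.mad_ms2[~active]):.4f} m/s^2")
d = displacement_from_acceleration(0.02, 10.0)
print(f"threshold kinematics: a hand at rest under 0.02 m/s^2 travels {d:.1f} m in 10 s")
# The active share tracks the patient's drawn activity profile (~13 % for a
# community patient); idle MAD sits well below the 0.02 m/s^2 threshold.
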