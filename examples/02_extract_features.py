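"""Extract the full feature bank from one 30 s recording.

A severity-3 rest-tremor recording is simulated, preprocessed (gravity
high-pass, 20 Hz low-pass, magnitude) and turned into 323 named features.
The printed spectral features show the tremor peak sitting in the 4-6 Hz
band.
"""

import numpy as np

from pdsense import SyntheticConfig, generate_patient, simulate_exercise_signal
from pdsense.cohort import SeverityLabels
from pdsense.features import extract_recording_features

config = SyntheticConfig(n_patients=1, seed=7)
profile = generate_patient(config, 0)
labels = SeverityLabels(tremor=3, bradykinesia=0, stiffness=0, dyskinesia=0,
                        trs_clinician=-1.0, trs_patient=-1.0)
rec = simulate_exercise_signal(
    profile, labels, "phone", "accelerometer", "right", 1,
    np.random.default_rng(1), config,
)
features = extract_recording_features(rec)
print(f"features per recording: {len(features)}")
for name in (
    "Phone-ACC-#1/Right/M/Frequency of max power (3-9 Hz)",
    "Phone-ACC-#1/Right/M/Spectral centroid (0-25 Hz)",
    "Phone-ACC-#1/Right/M/Standard deviation",
    "Phone-ACC-#1/Right/-/Correlation (X,Y)",
):
    print(f"{name:55s} {features[name]: .4f}")
print("-> the max-power frequency falls in the 4-6 Hz tremor band and the")
print("   centroid is pulled toward it; axis correlations reflect the")
print("   tremor direction projected onto the (randomly rotated) device axes.")
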