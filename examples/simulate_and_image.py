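"""Simulate a motor-imagery session and image one trial.

Generates labeled 64-channel trials with a contralateral mu-band ERD,
computes the Welch PSD of one trial, places the ten 0.5 Hz sub-band
powers on the electrode grid and interpolates them into the
110 x 100 x 10 spatial-spectral tensor the classifier consumes.
"""

import numpy as np

from mitopo import (
    SyntheticConfig,
    assemble_tensor,
    build_topology,
    default_layout,
    generate,
    segment_psd,
    subband_power,
)

layout = default_layout()
trials = generate(SyntheticConfig(n_trials_per_class=5, erd_effect=0.6, seed=7))
trial = trials[0]
print(f"{len(trials)} trials of shape {trial.samples.shape} "
      f"({trial.sampling_rate:g} Hz); first label: {trial.class_label}")

psd = segment_psd(trial)
print(f"Welch PSD: {psd.power.shape[1]} one-sided bins, "
      f"{psd.resolution:g} Hz resolution")

powers = subband_power(psd, band=(10.0, 15.0), n_subbands=10)
grid = build_topology(powers.power[:, 0], layout)
print(f"topology matrix {grid.values.shape} with "
      f"{np.count_nonzero(grid.values)} electrode cells "
      "(remaining cells are structural zeros)")

tensor = assemble_tensor(powers, layout)
print(f"feature tensor {tensor.values.shape}: 110 x 100 interpolated "
      "scalp maps, one frame per 0.5 Hz sub-band of the 10-15 Hz mu band")

# The contralateral ERD is visible as a left/right asymmetry in the
# C3/C4 regions of the mu-band maps.
c3 = layout.placement[layout.channel_index("C3") + 1]
c4 = layout.placement[layout.channel_index("C4") + 1]
frame = tensor.values[:, :, 4]
r3, c3_ = (c3[0] - 1) * 10, (c3[1] - 1) * 10
r4, c4_ = (c4[0] - 1) * 10, (c4[1] - 1) * 10
print(f"mu power near C3 {frame[r3, c3_]:.1f} vs C4 {frame[r4, c4_]:.1f} "
      f"uV^2/Hz for a {trial.class_label} trial "
      "(left-fist imagery suppresses the right hemisphere)")
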