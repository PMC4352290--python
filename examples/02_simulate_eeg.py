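"""Simulate the study: counterbalanced schedule, epoched EEG, behaviour.

Generates a reduced-scale version (3 participants, 20 trials/cell) of the
2 (objecthood) x 3 (spatial frequency) within-subject design and writes
one participant's epochs to the HDF5 container.
"""

import numpy as np

from sfgamma import (
    ExperimentDesign,
    GroundTruthEffects,
    generate_design,
    simulate_behavior,
    simulate_epochs,
    write_epochs,
)
from sfgamma.montage import CHANNELS_POSTERIOR_14

design = ExperimentDesign(n_participants=3, trials_per_cell=20,
                          channels=list(CHANNELS_POSTERIOR_14))
truth = GroundTruthEffects()  # study-scale effect sizes and noise

schedule = generate_design(design, seed=0)
print("schedule:", len(schedule), "trials;",
      schedule.groupby(['objecthood', 'frequency']).size().iloc[0], "per cell/participant")

epochs = simulate_epochs(schedule, truth, seed=0, design=design, participants=[1])
print(f"epochs: {epochs.data.shape} (trials x channels x time) at {epochs.srate:g} Hz, "
      f"window [{epochs.times[0]:.2f}, {epochs.times[-1]:.2f}] s")
print(f"single-trial RMS {np.sqrt((epochs.data**2).mean()):.1f} uV "
      "(1/f noise + line noise + components)")

write_epochs(epochs, "scratch_epochs_p1.h5")
print("wrote scratch_epochs_p1.h5 (HDF5 container, schema-versioned)")

behavior = simulate_behavior(schedule, truth, seed=0)
rt = behavior[behavior["correct"]].groupby("objecthood")["rt_ms"].mean()
err = 100 * (1 - behavior.groupby("objecthood")["correct"].mean())
print("\nbehaviour (lognormal RTs, Bernoulli errors):")
print(f"  RT correct trials: object {rt['object']:.0f} ms, "
      f"non-object {rt['nonobject']:.0f} ms")
print(f"  errors: object {err['object']:.1f}%, non-object {err['nonobject']:.1f}%")
print("(objects are categorised more slowly and less accurately)")
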