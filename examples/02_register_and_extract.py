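"""Register a jittered synthetic frame sequence and extract the region Awrf.

The generator returns the true inter-frame shifts, so registration accuracy
is measured exactly rather than estimated.
"""

import numpy as np

import acetowhite as aw
from acetowhite.datasets import TissueClass

kinetics = {
    c: aw.ClassKinetics(theta=k.theta, noise_sd=0.0, drift_amplitude=0.0)
    for c, k in aw.DEFAULT_KINETICS.items()
}
config = aw.GeneratorConfig(
    class_counts={TissueClass.HSIL: 1},
    frame_shape=(80, 100),
    jitter_sd=2.0,
    n_post=40,
    seed=3,
)
seq, true_shifts, traces = aw.generate_image_sequence(config, kinetics)
aligned, est_shifts = aw.register_sequence(seq, max_shift=10)

errors = np.abs(est_shifts - true_shifts)
print(f"frames: {len(seq)}, frame shape: {seq.frame_shape}")
print(f"max |true shift| per axis: {np.abs(true_shifts).max(axis=0)}")
print(f"max shift estimation error: {errors.max()} px")

region = aw.RegionSpec(80 // 2 - 16, 100 // 2 - 16, 32, 32)
awrf = aw.extract_awrf(aligned, region)
residual = np.abs(awrf.values - traces[0].values).max()
print(f"extracted-vs-true Awrf max deviation: {residual:.2e} gray levels")
print(
    "\nA zero shift error means normalized cross-correlation undid the "
    "simulated patient motion exactly; the extracted region trace then "
    "matches the generating kinetics to rounding error."
)
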