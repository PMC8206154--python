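"""Size tuning and surround-orientation tuning of the model neuron.

A grating masked at increasing diameters: the mean spike count peaks at the
RF-sized stimulus and then shrinks, while the Fano factor keeps decreasing as
the stimulus grows — larger stimuli raise the normalization signal lambda and
so reduce posterior uncertainty. A surround annulus matched in orientation to
the center suppresses both mean and FF more than an orthogonal surround.
"""

import numpy as np

from gsmvar import (
    FilterBankSpec,
    GSMParams,
    apply_filterbank,
    build_filterbank,
    estimate_noise_cov,
    make_grating,
    make_texture_ensemble,
    run_size_tuning,
    run_surround_orientation,
    train_moment_matching,
)

spec = FilterBankSpec()
bank = build_filterbank(spec)
train = make_texture_ensemble("pink_texture", 10000, spec.patch_size_px, seed=0)
params = GSMParams(
    C_g=train_moment_matching(apply_filterbank(bank, train)),
    C_noise=estimate_noise_cov(bank, n_patches=10000, seed=1),
)

base = make_grating(spec, spec.patch_extent_deg)
size = run_size_tuning(params, bank, base, [0.34, 0.55, 0.90, 2.4, 3.8], c=15.0, seed=0)
print("Size tuning (grating diameters in degrees):")
print(size[["diameter_deg", "mean", "ff", "lam", "e_nu"]].round(3).to_string(index=False))
print(
    "-> mean peaks at the RF-sized 0.9 deg stimulus; FF and the inferred\n"
    "   modulator keep moving monotonically as lambda grows with size.\n"
)

surr = run_surround_orientation(params, bank, [0.0, 45.0, 90.0], c=40.0, seed=0)
print("Surround-orientation tuning (center at 90 deg, matched surround = 90):")
print(surr[["condition", "mean", "ff", "lam", "e_nu"]].round(3).to_string(index=False))
print(
    "-> the matched surround yields the largest lambda and modulator estimate\n"
    "   and hence the strongest suppression of both mean and variability."
)
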