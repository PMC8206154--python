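"""Train a GSM on texture patches and sample the posterior for one stimulus.

Builds the 18-filter bank (RF quadrature pair + 8 surround pairs), trains the
feature covariance by moment matching on 10,000 pink-texture patches, adds the
white-noise observation covariance, and then infers the posterior over
(modulator, features) for a full-contrast grating. The 400 posterior samples
play the role of 400 trials of a model neuron.
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
    posterior_noisy,
    response_stats,
    train_moment_matching,
)

spec = FilterBankSpec()
bank = build_filterbank(spec)
patches = make_texture_ensemble("pink_texture", 10000, spec.patch_size_px, seed=0)
C_g = train_moment_matching(apply_filterbank(bank, patches))
C_noise = estimate_noise_cov(bank, n_patches=10000, seed=1)
params = GSMParams(C_g=C_g, C_noise=C_noise)

stim = make_grating(spec, diameter_deg=0.9)  # RF-sized, matched orientation
x = apply_filterbank(bank, stim)
post = posterior_noisy(x, params, n_samples=400, seed=7)
resp = response_stats(post, c=15.0)

print(f"lambda (normalization signal)   : {post.lam:.2f}")
print(f"posterior modulator mean E[nu|x]: {post.e_nu:.2f}")
print(f"spike count mean over 400 trials: {resp.mean:.2f}")
print(f"spike count variance            : {resp.variance:.2f}")
print(f"Fano factor                     : {resp.ff:.3f}")
print(
    "\nThe Fano factor is the across-trial variance/mean; under sampling-based\n"
    "inference it measures the width of the posterior over the RF feature."
)
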