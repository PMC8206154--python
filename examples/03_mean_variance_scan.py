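"""Across-image mean-variance relation of the model neuron.

Runs the model over 1,000 texture patches with above-median RF signal and
correlates the Fano factor with the mean spike count across images: under
multiplicative-mixer inference the two are positively associated, unlike an
additive-modulator model whose posterior width never varies with the input.
"""

import numpy as np

from gsmvar import (
    FilterBankSpec,
    GSMParams,
    additive_control_posterior_1d,
    apply_filterbank,
    build_filterbank,
    estimate_noise_cov,
    make_texture_ensemble,
    rf_signal_strength,
    run_mean_variance_scan,
    train_moment_matching,
)

spec = FilterBankSpec()
bank = build_filterbank(spec)
train = make_texture_ensemble("pink_texture", 10000, spec.patch_size_px, seed=0)
params = GSMParams(
    C_g=train_moment_matching(apply_filterbank(bank, train)),
    C_noise=estimate_noise_cov(bank, n_patches=10000, seed=1),
)

imgs = make_texture_ensemble("pink_texture", 2000, spec.patch_size_px, seed=7)
strength = rf_signal_strength(apply_filterbank(bank, imgs))
sel = imgs[strength >= np.median(strength)][:1000]
res = run_mean_variance_scan(params, bank, sel, c=2.0, seed=3)

print(f"images analyzed                 : {len(res.table)}")
print(f"Pearson r (FF vs mean)          : {res.pearson_r:.3f}")
print(f"two-sided p value               : {res.p_value:.2e}")
print(f"linear-fit slope (FF per spike) : {res.slope:.4f}")

v1 = additive_control_posterior_1d(1.0, 1.0, 2.0, 0.5)[1]
v2 = additive_control_posterior_1d(100.0, 1.0, 2.0, 0.5)[1]
print(
    f"\nAdditive-modulator control: posterior variance at x=1 is {v1:.3f} and at "
    f"x=100 is {v2:.3f} —\nidentical, so an additive modulator predicts no "
    "mean-variance coupling at all."
)
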