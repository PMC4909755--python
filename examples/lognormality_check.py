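"""Is a simulated region-size distribution lognormal?

Fragmentation by repeated noisy halving multiplies many independent
factors, so log region volumes are close to normal.  This script fits a
Gaussian to the log volumes of one simulated parcellation, tests the fit
with a one-sample Kolmogorov-Smirnov test, and shows the first QQ points.
"""

import brainparc as bp

tree = bp.run_fragmentation(bp.ModelParams(mu=0.0, n_target=500, seed=3))
volumes = tree.leaf_volumes()

fit = bp.fit_log_gaussian(volumes)
ks = bp.ks_lognormality(volumes)
ks_boot = bp.ks_lognormality(volumes, lilliefors=True, n_resamples=500, seed=0)

print(f"n = {fit.n} regions")
print(f"mean ln v = {fit.log_mean:.3f}, sigma(ln v) = {fit.sigma:.3f}")
print(f"KS D = {ks.statistic:.4f}, classical p = {ks.p_value:.3f}")
print(f"Lilliefors (bootstrap) p = {ks_boot.p_value:.3f}")

qq = bp.qq_points(volumes)
print("first QQ points (theoretical, observed):")
for theo, obs in qq[:3]:
    print(f"  {theo:8.3f}  {obs:8.3f}")

# A large p means the log volumes are statistically indistinguishable from
# normal, i.e. the sizes are close to lognormal; QQ points on the identity
# line say the same graphically.  The bootstrap p corrects for fitting the
# Gaussian's parameters on the same sample.
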