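"""Hebbian plasticity whose equilibrium is an outer-product power law.

Connection strengths obey dC_ij/dt = eps1 f_i^alpha C_ij^beta f_j^gamma
- eps2 C_ij with area activities f proportional to area volumes.  For
beta < 1 the strengths relax to C*_ij ∝ v_i^(alpha/(1-beta)) *
v_j^(gamma/(1-beta)), i.e. the power-law macroconnectome with incoming
exponent eta = gamma/(1-beta) and outgoing exponent kappa =
alpha/(1-beta).  The script verifies the closed form by integrating the
ODE from a random start and fitting the equilibrium.
"""

import numpy as np

import brainparc as bp

params = bp.HebbianParams(alpha=0.65, beta=0.4, gamma=1.6)
eta, kappa = bp.predicted_exponents(params)
print(f"closed form: eta = gamma/(1-beta) = {eta:.4f}, "
      f"kappa = alpha/(1-beta) = {kappa:.4f}")

rng = np.random.default_rng(0)
volumes = np.exp(rng.normal(0.0, 0.5, 10))
C0 = np.exp(rng.normal(0.0, 1.0, (10, 10)))  # random initial wiring

eq = bp.integrate_to_equilibrium(C0, volumes, params, tol=1e-10)
fit_in = bp.fit_power_law(eq[0], volumes)      # one target row vs sources
fit_out = bp.fit_power_law(eq[:, 0], volumes)  # one source column vs targets

print(f"integrated ODE, then log-log fit:")
print(f"  incoming exponent = {fit_in.exponent:.4f} (r^2 = {fit_in.r_squared:.6f})")
print(f"  outgoing exponent = {fit_out.exponent:.4f}")

resid = np.abs(bp.hebbian_rhs(eq, volumes, params)).max()
print(f"max |dC/dt| at equilibrium: {resid:.2e}")

# With beta = 0.4 and gamma = 1.6 the rule reproduces eta ~ 2.67, the
# scaling measured for incoming connections of primary visual cortex,
# rather than the naive eta = 1 of the pure outer-product model.
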