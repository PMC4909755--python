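# brainparc

Evolutionary model of how a brain came to have the regions it has — and
what that implies for how the regions are wired together.

`brainparc` is a Python library (with a thin CLI) for researchers studying
comparative neuroanatomy and mesoscale connectomics.  It treats a brain's
regional organisation as the end state of **iterative fragmentation**:
over evolutionary time, existing brain regions (*parcellation units*,
PUs) split in two and specialise.  The package simulates this process,
quantifies the resulting (approximately lognormal) region-size
distributions, infers the process's bias parameter from real dispersion
statistics, and follows the model through to region-to-region
connectivity.

## The model

**Fragmentation.**  Starting from a single region, at each step one
current region *i* is chosen to split with probability

```
p_i = v_i^mu / Z,        Z = sum_j v_j^mu
```

where `v_i` is its volume and `mu` is the bias exponent: `mu = 0` is
uniform splitting, `mu > 0` preferentially splits large regions
(homogenising sizes), `mu < 0` splits small ones (widening the size
distribution).  A split produces two halves perturbed by multiplicative
noise (normal, mean 1, 10% sd) that conserves the parent volume.  Each
step adds one PU, so the PU count doubles as the evolutionary clock.

**Statistics.**  Log region volumes are fitted with a Gaussian; the
dispersion `sigma(ln v)` (natural-log units) summarises a parcellation,
and a Kolmogorov–Smirnov test and QQ points assess lognormality.

**Inference of `mu`.**  For each `mu` on a grid, many simulated runs at
the observed PU count give the sampling distribution of `sigma`; the 5th–
95th percentile band, intersected with the observed `sigma`, yields a 90%
confidence interval for `mu`.

**Connectivity.**  If the ancestral neuron pool was uniformly randomly
wired, fragmentation predicts a rank-one macroconnectome
`C_ij ∝ v_i v_j`.  Row-normalising to the fraction of labeled neurons
(FLN) gives `FLN_ij ∝ v_j`, i.e. a power law in source volume with
exponent `eta = 1`.  Empirical exponents are steeper; the package fits
`eta` (incoming) and `kappa` (outgoing) by log–log least squares over
non-zero connections, and implements the multiplicative Hebbian rule

```
dC_ij/dt = eps1 * f_i^alpha * C_ij^beta * f_j^gamma - eps2 * C_ij
```

whose equilibrium (for `beta < 1`, activities `f_i ∝ v_i`) is an
outer-product power law with `eta = gamma/(1-beta)` and
`kappa = alpha/(1-beta)` — steep exponents included.

## Worked example

Infer the splitting bias for a macaque-like cortex (91 areas, observed
`sigma(ln v) = 1.24`):

```python
import brainparc as bp

env = bp.sigma_envelope(n_pu=91, n_sims=1000, seed=42)
interval = bp.infer_mu_interval(1.24, env)
print(interval.mu_low, interval.mu_high)
```

Running `python examples/infer_mu.py` prints:

```
observed sigma(ln v) = 1.24 at 91 parcellation units
90% confidence interval for mu: [-0.042, 0.352]
contains mu = 0 (uniform splitting): True
```

The data are consistent with uniform splitting but favour a mild bias
toward fragmenting larger regions.  The other `examples/` scripts cover
simulation and tree export (`simulate_parcellation.py`), lognormality
testing (`lognormality_check.py`), connectome scaling fits
(`connectome_scaling.py`) and the Hebbian equilibrium
(`hebbian_fixed_point.py`); each prints its numbers with a note on what
they mean.

The same functionality is available from the shell:

```
brainparc simulate --mu 0.14 --n-target 100 --seed 1 --out run1
brainparc infer-mu --sigma-obs 1.24 --n-pu 91 --seed 42 --out macaque
brainparc hebbian --alpha 0.65 --beta 0.4 --gamma 1.6
```

Every command writes a JSON metadata sidecar (parameters, seed, version)
so runs are reproducible byte for byte.

## Layout

- `src/brainparc/fragmentation.py` — the splitting process (tree and
  vectorised replicate simulators)
- `src/brainparc/stats.py` — lognormality statistics
- `src/brainparc/inference.py` — sigma envelope and `mu` intervals
- `src/brainparc/connectivity.py` — outer-product connectome, FLN,
  power-law fits
- `src/brainparc/hebbian.py` — plasticity rule, fixed point, integration
- `src/brainparc/synthetic.py` — synthetic volumes, hierarchies, FLN
  matrices
- `src/brainparc/io.py` — hierarchy CSV and Newick round trips
- `src/brainparc/cli.py` — the `brainparc` command

See `docs/methods.md` for modelling assumptions, numerical choices and
limitations.
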