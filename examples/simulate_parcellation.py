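"""Simulate the fragmentation of a brain into parcellation units.

Starting from a single region of unit volume, one region at a time is
chosen (with probability proportional to volume**mu) and split into two
noisy halves, until 100 regions exist.  The script prints the dispersion
of log region volumes — the statistic used throughout the package — and
writes the full fragmentation tree in Newick and CSV form.
"""

import numpy as np

import brainparc as bp

params = bp.ModelParams(mu=0.14, n_target=100, noise_sd=0.10, seed=1)
tree = bp.run_fragmentation(params)

volumes = tree.leaf_volumes()
fit = bp.fit_log_gaussian(volumes)
print(f"simulated {tree.n_leaves} parcellation units (mu = {params.mu})")
print(f"largest / smallest region volume: {volumes.max():.4g} / {volumes.min():.4g}")
print(f"sigma(ln v) = {fit.sigma:.3f} natural-log units")
print(f"total volume of all leaves: {volumes.sum():.12f} (conserved)")

bp.write_newick(tree, "parcellation_tree.nwk")
bp.write_hierarchy_csv(tree, "parcellation_tree.csv")
print("wrote parcellation_tree.nwk and parcellation_tree.csv")

# sigma(ln v) is the width of the region-size distribution: larger values
# mean a brain whose regions span more orders of magnitude in size.
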