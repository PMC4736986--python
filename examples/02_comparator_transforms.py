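"""The comparator transforms: quantile normalization and nonparanormal.

Shows how each places the same RNA-seq-like matrix on a training-compatible
scale, and what each preserves.
"""

import numpy as np

from tdmnorm import (SimulationConfig, build_target, npn_transform,
                     quantile_normalize_to_target, simulate_microarray,
                     to_rnaseq_like)

cfg = SimulationConfig(n_genes=100, n_samples=200, seed=2)
train = simulate_microarray(cfg)
rnaseq = to_rnaseq_like(train.matrix)

# Quantile normalization: every sample takes on the target marginal (tied
# input values -- e.g. the zeros created by rounding -- share one
# interpolated target value, so agreement is near- rather than bit-exact).
target = build_target(train.matrix)
qn = quantile_normalize_to_target(rnaseq, target)
dev = np.abs(np.sort(qn.values[:, 0]) - target.sorted_values).max()
print("quantile normalization")
print(f"  target length (= genes): {len(target)}")
print(f"  max |sorted sample - target|: {dev:.3f} log2 units")

# Nonparanormal: per-gene Winsorized Gaussian scores, unit sd per gene.
npn = npn_transform(rnaseq)
sds = npn.values.std(axis=1, ddof=1)
print("nonparanormal")
print(f"  per-gene sd: min {sds.min():.6f}, max {sds.max():.6f}")
print(f"  value range: [{npn.values.min():.2f}, {npn.values.max():.2f}] "
      "(Gaussian scores)")

# QN keeps only within-sample ranks; NPN keeps only per-gene cross-sample
# ranks.  Which information survives determines how each method behaves
# under noise in the evaluation harness.
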