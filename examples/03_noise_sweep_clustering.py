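"""Clustering robustness across the noise ladder.

Simulates matched microarray / RNA-seq-like data, fits PAM on the
microarray-like matrix, then scores each normalization of the increasingly
noisy RNA-seq-like duplicate by cluster-majority accuracy.
"""

from tdmnorm import NoiseLadder, SimulationConfig, run_noise_sweep_benchmark

cfg = SimulationConfig(n_genes=100, n_samples=200, seed=3)
ladder = NoiseLadder()  # 0.0 .. 3.8% in 0.2% steps

table = run_noise_sweep_benchmark(cfg, ladder=ladder,
                                  methods=("tdm", "qn", "npn", "log2"))
wide = table.pivot(index="noise_pct", columns="method", values="accuracy")
print(wide.to_string(float_format=lambda v: f"{v:.3f}"))

level0 = wide.iloc[0]
print(f"\nat 0% noise all methods agree: {level0.nunique() == 1} "
      f"(accuracy {level0.iloc[0]:.3f})")
# Accuracy 1.0 means every sample lands in a cluster whose majority class
# is its own; under the calibrated generator the class structure is strong
# enough that all transforms preserve it on clean data, and degradation
# appears only as the noise percentage grows.
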