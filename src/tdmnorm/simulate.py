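"""Synthetic expression data with known class structure.

The generator emulates the statistical footprint of a regulatory-network
expression simulator: a microarray-like log2 matrix whose samples fall into
a small number of experimental conditions, where "signal" genes shift their
mean between conditions, gene-gene correlation arises from shared latent
module factors, and "background" genes ignore the conditions.  A matched
RNA-seq-like matrix is produced by inverse-log transforming, rounding and
rescaling to a high dynamic range, and a graded ladder of Gaussian noise
(a percentage of each gene's standard deviation) degrades the matched data
from near-perfect to near-zero rank correlation with the original.

No network topology or read-level sequencing is simulated; only the
distributional properties the downstream evaluation exercises.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import LINEAR, LOG2, ExpressionMatrix, LabeledDataset

__all__ = [
    "SimulationConfig",
    "NoiseLadder",
    "simulate_microarray",
    "to_rnaseq_like",
    "add_noise",
    "make_noise_ladder",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Study design and generator constants.

    The head-line fields (500 genes, half background, 400 samples, 4
    conditions of 100 samples each, RNA-seq range [0, 1e6]) are the study
    conditions the harness evaluates under.  The remaining constants shape
    the log2 distribution; their defaults were calibrated once so that the
    default noise ladder spans the full range from faithful to fully
    scrambled data (see docs/methods.md) and are not meant to be swept.
    """

    n_genes: int = 500
    background_fraction: float = 0.5
    n_samples: int = 400
    n_conditions: int = 4
    rnaseq_max: float = 1_000_000.0
    seed: int = 0
    # log2-scale shape constants (see docs/methods.md for the calibration)
    baseline_range: tuple[float, float] = (6.5, 9.5)
    gene_sd_range: tuple[float, float] = (1.8, 2.6)
    factor_loading_range: tuple[float, float] = (0.6, 1.2)
    genes_per_module: int = 20
    effect_size: float = 1.8
    floor_log2: float = 6.0
    saturation_log2: float = 14.0

    def __post_init__(self) -> None:
        if self.n_genes < 2 or self.n_samples < 2:
            raise ValueError("need at least 2 genes and 2 samples")
        if self.n_conditions < 2 or self.n_samples % self.n_conditions != 0:
            raise ValueError("n_samples must be divisible by n_conditions >= 2")
        if not 0.0 < self.background_fraction < 1.0:
            raise ValueError("background_fraction must be in (0, 1)")
        if self.rnaseq_max <= 0:
            raise ValueError("rnaseq_max must be positive")
        if self.effect_size < 0:
            raise ValueError("effect_size must be non-negative")
        if not self.floor_log2 < self.saturation_log2:
            raise ValueError("floor_log2 must be below saturation_log2")


@dataclass(frozen=True)
class NoiseLadder:
    """Ascending noise percentages; default 0.0-3.8% in 0.2% steps."""

    percentages: tuple[float, ...] = tuple(round(0.2 * i, 1) for i in range(20))

    def __post_init__(self) -> None:
        p = tuple(float(x) for x in self.percentages)
        if len(p) == 0 or any(x < 0 for x in p) or any(np.diff(p) <= 0):
            raise ValueError("percentages must be non-negative and ascending")
        object.__setattr__(self, "percentages", p)

    def __len__(self) -> int:
        return len(self.percentages)


def _condition_levels(k: int) -> np.ndarray:
    """Equally spaced, zero-mean condition offsets with unit population sd."""
    levels = np.arange(k, dtype=float) - (k - 1) / 2.0
    return levels / levels.std()


def simulate_microarray(cfg: SimulationConfig) -> LabeledDataset:
    """Generate a condition-labelled microarray-like log2 matrix.

    Per gene g and sample s:
    ``x[g, s] = mu_g + lambda_g * f[module(g), s] + delta[g, cond(s)] + eps``
    with ``eps ~ N(0, sd_g^2)``, clipped into ``[floor_log2,
    saturation_log2]`` (scanner background floor and saturation).  Signal
    genes (ids ``sig####``) receive condition offsets ``delta`` that are a
    per-gene random permutation of equally spaced, zero-mean levels scaled
    to ``effect_size`` total-sd units; background genes (ids ``bkg####``)
    receive none.  The balanced (zero-mean, equal per condition) offsets
    keep every condition's overall intensity level equal, so class identity
    lives in which genes move, not in a global shift.  Module factors ``f``
    are shared across the genes of a module, inducing gene-gene
    correlation.  Deterministic given the config (seed included).
    """
    rng = np.random.default_rng(cfg.seed)
    n_signal = int(round(cfg.n_genes * (1.0 - cfg.background_fraction)))
    n_bkg = cfg.n_genes - n_signal
    per_cond = cfg.n_samples // cfg.n_conditions

    mu = rng.uniform(*cfg.baseline_range, size=cfg.n_genes)
    gene_sd = rng.uniform(*cfg.gene_sd_range, size=cfg.n_genes)
    loading = rng.uniform(*cfg.factor_loading_range, size=cfg.n_genes)
    loading *= rng.choice([-1.0, 1.0], size=cfg.n_genes)
    n_modules = max(2, cfg.n_genes // cfg.genes_per_module)
    module = rng.integers(0, n_modules, size=cfg.n_genes)
    factors = rng.normal(size=(n_modules, cfg.n_samples))

    total_sd = np.sqrt(gene_sd**2 + loading**2)
    levels = _condition_levels(cfg.n_conditions)
    delta = np.zeros((cfg.n_genes, cfg.n_conditions))
    for g in range(n_signal):  # signal genes occupy the first rows
        delta[g] = cfg.effect_size * total_sd[g] * rng.permutation(levels)

    cond = np.repeat(np.arange(cfg.n_conditions), per_cond)
    values = (
        mu[:, None]
        + loading[:, None] * factors[module, :]
        + delta[:, cond]
        + rng.normal(size=(cfg.n_genes, cfg.n_samples)) * gene_sd[:, None]
    )
    values = np.clip(values, cfg.floor_log2, cfg.saturation_log2)

    gene_ids = [f"sig{i:04d}" for i in range(n_signal)] + [
        f"bkg{i:04d}" for i in range(n_bkg)
    ]
    sample_ids = [f"s{i:04d}" for i in range(cfg.n_samples)]
    labels = [f"c{c + 1}" for c in cond]
    return LabeledDataset(
        matrix=ExpressionMatrix(gene_ids, sample_ids, values, LOG2),
        labels=labels,
    )


def to_rnaseq_like(m: ExpressionMatrix, rnaseq_max: float = 1_000_000.0) -> ExpressionMatrix:
    """Inverse-log, round and rescale to ``[0, rnaseq_max]``.

    Emulates the higher dynamic range of RNA-seq on samples matched to the
    log2 input: the output is a monotone transform of the input up to
    rounding, integer-valued, with pooled minimum 0 and maximum
    ``rnaseq_max``.
    """
    if m.space != LOG2:
        raise ValueError("to_rnaseq_like expects a log2-space matrix")
    linear = 2.0 ** m.values
    lo, hi = linear.min(), linear.max()
    if hi <= lo:
        raise ValueError("constant matrix: rescale undefined")
    values = np.round((linear - lo) / (hi - lo) * rnaseq_max)
    return m.with_values(values, space=LINEAR)


def add_noise(m: ExpressionMatrix, pct: float, seed: int) -> ExpressionMatrix:
    """Add per-gene Gaussian noise with sd ``(pct/100) * sd(gene)``.

    Linear-space results are floored at 0 so downstream log/TDM
    preconditions continue to hold.  ``pct = 0`` is the identity.
    """
    if pct < 0:
        raise ValueError("pct must be non-negative")
    if pct == 0:
        return m.with_values(m.values.copy())
    rng = np.random.default_rng(seed)
    sd = m.values.std(axis=1, ddof=1)
    noisy = m.values + rng.normal(size=m.values.shape) * (pct / 100.0 * sd)[:, None]
    if m.space == LINEAR:
        noisy = np.maximum(noisy, 0.0)
    return m.with_values(noisy)


def make_noise_ladder(m: ExpressionMatrix, ladder: NoiseLadder | None = None,
                      seed: int = 0) -> list[ExpressionMatrix]:
    """One independently seeded noisy copy per ladder level (level i uses
    ``seed + i``); a leading 0% level reproduces the input exactly."""
    if ladder is None:
        ladder = NoiseLadder()
    return [add_noise(m, pct, seed + i) for i, pct in enumerate(ladder.percentages)]
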