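"""Comparator transforms: quantile normalization to a target, nonparanormal.

Quantile normalization forces each test sample's marginal distribution onto
a reference ("target") distribution built from the training data, keeping
only within-sample rank information.  The nonparanormal maps each gene to
Winsorized Gaussian scores through its empirical CDF, estimating the
marginals of a Gaussian copula; it depends on the data only through ranks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import ndtri
from scipy.stats import rankdata

from .core import LOG2, ExpressionMatrix

__all__ = [
    "TargetDistribution",
    "build_target",
    "quantile_normalize_to_target",
    "npn_transform",
]


@dataclass(frozen=True)
class TargetDistribution:
    """A sorted reference distribution (one value per rank position)."""

    sorted_values: np.ndarray
    space: str = LOG2

    def __post_init__(self) -> None:
        v = np.asarray(self.sorted_values, dtype=float)
        if v.ndim != 1 or v.size == 0:
            raise ValueError("target must be a non-empty 1-D vector")
        if np.any(np.diff(v) < 0):
            raise ValueError("target values must be non-decreasing")
        object.__setattr__(self, "sorted_values", v)

    def __len__(self) -> int:
        return int(self.sorted_values.size)


def build_target(train: ExpressionMatrix) -> TargetDistribution:
    """Mean sorted profile of the training samples.

    Each sample (column) is sorted and the per-rank mean taken, the standard
    reduction of a multi-sample reference to a single target distribution.
    The target length equals the gene count.
    """
    return TargetDistribution(
        sorted_values=np.sort(train.values, axis=0).mean(axis=1),
        space=train.space,
    )


def quantile_normalize_to_target(test: ExpressionMatrix,
                                 target: TargetDistribution) -> ExpressionMatrix:
    """Quantile-normalize each sample independently onto ``target``.

    A value with (average, tie-aware) rank ``r`` among ``n`` sample values
    is replaced by the sorted target interpolated at quantile position
    ``(r - 1)/(n - 1)``; with equal lengths and no ties this reproduces the
    target multiset exactly.
    """
    m = len(target)
    n = test.n_genes
    out = np.empty_like(test.values)
    grid = np.arange(m, dtype=float)
    for j in range(test.n_samples):
        col = test.values[:, j]
        if n == 1:
            pos = np.array([0.5 * (m - 1)])
        else:
            ranks = rankdata(col)  # average ranks
            pos = (ranks - 1.0) / (n - 1.0) * (m - 1.0)
        out[:, j] = np.interp(pos, grid, target.sorted_values)
    return test.with_values(out, space=target.space)


def _winsor_delta(n: int) -> float:
    """Truncation level for the Winsorized nonparanormal estimator."""
    return 1.0 / (4.0 * n ** 0.25 * np.sqrt(np.pi * np.log(n)))


def npn_transform(m: ExpressionMatrix) -> ExpressionMatrix:
    """Nonparanormal (Winsorized Gaussian-score) transform, per gene.

    Genes are the copula's variables: each gene's empirical CDF values
    (average ranks over the ``n`` samples, divided by ``n``) are Winsorized
    into ``[delta, 1 - delta]`` with
    ``delta = 1 / (4 n^{1/4} sqrt(pi log n))``, passed through the
    standard-normal quantile function, and rescaled to unit sample standard
    deviation.  A constant gene carries no rank information and is set to
    zeros with a warning.
    """
    n = m.n_samples
    if n < 3:
        raise ValueError("nonparanormal transform needs at least 3 samples")
    delta = _winsor_delta(n)
    ranks = rankdata(m.values, axis=1)
    u = np.clip(ranks / n, delta, 1.0 - delta)
    scores = ndtri(u)
    constant = np.ptp(m.values, axis=1) == 0
    sd = scores.std(axis=1, ddof=1)
    if np.any(constant):
        which = [m.gene_ids[i] for i in np.flatnonzero(constant)[:5]]
        warnings.warn(
            f"{int(constant.sum())} constant gene(s) set to zero "
            f"(e.g. {which})", RuntimeWarning, stacklevel=2,
        )
        sd = np.where(constant, 1.0, sd)
        scores[constant, :] = 0.0
    return m.with_values(scores / sd[:, None], space=LOG2)
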