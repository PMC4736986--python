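"""Training Distribution Matching (TDM).

TDM makes RNA-seq style test data usable with models trained on
microarray-style (log2) data.  It summarizes the training distribution by
how many interquartile ranges fit between the third quartile and the
maximum (and, symmetrically, below the first quartile, floored at zero),
then uses those ratios to cap the test data's tails, maps the capped test
values linearly onto the training range in inverse-log space, and log2
transforms.  Within-matrix rank order is preserved except for ties created
by the tail capping, and the whole test matrix is adjusted as one pooled
distribution -- there is deliberately no per-sample variant, which would
over-normalize.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from .core import LINEAR, LOG2, ExpressionMatrix, log2_transform

__all__ = ["TdmParameters", "summarize_training", "tdm_transform", "tdm_normalize"]


@dataclass(frozen=True)
class TdmParameters:
    """Pooled training-distribution summary on the log2 scale.

    ``upper_ratio`` is (max - Q3)/IQR: the number of IQRs between the third
    quartile and the maximum.  ``lower_ratio`` is (Q1 - min)/IQR floored at
    zero.  These two unitless ratios are all TDM transfers from training to
    test.
    """

    train_min_log2: float
    train_q1_log2: float
    train_q3_log2: float
    train_max_log2: float
    iqr_log2: float
    upper_ratio: float
    lower_ratio: float

    def __post_init__(self) -> None:
        if not (self.train_min_log2 <= self.train_q1_log2
                <= self.train_q3_log2 <= self.train_max_log2):
            raise ValueError("require min <= Q1 <= Q3 <= max")
        if self.iqr_log2 <= 0:
            raise ValueError("degenerate training distribution (IQR = 0)")
        if self.upper_ratio < 0 or self.lower_ratio < 0:
            raise ValueError("spread ratios must be non-negative")

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, s: str) -> "TdmParameters":
        return cls(**json.loads(s))


def summarize_training(train: ExpressionMatrix, pseudocount: float = 1.0) -> TdmParameters:
    """Derive :class:`TdmParameters` from a training matrix.

    Quartiles and extremes are pooled over every entry of the matrix and
    computed with linear interpolation (type-7), the convention all the
    transforms in this package share.  Linear-space input is first log2
    transformed with ``pseudocount`` (microarray data usually arrive
    already on the log2 scale, but either choice is allowed).
    """
    if train.space == LINEAR:
        train = log2_transform(train, pseudocount)
    pooled = train.values.ravel()
    mn, mx = float(pooled.min()), float(pooled.max())
    q1, q3 = (float(q) for q in np.quantile(pooled, [0.25, 0.75]))
    iqr = q3 - q1
    if iqr <= 0:
        raise ValueError("degenerate training distribution (IQR = 0)")
    return TdmParameters(
        train_min_log2=mn,
        train_q1_log2=q1,
        train_q3_log2=q3,
        train_max_log2=mx,
        iqr_log2=iqr,
        upper_ratio=(mx - q3) / iqr,
        lower_ratio=max(0.0, (q1 - mn) / iqr),
    )


def tdm_transform(test: ExpressionMatrix, params: TdmParameters) -> ExpressionMatrix:
    """Map a linear-space test matrix into the training log2 range.

    The pooled test quartiles bound the usable test range at
    ``Q3 + upper_ratio * IQR`` above and ``max(0, Q1 - lower_ratio * IQR)``
    below; values outside are clipped (Winsorized), compressing the extreme
    tail.  The bounded range is then mapped affinely onto
    ``[2**train_min, 2**train_max]`` and log2 transformed, so every output
    lies in ``[train_min_log2, train_max_log2]``.
    """
    if test.space != LINEAR:
        raise ValueError("tdm_transform expects a linear-space test matrix")
    if np.any(test.values < 0):
        raise ValueError("test values must be non-negative")
    pooled = test.values.ravel()
    q1, q3 = np.quantile(pooled, [0.25, 0.75])
    iqr = q3 - q1
    if iqr <= 0:
        raise ValueError("degenerate test distribution (IQR = 0)")
    new_max = q3 + params.upper_ratio * iqr
    new_min = max(0.0, q1 - params.lower_ratio * iqr)
    clipped = np.clip(test.values, new_min, new_max)
    lo = 2.0 ** params.train_min_log2
    hi = 2.0 ** params.train_max_log2
    mapped = lo + (clipped - new_min) * (hi - lo) / (new_max - new_min)
    return test.with_values(np.log2(mapped), space=LOG2)


def tdm_normalize(train: ExpressionMatrix, test: ExpressionMatrix,
                  pseudocount: float = 1.0) -> ExpressionMatrix:
    """Convenience: summarize ``train`` then TDM-transform ``test``."""
    return tdm_transform(test, summarize_training(train, pseudocount))
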