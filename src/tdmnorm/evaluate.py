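"""Evaluation machinery: PAM clustering, L1 multinomial classification,
agreement metrics, and the noise-sweep / platform-transfer benchmarks.

The clustering side fits Partitioning Around Medoids (classic BUILD + SWAP)
on training-platform samples and assigns normalized test samples to the
nearest medoid; clustering quality is scored as cluster-majority accuracy
(the fraction of samples whose cluster's most common true class is their
own).  The supervised side trains L1-penalized multinomial logistic
regression with cross-validated penalty selection and scores transfers with
total accuracy, per-class balanced accuracy, Cohen's kappa and the
no-information rate.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from scipy.stats import kendalltau

from .core import ExpressionMatrix, LabeledDataset, align_genes, log2_transform
from .normalizers import TargetDistribution, build_target, npn_transform, \
    quantile_normalize_to_target
from .tdm import TdmParameters, summarize_training, tdm_transform
from .simulate import NoiseLadder, SimulationConfig, add_noise, \
    make_noise_ladder, simulate_microarray, to_rnaseq_like

__all__ = [
    "PamModel",
    "ClassifierModel",
    "EvaluationReport",
    "pam_fit",
    "pam_assign",
    "cluster_majority_accuracy",
    "train_l1_multinomial",
    "predict_classes",
    "score_predictions",
    "variability_f_score",
    "mean_kendall_tau",
    "run_noise_sweep_benchmark",
    "run_transfer_benchmark",
    "NORMALIZATION_METHODS",
]

NORMALIZATION_METHODS = ("tdm", "qn", "npn", "log2", "untransformed")


# -- PAM -------------------------------------------------------------------

@dataclass
class PamModel:
    """k medoids (actual training samples) enabling nearest-medoid
    assignment of new samples."""

    k: int
    medoid_samples: np.ndarray  # genes x k
    medoid_ids: list[str]
    gene_ids: list[str]
    labels: np.ndarray  # training clustering (cluster index per sample)
    cost: float
    distance: str = "euclidean"


def _pam_cost(D: np.ndarray, medoids: list[int]) -> float:
    return float(D[:, medoids].min(axis=1).sum())


def pam_fit(train: ExpressionMatrix, k: int, seed: int | None = None) -> PamModel:
    """Classic PAM: greedy BUILD seeding then best-improvement SWAP.

    Samples are the points, with Euclidean distance in gene space.  The
    algorithm is deterministic given input order (``seed`` is accepted for
    interface symmetry but unused); the final cost is a local optimum under
    single medoid/non-medoid swaps.
    """
    n = train.n_samples
    if not 2 <= k <= n:
        raise ValueError(f"need 2 <= k <= n samples, got k={k}, n={n}")
    X = train.values.T
    D = cdist(X, X)

    # BUILD: first medoid minimizes total distance; each next greedily
    # maximizes the cost reduction.
    medoids = [int(np.argmin(D.sum(axis=1)))]
    nearest = D[:, medoids[0]].copy()
    while len(medoids) < k:
        gain = np.maximum(nearest[:, None] - D, 0.0).sum(axis=0)
        gain[medoids] = -1.0
        best = int(np.argmax(gain))
        medoids.append(best)
        nearest = np.minimum(nearest, D[:, best])

    # SWAP: accept the best strictly improving swap until none remains.
    cost = _pam_cost(D, medoids)
    improved = True
    while improved:
        improved = False
        best_cost, best_swap = cost, None
        in_medoids = set(medoids)
        for mi, m in enumerate(medoids):
            others = [md for md in medoids if md != m]
            base = D[:, others].min(axis=1) if others else np.full(n, np.inf)
            for h in range(n):
                if h in in_medoids:
                    continue
                c = float(np.minimum(base, D[:, h]).sum())
                if c < best_cost - 1e-12:
                    best_cost, best_swap = c, (mi, h)
        if best_swap is not None:
            medoids[best_swap[0]] = best_swap[1]
            cost = best_cost
            improved = True

    medoids_arr = np.array(medoids)
    labels = np.argmin(D[:, medoids_arr], axis=1)
    return PamModel(
        k=k,
        medoid_samples=train.values[:, medoids_arr].copy(),
        medoid_ids=[train.sample_ids[i] for i in medoids],
        gene_ids=list(train.gene_ids),
        labels=labels,
        cost=cost,
    )


def pam_assign(model: PamModel, test: ExpressionMatrix) -> np.ndarray:
    """Assign each test sample to its nearest medoid (ties -> lowest index)."""
    if list(test.gene_ids) != model.gene_ids:
        raise ValueError("test genes do not match the model's gene order")
    return np.argmin(cdist(test.values.T, model.medoid_samples.T), axis=1)


def cluster_majority_accuracy(clusters, truth) -> float:
    """Fraction of samples whose cluster's modal true class is their own.

    Modal-class ties within a cluster are broken alphabetically.
    """
    clusters = list(clusters)
    truth = [str(t) for t in truth]
    if len(clusters) == 0 or len(clusters) != len(truth):
        raise ValueError("clusters and truth must be equal-length, non-empty")
    correct = 0
    for c in set(clusters):
        members = [t for cl, t in zip(clusters, truth) if cl == c]
        counts = Counter(members)
        top = max(counts.values())
        modal = min(cls for cls, n in counts.items() if n == top)
        correct += counts[modal]
    return correct / len(truth)


# -- supervised ------------------------------------------------------------

@dataclass
class ClassifierModel:
    """L1 multinomial logistic model on the original feature scale."""

    classes: list[str]
    coefficients: np.ndarray  # n_classes x n_genes
    intercepts: np.ndarray  # n_classes
    penalty: float  # selected regularization strength (1/C)
    gene_ids: list[str]


def train_l1_multinomial(data: LabeledDataset, n_folds: int = 100,
                         seed: int = 0, n_penalties: int = 10) -> ClassifierModel:
    """Fit L1-penalized multinomial logistic regression.

    Features are standardized internally; the penalty is chosen over a
    descending path as the minimizer of mean cross-validated multinomial
    deviance, the model is refit on all data at that penalty, and the
    coefficients are returned on the original scale.  ``n_folds`` is capped
    (with a warning) at the smallest class size so folds stay stratifiable.
    """
    from sklearn.linear_model import LogisticRegressionCV
    from sklearn.model_selection import StratifiedKFold

    y = np.array(data.labels)
    classes = sorted(set(y))
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    min_class = min(Counter(y).values())
    folds = min(n_folds, min_class)
    if folds < n_folds:
        warnings.warn(
            f"n_folds capped at smallest class size ({folds})", RuntimeWarning,
            stacklevel=2,
        )
    if folds < 2:
        raise ValueError("need at least 2 samples in every class")

    X = data.matrix.values.T
    mean = X.mean(axis=0)
    scale = X.std(axis=0)
    scale[scale == 0] = 1.0
    Xs = (X - mean) / scale

    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    clf = LogisticRegressionCV(
        Cs=np.logspace(-3, 2, n_penalties),
        cv=cv,
        penalty="l1",
        solver="saga",
        scoring="neg_log_loss",
        max_iter=5000,
        tol=1e-4,
        random_state=seed,
        refit=True,
    )
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*onvergence.*")
        clf.fit(Xs, y)

    coef_std = clf.coef_
    intercept_std = clf.intercept_
    if coef_std.shape[0] == 1:  # binary: expand to one row per class
        coef_std = np.vstack([-coef_std[0], coef_std[0]])
        intercept_std = np.array([-intercept_std[0], intercept_std[0]])
    coef = coef_std / scale
    intercept = intercept_std - coef_std @ (mean / scale)
    return ClassifierModel(
        classes=[str(c) for c in clf.classes_],
        coefficients=coef,
        intercepts=intercept,
        penalty=float(1.0 / np.atleast_1d(clf.C_)[0]),
        gene_ids=list(data.matrix.gene_ids),
    )


def predict_classes(model: ClassifierModel, test: ExpressionMatrix) -> list[str]:
    """Argmax of class scores; ties go to the first class in model order."""
    if list(test.gene_ids) != model.gene_ids:
        raise ValueError("test genes do not match the model's gene order")
    scores = test.values.T @ model.coefficients.T + model.intercepts
    return [model.classes[i] for i in np.argmax(scores, axis=1)]


@dataclass
class EvaluationReport:
    """Agreement metrics between predicted and true class labels."""

    total_accuracy: float
    kappa: float
    balanced_accuracy: dict[str, float]
    no_information_rate: float
    confusion: pd.DataFrame  # rows = truth, cols = predicted

    def to_dict(self) -> dict:
        return {
            "total_accuracy": float(self.total_accuracy),
            "kappa": float(self.kappa),
            "balanced_accuracy": {k: float(v) for k, v in self.balanced_accuracy.items()},
            "no_information_rate": float(self.no_information_rate),
            "confusion": {t: {c: int(v) for c, v in row.items()}
                          for t, row in self.confusion.iterrows()},
        }


def score_predictions(pred, truth) -> EvaluationReport:
    """Total accuracy, Cohen's kappa, one-vs-rest balanced accuracy per
    class, no-information rate, and the confusion matrix.

    Kappa is ``(p_o - p_e) / (1 - p_e)`` with ``p_e`` from the product of
    marginals; when both sides are the same constant (``p_e = 1``) kappa is
    defined as 1.  Balanced accuracy is the mean of sensitivity and
    specificity with the class as positive.
    """
    pred = [str(p) for p in pred]
    truth = [str(t) for t in truth]
    if len(pred) == 0 or len(pred) != len(truth):
        raise ValueError("pred and truth must be equal-length, non-empty")
    classes = sorted(set(pred) | set(truth))
    n = len(truth)
    conf = pd.DataFrame(0, index=classes, columns=classes, dtype=int)
    for t, p in zip(truth, pred):
        conf.loc[t, p] += 1
    C = conf.to_numpy()
    p_o = np.trace(C) / n
    p_e = float((C.sum(axis=1) / n) @ (C.sum(axis=0) / n))
    kappa = 1.0 if p_e >= 1.0 else (p_o - p_e) / (1.0 - p_e)
    bacc = {}
    for i, cls in enumerate(classes):
        tp = C[i, i]
        fn = C[i, :].sum() - tp
        fp = C[:, i].sum() - tp
        tn = n - tp - fn - fp
        sens = tp / (tp + fn) if tp + fn > 0 else np.nan
        spec = tn / (tn + fp) if tn + fp > 0 else np.nan
        bacc[cls] = (sens + spec) / 2.0
    nir = max(Counter(truth).values()) / n
    return EvaluationReport(
        total_accuracy=float(p_o),
        kappa=float(kappa),
        balanced_accuracy=bacc,
        no_information_rate=float(nir),
        confusion=conf,
    )


# -- distributional diagnostics -------------------------------------------

def variability_f_score(data: LabeledDataset, n_quantiles: int = 100) -> float:
    """Between-class vs within-class variability of per-sample distributions.

    Each sample is summarized by ``n_quantiles`` empirical quantiles; at
    each quantile position a one-way ANOVA ratio of between-class to
    within-class mean squares is computed across samples, and the ratios
    are averaged over positions.  A score near 1 means class membership
    does not move the samples' distributions; >> 1 means it does, in which
    case quantile-style normalization risks removing that signal.
    """
    y = np.array(data.labels)
    classes = sorted(set(y))
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    counts = Counter(y)
    if min(counts.values()) < 2:
        raise ValueError("every class needs at least 2 samples")
    qs = np.linspace(0.0, 1.0, n_quantiles)
    Q = np.quantile(data.matrix.values, qs, axis=0)  # n_quantiles x n_samples
    n = len(y)
    k = len(classes)
    grand = Q.mean(axis=1)
    ssb = np.zeros(n_quantiles)
    ssw = np.zeros(n_quantiles)
    for cls in classes:
        block = Q[:, y == cls]
        m = block.mean(axis=1)
        ssb += block.shape[1] * (m - grand) ** 2
        ssw += ((block - m[:, None]) ** 2).sum(axis=1)
    msb = ssb / (k - 1)
    msw = ssw / (n - k)
    valid = msw > 0
    if not np.any(valid):
        raise ValueError("within-class variability is zero at every quantile")
    return float(np.mean(msb[valid] / msw[valid]))


def mean_kendall_tau(a: ExpressionMatrix, b: ExpressionMatrix) -> float:
    """Mean per-sample Kendall's tau-b between matched columns.

    Tau-b's tie correction matters because rounded RNA-seq-like data
    contain ties (notably at zero after noise flooring).
    """
    if a.values.shape != b.values.shape:
        raise ValueError("matrices must have identical dimensions")
    taus = [
        kendalltau(a.values[:, j], b.values[:, j]).statistic
        for j in range(a.n_samples)
    ]
    return float(np.mean(taus))


# -- benchmarks ------------------------------------------------------------

def _apply_method(method: str, noisy: ExpressionMatrix,
                  params: TdmParameters, target: TargetDistribution) -> ExpressionMatrix:
    if method == "tdm":
        return tdm_transform(noisy, params)
    if method == "qn":
        return quantile_normalize_to_target(noisy, target)
    if method == "npn":
        return npn_transform(noisy)
    if method == "log2":
        return log2_transform(noisy, 1.0)
    if method == "untransformed":
        return noisy
    raise ValueError(f"unknown method {method!r}; choose from {NORMALIZATION_METHODS}")


def run_noise_sweep_benchmark(cfg: SimulationConfig,
                              ladder: NoiseLadder | None = None,
                              methods=NORMALIZATION_METHODS,
                              seed: int | None = None,
                              refit: bool = False) -> pd.DataFrame:
    """Clustering accuracy of each normalization across the noise ladder.

    Simulates matched microarray / RNA-seq-like data, fits PAM
    (k = number of conditions) on the microarray-like matrix, then for
    every noise level and method normalizes the noisy RNA-seq-like matrix
    (TDM and QN use the microarray data as reference; NPN and log2 stand
    alone), assigns samples to the trained medoids (or refits PAM per
    normalized dataset when ``refit``), and scores cluster-majority
    accuracy.  Because the nonparanormal places data on a Gaussian-score
    scale, its reference PAM is fit on the NPN-transformed training matrix
    (both sides of the comparison are transformed).  Returns a tidy frame
    with columns ``noise_pct, method, accuracy``.
    """
    if ladder is None:
        ladder = NoiseLadder()
    for m in methods:
        if m not in NORMALIZATION_METHODS:
            raise ValueError(f"unknown method {m!r}")
    if seed is not None:
        cfg = replace(cfg, seed=seed)
    micro = simulate_microarray(cfg)
    rnaseq = to_rnaseq_like(micro.matrix, cfg.rnaseq_max)
    params = summarize_training(micro.matrix)
    target = build_target(micro.matrix)
    model = pam_fit(micro.matrix, k=cfg.n_conditions)
    npn_model = (
        pam_fit(npn_transform(micro.matrix), k=cfg.n_conditions)
        if "npn" in methods and not refit else None
    )
    noisy_ladder = make_noise_ladder(rnaseq, ladder, seed=cfg.seed + 1)
    rows = []
    for pct, noisy in zip(ladder.percentages, noisy_ladder):
        for method in methods:
            normalized = _apply_method(method, noisy, params, target)
            if refit:
                local = pam_fit(normalized, k=cfg.n_conditions)
                clusters = local.labels
            else:
                ref = npn_model if method == "npn" else model
                clusters = pam_assign(ref, normalized)
            acc = cluster_majority_accuracy(clusters, micro.labels)
            rows.append({"noise_pct": pct, "method": method, "accuracy": acc})
    return pd.DataFrame(rows)


def run_transfer_benchmark(cfg: SimulationConfig, noise_pct: float,
                           methods=NORMALIZATION_METHODS, n_folds: int = 20,
                           seed: int | None = None) -> pd.DataFrame:
    """Supervised platform transfer at one noise level.

    Trains the L1 multinomial classifier on the microarray-like matrix and
    scores its predictions on the noisy RNA-seq-like matrix under each
    normalization.  Returns a tidy frame with columns ``method,
    total_accuracy, kappa, no_information_rate``.
    """
    if seed is not None:
        cfg = replace(cfg, seed=seed)
    micro = simulate_microarray(cfg)
    rnaseq = to_rnaseq_like(micro.matrix, cfg.rnaseq_max)
    noisy = add_noise(rnaseq, noise_pct, cfg.seed + 1)
    params = summarize_training(micro.matrix)
    target = build_target(micro.matrix)
    clf = train_l1_multinomial(micro, n_folds=n_folds, seed=cfg.seed)
    rows = []
    for method in methods:
        normalized = _apply_method(method, noisy, params, target)
        pred = predict_classes(clf, normalized)
        report = score_predictions(pred, micro.labels)
        rows.append({
            "method": method,
            "total_accuracy": report.total_accuracy,
            "kappa": report.kappa,
            "no_information_rate": report.no_information_rate,
        })
    return pd.DataFrame(rows)
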