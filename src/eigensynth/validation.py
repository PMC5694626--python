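"""Evaluation battery for synthetic datasets.

Four kinds of checks, mirroring how generative neuroimaging models are
validated against a cohort:

* **Voxels-as-features (VAF) classification** — a linear-kernel SVM on raw
  voxel intensities, nested cross-validation (stratified outer folds, the
  regularization constant C chosen by an inner grid search on the
  training portion only). Reports accuracy / sensitivity / specificity
  with across-fold standard deviations.
* **Generalization experiment** — inside each outer fold, a generative
  model is fitted on the real training portion only, a synthetic training
  set is drawn from it, the classifier is trained on the synthetic images
  and tested on the held-out real fold. No held-out subject ever touches
  the basis, the densities or any training statistic.
* **Resubstitution experiment** — a classifier trained on all real data
  is evaluated (a) on that same data (resubstitution accuracy, near 1 for
  separable problems) and (b) on a synthetic set generated from the very
  same data. The gap between the two measures how dependent the
  synthetic images are on their source.
* **Mass-univariate two-sample t-maps** with family-wise-error control by
  Bonferroni or by the permutation max-|t| null distribution. (The
  random-field-theory thresholds of common SPM pipelines need smoothness
  estimation that is out of scope here; Bonferroni is conservative,
  permutation maxT is exact under exchangeability.)

The optimal-truncation rule is the one used to pick L: the largest L
whose generalization accuracy stays within one standard deviation of the
real-data baseline.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.exceptions import ConvergenceWarning
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.svm import SVC

from .io_imaging import VoxelDataset
from .synthesis import fit_generative_model, synthesize_classes

__all__ = [
    "ClassifierReport",
    "TMapResult",
    "ConfigurationError",
    "DEFAULT_C_GRID",
    "vaf_cross_validate",
    "experiment_generalization",
    "experiment_resubstitution",
    "select_optimal_L",
    "class_mean_separation",
    "tmap_two_sample",
]

logger = logging.getLogger(__name__)

DEFAULT_C_GRID = (0.01, 0.1, 1.0, 10.0, 100.0)

#: iteration budget for the libsvm solver. Rank-deficient training sets
#: (synthetic images at small L) can otherwise spin near-indefinitely at
#: large C while the decision function has long stabilized.
SVM_MAX_ITER = 100_000


class ConfigurationError(ValueError):
    """Fold/class configuration is unsatisfiable (e.g. class smaller than folds)."""


@dataclass
class ClassifierReport:
    """Fold-aggregated VAF metrics; class_a is the positive class."""

    accuracy: float
    sensitivity: float
    specificity: float
    accuracy_sd: float
    sensitivity_sd: float
    specificity_sd: float
    fold_accuracy: np.ndarray
    fold_sensitivity: np.ndarray
    fold_specificity: np.ndarray
    chosen_C: list = field(default_factory=list)
    positive_class: object = None
    negative_class: object = None

    @property
    def n_folds(self) -> int:
        return len(self.fold_accuracy)

    def __str__(self) -> str:  # Table-style one-liner
        return (
            f"acc {self.accuracy:.3f} [{self.accuracy_sd:.3f}]  "
            f"sens {self.sensitivity:.3f} [{self.sensitivity_sd:.3f}]  "
            f"spec {self.specificity:.3f} [{self.specificity_sd:.3f}]"
        )


def _report_from_folds(acc, sens, spec, chosen_C, class_a, class_b) -> ClassifierReport:
    acc = np.asarray(acc, dtype=float)
    sens = np.asarray(sens, dtype=float)
    spec = np.asarray(spec, dtype=float)
    sd = (lambda v: float(v.std(ddof=1)) if v.size > 1 else 0.0)
    return ClassifierReport(
        accuracy=float(acc.mean()),
        sensitivity=float(sens.mean()),
        specificity=float(spec.mean()),
        accuracy_sd=sd(acc),
        sensitivity_sd=sd(sens),
        specificity_sd=sd(spec),
        fold_accuracy=acc,
        fold_sensitivity=sens,
        fold_specificity=spec,
        chosen_C=list(chosen_C),
        positive_class=class_a,
        negative_class=class_b,
    )


def _binary_subset(dataset: VoxelDataset, class_a, class_b):
    rows = np.concatenate([dataset.class_rows(class_a), dataset.class_rows(class_b)])
    sub = dataset.subset(np.sort(rows))
    y = (sub.labels == class_a).astype(int)  # positive class = class_a (disease)
    return sub, y


def _fit_inner_svm(x, y, c_grid, inner_folds: int, seed: int) -> GridSearchCV:
    inner = StratifiedKFold(n_splits=inner_folds, shuffle=True, random_state=seed)
    search = GridSearchCV(
        SVC(kernel="linear", max_iter=SVM_MAX_ITER), {"C": list(c_grid)},
        cv=inner, scoring="accuracy", n_jobs=None,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        search.fit(x, y)
    return search


def _binary_metrics(y_true, y_pred) -> tuple[float, float, float]:
    acc = float(np.mean(y_true == y_pred))
    pos = y_true == 1
    neg = ~pos
    sens = float(np.mean(y_pred[pos] == 1)) if pos.any() else np.nan
    spec = float(np.mean(y_pred[neg] == 0)) if neg.any() else np.nan
    return acc, sens, spec


def vaf_cross_validate(
    dataset: VoxelDataset,
    class_a,
    class_b,
    folds: int = 10,
    inner_folds: int = 5,
    c_grid=DEFAULT_C_GRID,
    seed: int = 0,
) -> ClassifierReport:
    """Nested-CV linear SVM on raw voxel intensities (class_a positive)."""
    sub, y = _binary_subset(dataset, class_a, class_b)
    counts = np.bincount(y)
    if counts.min() < folds:
        raise ConfigurationError(
            f"smallest class has {counts.min()} subjects; cannot run {folds}-fold CV"
        )
    outer = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    accs, senss, specs, cs = [], [], [], []
    for train_idx, test_idx in outer.split(sub.data, y):
        search = _fit_inner_svm(sub.data[train_idx], y[train_idx], c_grid,
                                inner_folds, seed)
        pred = search.predict(sub.data[test_idx])
        a, s, p = _binary_metrics(y[test_idx], pred)
        accs.append(a)
        senss.append(s)
        specs.append(p)
        cs.append(search.best_params_["C"])
    return _report_from_folds(accs, senss, specs, cs, class_a, class_b)


def experiment_generalization(
    original: VoxelDataset,
    class_a,
    class_b,
    estimator: str = "mvn",
    L: int | None = None,
    n_per_class: int = 200,
    folds: int = 10,
    inner_folds: int = 5,
    c_grid=DEFAULT_C_GRID,
    seed: int = 0,
    force_alpha: float | None = None,
    fold_artifacts: list | None = None,
) -> ClassifierReport:
    """Train on synthetic images, test on held-out real images.

    Per outer fold, the eigenbrain basis and the class densities are
    fitted on the real training portion only; ``n_per_class`` images per
    class are synthesized from them and the SVM (inner-CV grid search
    included) sees only those synthetic images before predicting the
    held-out real fold.

    Passing a list as ``fold_artifacts`` records, per fold, the train/test
    indices, the synthetic training matrix and the fold accuracy — the
    hook by which the leakage contract (held-out data cannot influence
    the fold's generative model) is verified.
    """
    sub, y = _binary_subset(original, class_a, class_b)
    counts = np.bincount(y)
    if counts.min() < folds:
        raise ConfigurationError(
            f"smallest class has {counts.min()} subjects; cannot run {folds}-fold CV"
        )
    outer = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    accs, senss, specs, cs = [], [], [], []
    for fold, (train_idx, test_idx) in enumerate(outer.split(sub.data, y)):
        train = sub.subset(train_idx)
        fit_L = None if L is None else min(L, len(train_idx) - 1)
        if L is not None and fit_L != L:
            logger.info("fold %d: L capped at training rank %d", fold, fit_L)
        gen = fit_generative_model(train, estimator=estimator, L=fit_L,
                                   force_alpha=force_alpha)
        synth = synthesize_classes(
            gen, n_per_class, seed=(seed * 10007 + fold) % (2**31),
            classes=[class_a, class_b],
        )
        y_synth = (synth.labels == class_a).astype(int)
        search = _fit_inner_svm(synth.data, y_synth, c_grid, inner_folds, seed)
        pred = search.predict(sub.data[test_idx])
        a, s, p = _binary_metrics(y[test_idx], pred)
        accs.append(a)
        senss.append(s)
        specs.append(p)
        cs.append(search.best_params_["C"])
        if fold_artifacts is not None:
            fold_artifacts.append({
                "fold": fold,
                "train_idx": train_idx.copy(),
                "test_idx": test_idx.copy(),
                "synthetic_data": synth.data.copy(),
                "accuracy": a,
            })
    return _report_from_folds(accs, senss, specs, cs, class_a, class_b)


def experiment_resubstitution(
    original: VoxelDataset,
    class_a,
    class_b,
    estimator: str = "mvn",
    L: int | None = None,
    n_per_class: int = 200,
    n_repeats: int = 5,
    inner_folds: int = 5,
    c_grid=DEFAULT_C_GRID,
    seed: int = 0,
) -> tuple[ClassifierReport, ClassifierReport]:
    """Resubstitution accuracy vs accuracy on a synthetic test set.

    Returns (resubstitution report, synthetic-test report). The classifier
    is trained once on all real data of the two classes; the synthetic
    test sets are ``n_repeats`` independent draws from a generative model
    fitted on that same data, so the spread of the second report reflects
    synthesis variability only.
    """
    sub, y = _binary_subset(original, class_a, class_b)
    search = _fit_inner_svm(sub.data, y, c_grid, inner_folds, seed)
    a, s, p = _binary_metrics(y, search.predict(sub.data))
    resub = _report_from_folds([a], [s], [p], [search.best_params_["C"]],
                               class_a, class_b)

    gen = fit_generative_model(sub, estimator=estimator, L=L)
    accs, senss, specs = [], [], []
    for rep in range(n_repeats):
        synth = synthesize_classes(
            gen, n_per_class, seed=(seed * 10007 + 31 * rep + 1) % (2**31),
            classes=[class_a, class_b],
        )
        y_synth = (synth.labels == class_a).astype(int)
        a, s, p = _binary_metrics(y_synth, search.predict(synth.data))
        accs.append(a)
        senss.append(s)
        specs.append(p)
    synth_report = _report_from_folds(accs, senss, specs,
                                      [search.best_params_["C"]] * n_repeats,
                                      class_a, class_b)
    return resub, synth_report


def select_optimal_L(
    dataset: VoxelDataset,
    class_a,
    class_b,
    estimator: str = "mvn",
    L_grid=(5, 10, 20, 40),
    baseline: ClassifierReport | None = None,
    n_per_class: int = 200,
    folds: int = 10,
    seed: int = 0,
) -> tuple[int, pd.DataFrame]:
    """Largest L whose generalization accuracy stays within one SD of baseline.

    Returns the selected L and the full sweep table. When no candidate
    falls inside the baseline band, the L with accuracy closest to the
    baseline mean is returned with a logged warning.
    """
    if baseline is None:
        baseline = vaf_cross_validate(dataset, class_a, class_b, folds=folds, seed=seed)
    lo = baseline.accuracy - baseline.accuracy_sd
    hi = baseline.accuracy + baseline.accuracy_sd
    rows = []
    for L in sorted(set(int(l) for l in L_grid)):
        report = experiment_generalization(
            dataset, class_a, class_b, estimator=estimator, L=L,
            n_per_class=n_per_class, folds=folds, seed=seed,
        )
        rows.append({
            "L": L,
            "accuracy": report.accuracy,
            "accuracy_sd": report.accuracy_sd,
            "in_band": lo <= report.accuracy <= hi,
        })
    sweep = pd.DataFrame(rows)
    in_band = sweep[sweep["in_band"]]
    if len(in_band):
        chosen = int(in_band["L"].max())
    else:
        chosen = int(sweep.loc[(sweep["accuracy"] - baseline.accuracy).abs().idxmin(), "L"])
        logger.warning(
            "no L in the baseline band [%.3f, %.3f]; falling back to closest L=%d",
            lo, hi, chosen,
        )
    return chosen, sweep


def class_mean_separation(density_a, density_b, debias: bool = True) -> float:
    """Euclidean distance between two fitted class latent means.

    The naive norm ||mu_a - mu_b|| is upward-biased: each sample mean
    carries within-class variance, so E||m_a - m_b||^2 exceeds the true
    squared separation by tr(Sigma_a)/K_a + tr(Sigma_b)/K_b. With
    ``debias`` (default) that term, estimated from the fitted
    covariances, is subtracted before the square root.
    """
    diff2 = float(np.sum((density_a.mu - density_b.mu) ** 2))
    if debias:
        diff2 -= float(np.trace(density_a.sigma)) / density_a.K_c
        diff2 -= float(np.trace(density_b.sigma)) / density_b.K_c
    return float(np.sqrt(max(diff2, 0.0)))


# ---------------------------------------------------------------------------
# mass-univariate two-sample t-maps


@dataclass
class TMapResult:
    """Voxelwise two-sample t statistics with an FWE-corrected threshold.

    ``significant_mask`` is true exactly where |t| > threshold (two-sided
    convention).
    """

    t_values: np.ndarray
    threshold: float
    significant_mask: np.ndarray
    correction: str
    alpha: float
    df: int

    @property
    def n_significant(self) -> int:
        return int(self.significant_mask.sum())


def _two_sample_t(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pooled-variance t per voxel, df = K_a + K_b - 2; 0/0 -> t = 0."""
    ka, kb = a.shape[0], b.shape[0]
    va = a.var(axis=0, ddof=1)
    vb = b.var(axis=0, ddof=1)
    pooled = ((ka - 1) * va + (kb - 1) * vb) / (ka + kb - 2)
    denom = np.sqrt(pooled * (1.0 / ka + 1.0 / kb))
    diff = a.mean(axis=0) - b.mean(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(denom > 0, diff / denom, 0.0)
    return t


def tmap_two_sample(
    group_a: np.ndarray,
    group_b: np.ndarray,
    correction: str = "permutation",
    alpha: float = 0.05,
    n_perm: int = 1000,
    seed: int = 0,
) -> TMapResult:
    """Two-sample t-map with family-wise error control.

    ``bonferroni``: the threshold is the two-sided t quantile at alpha/N
    with N the number of voxels. ``permutation``: the threshold is the
    (1 - alpha) quantile of the max-|t| distribution over ``n_perm``
    random relabelings of the pooled subjects (exact FWE under
    exchangeability). Zero-variance voxels get t = 0 by convention.
    """
    if isinstance(group_a, VoxelDataset):
        group_a = group_a.data
    if isinstance(group_b, VoxelDataset):
        group_b = group_b.data
    a = np.atleast_2d(np.asarray(group_a, dtype=np.float64))
    b = np.atleast_2d(np.asarray(group_b, dtype=np.float64))
    if a.shape[1] != b.shape[1]:
        raise ValueError("groups must have equal voxel counts")
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise ValueError("each group needs at least 2 subjects")
    ka, kb = a.shape[0], b.shape[0]
    n_vox = a.shape[1]
    df = ka + kb - 2
    t = _two_sample_t(a, b)

    if correction == "bonferroni":
        threshold = float(stats.t.ppf(1.0 - alpha / (2.0 * n_vox), df))
    elif correction == "permutation":
        rng = np.random.default_rng(seed)
        pooled = np.vstack([a, b])
        null_max = np.empty(n_perm)
        for i in range(n_perm):
            perm = rng.permutation(ka + kb)
            null_max[i] = np.abs(
                _two_sample_t(pooled[perm[:ka]], pooled[perm[ka:]])
            ).max()
        threshold = float(np.quantile(null_max, 1.0 - alpha, method="higher"))
    else:
        raise ValueError(f"correction must be 'bonferroni' or 'permutation', got {correction!r}")

    significant = np.abs(t) > threshold
    return TMapResult(
        t_values=t,
        threshold=threshold,
        significant_mask=significant,
        correction=correction,
        alpha=alpha,
        df=df,
    )
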