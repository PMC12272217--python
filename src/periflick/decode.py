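"""Single-trial decoding of attended side and permutation-calibrated chance.

Features are the amplitudes of the two RESS components (13 and 15 Hz tag
filters) over the cue phase of each trial.  A linear discriminant with
pooled within-class covariance is scored by stratified five-fold
cross-validation; statistical significance of the observed accuracy is
calibrated against an empirical null distribution obtained by re-scoring
200 random label permutations of the same dataset, whose 95th and 99th
percentiles define the alpha = .05 / .01 significance boundaries.

The cross-validated discriminant is evaluated by an internal vectorised
implementation whose predictions match scikit-learn's
``LinearDiscriminantAnalysis`` (asserted in the test suite); the
permutation loop would be prohibitively slow through the estimator API.
``engine='sklearn'`` routes scoring through scikit-learn directly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import Epochs
from .ress import RESSFilter, apply_filter, gaussian_bandpass

__all__ = [
    "ClassificationResult",
    "PhaseThreshold",
    "extract_features",
    "features_to_xy",
    "fit_phase_threshold",
    "lda_crossval",
    "permutation_null",
]


@dataclass
class ClassificationResult:
    """Cross-validated accuracy with (optionally) its permutation null.

    Accuracies are percentages.  ``boundary_95``/``boundary_99`` are the
    95th/99th percentiles of the null distribution; the observed accuracy
    is significant only when *strictly above* the boundary.
    """

    fold_accuracies: np.ndarray
    mean_accuracy: float
    seed: int | None = None
    null_distribution: np.ndarray | None = field(default=None, repr=False)
    boundary_95: float | None = None
    boundary_99: float | None = None
    significant_05: bool | None = None
    significant_01: bool | None = None
    n_perm: int = 0


@dataclass
class PhaseThreshold:
    """Baseline-vs-task SNR cutoff from a shallow decision tree.

    The tree (depth <= 2, at most two features considered) is fitted on
    pooled single-trial SNR values from the fixation phase versus the cue
    and target phases; the reported scalar threshold is the root-node
    split, i.e. the horizontal line separating baseline from entrained
    activity.
    """

    threshold: float
    condition: str | None = None
    accuracy: float = 0.0
    informative: bool = True
    splits: list[dict] = field(default_factory=list, repr=False)


def extract_features(
    epochs: Epochs,
    filters: dict[float, RESSFilter] | list[RESSFilter],
    window: tuple[float, float] | None = None,
    fwhm: float = 1.0,
) -> pd.DataFrame:
    """Per-trial RESS component amplitudes over the cue phase.

    For each tag-frequency filter, the component time series is narrowband
    filtered at the filter's target frequency and its RMS over the cue
    window taken as the trial's amplitude.  Returns one row per trial with
    columns ``amp_<freq>`` per filter plus the trial metadata (``side``,
    ``condition``, ``trial``).
    """
    if isinstance(filters, dict):
        filters = list(filters.values())
    if not filters:
        raise ValueError("at least one fitted RESS filter is required")
    if window is None:
        cue = epochs.phase_onsets.get("cue", 3.0)
        target = epochs.phase_onsets.get("target", cue + 3.0)
        window = (cue, target)
    sl = epochs.time_slice(*window)
    if sl.stop <= sl.start:
        raise ValueError("feature window outside epochs")

    out = epochs.metadata.copy().reset_index(drop=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        for filt in filters:
            comp = apply_filter(epochs, filt)
            narrow = gaussian_bandpass(comp, filt.target_freq, fwhm, epochs.sfreq)
            amp = np.sqrt(np.mean(narrow[:, sl] ** 2, axis=1))
            out[f"amp_{filt.target_freq:g}"] = amp
    return out


def features_to_xy(
    features: pd.DataFrame, label_col: str = "side"
) -> tuple[np.ndarray, np.ndarray]:
    """Feature matrix (amplitude columns) and binary label vector."""
    amp_cols = [c for c in features.columns if c.startswith("amp_")]
    X = features[amp_cols].to_numpy(dtype=float)
    labels = features[label_col].to_numpy()
    classes = np.unique(labels)
    if len(classes) != 2:
        raise ValueError(f"need exactly 2 classes, got {list(classes)}")
    y = (labels == classes[1]).astype(int)
    return X, y


# ---------------------------------------------------------------------------
# linear discriminant scoring


def _stratified_folds(y: np.ndarray, n_splits: int, rng: np.random.Generator):
    """Seeded stratified fold assignment; yields (train_idx, test_idx)."""
    y = np.asarray(y)
    fold_of = np.empty(len(y), dtype=int)
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        idx = rng.permutation(idx)
        fold_of[idx] = np.arange(len(idx)) % n_splits
    for k in range(n_splits):
        test = np.flatnonzero(fold_of == k)
        train = np.flatnonzero(fold_of != k)
        yield train, test


def _lda_predict(Xtr: np.ndarray, ytr: np.ndarray, Xte: np.ndarray) -> np.ndarray:
    """Pooled-covariance linear discriminant prediction (binary labels 0/1)."""
    mu0 = Xtr[ytr == 0].mean(axis=0)
    mu1 = Xtr[ytr == 1].mean(axis=0)
    d0 = Xtr[ytr == 0] - mu0
    d1 = Xtr[ytr == 1] - mu1
    cov = (d0.T @ d0 + d1.T @ d1) / (len(ytr) - 2)
    cov_inv = np.linalg.pinv(cov)
    p1 = (ytr == 1).mean()
    w = cov_inv @ (mu1 - mu0)
    b = (
        -0.5 * (mu1 @ cov_inv @ mu1 - mu0 @ cov_inv @ mu0)
        + np.log(p1 / (1 - p1))
    )
    return (Xte @ w + b > 0).astype(int)


def _sklearn_predict(Xtr: np.ndarray, ytr: np.ndarray, Xte: np.ndarray) -> np.ndarray:
    from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

    return LinearDiscriminantAnalysis().fit(Xtr, ytr).predict(Xte)


def _cv_accuracies(
    X: np.ndarray,
    y: np.ndarray,
    rng: np.random.Generator,
    n_splits: int,
    engine: str,
) -> np.ndarray:
    predict = _lda_predict if engine == "numpy" else _sklearn_predict
    accs = []
    for train, test in _stratified_folds(y, n_splits, rng):
        if len(np.unique(y[train])) < 2 or len(test) == 0:
            raise ValueError(
                "a fold lost a class; reduce n_splits or rebalance labels"
            )
        accs.append(float((predict(X[train], y[train], X[test]) == y[test]).mean()))
    return np.asarray(accs)


def lda_crossval(
    X: np.ndarray,
    y: np.ndarray,
    seed: int | None = 0,
    n_splits: int = 5,
    engine: str = "numpy",
) -> ClassificationResult:
    """Stratified k-fold cross-validated LDA accuracy (percent).

    Folds are stratified (class proportions preserved) and shuffled under
    the given seed, so a fixed seed yields identical fold assignments and
    an identical result.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if len(X) != len(y):
        raise ValueError("X and y must have equal length")
    if len(X) < 2 * n_splits:
        raise ValueError(f"need at least {2 * n_splits} trials for {n_splits} folds")
    if len(np.unique(y)) != 2:
        raise ValueError("labels must be binary")
    if engine not in ("numpy", "sklearn"):
        raise ValueError("engine must be 'numpy' or 'sklearn'")
    rng = np.random.default_rng(seed)
    accs = _cv_accuracies(X, y, rng, n_splits, engine)
    return ClassificationResult(
        fold_accuracies=accs * 100.0,
        mean_accuracy=float(accs.mean() * 100.0),
        seed=seed,
    )


def permutation_null(
    X: np.ndarray,
    y: np.ndarray,
    n_perm: int = 200,
    seed: int | None = 0,
    n_splits: int = 5,
    engine: str = "numpy",
) -> ClassificationResult:
    """Observed accuracy with its label-permutation null distribution.

    Each of the ``n_perm`` permutations fully shuffles the labels
    (preserving class counts), re-draws the cross-validation folds, and is
    scored exactly like the observed data.  The empirical 95th and 99th
    percentiles (linear interpolation) of the null become the significance
    boundaries; the observed accuracy is flagged significant only when
    strictly above them.
    """
    if n_perm < 20:
        warnings.warn(
            f"n_perm={n_perm} gives unstable tail percentiles",
            RuntimeWarning,
            stacklevel=2,
        )
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    rng = np.random.default_rng(seed)
    observed = _cv_accuracies(X, y, rng, n_splits, engine).mean() * 100.0
    null = np.empty(n_perm)
    for i in range(n_perm):
        y_perm = rng.permutation(y)
        null[i] = _cv_accuracies(X, y_perm, rng, n_splits, engine).mean() * 100.0
    b95, b99 = np.percentile(null, [95, 99])
    return ClassificationResult(
        fold_accuracies=np.array([observed]),
        mean_accuracy=float(observed),
        seed=seed,
        null_distribution=null,
        boundary_95=float(b95),
        boundary_99=float(b99),
        significant_05=bool(observed > b95),
        significant_01=bool(observed > b99),
        n_perm=n_perm,
    )


def fit_phase_threshold(
    fixation_snr: np.ndarray,
    task_snr: np.ndarray,
    condition: str | None = None,
    seed: int = 0,
) -> PhaseThreshold:
    """SNR cutoff between fixation baseline and cue/target entrainment.

    A decision tree of maximal depth 2, considering at most two features,
    is trained on pooled single-trial SNR values (fixation phase = class 0,
    cue/target phases = class 1); the root-node split value is reported as
    the threshold.  A threshold from statistically indistinguishable
    classes is flagged uninformative.
    """
    from sklearn.tree import DecisionTreeClassifier

    fixation_snr = np.asarray(fixation_snr, dtype=float).reshape(len(fixation_snr), -1)
    task_snr = np.asarray(task_snr, dtype=float).reshape(len(task_snr), -1)
    if len(fixation_snr) == 0 or len(task_snr) == 0:
        raise ValueError("both phases need at least one trial")
    X = np.vstack([fixation_snr, task_snr])
    y = np.concatenate([np.zeros(len(fixation_snr)), np.ones(len(task_snr))])
    if np.ptp(X) == 0:
        raise ValueError("degenerate input: all SNR values identical")

    tree = DecisionTreeClassifier(
        max_depth=2, max_features=min(2, X.shape[1]), random_state=seed
    ).fit(X, y)
    root_threshold = tree.tree_.threshold[0]
    if root_threshold == -2:  # leaf-only tree: no split found
        raise ValueError("decision tree found no split between phases")
    accuracy = float((tree.predict(X) == y).mean())
    splits = [
        {"node": int(i), "feature": int(f), "threshold": float(t)}
        for i, (f, t) in enumerate(zip(tree.tree_.feature, tree.tree_.threshold))
        if f >= 0
    ]
    return PhaseThreshold(
        threshold=float(root_threshold),
        condition=condition,
        accuracy=accuracy,
        informative=accuracy >= 0.6,
        splits=splits,
    )
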