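"""Alert/fatigue classification: RFE feature selection, grid-searched SVM,
repeated two-fold cross-validation, permutation significance, and the
condition-contrast report.

The modelling surface follows the estimator/results convention:
``FatigueClassifier`` is built from a :class:`LabeledFeatures` table and
``fit()`` returns a :class:`ClassificationResults` object carrying metric
distributions over cross-validation repetitions, a ``summary()`` table and
the permutation test.

The paired design (each subject contributes one alert and one fatigue
sample) is respected throughout: folds split subjects, never a subject's
two samples, and the permutation null swaps labels within a subject's
pair.  A sample-level split and whole-dataset feature selection remain
available for comparison with protocols that selected features before
cross-validation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .parcellation import Atlas, map_roi_to_lobe

__all__ = [
    "LabeledFeatures",
    "ClassificationResults",
    "FatigueClassifier",
    "PermutationResult",
    "ContrastReport",
    "DEFAULT_GRID",
    "rfe_select",
    "feature_count_sweep",
    "grid_search_svm",
    "repeated_twofold_cv",
    "permutation_test",
    "permutation_pvalue",
    "condition_contrast",
]

#: kernel/cost/width grid searched when no grid is supplied
DEFAULT_GRID: list[dict] = [
    {"kernel": ["linear"], "C": [0.1, 1.0, 10.0, 100.0]},
    {"kernel": ["rbf"], "C": [0.1, 1.0, 10.0, 100.0],
     "gamma": ["scale", 0.01, 0.1, 1.0]},
]


# ---------------------------------------------------------------------------
# containers


@dataclass
class LabeledFeatures:
    """Samples x features with binary condition labels and subject pairing.

    ``y`` is 1 for fatigue (positive class) and 0 for alert.
    """

    X: np.ndarray
    y: np.ndarray
    subject_ids: np.ndarray
    feature_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=int)
        self.subject_ids = np.asarray(self.subject_ids)
        n = self.X.shape[0]
        if self.y.shape != (n,) or self.subject_ids.shape != (n,):
            raise ValueError("X, y and subject_ids disagree on sample count")
        if not np.all(np.isfinite(self.X)):
            raise ValueError("feature matrix contains missing/non-finite values")
        if not set(np.unique(self.y)) <= {0, 1}:
            raise ValueError("labels must be binary (0 = alert, 1 = fatigue)")
        if not self.feature_labels:
            self.feature_labels = [f"f{i}" for i in range(self.X.shape[1])]
        if len(self.feature_labels) != self.X.shape[1]:
            raise ValueError("feature_labels length does not match X columns")

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame,
                       label_col: str = "condition",
                       subject_col: str = "subject_id") -> "LabeledFeatures":
        """Build from a tidy frame with condition/subject columns."""
        y = df[label_col].map({"alert": 0, "fatigue": 1})
        if y.isna().any():
            raise ValueError("condition column must contain only alert/fatigue")
        feats = df.drop(columns=[label_col, subject_col])
        return cls(X=feats.to_numpy(), y=y.to_numpy(),
                   subject_ids=df[subject_col].to_numpy(),
                   feature_labels=list(feats.columns))

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    def select(self, idx) -> "LabeledFeatures":
        idx = np.asarray(idx, dtype=int)
        return LabeledFeatures(
            X=self.X[:, idx], y=self.y.copy(), subject_ids=self.subject_ids.copy(),
            feature_labels=[self.feature_labels[i] for i in idx],
        )

    def select_samples(self, idx) -> "LabeledFeatures":
        idx = np.asarray(idx, dtype=int)
        return LabeledFeatures(
            X=self.X[idx], y=self.y[idx], subject_ids=self.subject_ids[idx],
            feature_labels=list(self.feature_labels),
        )

    def with_labels(self, y: np.ndarray) -> "LabeledFeatures":
        return LabeledFeatures(X=self.X, y=np.asarray(y, dtype=int),
                               subject_ids=self.subject_ids,
                               feature_labels=list(self.feature_labels))


# ---------------------------------------------------------------------------
# RFE


def _linear_svm_weights(X: np.ndarray, y: np.ndarray, C: float) -> np.ndarray:
    from sklearn.svm import SVC

    clf = SVC(kernel="linear", C=C)
    clf.fit(X, y)
    return np.asarray(clf.coef_).ravel()


def rfe_select(
    data: LabeledFeatures,
    keep_fraction: float,
    step_fraction: float = 0.01,
    C: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Recursive feature elimination with a linear maximal-margin ranker.

    Repeatedly fits a linear SVM, ranks features by squared weight, and
    drops the lowest ``step_fraction`` of the *original* feature count per
    round until ``keep_fraction`` of the features remain.

    Returns
    -------
    selected : ndarray of int
        Indices of the surviving features, ascending.
    ranking : ndarray of int
        Elimination rank per feature: 1 = kept to the end; higher = dropped
        earlier.
    """
    if not (0 < keep_fraction <= 1):
        raise ValueError("keep_fraction must lie in (0, 1]")
    for label in (0, 1):
        if np.sum(data.y == label) < 2:
            raise ValueError("need at least 2 samples per class for RFE")
    n_total = data.n_features
    n_keep = int(round(keep_fraction * n_total))
    if n_keep < 1:
        raise ValueError(
            f"keep_fraction {keep_fraction} of {n_total} features keeps none"
        )
    step = max(1, int(round(step_fraction * n_total)))

    remaining = np.arange(n_total)
    ranking = np.ones(n_total, dtype=int)
    round_no = 0
    while remaining.size > n_keep:
        w2 = _linear_svm_weights(data.X[:, remaining], data.y, C) ** 2
        n_drop = min(step, remaining.size - n_keep)
        drop_local = np.argsort(w2, kind="stable")[:n_drop]
        round_no += 1
        ranking[remaining[drop_local]] = 1 + round_no
        remaining = np.delete(remaining, drop_local)
    # re-express ranks so earlier-dropped features rank higher
    if round_no:
        dropped = ranking > 1
        ranking[dropped] = 1 + (round_no + 2 - ranking[dropped])
    return remaining, ranking


def feature_count_sweep(
    data: LabeledFeatures,
    percentages: "list[int]",
    n_reps: int = 20,
    seed: int = 0,
    svm_params: "dict | None" = None,
    step_fraction: float = 0.05,
) -> pd.DataFrame:
    """Cross-validated accuracy as a function of the RFE retention level.

    For each percentage, features are selected once on the full data (the
    protocol this sweep emulates) and accuracy is estimated with repeated
    two-fold CV.  Returns a frame indexed by percentage with an
    ``accuracy`` column; the argmax row is the suggested operating point.
    """
    rows = []
    for pct in percentages:
        if not (1 <= pct <= 99):
            raise ValueError(f"percentage {pct} outside 1..99")
        sel, _ = rfe_select(data, keep_fraction=pct / 100.0,
                            step_fraction=step_fraction)
        res = repeated_twofold_cv(
            data.select(sel), n_reps=n_reps, seed=seed,
            svm_params=svm_params or {"kernel": "linear", "C": 1.0},
        )
        rows.append({"percentage": pct, "n_features": sel.size,
                     "accuracy": res.accuracy_mean})
    return pd.DataFrame(rows).set_index("percentage")


# ---------------------------------------------------------------------------
# SVM fitting


def grid_search_svm(
    X: np.ndarray,
    y: np.ndarray,
    grid: "list[dict] | dict | None" = None,
    inner_folds: int = 2,
    seed: int = 0,
):
    """Exhaustive grid search over SVM hyper-parameters.

    Ties in inner-CV accuracy are broken by grid order (first wins).
    Returns (fitted classifier refit on all of X/y, chosen parameter dict).
    """
    from sklearn.model_selection import GridSearchCV, StratifiedKFold
    from sklearn.svm import SVC

    if grid is None:
        grid = DEFAULT_GRID
    if isinstance(grid, dict):
        grid = [grid]
    if not grid or all(not g for g in grid):
        raise ValueError("parameter grid is empty")
    n_per_class = min(np.sum(y == 0), np.sum(y == 1))
    cv = StratifiedKFold(n_splits=min(inner_folds, max(2, n_per_class)),
                         shuffle=True, random_state=seed)
    gs = GridSearchCV(SVC(), grid, scoring="accuracy", cv=cv, refit=True)
    gs.fit(X, y)
    return gs.best_estimator_, dict(gs.best_params_)


# ---------------------------------------------------------------------------
# repeated two-fold CV


@dataclass
class ClassificationResults:
    """Metric distributions over cross-validation repetitions."""

    sensitivity: np.ndarray  # per repetition
    specificity: np.ndarray
    accuracy: np.ndarray
    best_params: list
    n_repetitions: int
    settings: dict = field(default_factory=dict)
    model: "FatigueClassifier | None" = None

    @property
    def sensitivity_mean(self) -> float:
        return float(self.sensitivity.mean())

    @property
    def specificity_mean(self) -> float:
        return float(self.specificity.mean())

    @property
    def accuracy_mean(self) -> float:
        return float(self.accuracy.mean())

    def summary(self) -> str:
        """Plain-text results table in percent, mean +- sd over repetitions."""
        lines = [
            "Alert/fatigue classification "
            f"({self.n_repetitions} x two-fold cross-validation)",
            "-" * 58,
            f"{'metric':<14}{'mean %':>10}{'sd %':>10}",
        ]
        for name, arr in (("sensitivity", self.sensitivity),
                          ("specificity", self.specificity),
                          ("accuracy", self.accuracy)):
            lines.append(f"{name:<14}{100 * arr.mean():>10.1f}{100 * arr.std():>10.1f}")
        for key, val in self.settings.items():
            lines.append(f"{key:<24}{val}")
        return "\n".join(lines)

    def plot_accuracy(self, ax=None):
        """Histogram of per-repetition accuracy."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.hist(self.accuracy, bins=20, range=(0, 1), color="steelblue")
        ax.axvline(self.accuracy_mean, color="k", ls="--",
                   label=f"mean = {self.accuracy_mean:.2f}")
        ax.set_xlabel("accuracy")
        ax.set_ylabel("repetitions")
        ax.legend()
        return ax


def _subject_twofold_split(
    data: LabeledFeatures, rng: np.random.Generator, subject_level: bool,
    max_attempts: int = 100,
) -> tuple[np.ndarray, np.ndarray]:
    """Random two-fold split; subject-level keeps each subject's pair together."""
    n = data.n_samples
    if subject_level:
        subjects = np.unique(data.subject_ids)
        perm = rng.permutation(subjects)
        half = len(subjects) // 2
        in_a = np.isin(data.subject_ids, perm[:half])
        return np.flatnonzero(in_a), np.flatnonzero(~in_a)
    for _ in range(max_attempts):
        perm = rng.permutation(n)
        a, b = perm[: n // 2], perm[n // 2 :]
        if len(set(data.y[a])) == 2 and len(set(data.y[b])) == 2:
            return np.sort(a), np.sort(b)
    raise RuntimeError(
        f"could not draw a two-fold split with both classes in each fold "
        f"after {max_attempts} attempts"
    )


def _fit_predict(
    train: LabeledFeatures,
    test: LabeledFeatures,
    svm_params: "dict | None",
    grid: "list[dict] | None",
    rfe_keep: "float | None",
    rfe_step: float,
    standardize: bool,
    seed: int,
) -> tuple[np.ndarray, "dict | None"]:
    """One fold: optional scaling + in-fold RFE + (grid-searched) SVM."""
    from sklearn.preprocessing import StandardScaler
    from sklearn.svm import SVC

    Xtr, Xte = train.X, test.X
    if standardize:
        scaler = StandardScaler().fit(Xtr)
        Xtr, Xte = scaler.transform(Xtr), scaler.transform(Xte)
    if rfe_keep is not None and rfe_keep < 1.0:
        sel, _ = rfe_select(
            LabeledFeatures(Xtr, train.y, train.subject_ids,
                            list(train.feature_labels)),
            keep_fraction=rfe_keep, step_fraction=rfe_step,
        )
        Xtr, Xte = Xtr[:, sel], Xte[:, sel]
    if grid is not None:
        clf, params = grid_search_svm(Xtr, train.y, grid, seed=seed)
    else:
        clf = SVC(**(svm_params or {"kernel": "linear", "C": 1.0}))
        clf.fit(Xtr, train.y)
        params = None
    return clf.predict(Xte), params


def repeated_twofold_cv(
    data: LabeledFeatures,
    n_reps: int = 1000,
    subject_level: bool = True,
    seed: int = 0,
    svm_params: "dict | None" = None,
    grid: "list[dict] | None" = None,
    rfe_keep: "float | None" = None,
    rfe_step: float = 0.01,
    standardize: bool = True,
) -> ClassificationResults:
    """Repeated two-fold cross-validation of the full decision pipeline.

    Per repetition the samples are split into two folds (subject-level by
    default); each fold serves once as the training set and once as the
    test set, confusion counts are pooled over both directions, and the
    metrics of the repetition are computed from the pooled counts.  Means
    over repetitions are the headline numbers.

    Selection (``rfe_keep``) and standardization are fit inside each
    training fold — no test-fold information reaches the model.
    """
    for label in (0, 1):
        if len(np.unique(data.subject_ids[data.y == label])) < 2:
            raise ValueError("need at least 2 subjects per class")
    rng = np.random.default_rng(seed)
    sens = np.empty(n_reps)
    spec = np.empty(n_reps)
    acc = np.empty(n_reps)
    chosen = []
    for rep in range(n_reps):
        fold_a, fold_b = _subject_twofold_split(data, rng, subject_level)
        tp = tn = fp = fn = 0
        rep_params = []
        for train_idx, test_idx in ((fold_a, fold_b), (fold_b, fold_a)):
            train, test = data.select_samples(train_idx), data.select_samples(test_idx)
            pred, params = _fit_predict(
                train, test, svm_params, grid, rfe_keep, rfe_step,
                standardize, seed=int(rng.integers(2**31)),
            )
            tp += int(np.sum((pred == 1) & (test.y == 1)))
            tn += int(np.sum((pred == 0) & (test.y == 0)))
            fp += int(np.sum((pred == 1) & (test.y == 0)))
            fn += int(np.sum((pred == 0) & (test.y == 1)))
            rep_params.append(params)
        sens[rep] = tp / (tp + fn) if tp + fn else np.nan
        spec[rep] = tn / (tn + fp) if tn + fp else np.nan
        acc[rep] = (tp + tn) / (tp + tn + fp + fn)
        chosen.append(rep_params)
    return ClassificationResults(
        sensitivity=sens, specificity=spec, accuracy=acc,
        best_params=chosen, n_repetitions=n_reps,
        settings={
            "subject_level_folds": subject_level,
            "standardize": standardize,
            "rfe_keep": rfe_keep,
            "grid": "searched" if grid is not None else (svm_params or "linear C=1"),
            "seed": seed,
        },
    )


# ---------------------------------------------------------------------------
# permutation test


@dataclass
class PermutationResult:
    p_value: float
    p_smoothed: float  # (b + 1) / (n + 1) estimate
    observed: float
    null_distribution: np.ndarray
    n_permutations: int

    def __str__(self) -> str:
        p = (f"< {1.0 / self.n_permutations:g}" if self.p_value == 0
             else f"= {self.p_value:g}")
        return (f"observed accuracy {self.observed:.3f}, permutation p {p} "
                f"({self.n_permutations} permutations)")


def permutation_pvalue(observed: float, null_values: np.ndarray) -> float:
    """Fraction of permuted statistics strictly better than the observed."""
    null_values = np.asarray(null_values, dtype=float)
    return float(np.sum(null_values > observed) / null_values.size)


def permutation_test(
    data: LabeledFeatures,
    n_perm: int = 1000,
    n_reps: int = 10,
    seed: int = 0,
    fast_mode: bool = False,
    **cv_kwargs,
) -> PermutationResult:
    """Label-permutation significance of the cross-validated accuracy.

    Labels are permuted within the paired structure: each subject's
    alert/fatigue pair is swapped with probability 1/2, preserving class
    balance and the pairing.  The observed statistic and every permuted
    statistic are mean accuracies over ``n_reps`` CV repetitions computed
    by the identical procedure.

    With ``fast_mode`` the feature set selected on the observed labels is
    frozen and reused for the permuted refits (cheaper, slightly
    anti-conservative about the selection step); by default any selection
    in ``cv_kwargs`` is re-run per permutation.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)

    eval_kwargs = dict(cv_kwargs)
    eval_data = data
    if fast_mode and cv_kwargs.get("rfe_keep") is not None:
        sel, _ = rfe_select(data, keep_fraction=cv_kwargs["rfe_keep"],
                            step_fraction=cv_kwargs.get("rfe_step", 0.01))
        eval_data = data.select(sel)
        eval_kwargs["rfe_keep"] = None

    def statistic(d: LabeledFeatures, stat_seed: int) -> float:
        return repeated_twofold_cv(d, n_reps=n_reps, seed=stat_seed,
                                   **eval_kwargs).accuracy_mean

    observed = statistic(eval_data, int(rng.integers(2**31)))
    subjects = np.unique(data.subject_ids)
    null = np.empty(n_perm)
    for b in range(n_perm):
        flip = subjects[rng.random(subjects.size) < 0.5]
        y_perm = np.where(np.isin(data.subject_ids, flip), 1 - data.y, data.y)
        null[b] = statistic(eval_data.with_labels(y_perm), int(rng.integers(2**31)))
    p = permutation_pvalue(observed, null)
    return PermutationResult(
        p_value=p,
        p_smoothed=float((np.sum(null > observed) + 1) / (n_perm + 1)),
        observed=observed, null_distribution=null, n_permutations=n_perm,
    )


# ---------------------------------------------------------------------------
# model / results front end


class FatigueClassifier:
    """SVM alert/fatigue model over a connectivity or spectral feature table.

    Parameters
    ----------
    features : LabeledFeatures
        Paired samples (one alert + one fatigue per subject).
    rfe_keep_fraction : float, optional
        Fraction of features retained by in-fold recursive elimination
        (None disables selection).
    grid : list of dict, optional
        SVM hyper-parameter grid; the package default grid if "default",
        or None for a fixed linear SVM.
    """

    def __init__(
        self,
        features: LabeledFeatures,
        rfe_keep_fraction: "float | None" = None,
        rfe_step_fraction: float = 0.01,
        grid: "list[dict] | str | None" = None,
        svm_params: "dict | None" = None,
        standardize: bool = True,
        subject_level: bool = True,
    ) -> None:
        self.features = features
        self.rfe_keep_fraction = rfe_keep_fraction
        self.rfe_step_fraction = rfe_step_fraction
        self.grid = DEFAULT_GRID if grid == "default" else grid
        self.svm_params = svm_params
        self.standardize = standardize
        self.subject_level = subject_level

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kwargs) -> "FatigueClassifier":
        return cls(LabeledFeatures.from_dataframe(df), **kwargs)

    def fit(self, n_reps: int = 1000, seed: int = 0) -> ClassificationResults:
        """Run the repeated two-fold cross-validation and collect results."""
        res = repeated_twofold_cv(
            self.features, n_reps=n_reps, seed=seed,
            subject_level=self.subject_level,
            svm_params=self.svm_params, grid=self.grid,
            rfe_keep=self.rfe_keep_fraction, rfe_step=self.rfe_step_fraction,
            standardize=self.standardize,
        )
        res.model = self
        return res

    def permutation_test(self, n_perm: int = 1000, n_reps: int = 10,
                         seed: int = 0, fast_mode: bool = False) -> PermutationResult:
        return permutation_test(
            self.features, n_perm=n_perm, n_reps=n_reps, seed=seed,
            fast_mode=fast_mode, subject_level=self.subject_level,
            svm_params=self.svm_params, grid=self.grid,
            rfe_keep=self.rfe_keep_fraction, rfe_step=self.rfe_step_fraction,
            standardize=self.standardize,
        )


# ---------------------------------------------------------------------------
# condition contrast


@dataclass
class ContrastReport:
    """Fatigue-minus-alert strength differences of the selected connections."""

    pairs: list[tuple[str, str]]
    differences: np.ndarray  # mean over subjects, fatigue - alert
    lobes: list[tuple[str, str]]
    n_increased: int
    n_decreased: int
    n_zero: int
    lobe_shares: dict[str, float]  # endpoint share per lobe, sums to 1
    n_intra: int
    n_inter: int
    intra_by_lobe: dict[str, int]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "roi_a": [p[0] for p in self.pairs],
            "roi_b": [p[1] for p in self.pairs],
            "lobe_a": [l[0] for l in self.lobes],
            "lobe_b": [l[1] for l in self.lobes],
            "difference": self.differences,
            "direction": ["increased" if d > 0 else "decreased" if d < 0 else "zero"
                          for d in self.differences],
        })

    def summary(self) -> str:
        lines = [
            f"{len(self.pairs)} selected connections: "
            f"{self.n_increased} increased / {self.n_decreased} decreased "
            f"in fatigue" + (f" / {self.n_zero} unchanged" if self.n_zero else ""),
            f"intra-regional {self.n_intra}, inter-regional {self.n_inter}",
            "endpoint share by lobe: "
            + ", ".join(f"{lobe} {100 * share:.1f}%"
                        for lobe, share in sorted(self.lobe_shares.items(),
                                                  key=lambda kv: -kv[1])),
        ]
        return "\n".join(lines)


def condition_contrast(
    alert_matrices: list,
    fatigue_matrices: list,
    selected: "list[int]",
    atlas: "Atlas | None" = None,
) -> ContrastReport:
    """Contrast selected connections between conditions.

    ``alert_matrices`` / ``fatigue_matrices`` are per-subject
    ConnectivityMatrix lists in matching subject order; ``selected`` holds
    indices into the row-major strict-lower-triangle vectorization.
    """
    from .connectivity import lower_triangle_pairs

    if len(alert_matrices) != len(fatigue_matrices) or not alert_matrices:
        raise ValueError("alert and fatigue matrix lists must match and be non-empty")
    names = alert_matrices[0].node_names
    for m in (*alert_matrices, *fatigue_matrices):
        if m.node_names != names:
            raise ValueError("connectivity matrices disagree on node names")
    pairs_all = lower_triangle_pairs(len(names))
    alert_stack = np.stack([m.values for m in alert_matrices])
    fatigue_stack = np.stack([m.values for m in fatigue_matrices])
    diff_mat = (fatigue_stack - alert_stack).mean(axis=0)

    def lobe_of(name: str) -> str:
        # ROIs with no lobe entry anywhere are pooled as "other"
        try:
            return map_roi_to_lobe(atlas, name)
        except KeyError:
            return "other"

    pairs, lobes, diffs = [], [], []
    for k in selected:
        i, j = pairs_all[k]
        pairs.append((names[i], names[j]))
        lobes.append((lobe_of(names[i]), lobe_of(names[j])))
        diffs.append(diff_mat[i, j])
    diffs = np.asarray(diffs)

    lobe_counts: dict[str, int] = {}
    intra_by_lobe: dict[str, int] = {}
    n_intra = 0
    for la, lb in lobes:
        lobe_counts[la] = lobe_counts.get(la, 0) + 1
        lobe_counts[lb] = lobe_counts.get(lb, 0) + 1
        if la == lb:
            n_intra += 1
            intra_by_lobe[la] = intra_by_lobe.get(la, 0) + 1
    total_endpoints = 2 * len(lobes) if lobes else 1
    return ContrastReport(
        pairs=pairs,
        differences=diffs,
        lobes=lobes,
        n_increased=int(np.sum(diffs > 0)),
        n_decreased=int(np.sum(diffs < 0)),
        n_zero=int(np.sum(diffs == 0)),
        lobe_shares={lobe: c / total_endpoints for lobe, c in lobe_counts.items()},
        n_intra=n_intra,
        n_inter=len(lobes) - n_intra,
        intra_by_lobe=intra_by_lobe,
    )
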