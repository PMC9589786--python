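"""MFCC baseline, feature combination/selection and grouped evaluation.

The baseline represents each recording by 12 mel-frequency cepstral
coefficient trajectories summarised with six statistics each (72 features).
The combined model joins these with the 16 distortion features (88 total)
and keeps the top-k (default 45) by random-forest importance, ranked on the
training portion only.  Evaluation uses an 80/20 split at the subject-group
level (no patient/speaker straddles train and test), five-fold grouped
cross-validation for hyper-parameter search, and class weights inverse to
the training class frequencies.  Metrics:

    accuracy = (TP + TN) / (TP + TN + FP + FN)
    recall   = TP / (TP + FN)
    jaccard  = (TP + TN) / (2 (P + N) - (TP + TN))

plus AUROC (one-vs-rest macro for multi-class).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.fft
from scipy import signal as sps
from sklearn.ensemble import AdaBoostClassifier, RandomForestClassifier
from sklearn.inspection import permutation_importance
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import GroupKFold, GroupShuffleSplit, RandomizedSearchCV
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .preprocess import Signal, mel_filterbank

__all__ = [
    "FeatureTable",
    "EvalProtocol",
    "EvalReport",
    "MFCC_STAT_NAMES",
    "mfcc_features",
    "mfcc_feature_names",
    "combine_and_select",
    "evaluate",
    "rank_features",
    "metrics_from_counts",
    "CLASSIFIER_NAMES",
]

_META_COLS = ("id", "group", "label")


@dataclass(frozen=True)
class FeatureTable:
    """One row per recording: id, group, class label and a feature vector."""

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.frame
        for col in _META_COLS:
            if col not in df.columns:
                raise ValueError(f"feature table needs a {col!r} column")
        if df.isna().any().any():
            raise ValueError("feature table must not contain missing values")
        if (df["group"].astype(str) == "").any():
            raise ValueError("every row needs a group label")
        if df["id"].duplicated().any():
            raise ValueError("recording ids must be unique")

    @classmethod
    def from_arrays(cls, ids, groups, labels, X, feature_names) -> "FeatureTable":
        X = np.asarray(X, dtype=np.float64)
        if X.shape != (len(ids), len(feature_names)):
            raise ValueError("X shape does not match ids x feature_names")
        df = pd.DataFrame(X, columns=list(feature_names))
        df.insert(0, "label", list(labels))
        df.insert(0, "group", list(groups))
        df.insert(0, "id", list(ids))
        return cls(df.reset_index(drop=True))

    @property
    def feature_names(self) -> list[str]:
        return [c for c in self.frame.columns if c not in _META_COLS]

    @property
    def X(self) -> np.ndarray:
        return self.frame[self.feature_names].to_numpy(dtype=np.float64)

    @property
    def y(self) -> np.ndarray:
        return self.frame["label"].to_numpy()

    @property
    def groups(self) -> np.ndarray:
        return self.frame["group"].to_numpy()

    @property
    def ids(self) -> np.ndarray:
        return self.frame["id"].to_numpy()

    def __len__(self) -> int:
        return len(self.frame)

    def select(self, feature_names) -> "FeatureTable":
        cols = list(_META_COLS) + list(feature_names)
        return FeatureTable(self.frame[cols].copy())


# ---------------------------------------------------------------------------
# MFCC baseline features
# ---------------------------------------------------------------------------

MFCC_STAT_NAMES = ("mean", "std", "min", "max", "absdiff_mean", "absdiff_std")


def mfcc_feature_names(n_mfcc: int = 12) -> list[str]:
    return [f"mfcc{k + 1}_{s}" for k in range(n_mfcc) for s in MFCC_STAT_NAMES]


def _mfcc_trajectories(
    signal: Signal, n_mfcc: int, n_mels: int = 26, win_s: float = 0.025, hop_s: float = 0.010
) -> np.ndarray:
    """(n_mfcc, n_frames) cepstral trajectories: mel log-power -> DCT-II."""
    nperseg = max(16, int(round(win_s * signal.rate)))
    hop = max(1, int(round(hop_s * signal.rate)))
    nfft = int(2 ** np.ceil(np.log2(nperseg)))
    n_frames = 1 + (len(signal) - nperseg) // hop if len(signal) >= nperseg else 0
    if n_frames < 2:
        raise ValueError(
            f"signal too short for MFCCs: need >= {nperseg + hop} samples, "
            f"got {len(signal)}"
        )
    idx = hop * np.arange(n_frames)[:, None] + np.arange(nperseg)[None, :]
    frames = signal.samples[idx] * sps.windows.hann(nperseg, sym=False)
    power = np.abs(np.fft.rfft(frames, n=nfft, axis=1)) ** 2
    weights, _ = mel_filterbank(n_mels, nfft, signal.rate)
    mel_power = power @ weights.T
    log_mel = np.log(mel_power + 1e-10)
    cepstra = scipy.fft.dct(log_mel, type=2, axis=1, norm="ortho")
    return cepstra[:, :n_mfcc].T


def mfcc_features(signal: Signal, n_mfcc: int = 12) -> np.ndarray:
    """The 72-dimensional MFCC statistics vector.

    For each of the ``n_mfcc`` coefficient trajectories: mean, standard
    deviation, min, max, mean and standard deviation of the absolute
    successive difference — in that fixed order, coefficient-major.
    """
    traj = _mfcc_trajectories(signal, n_mfcc)
    feats = trajectory_statistics(traj)
    return feats


def trajectory_statistics(trajectories: np.ndarray) -> np.ndarray:
    """Six summary statistics per row, concatenated row-major."""
    traj = np.asarray(trajectories, dtype=np.float64)
    absdiff = np.abs(np.diff(traj, axis=1))
    stats = np.stack(
        [
            traj.mean(axis=1),
            traj.std(axis=1),
            traj.min(axis=1),
            traj.max(axis=1),
            absdiff.mean(axis=1),
            absdiff.std(axis=1),
        ],
        axis=1,
    )
    return stats.ravel()


# ---------------------------------------------------------------------------
# Feature combination and selection
# ---------------------------------------------------------------------------

def combine_and_select(
    distortion: FeatureTable,
    mfcc: FeatureTable,
    k: int = 45,
    seed: int = 0,
    train_ids=None,
) -> FeatureTable:
    """Join distortion + MFCC features and keep the top-k by RF importance.

    The importance ranking is fitted on the rows whose ids are in
    ``train_ids`` only (all rows if None — only sensible when no held-out
    evaluation follows).  Selection is reproducible under a fixed seed.
    """
    d, m = distortion.frame, mfcc.frame
    if set(d["id"]) != set(m["id"]):
        raise ValueError("distortion and MFCC tables must cover the same ids")
    merged = d.merge(
        m.drop(columns=["group", "label"]), on="id", validate="one_to_one"
    )
    combined = FeatureTable(merged)
    names = combined.feature_names
    if k >= len(names):
        return combined
    mask = (
        np.ones(len(combined), dtype=bool)
        if train_ids is None
        else np.isin(combined.ids, np.asarray(list(train_ids)))
    )
    if mask.sum() == 0:
        raise ValueError("train_ids match no rows")
    rf = RandomForestClassifier(n_estimators=200, random_state=seed)
    rf.fit(combined.X[mask], combined.y[mask])
    order = np.argsort(rf.feature_importances_)[::-1][:k]
    keep = [names[i] for i in sorted(order)]  # stable original column order
    return combined.select(keep)


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

def metrics_from_counts(tp: int, tn: int, fp: int, fn: int) -> dict[str, float]:
    """Accuracy, recall and Jaccard from confusion counts."""
    p, n = tp + fn, tn + fp
    total = p + n
    if total == 0:
        raise ValueError("no samples")
    correct = tp + tn
    return {
        "accuracy": correct / total,
        "recall": tp / p if p else float("nan"),
        "jaccard": correct / (2 * total - correct),
    }


@dataclass(frozen=True)
class EvalReport:
    """Held-out evaluation: confusion counts, metrics and split provenance."""

    model: str
    accuracy: float
    recall: float
    jaccard: float
    auroc: float
    counts: dict[str, dict[str, int]]  # per-class one-vs-rest TP/TN/FP/FN
    per_class: dict[str, dict[str, float]]
    train_groups: tuple[str, ...]
    test_groups: tuple[str, ...]
    seed: int
    best_params: dict = field(default_factory=dict)

    def summary(self) -> str:
        lines = [
            f"model={self.model}  accuracy={self.accuracy:.3f}  "
            f"recall={self.recall:.3f}  jaccard={self.jaccard:.3f}  "
            f"auroc={self.auroc:.3f}",
            f"test groups ({len(self.test_groups)}): {', '.join(self.test_groups)}",
        ]
        for cls, met in self.per_class.items():
            c = self.counts[cls]
            lines.append(
                f"  {cls}: TP={c['TP']} TN={c['TN']} FP={c['FP']} FN={c['FN']} "
                f"recall={met['recall']:.3f} jaccard={met['jaccard']:.3f}"
            )
        return "\n".join(lines)


@dataclass(frozen=True)
class EvalProtocol:
    """Grouped 80/20 split + five-fold grouped CV hyper-parameter search.

    ``n_search_iter=0`` skips the randomized search and fits each model with
    its default hyper-parameters (fast path).
    """

    test_size: float = 0.2
    cv_folds: int = 5
    n_search_iter: int = 10
    seed: int = 0
    models: tuple[str, ...] = ("rf",)


CLASSIFIER_NAMES = ("lr", "svm", "rf", "knn", "adaboost", "xgboost")

_PARAM_GRIDS = {
    "lr": {"clf__C": [0.01, 0.1, 1.0, 10.0, 100.0]},
    "svm": {"clf__C": [0.1, 1.0, 10.0, 100.0], "clf__gamma": ["scale", 0.01, 0.1, 1.0]},
    "rf": {
        "clf__n_estimators": [100, 200, 400],
        "clf__max_depth": [None, 4, 8, 16],
        "clf__min_samples_leaf": [1, 2, 4],
    },
    "knn": {"clf__n_neighbors": [1, 3, 5, 7, 9], "clf__weights": ["uniform", "distance"]},
    "adaboost": {
        "clf__n_estimators": [50, 100, 200],
        "clf__learning_rate": [0.1, 0.5, 1.0],
    },
    "xgboost": {
        "clf__n_estimators": [50, 100, 200],
        "clf__max_depth": [2, 4, 6],
        "clf__learning_rate": [0.05, 0.1, 0.3],
    },
}


def _make_estimator(name: str, class_weight: dict, seed: int, n_classes: int):
    if name == "lr":
        clf = LogisticRegression(max_iter=5000, class_weight=class_weight)
    elif name == "svm":
        clf = SVC(probability=True, class_weight=class_weight, random_state=seed)
    elif name == "rf":
        clf = RandomForestClassifier(
            n_estimators=200, class_weight=class_weight, random_state=seed
        )
    elif name == "knn":
        # nearest neighbours has no class-weight notion; left unweighted
        clf = KNeighborsClassifier()
    elif name == "adaboost":
        clf = AdaBoostClassifier(random_state=seed)
    elif name == "xgboost":
        from xgboost import XGBClassifier

        clf = XGBClassifier(
            n_estimators=100,
            eval_metric="logloss",
            random_state=seed,
            verbosity=0,
        )
    else:
        raise ValueError(f"unknown classifier {name!r}; known: {CLASSIFIER_NAMES}")
    return Pipeline([("scale", StandardScaler()), ("clf", clf)])


def _class_weights(y_train: np.ndarray) -> dict:
    """Weights inversely proportional to training class frequencies."""
    classes, counts = np.unique(y_train, return_counts=True)
    n = len(y_train)
    return {c: n / (len(classes) * cnt) for c, cnt in zip(classes, counts)}


def _ovr_counts(y_true, y_pred, cls) -> dict[str, int]:
    t = y_true == cls
    p = y_pred == cls
    return {
        "TP": int(np.sum(t & p)),
        "TN": int(np.sum(~t & ~p)),
        "FP": int(np.sum(~t & p)),
        "FN": int(np.sum(t & ~p)),
    }


def grouped_split(
    groups: np.ndarray, test_size: float, seed: int, labels: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """80/20 style split at the group level; returns (train_idx, test_idx).

    With ``labels`` given (and each group carrying a single class, as when
    groups are patients with one diagnosis) the group draw is stratified per
    class, so every class appears on both sides of the split.
    """
    groups = np.asarray(groups)
    if labels is not None:
        frame = pd.DataFrame({"group": groups, "label": np.asarray(labels)})
        per_group = frame.groupby("group")["label"].nunique()
        if (per_group == 1).all():
            rng = np.random.default_rng(seed)
            group_label = frame.drop_duplicates("group").set_index("group")["label"]
            test_groups: list = []
            for cls in np.unique(group_label.values):
                cls_groups = np.sort(group_label.index[group_label.values == cls])
                n_test = max(1, int(round(test_size * len(cls_groups))))
                if n_test >= len(cls_groups):
                    raise ValueError(
                        f"class {cls!r} has too few groups for a "
                        f"{test_size:.0%} held-out split"
                    )
                test_groups.extend(rng.permutation(cls_groups)[:n_test])
            test_mask = np.isin(groups, test_groups)
            return np.flatnonzero(~test_mask), np.flatnonzero(test_mask)
    gss = GroupShuffleSplit(n_splits=1, test_size=test_size, random_state=seed)
    train_idx, test_idx = next(gss.split(np.zeros(len(groups)), groups=groups))
    return train_idx, test_idx


def evaluate(
    features: FeatureTable, protocol: EvalProtocol = EvalProtocol()
) -> dict[str, EvalReport]:
    """Train the configured classifiers and report held-out metrics.

    The split is at the group level; the CV objective is accuracy for
    multi-class tasks and AUROC for binary ones; class weights are inverse
    to training class frequencies; all randomness is seeded.
    """
    y = features.y
    groups = features.groups
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    for cls in classes:
        if len(np.unique(groups[y == cls])) < 2:
            raise ValueError(
                f"class {cls!r} has a single group; a grouped split would "
                "leak it entirely into one side"
            )
    X = features.X
    train_idx, test_idx = grouped_split(
        groups, protocol.test_size, protocol.seed, labels=y
    )
    X_tr, y_tr, g_tr = X[train_idx], y[train_idx], groups[train_idx]
    X_te, y_te = X[test_idx], y[test_idx]
    binary = len(classes) == 2
    scoring = "roc_auc" if binary else "accuracy"
    weights = _class_weights(y_tr)

    # xgboost wants integer labels; encode uniformly for all models
    class_to_int = {c: i for i, c in enumerate(classes)}
    y_tr_enc = np.array([class_to_int[c] for c in y_tr])
    weights_enc = {class_to_int[c]: w for c, w in weights.items()}
    sample_weight = np.array([weights[c] for c in y_tr])

    reports: dict[str, EvalReport] = {}
    for name in protocol.models:
        est = _make_estimator(name, weights_enc, protocol.seed, len(classes))
        fit_params = {}
        if name in ("adaboost", "xgboost"):
            fit_params["clf__sample_weight"] = sample_weight
        if protocol.n_search_iter > 0:
            cv = GroupKFold(n_splits=min(protocol.cv_folds, len(np.unique(g_tr))))
            search = RandomizedSearchCV(
                est,
                _PARAM_GRIDS[name],
                n_iter=protocol.n_search_iter,
                scoring=scoring,
                cv=cv,
                random_state=protocol.seed,
                n_jobs=1,
                error_score="raise",
            )
            search.fit(X_tr, y_tr_enc, groups=g_tr, **fit_params)
            model = search.best_estimator_
            best_params = dict(search.best_params_)
        else:
            est.fit(X_tr, y_tr_enc, **fit_params)
            model = est
            best_params = {}

        y_pred_enc = model.predict(X_te)
        y_pred = classes[np.asarray(y_pred_enc, dtype=int)]
        proba = model.predict_proba(X_te)
        if binary:
            auroc = float(roc_auc_score((y_te == classes[1]).astype(int), proba[:, 1]))
        else:
            y_te_enc = np.array([class_to_int[c] for c in y_te])
            auroc = float(
                roc_auc_score(
                    y_te_enc, proba, multi_class="ovr", average="macro",
                    labels=np.arange(len(classes)),
                )
            )
        counts = {str(c): _ovr_counts(y_te, y_pred, c) for c in classes}
        per_class = {
            c: metrics_from_counts(**{k.lower(): v for k, v in cc.items()})
            for c, cc in counts.items()
        }
        reports[name] = EvalReport(
            model=name,
            accuracy=float(np.mean(y_pred == y_te)),
            recall=float(np.mean([m["recall"] for m in per_class.values()])),
            jaccard=float(np.mean([m["jaccard"] for m in per_class.values()])),
            auroc=auroc,
            counts=counts,
            per_class=per_class,
            train_groups=tuple(sorted(set(map(str, g_tr)))),
            test_groups=tuple(sorted(set(map(str, groups[test_idx])))),
            seed=protocol.seed,
            best_params=best_params,
        )
    return reports


# ---------------------------------------------------------------------------
# Feature ranking
# ---------------------------------------------------------------------------

def rank_features(
    features: FeatureTable, method: str = "rf_importance", seed: int = 0
) -> pd.DataFrame:
    """Importance-ordered feature ranking (descending score).

    ``rf_importance`` uses random-forest impurity importances;
    ``permutation`` uses seeded permutation importance of the same forest
    (the model-agnostic backend).  Deterministic under a fixed seed.
    """
    rf = RandomForestClassifier(n_estimators=200, random_state=seed)
    rf.fit(features.X, features.y)
    if method == "rf_importance":
        scores = rf.feature_importances_
    elif method == "permutation":
        result = permutation_importance(
            rf, features.X, features.y, n_repeats=10, random_state=seed
        )
        scores = result.importances_mean
    else:
        raise ValueError(
            f"unknown ranking method {method!r}; use 'rf_importance' or "
            "'permutation'"
        )
    df = pd.DataFrame({"feature": features.feature_names, "score": scores})
    return df.sort_values(
        ["score", "feature"], ascending=[False, True], kind="stable"
    ).reset_index(drop=True)


def top_features_report(ranking: pd.DataFrame, k: int = 10) -> str:
    lines = [f"{i + 1:2d}. {row.feature:24s} {row.score:.4f}"
             for i, row in ranking.head(k).iterrows()]
    return "\n".join(lines)
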