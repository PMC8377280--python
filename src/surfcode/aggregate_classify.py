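"""Subject-level aggregation and classification.

Per-patch sparse codes are max-pooled (coordinate-wise signed maximum)
into one m-vector per subject.  Binary amyloid status comes from a
centiloid cutoff (>= 37.1 is positive).  Classification uses a random
forest at library defaults inside repeated stratified 10-fold
cross-validation, with random undersampling of the majority class applied
to each training fold only.  Metrics: ACC, SEN, SPE, B-ACC and the
trapezoidal ROC AUC (ties by midpoint ranking).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import KFold, StratifiedKFold

from .io_formats import RunLogger

CENTILOID_CUTOFF = 37.1

METRIC_NAMES = ("ACC", "B-ACC", "SPE", "SEN", "AUC")


@dataclass
class SubjectRepresentation:
    subject_id: str
    pooled: np.ndarray  # (m,)
    label: int  # 1 = positive, 0 = negative


@dataclass
class CvResult:
    """Predictions and metrics from repeated k-fold cross-validation."""

    fold_assignments: np.ndarray  # (repeats, n) fold index per sample
    y_true: np.ndarray  # (n,)
    y_pred: np.ndarray  # (repeats, n)
    y_score: np.ndarray  # (repeats, n)
    per_repeat: pd.DataFrame  # one row per repeat, METRIC_NAMES columns
    summary: pd.DataFrame  # index METRIC_NAMES, columns mean/ci_lo/ci_hi
    seed: int = 0

    def fold_hash(self) -> str:
        return hashlib.sha256(self.fold_assignments.tobytes()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# pooling and labeling
# ---------------------------------------------------------------------------


def max_pool(codes: np.ndarray, mode: str = "max") -> np.ndarray:
    """Coordinate-wise maximum over a subject's patch codes (m x n_patches).

    ``mode='max'`` is the signed maximum; ``mode='abs-max'`` keeps the
    entry of largest magnitude (sign preserved).
    """
    codes = np.asarray(codes, dtype=np.float64)
    if codes.ndim != 2 or codes.shape[1] < 1:
        raise ValueError("codes must be (m, n_patches) with n_patches >= 1")
    if mode == "max":
        return codes.max(axis=1)
    if mode == "abs-max":
        idx = np.abs(codes).argmax(axis=1)
        return codes[np.arange(codes.shape[0]), idx]
    raise ValueError(f"unknown pooling mode {mode!r}")


def pool_subjects(Z: np.ndarray, subject_ids: np.ndarray,
                  mode: str = "max") -> dict[str, np.ndarray]:
    """Group code columns by subject and max-pool each group."""
    out: dict[str, np.ndarray] = {}
    ids = np.asarray(subject_ids)
    for sid in pd.unique(ids):
        out[str(sid)] = max_pool(Z[:, ids == sid], mode=mode)
    return out


def centiloid_label(centiloid: float, cutoff: float = CENTILOID_CUTOFF) -> int:
    """1 (positive) iff centiloid >= cutoff, else 0."""
    if not np.isfinite(centiloid):
        raise ValueError(f"centiloid must be finite, got {centiloid}")
    return int(centiloid >= cutoff)


def build_representations(pooled: dict[str, np.ndarray], metadata: pd.DataFrame,
                          ) -> list[SubjectRepresentation]:
    """Join pooled vectors with binary labels from the metadata table."""
    meta = metadata.set_index("subject_id")
    reps = []
    for sid, vec in pooled.items():
        if sid not in meta.index:
            raise KeyError(f"subject {sid!r} missing from metadata")
        status = meta.at[sid, "abeta_status"]
        reps.append(SubjectRepresentation(sid, vec, int(status == "positive")))
    return reps


def _reps_to_arrays(reps: list[SubjectRepresentation]
                    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    X = np.stack([r.pooled for r in reps])
    y = np.array([r.label for r in reps], dtype=int)
    ids = np.array([r.subject_id for r in reps], dtype=object)
    return X, y, ids


# ---------------------------------------------------------------------------
# undersampling
# ---------------------------------------------------------------------------


def undersample(labels: np.ndarray, seed: int | np.random.Generator = 0) -> np.ndarray:
    """Indices keeping all minority samples and an equal-size random subset
    of the majority, drawn without replacement; returned sorted."""
    labels = np.asarray(labels, dtype=int)
    classes, counts = np.unique(labels, return_counts=True)
    if classes.size < 2:
        raise ValueError("undersample needs both classes present")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_min = int(counts.min())
    parts = []
    for cls, count in zip(classes, counts):
        idx = np.flatnonzero(labels == cls)
        if count > n_min:
            idx = rng.choice(idx, size=n_min, replace=False)
        parts.append(idx)
    return np.sort(np.concatenate(parts))


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------


def roc_auc(y_true: np.ndarray, y_score: np.ndarray) -> float | None:
    """AUC of the ROC by the rank (Mann-Whitney) formulation, which equals
    trapezoidal integration with tied scores handled by midpoint ranking.
    Returns None when one class is absent."""
    y_true = np.asarray(y_true, dtype=int)
    y_score = np.asarray(y_score, dtype=float)
    n_pos = int((y_true == 1).sum())
    n_neg = int((y_true == 0).sum())
    if n_pos == 0 or n_neg == 0:
        return None
    ranks = stats.rankdata(y_score)  # average ranks on ties
    return float((ranks[y_true == 1].sum() - n_pos * (n_pos + 1) / 2.0)
                 / (n_pos * n_neg))


def compute_metrics(y_true: np.ndarray, y_pred: np.ndarray,
                    y_score: np.ndarray | None = None) -> dict[str, float | None]:
    """ACC, B-ACC, SPE, SEN and AUC from labels, predictions and scores."""
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred length mismatch")
    tp = int(((y_true == 1) & (y_pred == 1)).sum())
    tn = int(((y_true == 0) & (y_pred == 0)).sum())
    fp = int(((y_true == 0) & (y_pred == 1)).sum())
    fn = int(((y_true == 1) & (y_pred == 0)).sum())
    n = tp + tn + fp + fn
    sen = tp / (tp + fn) if (tp + fn) else float("nan")
    spe = tn / (tn + fp) if (tn + fp) else float("nan")
    return {
        "ACC": (tp + tn) / n if n else float("nan"),
        "B-ACC": (sen + spe) / 2.0,
        "SPE": spe,
        "SEN": sen,
        "AUC": roc_auc(y_true, y_score) if y_score is not None else None,
    }


def _t_ci(values: np.ndarray, level: float = 0.95) -> tuple[float, float, float]:
    """Mean and Student-t confidence interval over repeat means."""
    values = np.asarray(values, dtype=float)
    mean = float(values.mean())
    if values.size < 2 or np.isnan(values).any():
        return mean, float("nan"), float("nan")
    half = stats.t.ppf(0.5 + level / 2.0, values.size - 1) * values.std(ddof=1) / np.sqrt(values.size)
    return mean, mean - float(half), mean + float(half)


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------


def _default_forest(seed: int) -> RandomForestClassifier:
    # library defaults; only the seed is pinned for reproducibility
    return RandomForestClassifier(random_state=seed)


def cross_validate(reps: list[SubjectRepresentation], folds: int = 10,
                   repeats: int = 5, seed: int = 0, stratify: bool = True,
                   logger: RunLogger | None = None) -> CvResult:
    """Repeated k-fold CV of a default random forest on pooled vectors.

    Per repeat the data are shuffled and split into `folds` folds
    (stratified by label unless `stratify` is off); per fold the training
    portion alone is undersampled to class balance before fitting.  Every
    sample is predicted exactly once per repeat.  Metrics are computed per
    repeat and summarized as mean with a 95% Student-t interval.
    """
    X, y, ids = _reps_to_arrays(reps)
    n = len(y)
    if np.unique(y).size < 2:
        raise ValueError("cross_validate needs both classes present")
    fold_assignments = np.full((repeats, n), -1, dtype=int)
    y_pred = np.zeros((repeats, n), dtype=int)
    y_score = np.zeros((repeats, n), dtype=float)
    rows = []
    for rep in range(repeats):
        rep_seed = seed + rep
        assignment = _make_folds(y, folds, rep_seed, stratify)
        fold_assignments[rep] = assignment
        for k in range(folds):
            test = np.flatnonzero(assignment == k)
            train = np.flatnonzero(assignment != k)
            sub = train[undersample(y[train], seed=rep_seed * folds + k)]
            assert np.intersect1d(ids[sub], ids[test]).size == 0  # leakage guard
            clf = _default_forest(rep_seed)
            clf.fit(X[sub], y[sub])
            y_pred[rep, test] = clf.predict(X[test])
            pos_col = int(np.flatnonzero(clf.classes_ == 1)[0])
            y_score[rep, test] = clf.predict_proba(X[test])[:, pos_col]
        rows.append(compute_metrics(y, y_pred[rep], y_score[rep]))
    per_repeat = pd.DataFrame(rows, columns=list(METRIC_NAMES))
    summary = pd.DataFrame(
        [_t_ci(per_repeat[mname].to_numpy(dtype=float)) for mname in METRIC_NAMES],
        index=list(METRIC_NAMES), columns=["mean", "ci_lo", "ci_hi"],
    )
    result = CvResult(fold_assignments, y, y_pred, y_score, per_repeat, summary, seed)
    if logger is not None:
        params = _default_forest(seed).get_params()
        logger.log("cross_validate", folds=folds, repeats=repeats, seed=seed,
                   stratify=stratify, fold_hash=result.fold_hash(),
                   forest_params={k: v for k, v in params.items()})
    return result


def _make_folds(y: np.ndarray, folds: int, seed: int, stratify: bool) -> np.ndarray:
    """Fold index per sample; re-draws with the next seed if any training
    split would be single-class (logged via warning by caller)."""
    n = len(y)
    for attempt in range(100):
        splitter = (StratifiedKFold if stratify else KFold)(
            n_splits=folds, shuffle=True, random_state=seed + attempt)
        assignment = np.full(n, -1, dtype=int)
        args = (np.zeros(n), y) if stratify else (np.zeros(n),)
        for k, (_, test) in enumerate(splitter.split(*args)):
            assignment[test] = k
        ok = all(np.unique(y[assignment != k]).size == 2 for k in range(folds))
        if ok:
            return assignment
    raise RuntimeError("could not build folds with both classes in every training split")


def external_validate(train_reps: list[SubjectRepresentation],
                      test_reps: list[SubjectRepresentation],
                      seed: int = 0) -> dict[str, float | None]:
    """Train once on the (undersampled) training cohort, evaluate once on a
    disjoint external cohort.  Overlapping subject IDs are an error."""
    Xtr, ytr, ids_tr = _reps_to_arrays(train_reps)
    Xte, yte, ids_te = _reps_to_arrays(test_reps)
    overlap = np.intersect1d(ids_tr, ids_te)
    if overlap.size:
        raise ValueError(f"subject IDs in both train and test sets: {overlap.tolist()}")
    sub = undersample(ytr, seed=seed)
    clf = _default_forest(seed)
    clf.fit(Xtr[sub], ytr[sub])
    pos_col = int(np.flatnonzero(clf.classes_ == 1)[0])
    return compute_metrics(yte, clf.predict(Xte), clf.predict_proba(Xte)[:, pos_col])


# ---------------------------------------------------------------------------
# grid search
# ---------------------------------------------------------------------------


@dataclass
class GridSearchResult:
    best: dict
    table: pd.DataFrame  # one row per candidate: params + mean_acc + CI


def grid_search(candidates: list[dict], tuning_cohort, seed: int = 0,
                folds: int = 10, repeats: int = 5,
                eval_ids: set[str] | None = None,
                pipeline=None) -> GridSearchResult:
    """Run the full pipeline per candidate setting on the tuning cohort and
    pick the highest mean CV accuracy (ties toward smaller m, then smaller
    patch size).

    `pipeline(cohort, params, seed, folds, repeats) -> CvResult` defaults to
    :func:`surfcode.pipeline.run_pipeline_cv`.  `eval_ids` guards against
    tuning on subjects reserved for evaluation.
    """
    if not candidates:
        raise ValueError("empty candidate grid")
    if eval_ids:
        tune_ids = set(tuning_cohort.metadata["subject_id"])
        overlap = tune_ids & set(eval_ids)
        if overlap:
            raise ValueError(f"tuning/evaluation subject overlap: {sorted(overlap)}")
    if pipeline is None:
        from .pipeline import run_pipeline_cv
        pipeline = run_pipeline_cv
    rows = []
    for params in candidates:
        result = pipeline(tuning_cohort, params, seed=seed, folds=folds, repeats=repeats)
        mean, lo, hi = result.summary.loc["ACC", ["mean", "ci_lo", "ci_hi"]]
        rows.append({**params, "mean_acc": mean, "ci_lo": lo, "ci_hi": hi})
    table = pd.DataFrame(rows)
    order = table.sort_values(
        by=["mean_acc", "m", "patch_size"], ascending=[False, True, True],
        kind="stable",
    )
    best = candidates[int(order.index[0])]
    return GridSearchResult(best=best, table=table)
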