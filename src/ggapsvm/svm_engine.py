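"""RBF-kernel SVM training, grid search and jackknife (leave-one-out) evaluation.

Hyperparameters are tuned over a powers-of-two grid, C from 2^15 down to
2^-5 and gamma from 2^-5 down to 2^-15, scored by jackknife accuracy.
The final model is a C-SVC with an RBF kernel plus Platt-style sigmoid
calibration so predictions carry class probabilities; the class whose
probability exceeds 0.5 is the predicted label.  Alkaline is the positive
class everywhere.

Leave-one-out evaluation is exact but heavily used (the IFS scan refits it
for every subset size), so the inner loop goes through scikit-learn's
low-level LibSVM binding and skips refits for held-out samples that are
not support vectors of the full-data model: removing a non-support vector
leaves the KKT solution — and therefore the held-out prediction —
unchanged.  A test cross-checks this fast path against a naive per-fold
``SVC`` loop.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import joblib
import numpy as np
from sklearn.svm import SVC

from .ggap_features import DIPEPTIDES, encode_sequence
from .metrics import ConfusionCounts
from .sequence_io import ACIDIC, ALKALINE, ProteinRecord

try:  # pragma: no cover - import guard
    from sklearn.svm import _libsvm as _llsvm

    _llsvm.set_verbosity_wrap(0)
    _HAVE_LOWLEVEL = True
except Exception:  # pragma: no cover
    _llsvm = None
    _HAVE_LOWLEVEL = False

MODEL_FORMAT_VERSION = 1
#: Seed for the internal cross-validation used by Platt probability calibration.
CALIBRATION_SEED = 0


@dataclass(frozen=True)
class SVMGridSpec:
    """Powers-of-two search grid for (C, gamma).

    Defaults: C exponents +15 down to -5 and gamma exponents -5 down to
    -15, both in steps of 1 (multiplicative factor 2), i.e. 21 x 11 = 231
    grid points.  ``gamma_exp_step`` widens the gamma step for the coarser
    reading of the search schedule.
    """

    c_exp_max: int = 15
    c_exp_min: int = -5
    gamma_exp_max: int = -5
    gamma_exp_min: int = -15
    c_exp_step: int = 1
    gamma_exp_step: int = 1
    base: float = 2.0

    def __post_init__(self) -> None:
        if self.c_exp_max < self.c_exp_min or self.gamma_exp_max < self.gamma_exp_min:
            raise ValueError("exponent ranges must be non-empty")
        if self.c_exp_step < 1 or self.gamma_exp_step < 1:
            raise ValueError("exponent steps must be positive")

    @property
    def c_values(self) -> list[float]:
        exps = range(self.c_exp_min, self.c_exp_max + 1, self.c_exp_step)
        return [float(self.base**e) for e in exps]

    @property
    def gamma_values(self) -> list[float]:
        exps = range(self.gamma_exp_min, self.gamma_exp_max + 1, self.gamma_exp_step)
        return [float(self.base**e) for e in exps]

    @property
    def n_points(self) -> int:
        return len(self.c_values) * len(self.gamma_values)


def median_heuristic_gamma(X: np.ndarray) -> float:
    """RBF bandwidth by the median heuristic: 1 / median squared distance.

    Dipeptide-composition vectors are compressed into a tiny ball (squared
    distances of order 0.01), so every gamma in a LibSVM-style grid leaves
    the kernel nearly constant and the SVM degenerates to a majority vote.
    Under balanced leave-one-out that degenerate vote always picks the
    class *opposite* the held-out sample, giving accuracy near 0 on null
    data rather than 0.5.  A bandwidth matched to the data scale keeps the
    kernel informative, which matters for calibration checks on
    signal-free data.
    """
    from scipy.spatial.distance import pdist

    med = float(np.median(pdist(np.asarray(X, dtype=np.float64), "sqeuclidean")))
    if med <= 0:
        raise ValueError("degenerate data: median pairwise distance is zero")
    return 1.0 / med


def _as_binary(labels: Sequence[str] | np.ndarray) -> np.ndarray:
    """Map class names to float codes (acidic -> 0, alkaline -> 1)."""
    labels = np.asarray(labels)
    y = np.where(labels == ALKALINE, 1.0, 0.0)
    known = (labels == ALKALINE) | (labels == ACIDIC)
    if not known.all():
        bad = sorted(set(labels[~known]))
        raise ValueError(f"unknown class labels: {', '.join(map(str, bad))}")
    return y


def _loo_lowlevel(X: np.ndarray, y: np.ndarray, c: float, gamma: float, want_scores: bool):
    """Exact LOO predictions (and decision scores) via the LibSVM binding."""
    M = len(y)
    X = np.ascontiguousarray(X, dtype=np.float64)
    fit_kw = dict(svm_type=0, kernel="rbf", C=c, gamma=gamma)

    def fit(Xt, yt):
        return _llsvm.fit(Xt, yt, **fit_kw)

    def dec_alkaline(model, Xq, y_first):
        dec = _llsvm.decision_function(
            np.ascontiguousarray(Xq), *model[:7], svm_type=0, kernel="rbf", gamma=gamma
        ).ravel()
        # LibSVM orients decision values toward its first-seen training label
        return dec if y_first == 1.0 else -dec

    full = fit(X, y)
    support = set(full[0].tolist())
    preds = np.empty(M)
    scores = np.empty(M) if want_scores else None
    full_pred = _llsvm.predict(X, *full[:7], svm_type=0, kernel="rbf", gamma=gamma)
    if want_scores:
        full_scores = dec_alkaline(full, X, y[0])
    arange = np.arange(M)
    for i in range(M):
        if i not in support:
            # removing a non-support vector leaves the solution unchanged
            preds[i] = full_pred[i]
            if want_scores:
                scores[i] = full_scores[i]
            continue
        idx = np.delete(arange, i)
        Xi = np.ascontiguousarray(X[idx])
        model = fit(Xi, y[idx])
        preds[i] = _llsvm.predict(
            np.ascontiguousarray(X[i : i + 1]), *model[:7], svm_type=0, kernel="rbf", gamma=gamma
        )[0]
        if want_scores:
            scores[i] = dec_alkaline(model, X[i : i + 1], y[idx][0])[0]
    return preds, scores


def _loo_sklearn(X: np.ndarray, y: np.ndarray, c: float, gamma: float, want_scores: bool):
    """Reference LOO loop through the public SVC interface."""
    M = len(y)
    preds = np.empty(M)
    scores = np.empty(M) if want_scores else None
    arange = np.arange(M)
    for i in range(M):
        idx = np.delete(arange, i)
        clf = SVC(C=c, kernel="rbf", gamma=gamma)
        clf.fit(X[idx], y[idx])
        preds[i] = clf.predict(X[i : i + 1])[0]
        if want_scores:
            # classes_ = [0., 1.]; decision_function is oriented toward class 1
            scores[i] = clf.decision_function(X[i : i + 1])[0]
    return preds, scores


def jackknife_evaluate(
    X: np.ndarray,
    labels: Sequence[str] | np.ndarray,
    c_value: float,
    gamma_value: float,
    return_scores: bool = False,
    use_lowlevel: bool = True,
):
    """Leave-one-out evaluation of an RBF SVC at fixed (C, gamma).

    Each sample is predicted by a model trained on the other M - 1; the
    confusion counts treat alkaline as positive.  The result is a pure
    function of the data and hyperparameters.  With ``return_scores`` the
    per-sample decision values for the alkaline class are returned as well
    (for ROC/AUC).

    Raises
    ------
    ValueError
        If either class has fewer than two samples ("degenerate fold").
    """
    if c_value <= 0 or gamma_value <= 0:
        raise ValueError("C and gamma must be positive")
    X = np.asarray(X, dtype=np.float64)
    y = _as_binary(labels)
    M = len(y)
    if M < 3:
        raise ValueError("need at least three samples for jackknife")
    n_pos, n_neg = int(y.sum()), int(M - y.sum())
    if n_pos < 2 or n_neg < 2:
        raise ValueError("degenerate fold: a leave-one-out training set would be single-class")
    loo = _loo_lowlevel if (use_lowlevel and _HAVE_LOWLEVEL) else _loo_sklearn
    preds, scores = loo(X, y, c_value, gamma_value, return_scores)
    counts = ConfusionCounts(
        tp=int(((preds == 1) & (y == 1)).sum()),
        fn=int(((preds == 0) & (y == 1)).sum()),
        fp=int(((preds == 1) & (y == 0)).sum()),
        tn=int(((preds == 0) & (y == 0)).sum()),
    )
    if return_scores:
        return counts, scores
    return counts


def grid_search(
    X: np.ndarray,
    labels: Sequence[str] | np.ndarray,
    spec: SVMGridSpec | None = None,
) -> tuple[float, float, float]:
    """Pick (C, gamma) maximising jackknife accuracy over the grid.

    Ties are broken toward smaller C, then larger gamma (smoother models).
    Returns ``(c_value, gamma_value, best_accuracy)``.
    """
    spec = spec or SVMGridSpec()
    best: tuple[float, float, float] | None = None
    # ascending C, descending gamma: the first strict improvement wins ties
    for c in spec.c_values:
        for gamma in sorted(spec.gamma_values, reverse=True):
            acc = jackknife_evaluate(X, labels, c, gamma).accuracy
            if best is None or acc > best[2]:
                best = (c, gamma, acc)
    return best


@dataclass
class TrainedClassifier:
    """A fitted, probability-calibrated RBF SVC plus everything needed to
    reproduce its feature space: gap, feature subset and dipeptide ordering."""

    gap: int
    feature_indices: tuple[int, ...]
    c_value: float
    gamma_value: float
    model: SVC
    dipeptide_order: tuple[str, ...] = DIPEPTIDES
    classes: tuple[str, str] = (ACIDIC, ALKALINE)
    calibration_seed: int = CALIBRATION_SEED
    version: int = MODEL_FORMAT_VERSION

    def save(self, path: str | Path) -> None:
        payload = {
            "format_version": self.version,
            "gap": self.gap,
            "feature_indices": list(self.feature_indices),
            "c_value": self.c_value,
            "gamma_value": self.gamma_value,
            "dipeptide_order": list(self.dipeptide_order),
            "classes": list(self.classes),
            "calibration_seed": self.calibration_seed,
            "model": self.model,
        }
        joblib.dump(payload, path)

    @classmethod
    def load(cls, path: str | Path) -> "TrainedClassifier":
        payload = joblib.load(path)
        version = payload.get("format_version")
        if version != MODEL_FORMAT_VERSION:
            raise ValueError(
                f"model file format version {version} does not match "
                f"supported version {MODEL_FORMAT_VERSION}"
            )
        return cls(
            gap=payload["gap"],
            feature_indices=tuple(payload["feature_indices"]),
            c_value=payload["c_value"],
            gamma_value=payload["gamma_value"],
            model=payload["model"],
            dipeptide_order=tuple(payload["dipeptide_order"]),
            classes=tuple(payload["classes"]),
            calibration_seed=payload["calibration_seed"],
            version=version,
        )


def train(
    values: np.ndarray,
    labels: Sequence[str] | np.ndarray,
    feature_indices: Sequence[int],
    c_value: float,
    gamma_value: float,
    gap: int,
) -> TrainedClassifier:
    """Fit the final RBF SVC (with Platt probability calibration) on all samples.

    ``values`` is the full M x 400 frequency matrix; the model is trained on
    the ``feature_indices`` columns only.
    """
    labels = np.asarray(labels)
    if len(set(labels.tolist())) < 2:
        raise ValueError("training requires samples from both classes")
    feature_indices = tuple(int(i) for i in feature_indices)
    X = np.asarray(values, dtype=np.float64)[:, feature_indices]
    model = SVC(
        C=c_value,
        kernel="rbf",
        gamma=gamma_value,
        probability=True,
        random_state=CALIBRATION_SEED,
    )
    model.fit(X, labels)
    return TrainedClassifier(
        gap=gap,
        feature_indices=feature_indices,
        c_value=c_value,
        gamma_value=gamma_value,
        model=model,
    )


@dataclass(frozen=True)
class PredictionResult:
    """Per-sequence class probabilities and the >0.5 label (or an error)."""

    id: str
    probability_acidic: float | None
    probability_alkaline: float | None
    predicted_label: str | None
    error: str | None = None


def predict(model: TrainedClassifier, records: Sequence[ProteinRecord]) -> list[PredictionResult]:
    """Classify records with a trained model; output order matches input.

    Sequences shorter than ``gap + 2`` yield a per-record error entry
    instead of aborting the batch.
    """
    results: list[PredictionResult] = []
    rows: list[np.ndarray] = []
    row_for: list[int] = []
    for k, rec in enumerate(records):
        try:
            vec = encode_sequence(rec.sequence, model.gap)
        except ValueError as exc:
            results.append(
                PredictionResult(rec.id, None, None, None, error=str(exc))
            )
            continue
        rows.append(vec[list(model.feature_indices)])
        row_for.append(k)
        results.append(None)  # placeholder, filled below
    if rows:
        proba = model.model.predict_proba(np.asarray(rows))
        class_order = list(model.model.classes_)
        i_acid = class_order.index(ACIDIC)
        i_alk = class_order.index(ALKALINE)
        j = 0
        for k, res in enumerate(results):
            if res is not None:
                continue
            p_acid = float(proba[j, i_acid])
            p_alk = float(proba[j, i_alk])
            label = ACIDIC if p_acid > 0.5 else ALKALINE
            results[k] = PredictionResult(records[k].id, p_acid, p_alk, label)
            j += 1
    return results


def predictions_to_frame(results: Sequence[PredictionResult]):
    """Tabulate predictions as (id, prob_acidic, prob_alkaline, label[, error])."""
    import pandas as pd

    return pd.DataFrame(
        {
            "id": [r.id for r in results],
            "prob_acidic": [r.probability_acidic for r in results],
            "prob_alkaline": [r.probability_alkaline for r in results],
            "label": [r.predicted_label for r in results],
            "error": [r.error for r in results],
        }
    )
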