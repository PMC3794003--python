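"""End-to-end workflow: gap scan, feature selection, final model and reports.

``run_full_selection`` reproduces the whole protocol on a pair of labelled
FASTA files: encode at every gap in the configured range, rank features by
ANOVA F, run the IFS jackknife scan, pick the globally best (g0, t0),
re-optimise (C, gamma) on the selected subset, evaluate it by jackknife
(with ROC/AUC from the held-out decision values) and train the final
calibrated classifier.  Every artefact — ranking and IFS-curve TSVs, the
IFS plot, the evaluation JSON, the model file and a provenance summary with
input checksums — lands in the output directory, and identical inputs,
config and seeds regenerate identical primary outputs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .anova_ifs import IFSResult, ifs_scan, rank_features, select_optimal
from .ggap_features import N_FEATURES, encode_dataset
from .metrics import PerformanceReport, compute_metrics, percent, roc_auc
from .sequence_io import SequenceDataset, load_labelled_fastas
from .svm_engine import (
    SVMGridSpec,
    TrainedClassifier,
    grid_search,
    jackknife_evaluate,
    train,
)


@dataclass
class RunConfig:
    """All knobs of a full selection run; mirrors the CLI flags."""

    gap_min: int = 0
    gap_max: int = 10
    min_length: int = 100
    grid: SVMGridSpec = field(default_factory=SVMGridSpec)
    ifs_mode: str = "fast"  # or "regrid"
    t_max: int = N_FEATURES
    nested: bool = False
    out_dir: str | Path = "ggapsvm_run"

    def __post_init__(self) -> None:
        if self.gap_min < 0 or self.gap_max < self.gap_min:
            raise ValueError("gap range must be non-empty and non-negative")
        if self.ifs_mode not in ("fast", "regrid"):
            raise ValueError("ifs_mode must be 'fast' or 'regrid'")
        if not 1 <= self.t_max <= N_FEATURES:
            raise ValueError(f"t_max must be in 1..{N_FEATURES}")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["out_dir"] = str(self.out_dir)
        return d

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        grid_kw = data.pop("grid", {})
        data.update({k: v for k, v in overrides.items() if v is not None})
        grid = overrides.get("grid") or SVMGridSpec(**grid_kw)
        data.pop("grid", None)
        return cls(grid=grid, **data)


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _plot_ifs_curves(results: list[IFSResult], path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4.5))
    for res in results:
        ax.plot(np.arange(1, len(res.accuracies) + 1), 100 * res.accuracies,
                lw=0.8, label=f"g={res.gap}")
    ax.set_xlabel("number of top-ranked g-gap dipeptides (t)")
    ax.set_ylabel("jackknife overall accuracy (%)")
    ax.legend(ncol=2, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def run_full_selection(
    acidic_fasta: str | Path,
    alkaline_fasta: str | Path,
    config: RunConfig,
) -> tuple[TrainedClassifier, dict]:
    """Run the complete selection protocol and write the report bundle.

    Returns the trained classifier and the summary dictionary (also written
    to ``summary.json`` in the output directory).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    dataset = load_labelled_fastas(
        acidic_fasta, alkaline_fasta, min_length=config.min_length
    )
    labels = np.asarray(dataset.labels)

    results: list[IFSResult] = []
    rankings = {}
    matrices = {}
    for gap in range(config.gap_min, config.gap_max + 1):
        matrix = encode_dataset(dataset, gap)
        ranking = rank_features(matrix)
        ranking.to_tsv(out / f"ranking_g{gap}.tsv")
        res = ifs_scan(matrix, ranking, config.grid, mode=config.ifs_mode, t_max=config.t_max)
        res.to_tsv(out / f"ifs_curve_g{gap}.tsv")
        results.append(res)
        rankings[gap] = ranking
        matrices[gap] = matrix

    g0, t0, peak_acc = select_optimal(results)
    subset = rankings[g0].order[:t0]
    X0 = matrices[g0].values[:, subset]

    c0, gamma0, _ = grid_search(X0, labels, config.grid)
    counts, scores = jackknife_evaluate(X0, labels, c0, gamma0, return_scores=True)
    report = compute_metrics(counts)
    _, auc = roc_auc(scores, labels)
    report.auc = auc
    report.to_json(out / "evaluation.json")

    model = train(matrices[g0].values, labels, subset, c0, gamma0, gap=g0)
    model_path = out / "model.joblib"
    model.save(model_path)
    _plot_ifs_curves(results, out / "ifs_curves.png")

    summary = {
        "package_version": __version__,
        "inputs": {
            "acidic_fasta": {"path": str(acidic_fasta), "sha256": _sha256(acidic_fasta)},
            "alkaline_fasta": {"path": str(alkaline_fasta), "sha256": _sha256(alkaline_fasta)},
        },
        "config": config.to_dict(),
        "n_samples": int(len(dataset)),
        "class_counts": dataset.class_counts(),
        "n_candidate_subsets": len(results) * config.t_max,
        "g0": int(g0),
        "t0": int(t0),
        "peak_ifs_accuracy": float(peak_acc),
        "final_c": float(c0),
        "final_gamma": float(gamma0),
        "jackknife": {
            **{k: (float(v) if v is not None else None) for k, v in report.to_dict().items()},
            "ac_percent": percent(report.accuracy),
            "sn_percent": percent(report.sensitivity),
            "sp_percent": percent(report.specificity),
        },
        "per_gap_peaks": [
            {"gap": int(r.gap), "peak_t": int(r.peak_t), "peak_accuracy": float(r.peak_accuracy)}
            for r in results
        ],
        "model_file": model_path.name,
    }
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return model, summary


def run_kfold_eval(
    values: np.ndarray,
    labels,
    c_value: float,
    gamma_value: float,
    k: int,
    seed: int,
    feature_indices=None,
) -> PerformanceReport:
    """Stratified k-fold cross-validation at fixed hyperparameters.

    Folds are a seeded stratified random partition; ``k = M`` degenerates
    to leave-one-out and matches :func:`jackknife_evaluate` exactly.  The
    seed is recorded nowhere else, so callers should log it: a different
    seed gives a different (equally valid) partition.
    """
    from sklearn.model_selection import StratifiedKFold
    from sklearn.svm import SVC

    from .metrics import ConfusionCounts
    from .sequence_io import ALKALINE

    labels = np.asarray(labels)
    X = np.asarray(values, dtype=np.float64)
    if feature_indices is not None:
        X = X[:, list(feature_indices)]
    M = len(labels)
    if k < 2:
        raise ValueError("k must be at least 2")
    y = (labels == ALKALINE).astype(int)
    class_sizes = [int((y == 0).sum()), int((y == 1).sum())]
    if k > M:
        raise ValueError("k cannot exceed the number of samples")
    if k == M:
        folds = [(np.delete(np.arange(M), i), np.array([i])) for i in range(M)]
    else:
        if k > min(class_sizes):
            raise ValueError("k cannot exceed the smaller class size")
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        folds = list(skf.split(X, y))
    tp = fn = fp = tn = 0
    scores = np.empty(M)
    for train_idx, test_idx in folds:
        if len(set(y[train_idx])) < 2:
            raise ValueError("degenerate fold: training split is single-class")
        clf = SVC(C=c_value, kernel="rbf", gamma=gamma_value)
        clf.fit(X[train_idx], y[train_idx])
        pred = clf.predict(X[test_idx])
        scores[test_idx] = clf.decision_function(X[test_idx])
        tp += int(((pred == 1) & (y[test_idx] == 1)).sum())
        fn += int(((pred == 0) & (y[test_idx] == 1)).sum())
        fp += int(((pred == 1) & (y[test_idx] == 0)).sum())
        tn += int(((pred == 0) & (y[test_idx] == 0)).sum())
    report = compute_metrics(ConfusionCounts(tp=tp, fn=fn, fp=fp, tn=tn))
    _, auc = roc_auc(scores, labels)
    report.auc = auc
    return report
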