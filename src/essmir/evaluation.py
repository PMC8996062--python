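"""Performance metrics, cross-validation protocols, and calibration.

Metrics follow the usual confusion-matrix definitions with essential = 1
as the positive class: accuracy, precision, recall, F1 (harmonic mean of
precision and recall), plus AUROC computed as the Mann–Whitney rank
statistic (ties contribute 1/2). When a metric's denominator is zero it is
reported as 0 and flagged, so aggregation over repetitions never fails.

Two protocols mirror how balanced pre-miRNA essentiality benchmarks of a
few hundred sequences are evaluated in practice:

* leave-one-out CV, pooling all n held-out scores into a single report
  (a per-fold ROC is undefined for singleton folds);
* stratified 5-fold CV repeated (by default 50 times) with repetition r
  seeded ``seed + r``, averaged arithmetically across repetitions.

Hyper-parameters are calibrated by a *sequential* (coordinate-wise) grid
search: parameters are scanned one at a time in a stated order, the
earlier ones frozen at their argmax while the later ones sit at defaults.
Ties break toward the first-listed value, so listing values simplest-first
biases toward simpler models.
"""

from __future__ import annotations

import dataclasses
import json
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy.stats import rankdata
from sklearn.base import clone
from sklearn.model_selection import StratifiedKFold

from .encoders import FeatureMatrix


class ProtocolError(ValueError):
    """The dataset cannot support the requested cross-validation protocol."""


class GridSearchError(RuntimeError):
    """Objective evaluation failed at an identified grid cell."""


def auroc_score(labels, scores) -> float:
    """Area under the ROC curve via the rank (Mann–Whitney) statistic.

    Equals the probability that a random positive outscores a random
    negative, with tied scores contributing 1/2.
    """
    y = np.asarray(labels, dtype=int)
    s = np.asarray(scores, dtype=float)
    n_pos = int(y.sum())
    n_neg = y.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ProtocolError("AUROC requires at least one positive and one negative")
    ranks = rankdata(s)
    return float((ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


@dataclasses.dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclasses.dataclass(frozen=True)
class MetricsReport:
    """The five performance statistics plus their underlying counts.

    ``undefined`` lists metrics whose denominator was zero (reported as 0).
    """

    accuracy: float
    precision: float
    recall: float
    f1: float
    auroc: float
    counts: ConfusionCounts
    protocol: str
    undefined: tuple[str, ...] = ()

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["counts"] = self.counts.to_dict()
        d["undefined"] = list(self.undefined)
        return d

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


def compute_metrics(labels, scores, cutoff: float = 0.5, protocol: str = "scores") -> MetricsReport:
    """Threshold scores at *cutoff* and compute the full metrics report.

    A score >= cutoff predicts the positive (essential) class.
    """
    y = np.asarray(labels, dtype=int)
    s = np.asarray(scores, dtype=float)
    if y.size == 0:
        raise ProtocolError("cannot compute metrics on an empty input")
    if y.shape != s.shape:
        raise ProtocolError(f"labels ({y.shape}) and scores ({s.shape}) differ in length")
    if not set(np.unique(y)) <= {0, 1}:
        raise ProtocolError("labels must be 0/1")
    if np.any(s < 0) or np.any(s > 1):
        raise ProtocolError("scores must lie in [0, 1]")

    pred = (s >= cutoff).astype(int)
    counts = ConfusionCounts(
        tp=int(np.sum((pred == 1) & (y == 1))),
        tn=int(np.sum((pred == 0) & (y == 0))),
        fp=int(np.sum((pred == 1) & (y == 0))),
        fn=int(np.sum((pred == 0) & (y == 1))),
    )
    undefined: list[str] = []

    def ratio(num: int, den: int, name: str) -> float:
        if den == 0:
            undefined.append(name)
            return 0.0
        return num / den

    acc = (counts.tp + counts.tn) / counts.total
    pre = ratio(counts.tp, counts.tp + counts.fp, "precision")
    rec = ratio(counts.tp, counts.tp + counts.fn, "recall")
    f1 = 0.0
    if pre + rec == 0:
        undefined.append("f1")
    else:
        f1 = 2 * pre * rec / (pre + rec)
    auc = auroc_score(y, s)
    return MetricsReport(
        accuracy=acc,
        precision=pre,
        recall=rec,
        f1=f1,
        auroc=auc,
        counts=counts,
        protocol=protocol,
        undefined=tuple(undefined),
    )


def _values_of(X) -> np.ndarray:
    return X.values if isinstance(X, FeatureMatrix) else np.asarray(X, dtype=float)


def _seeded_clone(model, seed: int):
    m = clone(model)
    if "random_state" in m.get_params():
        m.set_params(random_state=seed)
    return m


def loocv(X, y, model, seed: int = 0) -> MetricsReport:
    """Leave-one-out cross-validation with pooled held-out scores.

    Features are computed once up front (encoding is per-sequence, so this
    is leakage-free); each fold refits a clone of *model* seeded with
    *seed* on the remaining n−1 rows and scores the held-out row. All n
    scores are pooled into one report.
    """
    Xv = _values_of(X)
    y = np.asarray(y, dtype=int)
    n = y.size
    if Xv.shape[0] != n:
        raise ProtocolError("feature rows and labels differ in length")
    if int(y.sum()) < 2 or int((1 - y).sum()) < 2:
        raise ProtocolError(
            "leave-one-out needs at least 2 samples of each class so every "
            "training fold contains both classes"
        )
    scores = np.empty(n, dtype=float)
    mask = np.ones(n, dtype=bool)
    for i in range(n):
        mask[i] = False
        m = _seeded_clone(model, seed).fit(Xv[mask], y[mask])
        scores[i] = m.predict_proba(Xv[i : i + 1])[0, 1]
        mask[i] = True
    return compute_metrics(y, scores, protocol="loocv")


@dataclasses.dataclass(frozen=True)
class KFoldSummary:
    """Arithmetic mean (and spread) of per-repetition metric reports."""

    mean: dict[str, float]
    std: dict[str, float]
    folds: int
    reps: int
    seed: int

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


_METRIC_FIELDS = ("accuracy", "precision", "recall", "f1", "auroc")


def repeated_kfold(
    X, y, model, folds: int = 5, reps: int = 50, seed: int = 0
) -> tuple[KFoldSummary, list[MetricsReport]]:
    """Stratified k-fold CV repeated *reps* times; repetition r uses seed+r.

    Within each repetition, held-out scores from all folds are pooled into
    one report; reports are then averaged arithmetically across reps.
    """
    Xv = _values_of(X)
    y = np.asarray(y, dtype=int)
    n = y.size
    if n < folds:
        raise ProtocolError(f"{folds}-fold CV is infeasible with n={n} samples")
    if int(y.sum()) < folds or int((1 - y).sum()) < folds:
        raise ProtocolError(
            f"stratified {folds}-fold CV needs at least {folds} members of each class"
        )
    reports: list[MetricsReport] = []
    for r in range(reps):
        splitter = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed + r)
        scores = np.empty(n, dtype=float)
        for train_idx, test_idx in splitter.split(Xv, y):
            m = _seeded_clone(model, seed + r).fit(Xv[train_idx], y[train_idx])
            scores[test_idx] = m.predict_proba(Xv[test_idx])[:, 1]
        reports.append(
            compute_metrics(y, scores, protocol=f"kfold(folds={folds}, rep={r}, seed={seed + r})")
        )
    mean = {f: float(np.mean([getattr(rep, f) for rep in reports])) for f in _METRIC_FIELDS}
    std = {f: float(np.std([getattr(rep, f) for rep in reports])) for f in _METRIC_FIELDS}
    return KFoldSummary(mean=mean, std=std, folds=folds, reps=reps, seed=seed), reports


@dataclasses.dataclass(frozen=True)
class GridSpec:
    """An ordered coordinate-wise scan: parameter name -> value list."""

    params: Mapping[str, Sequence]
    objective: str = "auroc"

    def __post_init__(self) -> None:
        if not self.params or any(len(v) == 0 for v in self.params.values()):
            raise ValueError("every grid parameter needs a non-empty value list")


@dataclasses.dataclass(frozen=True)
class GridSearchResult:
    best_params: dict
    best_score: float
    trace: tuple[dict, ...]

    def trace_rows(self) -> list[dict]:
        return [dict(row) for row in self.trace]


def sequential_grid_search(
    objective: Callable[..., float],
    grid: GridSpec,
    defaults: Mapping | None = None,
) -> GridSearchResult:
    """Coordinate-wise scan of *grid* in its stated parameter order.

    Parameter 1 is scanned with all later parameters at their defaults
    (from *defaults*, or the objective's own keyword defaults); its argmax
    is frozen and the scan proceeds to parameter 2, and so on. Ties break
    toward the earlier-listed value. Returns the winning setting together
    with the complete (parameter, value, objective) trace for audit.
    """
    current: dict = dict(defaults or {})
    trace: list[dict] = []
    last_best = -np.inf
    for name, values in grid.params.items():
        best_value, best_score = None, -np.inf
        for value in values:
            trial = {**current, name: value}
            try:
                score = float(objective(**trial))
            except Exception as exc:
                raise GridSearchError(
                    f"objective evaluation failed at {name}={value!r} "
                    f"(fixed: {current!r}): {exc}"
                ) from exc
            trace.append({"param": name, "value": value, "objective": score, **current})
            if score > best_score:
                best_value, best_score = value, score
        current[name] = best_value
        last_best = best_score
    return GridSearchResult(best_params=current, best_score=float(last_best), trace=tuple(trace))


#: Calibration grids matching the published scan ranges for each scheme and
#: learner. The mismatch m-range depends on k (m <= k-1) and the tree
#: max_features range depends on the feature dimension n; both are resolved
#: at calibration time.
CALIBRATION_GRIDS: dict[str, dict[str, list]] = {
    "kmer": {"k": [1, 2, 3, 4, 5, 6]},
    "mismatch": {"k": [1, 2, 3, 4, 5, 6], "m": "0..k-1"},
    "subsequence": {
        "k": [2, 3, 4],
        "delta": [round(0.1 * i, 1) for i in range(1, 10)],
    },
    "psedsspc": {
        "d": list(range(1, 11)),
        "lam": list(range(1, 21)),
        "w": [round(0.1 * i, 1) for i in range(1, 10)],
    },
    "tree": {
        "splitter": ["best", "random"],
        "max_depth": list(range(3, 11)),
        "max_features": "3..n",
    },
    "boost": {
        "n_trees": list(range(50, 501, 10)),
        "learning_rate": [round(0.1 + 0.02 * i, 2) for i in range(21)],
        "max_depth": list(range(3, 11)),
        "reg_lambda": [round(0.1 * i, 1) for i in range(21)],
    },
}
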