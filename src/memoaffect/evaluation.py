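"""Metrics, confusion matrices and the evaluation protocols.

The confusion-matrix convention follows the published table: rows are the
classifier's output (predicted) class, columns the target (true) class, in
the order HVHA, HVLA, LVHA, LVLA.  Per-class precision, sensitivity,
specificity and F-measure come from one-vs-rest TP/FP/TN/FN counts; overall
accuracy is trace/total.

Protocols: three random 80/20 segment-level splits (replicating the study's
reporting; sibling segments of one trial may straddle the split), and
leave-one-subject-out validation with full retraining of the feature
extractor per fold.  Aggregation over splits uses the population (divide by
N) standard deviation, the convention that reconciles the published
per-split values with their printed mean/std row.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .crnn import CRNNConfig, extract_features, train_crnn
from .elm import elm_fit, elm_predict, internal_split
from .synthgen import QUADRANTS

logger = logging.getLogger(__name__)


@dataclass
class ConfusionMatrix:
    """4 x 4 counts: rows = predicted class, columns = true class."""

    counts: np.ndarray
    labels: Sequence[str] = QUADRANTS

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.labels), len(self.labels)):
            raise ValueError("confusion matrix shape does not match labels")
        if (self.counts < 0).any():
            raise ValueError("confusion-matrix cells must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass
class MetricsReport:
    """Per-class one-vs-rest metrics plus overall accuracy.

    A metric whose denominator is zero is undefined and reported as
    ``None`` (flagged in ``undefined``), never silently as 0.
    """

    precision: dict[str, float | None]
    sensitivity: dict[str, float | None]
    specificity: dict[str, float | None]
    f_measure: dict[str, float | None]
    accuracy: float
    undefined: list[tuple[str, str]] = field(default_factory=list)


def confusion_matrix(
    true_labels: Sequence, predicted_labels: Sequence, labels: Sequence[str] = QUADRANTS
) -> ConfusionMatrix:
    """Count (predicted, true) pairs into the row-predicted convention."""
    if len(true_labels) != len(predicted_labels):
        raise ValueError("label lists must have equal length")
    index = {lab: i for i, lab in enumerate(labels)}
    counts = np.zeros((len(labels), len(labels)), dtype=np.int64)
    for t, p in zip(true_labels, predicted_labels):
        if t not in index or p not in index:
            raise ValueError(f"unknown label in pair ({t!r}, {p!r})")
        counts[index[p], index[t]] += 1
    return ConfusionMatrix(counts, labels)


def metrics_from_cm(cm: ConfusionMatrix) -> MetricsReport:
    """Precision, sensitivity, specificity and F-measure per class."""
    c = cm.counts
    total = cm.total
    if total <= 0:
        raise ValueError("confusion matrix is empty")
    precision: dict[str, float | None] = {}
    sensitivity: dict[str, float | None] = {}
    specificity: dict[str, float | None] = {}
    f_measure: dict[str, float | None] = {}
    undefined: list[tuple[str, str]] = []

    def ratio(num, den, label, name):
        if den == 0:
            undefined.append((label, name))
            return None
        return num / den

    for i, lab in enumerate(cm.labels):
        tp = int(c[i, i])
        fp = int(c[i, :].sum()) - tp   # predicted i, truly something else
        fn = int(c[:, i].sum()) - tp   # truly i, predicted something else
        tn = total - tp - fp - fn
        precision[lab] = ratio(tp, tp + fp, lab, "precision")
        sensitivity[lab] = ratio(tp, tp + fn, lab, "sensitivity")
        specificity[lab] = ratio(tn, tn + fp, lab, "specificity")
        p, s = precision[lab], sensitivity[lab]
        if p is None or s is None or p + s == 0:
            undefined.append((lab, "f_measure"))
            f_measure[lab] = None
        else:
            f_measure[lab] = 2 * p * s / (p + s)
    return MetricsReport(
        precision=precision,
        sensitivity=sensitivity,
        specificity=specificity,
        f_measure=f_measure,
        accuracy=float(np.trace(c)) / total,
        undefined=undefined,
    )


def aggregate_accuracies(values: Sequence[float]) -> tuple[float, float]:
    """Mean and population (divide-by-N) standard deviation."""
    arr = np.asarray(values, dtype=float)
    return float(arr.mean()), float(arr.std(ddof=0))


@dataclass
class ProtocolResult:
    """Per-run accuracies with their mean/population-std aggregation."""

    accuracies: list[float]
    confusions: list[ConfusionMatrix] = field(default_factory=list)
    run_ids: list[str] = field(default_factory=list)

    @property
    def mean(self) -> float:
        return aggregate_accuracies(self.accuracies)[0]

    @property
    def std(self) -> float:
        return aggregate_accuracies(self.accuracies)[1]


@dataclass(frozen=True)
class PipelineConfig:
    """Everything one train-evaluate run needs downstream of the segments."""

    crnn: CRNNConfig = CRNNConfig()
    elm_hidden: int = 9000
    test_fraction: float = 0.2
    elm_validation_fraction: float = 0.2


def _index_labels(y: np.ndarray, labels: Sequence[str] = QUADRANTS) -> list[str]:
    return [labels[int(i)] for i in y]


def fit_and_score(
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_test: np.ndarray,
    y_test: np.ndarray,
    config: PipelineConfig,
    seed: int,
) -> tuple[float, ConfusionMatrix, dict]:
    """Train the CRNN extractor + ELM on the train side, score the test side.

    The ELM's internal 80:20 validation accuracy is reported alongside the
    fit (reporting only; nothing is tuned on it).
    """
    import dataclasses as _dc

    crnn_cfg = _dc.replace(config.crnn, seed=seed)
    params, history = train_crnn(X_train, y_train, crnn_cfg)
    feats_train = extract_features(X_train, params, crnn_cfg)
    feats_test = extract_features(X_test, params, crnn_cfg)

    rng = np.random.default_rng(np.random.SeedSequence([seed, 2]))
    (ftr, ytr), (fva, yva) = internal_split(
        feats_train, y_train, config.elm_validation_fraction, rng
    )
    model = elm_fit(ftr, ytr, n_hidden=config.elm_hidden, rng=rng)
    val_pred, _ = elm_predict(model, fva)
    val_acc = float((val_pred == yva).mean())

    pred, _ = elm_predict(model, feats_test)
    acc = float((pred == y_test).mean())
    cm = confusion_matrix(_index_labels(y_test), _index_labels(pred))
    info = {
        "elm_validation_accuracy": val_acc,
        "final_train_accuracy": history.epoch_accuracy[-1],
    }
    return acc, cm, info


def _split_indices(
    y: np.ndarray,
    test_fraction: float,
    random_state: int,
    groups: np.ndarray | None,
) -> tuple[np.ndarray, np.ndarray]:
    """One random 80/20 split: stratified at segment level, or group-held-out.

    ``groups=None`` reproduces the published protocol, which splits at
    segment level and therefore lets sibling segments of one trial straddle
    the train/test boundary.  Passing trial (or subject) identifiers keeps
    every group on one side of the split — the leakage-safe variant.
    """
    from sklearn.model_selection import GroupShuffleSplit, train_test_split

    idx = np.arange(y.size)
    if groups is None:
        tr, te = train_test_split(
            idx, test_size=test_fraction, random_state=random_state, stratify=y
        )
        return tr, te
    gss = GroupShuffleSplit(
        n_splits=1, test_size=test_fraction, random_state=random_state
    )
    return next(gss.split(idx, y, groups))


def random_split_protocol(
    X: np.ndarray,
    y: np.ndarray,
    config: PipelineConfig,
    n_repeats: int = 3,
    seed: int = 0,
    groups: np.ndarray | None = None,
) -> ProtocolResult:
    """``n_repeats`` random 80/20 splits (segment-level unless grouped)."""
    result = ProtocolResult(accuracies=[])
    ss = np.random.SeedSequence([seed, 3])
    child_seeds = ss.generate_state(n_repeats)
    for r, s in enumerate(child_seeds):
        s = int(s % (2**31 - 1))
        tr, te = _split_indices(y, config.test_fraction, s, groups)
        Xtr, Xte, ytr, yte = X[tr], X[te], y[tr], y[te]
        acc, cm, _ = fit_and_score(Xtr, ytr, Xte, yte, config, seed=s)
        result.accuracies.append(acc)
        result.confusions.append(cm)
        result.run_ids.append(f"split{r + 1}")
        logger.info("random split %d/%d: accuracy %.3f", r + 1, n_repeats, acc)
    return result


def loso_protocol(
    X: np.ndarray,
    y: np.ndarray,
    groups: np.ndarray,
    config: PipelineConfig,
    seed: int = 0,
) -> ProtocolResult:
    """Leave-one-subject-out: retrain extractor + ELM per held-out subject."""
    subjects = np.unique(groups)
    if subjects.size < 2:
        raise ValueError("leave-one-subject-out needs at least 2 subjects")
    result = ProtocolResult(accuracies=[])
    for k, subj in enumerate(subjects):
        mask = groups == subj
        if not mask.any():
            logger.warning("subject %s has no labeled segments; skipped", subj)
            continue
        if np.unique(y[~mask]).size < len(QUADRANTS):
            logger.warning(
                "subject %s fold: training side missing a class; skipped", subj
            )
            continue
        acc, cm, _ = fit_and_score(
            X[~mask], y[~mask], X[mask], y[mask], config, seed=seed + k
        )
        result.accuracies.append(acc)
        result.confusions.append(cm)
        result.run_ids.append(str(subj))
        logger.info("LOSO fold %s: accuracy %.3f", subj, acc)
    return result


def per_rhythm_evaluation(
    band_arrays: Mapping[str, tuple[np.ndarray, np.ndarray]],
    config: PipelineConfig,
    n_repeats: int = 3,
    seed: int = 0,
    include_combined: bool = False,
) -> dict[str, ProtocolResult]:
    """Run the random-split protocol per rhythm band.

    ``band_arrays`` maps band name -> (X, y) with identical sample order
    across bands.  With ``include_combined=True`` an extra entry trains one
    extractor per band and concatenates the per-band 32-dim features into
    the ELM (the all-band combination).
    """
    from sklearn.model_selection import train_test_split

    results = {
        band: random_split_protocol(X, y, config, n_repeats=n_repeats, seed=seed)
        for band, (X, y) in band_arrays.items()
    }
    if include_combined:
        import dataclasses as _dc

        bands = list(band_arrays)
        y = band_arrays[bands[0]][1]
        accs = []
        ss = np.random.SeedSequence([seed, 4])
        for r, s in enumerate(ss.generate_state(n_repeats)):
            s = int(s % (2**31 - 1))
            idx = np.arange(y.size)
            itr, ite = train_test_split(
                idx, test_size=config.test_fraction, random_state=s, stratify=y
            )
            feats_tr, feats_te = [], []
            for band in bands:
                Xb = band_arrays[band][0]
                cfg = _dc.replace(config.crnn, seed=s)
                params, _ = train_crnn(Xb[itr], y[itr], cfg)
                feats_tr.append(extract_features(Xb[itr], params, cfg))
                feats_te.append(extract_features(Xb[ite], params, cfg))
            rng = np.random.default_rng(np.random.SeedSequence([s, 5]))
            model = elm_fit(
                np.hstack(feats_tr), y[itr], n_hidden=config.elm_hidden, rng=rng
            )
            pred, _ = elm_predict(model, np.hstack(feats_te))
            accs.append(float((pred == y[ite]).mean()))
        results["combined"] = ProtocolResult(accuracies=accs)
    return results


def classifier_comparison(
    features: np.ndarray,
    labels: np.ndarray,
    seed: int = 0,
    test_fraction: float = 0.2,
    elm_hidden: int = 9000,
) -> dict[str, float]:
    """Accuracy of ELM vs softmax / SVM / kNN / random-forest baselines.

    All classifiers see the identical train/test fold of the same extracted
    features; the baselines run at their library defaults.
    """
    from sklearn.ensemble import RandomForestClassifier
    from sklearn.linear_model import LogisticRegression
    from sklearn.model_selection import train_test_split
    from sklearn.neighbors import KNeighborsClassifier
    from sklearn.svm import SVC

    Xtr, Xte, ytr, yte = train_test_split(
        features, labels, test_size=test_fraction, random_state=seed, stratify=labels
    )
    out: dict[str, float] = {}
    model = elm_fit(Xtr, ytr, n_hidden=elm_hidden, rng=seed)
    pred, _ = elm_predict(model, Xte)
    out["ELM"] = float((pred == yte).mean())
    baselines = {
        "softmax": LogisticRegression(max_iter=2000),
        "SVM": SVC(),
        "kNN": KNeighborsClassifier(),
        "RandomForest": RandomForestClassifier(random_state=seed),
    }
    for name, clf in baselines.items():
        clf.fit(Xtr, ytr)
        out[name] = float(clf.score(Xte, yte))
    return out
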