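"""Relevance-based evaluation of stopping policies.

Every window a stopping rule visits is a decision: waiting is a negative
decision, emitting is the single positive decision of the trial. Crossing
these with whether the current argmax equals the true label gives the four
outcomes (tp/fp/tn/fn) from which precision, recall, specificity and
F-score are computed. Accuracy, mean stopping time and the Wolpaw
information transfer rate complete the picture; cross-validated
hyper-parameter sweeps produce the accuracy-vs-time and precision-vs-time
curves used to compare methods.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import KFold, StratifiedKFold

from . import baselines, bds
from .reconvolution import fit_reconvolution_cca, predict_templates, score_stream
from .simulate import SyntheticDataset

logger = logging.getLogger(__name__)

METHODS = ("fixed", "static-acc", "static-target", "static-itr", "margin", "beta", "bds")


@dataclass
class TrialRecord:
    """All decisions one stopping rule made on one trial."""

    true_label: int
    predicted: int
    stop_window: int
    stop_time: float
    forced: bool
    pre_stop_argmax: list[int]  # argmax class at every visited pre-stop window


@dataclass
class DecisionLog:
    """Per-trial decision records; the substrate of precision/recall."""

    records: list[TrialRecord] = field(default_factory=list)

    def append(self, decision: bds.StoppingDecision, true_label: int) -> None:
        pre = [int(np.argmax(f.scores)) for f in decision.score_trace[:-1]]
        self.records.append(
            TrialRecord(
                true_label=int(true_label),
                predicted=decision.predicted,
                stop_window=decision.stop_window,
                stop_time=decision.stop_time,
                forced=decision.forced,
                pre_stop_argmax=pre,
            )
        )

    def __len__(self) -> int:
        return len(self.records)


@dataclass
class ConfusionCounts:
    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0


@dataclass
class MetricsRow:
    accuracy: float
    mean_stop_time: float
    precision: float
    recall: float
    specificity: float
    f_score: float
    itr: float
    hyper: float | None = None


def confusion_counts(log: DecisionLog, forced_positive: bool = True) -> ConfusionCounts:
    """Count the four decision outcomes over all per-window decisions.

    Pre-stop (negative) decisions: the current argmax equals the true label
    -> miss (fn), otherwise a correct rejection (tn). The stopping (positive)
    decision: prediction equals the true label -> hit (tp), otherwise a
    false accept (fp). A forced stop counts as a positive decision by
    default; with ``forced_positive=False`` it is scored as one more
    negative decision instead.
    """
    c = ConfusionCounts()
    for rec in log.records:
        for g in rec.pre_stop_argmax:
            if g == rec.true_label:
                c.fn += 1
            else:
                c.tn += 1
        if rec.forced and not forced_positive:
            if rec.predicted == rec.true_label:
                c.fn += 1
            else:
                c.tn += 1
        elif rec.predicted == rec.true_label:
            c.tp += 1
        else:
            c.fp += 1
    return c


def _safe_ratio(num: float, den: float, name: str) -> float:
    if den == 0:
        logger.warning("%s undefined (zero denominator); reporting 0", name)
        return 0.0
    return num / den


def precision(c: ConfusionCounts) -> float:
    return _safe_ratio(c.tp, c.tp + c.fp, "precision")


def recall(c: ConfusionCounts) -> float:
    return _safe_ratio(c.tp, c.tp + c.fn, "recall")


def specificity(c: ConfusionCounts) -> float:
    return _safe_ratio(c.tn, c.tn + c.fp, "specificity")


def f_score(c: ConfusionCounts) -> float:
    p, r = precision(c), recall(c)
    return _safe_ratio(2.0 * p * r, p + r, "f_score")


def itr(
    accuracy: float, n_classes: int, trial_time_s: float, overhead_s: float = 0.0
) -> float:
    """Wolpaw information transfer rate in bits per minute.

    bits/selection = log2 N + P log2 P + (1-P) log2((1-P)/(N-1)), with the
    P in {0, 1} limits taken and negative bit rates clipped to zero.
    """
    P, N = float(accuracy), int(n_classes)
    if not 0.0 <= P <= 1.0:
        raise ValueError("accuracy must be in [0, 1]")
    if N < 2 or trial_time_s <= 0:
        raise ValueError("need n_classes >= 2 and trial_time_s > 0")
    bits = np.log2(N)
    if P > 0:
        bits += P * np.log2(P)
    if P < 1:
        bits += (1 - P) * np.log2((1 - P) / (N - 1))
    bits = max(bits, 0.0)
    return float(bits * 60.0 / (trial_time_s + overhead_s))


@dataclass
class MethodSpec:
    """A stopping method plus its hyper-parameters.

    ``hyper`` is the method's swept hyper-parameter: cost ratio zeta for
    ``bds``; targeted accuracy for ``static-target``, ``margin`` and
    ``beta``; the stopping time in seconds for ``fixed`` (None = full
    length). ``static-acc`` and ``static-itr`` have no hyper-parameter.
    """

    name: str
    hyper: float | None = None
    similarity_kind: str = "inner"
    grid_step_s: float = 0.1
    inner_folds: int = 5
    forced_positive: bool = True
    overhead_s: float = 0.0

    def __post_init__(self) -> None:
        if self.name not in METHODS:
            raise ValueError(f"method must be one of {METHODS}")
        if self.name == "beta":
            self.similarity_kind = "pearson"
        if self.name == "bds":
            self.similarity_kind = "inner"


def _decode_fold(
    dataset: SyntheticDataset,
    spec: MethodSpec,
    train_idx: np.ndarray,
    test_idx: np.ndarray,
    grid: np.ndarray,
    seed: int,
) -> DecisionLog:
    fs = dataset.config.sample_rate
    trials, labels = dataset.trials, dataset.labels
    w, r = fit_reconvolution_cca(trials[train_idx], labels[train_idx], dataset.structures)
    templates = predict_templates(r, dataset.structures, fs)
    n_classes = templates.n_classes
    last = grid.size - 1

    if spec.name == "bds":
        model = bds.calibrate_bds(
            trials[train_idx], labels[train_idx], w, templates, grid,
            zeta=spec.hyper if spec.hyper is not None else 1.0,
        )
    elif spec.name == "margin":
        streams = [
            score_stream(trials[i], w, templates, grid, spec.similarity_kind)
            for i in train_idx
        ]
        rule = baselines.calibrate_margin(
            streams, labels[train_idx], grid,
            spec.hyper if spec.hyper is not None else 0.9,
        )
    elif spec.name in ("static-acc", "static-target", "static-itr"):
        curve = baselines.decoding_curve(
            trials[train_idx], labels[train_idx], dataset.structures, grid, fs,
            n_folds=spec.inner_folds, similarity_kind=spec.similarity_kind, seed=seed,
        )
        criterion = {
            "static-acc": "max-accuracy",
            "static-target": "targeted",
            "static-itr": "max-itr",
        }[spec.name]
        static = baselines.static_rule(
            curve, criterion, n_classes,
            target_accuracy=spec.hyper, overhead_s=spec.overhead_s,
        )
    elif spec.name == "fixed":
        if spec.hyper is None:
            k_fixed = last
        else:
            k_fixed = int(np.argmin(np.abs(grid / fs - spec.hyper)))

    log = DecisionLog()
    for i in test_idx:
        stream = score_stream(trials[i], w, templates, grid, spec.similarity_kind)
        if spec.name == "bds":
            decision = bds.decide(stream, model)
        elif spec.name == "margin":
            decision = baselines.apply_margin(stream, rule, fs)
        elif spec.name == "beta":
            decision = baselines.apply_beta(
                stream, spec.hyper if spec.hyper is not None else 0.95, grid, fs
            )
        else:
            k = static.stop_window if spec.name.startswith("static") else k_fixed
            decision = bds.StoppingDecision(
                stop_window=k,
                stop_time=float(grid[k] / fs),
                predicted=int(np.argmax(stream[k].scores)),
                forced=False,
                score_trace=list(stream[: k + 1]),
            )
        log.append(decision, dataset.labels[i])
    return log


def metrics_from_log(
    log: DecisionLog,
    n_classes: int,
    forced_positive: bool = True,
    overhead_s: float = 0.0,
    hyper: float | None = None,
) -> MetricsRow:
    """Summarize a decision log into one metrics row."""
    preds = np.array([r.predicted for r in log.records])
    truths = np.array([r.true_label for r in log.records])
    times = np.array([r.stop_time for r in log.records])
    acc = float((preds == truths).mean())
    mean_time = float(times.mean())
    c = confusion_counts(log, forced_positive)
    return MetricsRow(
        accuracy=acc,
        mean_stop_time=mean_time,
        precision=precision(c),
        recall=recall(c),
        specificity=specificity(c),
        f_score=f_score(c),
        itr=itr(acc, n_classes, mean_time, overhead_s),
        hyper=hyper,
    )


def crossvalidate(
    dataset: SyntheticDataset,
    spec: MethodSpec,
    n_folds: int = 5,
    seed: int = 0,
    return_logs: bool = False,
):
    """Cross-validated evaluation of one stopping method.

    Per fold: calibrate the classifier and stopping rule on the training
    split, decode the held-out trials on the decision grid, log every
    decision, and compute the metrics row. Returns a DataFrame with one row
    per fold plus a ``mean`` row (and optionally the per-fold decision logs).
    """
    fs = dataset.config.sample_rate
    grid = bds.make_grid(spec.grid_step_s, dataset.n_samples / fs, fs)
    labels = dataset.labels
    counts = np.bincount(labels)
    if counts.min() >= n_folds:
        splitter = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
        splits = list(splitter.split(dataset.trials, labels))
    else:
        splits = list(
            KFold(n_splits=n_folds, shuffle=True, random_state=seed).split(dataset.trials)
        )
    rows, logs = [], []
    for fold, (tr, te) in enumerate(splits):
        log = _decode_fold(dataset, spec, tr, te, grid, seed)
        row = metrics_from_log(
            log, dataset.config.n_classes, spec.forced_positive, spec.overhead_s,
            hyper=spec.hyper,
        )
        rows.append({"fold": fold, **row.__dict__})
        logs.append(log)
    df = pd.DataFrame(rows)
    mean = df.drop(columns="fold").mean(numeric_only=True)
    mean["fold"] = "mean"
    df = pd.concat([df, mean.to_frame().T], ignore_index=True)
    if return_logs:
        return df, logs
    return df


def sweep(
    dataset: SyntheticDataset,
    method: str,
    hyper_values,
    n_folds: int = 5,
    seed: int = 0,
    **spec_kwargs,
) -> pd.DataFrame:
    """One cross-validated metrics row per hyper-parameter value.

    The resulting table backs accuracy-vs-time and precision-vs-time curves.
    """
    hyper_values = list(hyper_values)
    if not hyper_values:
        raise ValueError("empty hyper-parameter grid")
    rows = []
    for h in hyper_values:
        spec = MethodSpec(name=method, hyper=float(h), **spec_kwargs)
        df = crossvalidate(dataset, spec, n_folds=n_folds, seed=seed)
        mean = df[df["fold"] == "mean"].iloc[0].drop("fold")
        mean["hyper"] = float(h)
        rows.append(mean)
    return pd.DataFrame(rows).reset_index(drop=True)
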