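"""Baseline stopping rules: fixed length, static rules from decoding curves,
the calibrated margin rule, and the calibration-free Beta rule.

These are the comparison methods the Bayesian stopping procedure is judged
against. The static rules pick one stopping time for all trials from an
inner cross-validated decoding curve; the margin rule learns per-window
thresholds on the gap between the best and runner-up scores; the Beta rule
fits a Beta distribution to the non-maximum correlations at test time and
stops when the maximum is a sufficiently improbable draw from it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.stats
from sklearn.model_selection import StratifiedKFold

from .bds import StoppingDecision
from .reconvolution import (
    ScoreVector,
    TemplateSet,
    fit_reconvolution_cca,
    predict_templates,
    score_stream,
)

logger = logging.getLogger(__name__)

STATIC_CRITERIA = ("max-accuracy", "targeted", "max-itr")


@dataclass
class DecodingCurve:
    """Cross-validated classification accuracy per decision-window length."""

    windows: np.ndarray  # samples, strictly increasing
    accuracy: np.ndarray  # fraction correct, averaged over folds
    sample_rate: float

    def __post_init__(self) -> None:
        self.windows = np.asarray(self.windows, dtype=int)
        self.accuracy = np.asarray(self.accuracy, dtype=float)
        if (np.diff(self.windows) <= 0).any():
            raise ValueError("windows must be strictly increasing")
        if ((self.accuracy < 0) | (self.accuracy > 1)).any():
            raise ValueError("accuracy must lie in [0, 1]")


@dataclass
class StaticStopRule:
    """Uniform stopping time for every trial."""

    stop_window: int  # index into the grid
    stop_len: int  # samples
    stop_time: float  # seconds
    criterion: str


@dataclass
class MarginRule:
    """Per-window thresholds on the best-minus-runner-up score margin."""

    thresholds: np.ndarray  # one per window; +inf = never stop here
    target_accuracy: float
    grid: np.ndarray


def decoding_curve(
    train_trials: np.ndarray,
    labels: np.ndarray,
    structures,
    grid: np.ndarray,
    sample_rate: float,
    n_folds: int = 5,
    similarity_kind: str = "inner",
    seed: int = 0,
) -> DecodingCurve:
    """Inner cross-validated decoding curve on the training split.

    Per fold: fit the reconvolution CCA classifier on the fold's training
    part, classify the validation trials at every window, then average the
    per-window accuracy over folds.
    """
    trials = np.asarray(train_trials, dtype=float)
    labels = np.asarray(labels, dtype=int)
    grid = np.asarray(grid, dtype=int)
    if trials.shape[0] < n_folds:
        raise ValueError("fewer trials than folds")
    counts = np.bincount(labels)
    stratify = counts.min() >= n_folds
    if stratify:
        splitter = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
        splits = splitter.split(trials, labels)
    else:
        from sklearn.model_selection import KFold

        splits = KFold(n_splits=n_folds, shuffle=True, random_state=seed).split(trials)
    acc = np.zeros((n_folds, grid.size))
    for k, (tr, va) in enumerate(splits):
        w, r = fit_reconvolution_cca(trials[tr], labels[tr], structures)
        templates = predict_templates(r, structures, sample_rate)
        for trial, y in zip(trials[va], labels[va]):
            stream = score_stream(trial, w, templates, grid, similarity_kind)
            preds = np.array([int(np.argmax(f.scores)) for f in stream])
            acc[k] += preds == y
        acc[k] /= va.size
    return DecodingCurve(grid, acc.mean(axis=0), sample_rate)


def static_rule(
    curve: DecodingCurve,
    criterion: str,
    n_classes: int,
    target_accuracy: float | None = None,
    overhead_s: float = 0.0,
) -> StaticStopRule:
    """Pick one stopping time from a decoding curve.

    ``max-accuracy``: earliest window attaining the curve maximum;
    ``targeted``: earliest window with accuracy >= target_accuracy, falling
    back to the max-accuracy window when the target is never reached;
    ``max-itr``: the window maximizing the information transfer rate.
    """
    from .evaluation import itr

    if curve.windows.size == 0:
        raise ValueError("empty decoding curve")
    if criterion == "max-accuracy":
        k = int(np.argmax(curve.accuracy))  # argmax returns the earliest maximum
    elif criterion == "targeted":
        if target_accuracy is None:
            raise ValueError("targeted criterion needs target_accuracy")
        hits = np.flatnonzero(curve.accuracy >= target_accuracy)
        if hits.size:
            k = int(hits[0])
        else:
            k = int(np.argmax(curve.accuracy))
            logger.info(
                "targeted accuracy %.2f never reached; falling back to the "
                "max-accuracy window", target_accuracy,
            )
    elif criterion == "max-itr":
        rates = [
            itr(p, n_classes, w / curve.sample_rate, overhead_s)
            for p, w in zip(curve.accuracy, curve.windows)
        ]
        k = int(np.argmax(rates))
    else:
        raise ValueError(f"criterion must be one of {STATIC_CRITERIA}")
    return StaticStopRule(
        stop_window=k,
        stop_len=int(curve.windows[k]),
        stop_time=float(curve.windows[k] / curve.sample_rate),
        criterion=criterion,
    )


def _margins(scores: np.ndarray) -> float:
    top2 = np.partition(scores, -2)[-2:]
    return float(top2[1] - top2[0])


def calibrate_margin(
    score_streams,
    labels: np.ndarray,
    grid: np.ndarray,
    target_accuracy: float,
) -> MarginRule:
    """Learn per-window margin thresholds achieving a targeted accuracy.

    For each window the candidate thresholds are the observed training
    margins; the smallest candidate m* such that the trials with margin
    >= m* are classified correctly at a rate >= target_accuracy becomes the
    threshold, or +inf if no candidate attains the target. A target of 0
    yields -inf (stop at the first window regardless of margin).
    """
    labels = np.asarray(labels, dtype=int)
    grid = np.asarray(grid, dtype=int)
    streams = [list(st) for st in score_streams]
    n_windows = grid.size
    thresholds = np.full(n_windows, np.inf)
    for s in range(n_windows):
        margins = np.array([_margins(st[s].scores) for st in streams])
        correct = np.array(
            [int(np.argmax(st[s].scores)) == y for st, y in zip(streams, labels)]
        )
        if target_accuracy <= 0:
            thresholds[s] = -np.inf
            continue
        for m_star in np.sort(np.unique(margins)):
            keep = margins >= m_star
            if keep.any() and correct[keep].mean() >= target_accuracy:
                thresholds[s] = m_star
                break
    return MarginRule(thresholds=thresholds, target_accuracy=target_accuracy, grid=grid)


def apply_margin(
    score_stream, rule: MarginRule, sample_rate: float
) -> StoppingDecision:
    """Stop as soon as the best-minus-runner-up margin reaches the learned
    threshold; forced argmax emission at the last window."""
    stream = list(score_stream)
    if len(stream) == 0:
        raise ValueError("empty score stream")
    if len(stream) != rule.grid.size:
        raise ValueError("score stream length must match the rule grid")
    trace: list[ScoreVector] = []
    last = len(stream) - 1
    for k, f in enumerate(stream):
        trace.append(f)
        if _margins(f.scores) >= rule.thresholds[k]:
            return StoppingDecision(
                stop_window=k,
                stop_time=float(rule.grid[k] / sample_rate),
                predicted=int(np.argmax(f.scores)),
                forced=False,
                score_trace=trace,
            )
        if k == last:
            return StoppingDecision(
                stop_window=k,
                stop_time=float(rule.grid[k] / sample_rate),
                predicted=int(np.argmax(f.scores)),
                forced=True,
                score_trace=trace,
            )
    raise AssertionError("unreachable")


def fit_beta_mle(samples: np.ndarray) -> tuple[float, float]:
    """Maximum-likelihood Beta(a, b) fit on (0, 1) samples, method-of-moments
    initialized; thin wrapper kept separate so tests can cross-check it."""
    a, b, _, _ = scipy.stats.beta.fit(samples, floc=0.0, fscale=1.0)
    return float(a), float(b)


def apply_beta(
    score_stream,
    target_accuracy: float,
    grid: np.ndarray,
    sample_rate: float,
    clip: float = 1e-6,
) -> StoppingDecision:
    """Calibration-free Beta rule on Pearson scores.

    Per window: map correlations through (rho + 1)/2 to [0, 1], fit a Beta
    distribution by maximum likelihood to the non-maximum mapped scores, and
    stop when the fitted CDF at the mapped maximum reaches the targeted
    accuracy, i.e. when the maximum is improbable under the non-target score
    distribution. Degenerate windows (all scores equal) never stop.
    """
    stream = list(score_stream)
    grid = np.asarray(grid, dtype=int)
    if len(stream) == 0:
        raise ValueError("empty score stream")
    if len(stream) != grid.size:
        raise ValueError("score stream length must match the grid")
    if stream[0].similarity_kind != "pearson":
        raise ValueError(
            "the Beta rule requires bounded (pearson) scores; the inner "
            "product is unbounded and unsupported"
        )
    if stream[0].scores.size < 3:
        raise ValueError("the Beta rule needs at least 3 classes")
    trace: list[ScoreVector] = []
    last = len(stream) - 1
    for k, f in enumerate(stream):
        trace.append(f)
        mapped = np.clip((f.scores + 1.0) / 2.0, clip, 1.0 - clip)
        best = int(np.argmax(f.scores))
        rest = np.delete(mapped, best)
        stop_here = False
        if np.ptp(rest) > 0:  # degenerate (all-equal) windows cannot stop
            a, b = fit_beta_mle(rest)
            stop_here = scipy.stats.beta.cdf(mapped[best], a, b) >= target_accuracy
        if stop_here or k == last:
            return StoppingDecision(
                stop_window=k,
                stop_time=float(grid[k] / sample_rate),
                predicted=best,
                forced=not stop_here,
                score_trace=trace,
            )
    raise AssertionError("unreachable")
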