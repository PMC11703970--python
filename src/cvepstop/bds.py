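"""Bayesian dynamic stopping (BDS): risk-minimizing trial-by-trial stopping.

The single-channel generative model is x = alpha * t_y + eps with iid
Gaussian noise eps ~ N(0, sigma). Under it, the inner-product score of a
candidate class is Gaussian, target scores ~ N(alpha*b1, sigma1) and
non-target scores ~ N(alpha*b0, sigma0), with moments computed from the
template Gram matrix at each decision-window length. The Bayes test for
"emit now" vs "wait" with false-positive/false-negative cost ratio zeta
reduces to a likelihood-ratio test whose log form is quadratic in the
score; the decision boundary eta is the root of that quadratic. A trial is
decoded as soon as any class score exceeds eta, or forcibly at the maximum
trial length t*.

Multi-class problems are handled one-vs-rest with equal class priors, which
merges the priors into the factor (N - 1) on the test threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .reconvolution import ScoreVector, SpatialFilter, TemplateSet

logger = logging.getLogger(__name__)


@dataclass
class DistributionParams:
    """Target/non-target Gaussian score moments at one window length.

    ``b1``/``b0`` are the mean target and cross template inner products
    (before alpha scaling); ``var1``/``var0`` the target and non-target
    score variances, each the sum of a noise term sigma^2*b1 and the spread
    of the per-class template inner products around their mean.
    """

    alpha: float
    sigma: float
    b1: float
    b0: float
    var1: float
    var0: float
    window_len: int

    @property
    def sigma1(self) -> float:
        return float(np.sqrt(self.var1))

    @property
    def sigma0(self) -> float:
        return float(np.sqrt(self.var0))


@dataclass
class QuadraticCoeffs:
    """Coefficients of the quadratic form of the log likelihood-ratio test:
    a*f^2 + b*f + c > 0 accepts (equivalently ln Lambda(f) > ln((N-1)*zeta))."""

    a: float
    b: float
    c: float
    zeta: float
    n_classes: int


@dataclass
class StoppingModel:
    """Calibrated per-window stopping parameters and decision boundaries."""

    grid: np.ndarray  # decision-window lengths, samples, strictly increasing
    params: list[DistributionParams]
    eta: np.ndarray  # decision boundary per window; +/-inf sentinels allowed
    zeta: float
    max_len: int  # forced-stop length t*, samples
    n_classes: int
    sample_rate: float

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=int)
        self.eta = np.asarray(self.eta, dtype=float)
        if (np.diff(self.grid) <= 0).any():
            raise ValueError("grid must be strictly increasing")
        if self.grid[-1] != self.max_len:
            raise ValueError("last grid window must equal max_len")
        if self.grid.size != self.eta.size or len(self.params) != self.grid.size:
            raise ValueError("grid, params and eta must have equal length")


@dataclass
class StoppingDecision:
    """Outcome of the sequential procedure for one trial."""

    stop_window: int
    stop_time: float  # seconds
    predicted: int
    forced: bool
    score_trace: list[ScoreVector] = field(default_factory=list)


def estimate_alpha_sigma(
    filtered_trials: np.ndarray, matched_templates: np.ndarray
) -> tuple[float, float]:
    """Least-squares estimate of the scale alpha and residual noise sigma.

    Both inputs are 1-D concatenations (training trials laid end to end, and
    the templates of their true labels likewise). alpha = (t.x)/(t.t); sigma
    is the population standard deviation of the residual x - alpha*t.
    """
    x = np.asarray(filtered_trials, dtype=float).ravel()
    t = np.asarray(matched_templates, dtype=float).ravel()
    if x.size != t.size:
        raise ValueError("data and template concatenations must have equal length")
    tt = t @ t
    if tt == 0:
        raise ValueError("matched templates are identically zero")
    alpha = float(t @ x / tt)
    if alpha < 0:
        logger.warning(
            "estimated alpha = %.4g is negative (anticorrelated projection); "
            "check the spatial-filter sign convention", alpha,
        )
    sigma = float(np.std(x - alpha * t))  # population convention (ddof=0)
    return alpha, sigma


def class_distribution_params(
    templates: TemplateSet | np.ndarray,
    window_len: int,
    alpha: float,
    sigma: float,
) -> DistributionParams:
    """Target/non-target Gaussian moments from the truncated template Gram.

    b1 = mean_i ||t_i||^2, b0 = mean_{i != j} t_i.t_j,
    var1 = sigma^2*b1 + mean_i (alpha*t_i.t_i - alpha*b1)^2,
    var0 = sigma^2*b1 + mean_{i != j} (alpha*t_i.t_j - alpha*b0)^2.
    """
    t = templates.truncated(window_len) if isinstance(templates, TemplateSet) else np.asarray(templates, dtype=float)[:, :window_len]
    N = t.shape[0]
    if N < 2:
        raise ValueError("at least 2 classes are required")
    G = t @ t.T
    diag = np.diag(G)
    off_mask = ~np.eye(N, dtype=bool)
    off = G[off_mask]
    b1 = float(diag.mean())
    b0 = float(off.mean())
    var1 = float(sigma**2 * b1 + np.mean((alpha * diag - alpha * b1) ** 2))
    var0 = float(sigma**2 * b1 + np.mean((alpha * off - alpha * b0) ** 2))
    return DistributionParams(alpha, sigma, b1, b0, var1, var0, window_len)


def log_likelihood_ratio(f, p: DistributionParams):
    """ln of the target/non-target Gaussian density ratio at score f.

    Direct form: ln(sigma0/sigma1) - (f - a*b1)^2/(2*var1)
    + (f - a*b0)^2/(2*var0). This is the oracle the quadratic test is
    verified against.
    """
    if p.var0 <= 0 or p.var1 <= 0:
        raise ValueError("variances must be positive")
    f = np.asarray(f, dtype=float)
    out = (
        0.5 * np.log(p.var0 / p.var1)
        - (f - p.alpha * p.b1) ** 2 / (2.0 * p.var1)
        + (f - p.alpha * p.b0) ** 2 / (2.0 * p.var0)
    )
    return float(out) if out.ndim == 0 else out


def quadratic_coefficients(
    p: DistributionParams, zeta: float, n_classes: int
) -> QuadraticCoeffs:
    """Coefficients of 2*var0*var1*(ln Lambda(f) - ln((N-1)*zeta)) as a
    polynomial in f, so that a*f^2 + b*f + c > 0 accepts the target
    hypothesis.

    a = var1 - var0
    b = -2*alpha*(var1*b0 - var0*b1)
    c = -alpha^2*(var0*b1^2 - var1*b0^2) + 2*var0*var1*ln(sigma0/(sigma1*(N-1)*zeta))
    """
    if zeta <= 0:
        raise ValueError("zeta must be positive")
    if n_classes < 2:
        raise ValueError("n_classes must be >= 2")
    a = p.var1 - p.var0
    b = -2.0 * p.alpha * (p.var1 * p.b0 - p.var0 * p.b1)
    c = -(p.alpha**2) * (p.var0 * p.b1**2 - p.var1 * p.b0**2) + 2.0 * p.var0 * p.var1 * (
        0.5 * np.log(p.var0 / p.var1) - np.log((n_classes - 1) * zeta)
    )
    return QuadraticCoeffs(float(a), float(b), float(c), float(zeta), int(n_classes))


def decision_boundary(q: QuadraticCoeffs, tol: float = 1e-12) -> float:
    """Root of the acceptance quadratic: the per-window score threshold eta.

    Uses the '+' branch (the larger root when a > 0, the typical case since
    target-norm spread inflates var1). Near-degenerate quadratics fall back
    to the linear solution -c/b. When no real root exists the quadratic has
    one sign everywhere and eta is a sentinel: -inf (always accept) if it is
    positive, +inf (never accept) otherwise.
    """
    a, b, c = q.a, q.b, q.c
    scale = abs(b) + abs(c)
    if abs(a) < tol * max(scale, 1.0):
        if abs(b) < tol * max(abs(c), 1.0):
            raise ValueError("degenerate stopping model: both a and b vanish")
        if b < 0:
            logger.debug("linear acceptance region is f < -c/b (b < 0)")
        return float(-c / b)
    if a < 0:
        logger.debug(
            "a = var1 - var0 < 0: acceptance region is an interval; using the "
            "single '+'-branch threshold"
        )
    disc = b * b - 4.0 * a * c
    if disc >= 0:
        return float((-b + np.sqrt(disc)) / (2.0 * a))
    # no real root: constant sign = sign of a
    return float(-np.inf) if a > 0 else float(np.inf)


def make_grid(step_s: float, max_s: float, sample_rate: float) -> np.ndarray:
    """Decision-window grid in samples: step_s, 2*step_s, ..., max_s.

    Default usage mirrors stimulation time points every 100 ms up to the
    maximum trial length.
    """
    step = int(round(step_s * sample_rate))
    max_len = int(round(max_s * sample_rate))
    if step < 1 or max_len < step:
        raise ValueError("invalid grid specification")
    grid = np.arange(step, max_len + 1, step)
    if grid[-1] != max_len:
        grid = np.append(grid, max_len)
    return grid


def calibrate_bds(
    train_trials: np.ndarray,
    labels: np.ndarray,
    w: SpatialFilter,
    templates: TemplateSet,
    grid: np.ndarray,
    zeta: float = 1.0,
    max_len: int | None = None,
) -> StoppingModel:
    """Estimate (alpha, sigma) once at full length, then per decision window
    the Gaussian moments and the decision boundary eta.

    ``train_trials`` is a K x C x T stack; the trials are spatially filtered
    and concatenated, matched against the concatenated templates of their
    true labels.
    """
    grid = np.asarray(grid, dtype=int)
    if max_len is None:
        max_len = int(grid[-1])
    trials = np.asarray(train_trials, dtype=float)
    labels = np.asarray(labels, dtype=int)
    px = w.project(trials)  # K x T
    x = px.ravel()
    t = templates.templates[labels].ravel()
    alpha, sigma = estimate_alpha_sigma(x, t)
    params, eta = [], []
    for s in grid:
        p = class_distribution_params(templates, int(s), alpha, sigma)
        q = quadratic_coefficients(p, zeta, templates.n_classes)
        params.append(p)
        eta.append(decision_boundary(q))
    return StoppingModel(
        grid=grid,
        params=params,
        eta=np.array(eta),
        zeta=zeta,
        max_len=max_len,
        n_classes=templates.n_classes,
        sample_rate=templates.sample_rate,
    )


def decide(score_stream, model: StoppingModel) -> StoppingDecision:
    """Run the sequential stopping procedure over a stream of score vectors.

    At each window, emit iff any inner-product score exceeds eta at that
    window (or the last window is reached). Among several passing classes
    the one with the highest target-distribution likelihood wins; with equal
    target variances across classes that is the score closest to the target
    mean alpha*b1. At a forced stop the plain argmax is emitted.
    """
    stream = list(score_stream)
    if len(stream) == 0:
        raise ValueError("empty score stream")
    if len(stream) != model.grid.size:
        raise ValueError("score stream length must match the model grid")
    trace: list[ScoreVector] = []
    last = len(stream) - 1
    for k, f in enumerate(stream):
        trace.append(f)
        scores = f.scores
        passing = np.flatnonzero(scores > model.eta[k])
        if passing.size > 0:
            target_mean = model.params[k].alpha * model.params[k].b1
            predicted = int(passing[np.argmin(np.abs(scores[passing] - target_mean))])
            return StoppingDecision(
                stop_window=k,
                stop_time=float(model.grid[k] / model.sample_rate),
                predicted=predicted,
                forced=False,
                score_trace=trace,
            )
        if k == last:
            return StoppingDecision(
                stop_window=k,
                stop_time=float(model.grid[k] / model.sample_rate),
                predicted=int(np.argmax(scores)),
                forced=True,
                score_trace=trace,
            )
    raise AssertionError("unreachable")
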