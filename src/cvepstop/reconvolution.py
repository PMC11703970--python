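"""Reconvolution CCA template matching for c-VEP decoding.

A single-trial recording X (channels x samples) is modelled as a rank-one
mixture of a virtual source channel that itself is the superposition of
transient responses to the short and long flashes of the stimulus sequence.
Canonical correlation analysis jointly learns the spatial filter w (mixing
inverse) and the temporal response kernel r such that w'X correlates
maximally with r'M_y, where M_y is the event structure matrix of the
attended stimulus. Class templates t_i = r'M_i then serve as matched-filter
references; trials are scored by inner product (the score the Bayesian
stopping model is built on) or Pearson correlation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .codes import StructureMatrix

logger = logging.getLogger(__name__)

SIMILARITY_KINDS = ("inner", "pearson")


@dataclass
class SpatialFilter:
    """Per-channel weights projecting multichannel EEG onto the source channel."""

    weights: np.ndarray

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float).ravel()
        if not np.isfinite(self.weights).all():
            raise ValueError("spatial filter weights must be finite")

    def project(self, X: np.ndarray) -> np.ndarray:
        """Project a (C x T) trial (or K x C x T stack) to the virtual channel."""
        X = np.asarray(X, dtype=float)
        return np.tensordot(self.weights, X, axes=(0, -2))


@dataclass
class TemporalResponse:
    """Concatenated event kernels, one block per event kind (length M)."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if not np.isfinite(self.values).all():
            raise ValueError("temporal response must be finite")


@dataclass
class TemplateSet:
    """Predicted source-channel responses t_i, one row per class."""

    templates: np.ndarray
    sample_rate: float

    def __post_init__(self) -> None:
        self.templates = np.atleast_2d(np.asarray(self.templates, dtype=float))

    @property
    def n_classes(self) -> int:
        return self.templates.shape[0]

    @property
    def n_samples(self) -> int:
        return self.templates.shape[1]

    def truncated(self, window_len: int) -> np.ndarray:
        return self.templates[:, :window_len]


@dataclass
class ScoreVector:
    """Per-class similarity scores at one decision-window length."""

    scores: np.ndarray
    similarity_kind: str
    window_len: int

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float).ravel()
        if self.similarity_kind not in SIMILARITY_KINDS:
            raise ValueError(f"similarity_kind must be one of {SIMILARITY_KINDS}")


def _as_structure_entries(structures) -> list[np.ndarray]:
    out = []
    for s in structures:
        out.append(s.entries.astype(float) if isinstance(s, StructureMatrix) else np.asarray(s, dtype=float))
    return out


def fit_reconvolution_cca(
    trials: np.ndarray,
    labels: np.ndarray,
    structures,
    ridge: float = 1e-8,
) -> tuple[SpatialFilter, TemporalResponse]:
    """Learn the spatial filter and temporal response from labeled trials.

    Builds the channel-wise concatenation S (C x K*T) of the K training
    trials and the stack D (M x K*T) of the structure matrices matching each
    trial's label, then solves the leading canonical pair maximizing the
    Pearson correlation between w'S and r'D.

    The generalized eigenproblem is regularized with a trace-scaled ridge on
    both auto-covariance blocks, since structure matrices are rank-deficient
    at short windows. Convention: w has unit Euclidean norm and the sign
    making the canonical correlation positive; r absorbs the remaining scale
    via a least-squares fit of r'D onto w'S, so that templates live on the
    amplitude scale of the projected data.
    """
    trials = np.asarray(trials, dtype=float)
    if trials.ndim != 3:
        raise ValueError("trials must be a K x C x T array")
    K, C, T = trials.shape
    if K < 2:
        raise ValueError("at least 2 training trials are required")
    labels = np.asarray(labels, dtype=int)
    if labels.shape != (K,):
        raise ValueError("labels must have one entry per trial")
    entries = _as_structure_entries(structures)
    n_classes = len(entries)
    if labels.min() < 0 or labels.max() >= n_classes:
        raise ValueError("labels must index the provided structure matrices")
    M = entries[0].shape[0]
    for e in entries:
        if e.shape != (M, T):
            raise ValueError("all structure matrices must be M x T")

    S = trials.transpose(1, 0, 2).reshape(C, K * T)
    D = np.hstack([entries[y] for y in labels])

    Sc = S - S.mean(axis=1, keepdims=True)
    Dc = D - D.mean(axis=1, keepdims=True)
    n = Sc.shape[1]
    Cxx = Sc @ Sc.T / n
    Cyy = Dc @ Dc.T / n
    Cxy = Sc @ Dc.T / n
    Cxx += ridge * (np.trace(Cxx) / C + 1.0) * np.eye(C)
    Cyy += ridge * (np.trace(Cyy) / M + 1.0) * np.eye(M)

    # leading canonical direction: Cxy Cyy^-1 Cyx w = rho^2 Cxx w
    A = Cxy @ scipy.linalg.solve(Cyy, Cxy.T, assume_a="pos")
    vals, vecs = scipy.linalg.eigh(A, Cxx)
    w = vecs[:, -1]
    w = w / np.linalg.norm(w)
    r = scipy.linalg.solve(Cyy, Cxy.T @ w, assume_a="pos")

    # deterministic sign: positive canonical correlation, w's largest-|.| entry positive
    if w[np.argmax(np.abs(w))] < 0:
        w = -w
        r = -r
    x_proj = w @ S
    d_proj = r @ D
    corr = np.corrcoef(x_proj, d_proj)[0, 1]
    if corr < 0:
        r = -r
        d_proj = -d_proj
    # scale: least squares of the template stream onto the projected data
    denom = d_proj @ d_proj
    if denom > 0:
        r = r * ((x_proj @ d_proj) / denom)
    return SpatialFilter(w), TemporalResponse(r)


def predict_templates(r: TemporalResponse, structures, sample_rate: float) -> TemplateSet:
    """Apply the temporal response to every class structure matrix: t_i = r'M_i."""
    entries = _as_structure_entries(structures)
    M = entries[0].shape[0]
    if r.values.size != M:
        raise ValueError(
            f"temporal response length {r.values.size} does not match "
            f"structure rows {M}"
        )
    templates = np.stack([r.values @ e for e in entries])
    return TemplateSet(templates, sample_rate=sample_rate)


def score_trial(
    X: np.ndarray,
    w: SpatialFilter,
    templates: TemplateSet,
    window_len: int,
    similarity_kind: str = "inner",
) -> ScoreVector:
    """Score one trial against every class template on [0, window_len).

    ``inner`` is the unnormalized dot product f_i = (w'X)·t_i (the score the
    Bayesian stopping model requires); ``pearson`` is the centered,
    normalized correlation.
    """
    X = np.asarray(X, dtype=float)
    if window_len > X.shape[-1] or window_len > templates.n_samples:
        raise ValueError("window_len exceeds trial or template length")
    if window_len < 1:
        raise ValueError("window_len must be >= 1")
    px = w.project(X)[:window_len]
    t = templates.truncated(window_len)
    if similarity_kind == "inner":
        scores = t @ px
    elif similarity_kind == "pearson":
        if window_len <= 1:
            raise ValueError("pearson similarity needs window_len > 1")
        pxc = px - px.mean()
        tc = t - t.mean(axis=1, keepdims=True)
        denom = np.linalg.norm(pxc) * np.linalg.norm(tc, axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            scores = np.where(denom > 0, tc @ pxc / denom, 0.0)
    else:
        raise ValueError(f"similarity_kind must be one of {SIMILARITY_KINDS}")
    return ScoreVector(scores, similarity_kind, window_len)


def score_stream(
    X: np.ndarray,
    w: SpatialFilter,
    templates: TemplateSet,
    grid: np.ndarray,
    similarity_kind: str = "inner",
) -> list[ScoreVector]:
    """Score one trial at every decision-window length in ``grid`` at once.

    Equivalent to calling :func:`score_trial` per window but computed with
    cumulative sums over samples, which keeps trial-by-trial decoding cheap.
    """
    grid = np.asarray(grid, dtype=int)
    px = w.project(np.asarray(X, dtype=float))
    t = templates.templates
    if grid.max() > min(px.size, templates.n_samples):
        raise ValueError("grid exceeds trial or template length")
    idx = grid - 1  # cumulative value at the window's last sample
    if similarity_kind == "inner":
        cum = np.cumsum(t * px[np.newaxis, :t.shape[1]], axis=1)
        mat = cum[:, idx].T
    elif similarity_kind == "pearson":
        if grid.min() <= 1:
            raise ValueError("pearson similarity needs window lengths > 1")
        n = grid.astype(float)
        sx = np.cumsum(px)[idx]
        sxx = np.cumsum(px**2)[idx]
        st = np.cumsum(t, axis=1)[:, idx]
        stt = np.cumsum(t**2, axis=1)[:, idx]
        sxt = np.cumsum(t * px[np.newaxis, :t.shape[1]], axis=1)[:, idx]
        cov = sxt - st * sx[np.newaxis, :] / n
        vx = sxx - sx**2 / n
        vt = stt - st**2 / n
        denom = np.sqrt(np.clip(vx[np.newaxis, :] * vt, 0.0, None))
        with np.errstate(invalid="ignore", divide="ignore"):
            mat = np.where(denom > 0, cov / denom, 0.0).T
    else:
        raise ValueError(f"similarity_kind must be one of {SIMILARITY_KINDS}")
    return [
        ScoreVector(mat[k], similarity_kind, int(grid[k])) for k in range(grid.size)
    ]


def classify(f: ScoreVector | np.ndarray) -> int:
    """Index of the maximum score; ties broken by the lowest class index."""
    scores = f.scores if isinstance(f, ScoreVector) else np.asarray(f, dtype=float)
    if scores.size == 0:
        raise ValueError("empty score vector")
    return int(np.argmax(scores))
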