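"""Pseudo-random stimulus code generation for c-VEP stimulation.

Builds maximum-length sequences (m-sequences) with linear feedback shift
registers, combines a preferred pair into a Gold code family, modulates the
codes so that every flash lasts one or two display frames, selects
low-correlation subsets, and assembles the binary event *structure matrices*
that the reconvolution decoder uses to position event kernels in time.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

#: Feedback tap sets (polynomial exponents, degree included) known to yield
#: maximum-length sequences for each register degree.
PRIMITIVE_TAPS: dict[int, tuple[int, ...]] = {
    2: (2, 1),
    3: (3, 2),
    4: (4, 3),
    5: (5, 3),
    6: (6, 1),
    7: (7, 6),
    8: (8, 6, 5, 4),
    9: (9, 5),
    10: (10, 7),
    11: (11, 9),
    12: (12, 11, 10, 4),
    13: (13, 12, 11, 8),
    14: (14, 13, 12, 2),
    15: (15, 14),
    16: (16, 15, 13, 4),
}

#: Default preferred pair of degree-6 primitive polynomials (octal 103, 147)
#: whose Gold family has three-valued cross-correlation.
PREFERRED_PAIR_DEGREE6: tuple[tuple[int, ...], tuple[int, ...]] = (
    (6, 1),
    (6, 5, 2, 1),
)


@dataclass
class BinarySequence:
    """A binary stimulus sequence presented at ``frame_rate`` Hz."""

    bits: np.ndarray
    frame_rate: float

    def __post_init__(self) -> None:
        self.bits = np.asarray(self.bits, dtype=np.uint8)
        if self.bits.ndim != 1:
            raise ValueError("bits must be one-dimensional")
        if not np.isin(self.bits, (0, 1)).all():
            raise ValueError("bits must be binary (0/1)")

    def __len__(self) -> int:
        return self.bits.size


@dataclass
class StimulusCodeSet:
    """Class-indexed binary code matrix (n_classes x n_frames)."""

    codes: np.ndarray
    frame_rate: float
    modulated: bool = False

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.uint8)
        if self.codes.ndim != 2:
            raise ValueError("codes must be a 2-D matrix (classes x frames)")
        if not np.isin(self.codes, (0, 1)).all():
            raise ValueError("codes must be binary (0/1)")

    @property
    def n_classes(self) -> int:
        return self.codes.shape[0]

    @property
    def n_frames(self) -> int:
        return self.codes.shape[1]


@dataclass
class StructureMatrix:
    """Binary event matrix; row (e, m) marks sample offsets m after onsets of
    event kind e, so that a temporal kernel r applied as ``r @ entries`` yields
    the predicted response."""

    entries: np.ndarray
    event_kinds: tuple[str, ...] = ("short", "long")
    response_len: int = 0
    sample_rate: float = 0.0

    @property
    def n_rows(self) -> int:
        return self.entries.shape[0]

    @property
    def n_samples(self) -> int:
        return self.entries.shape[1]


def lfsr_sequence(
    degree: int,
    taps: tuple[int, ...] | None = None,
    init_state: np.ndarray | None = None,
    require_maximal: bool = False,
) -> BinarySequence:
    """Generate one full period of a Fibonacci LFSR output sequence.

    Parameters
    ----------
    degree
        Register length d, 2 <= d <= 16.
    taps
        Polynomial exponents fed back (degree included); defaults to a known
        primitive polynomial for ``degree``.
    init_state
        Nonzero start state of length ``degree``; defaults to [1, 0, ..., 0].
    require_maximal
        If True, a period shorter than 2^d - 1 raises instead of warning.

    Returns
    -------
    BinarySequence
        One full period; frame rate is left at 60 Hz (the base presentation
        rate before two-duration modulation) and can be overridden downstream.
    """
    if not 2 <= degree <= 16:
        raise ValueError(f"degree must be in [2, 16], got {degree}")
    if taps is None:
        taps = PRIMITIVE_TAPS[degree]
    if max(taps) != degree:
        raise ValueError("taps must include the register degree")
    if init_state is None:
        state = np.zeros(degree, dtype=np.uint8)
        state[0] = 1
    else:
        state = np.asarray(init_state, dtype=np.uint8).copy()
    if state.size != degree:
        raise ValueError("init_state length must equal degree")
    if not state.any():
        raise ValueError("init_state must be nonzero (all-zero state is absorbing)")

    max_period = 2**degree - 1
    start = state.copy()
    out = []
    for _ in range(max_period):
        out.append(state[-1])
        fb = 0
        for t in taps:
            fb ^= state[t - 1]
        state = np.concatenate(([fb], state[:-1]))
        if np.array_equal(state, start):
            break
    period = len(out)
    if period < max_period:
        msg = (
            f"taps {taps} are not primitive for degree {degree}: "
            f"period {period} < {max_period}"
        )
        if require_maximal:
            raise ValueError(msg)
        warnings.warn(msg, stacklevel=2)
    return BinarySequence(np.array(out, dtype=np.uint8), frame_rate=60.0)


def gold_code_family(seq_u: BinarySequence, seq_v: BinarySequence) -> StimulusCodeSet:
    """Combine a preferred pair of m-sequences into the L + 2 member Gold family.

    The family consists of u, v, and u XOR (v cyclically shifted by k) for
    k = 0..L-1, where L is the common sequence length.
    """
    u, v = seq_u.bits, seq_v.bits
    if u.size != v.size:
        raise ValueError(f"sequence lengths differ: {u.size} vs {v.size}")
    if seq_u.frame_rate != seq_v.frame_rate:
        raise ValueError("sequences must share a frame rate")
    L = u.size
    rows = [u, v]
    for k in range(L):
        rows.append(u ^ np.roll(v, -k))
    return StimulusCodeSet(np.stack(rows), frame_rate=seq_u.frame_rate, modulated=False)


def modulate(code_set: StimulusCodeSet) -> StimulusCodeSet:
    """Apply two-duration modulation: duplicate every frame, then XOR with the
    alternating clock 0,1,0,1,...

    Doubles the frame rate and the sequence length; every maximal run of ones
    in the output spans one or two frames, i.e. flashes of 8.33 ms or 16.67 ms
    at a 120 Hz modulated rate.
    """
    if code_set.modulated:
        raise ValueError("code set is already modulated")
    up = np.repeat(code_set.codes, 2, axis=1)
    clock = np.tile(np.array([0, 1], dtype=np.uint8), code_set.n_frames)
    return StimulusCodeSet(
        up ^ clock[np.newaxis, :],
        frame_rate=2 * code_set.frame_rate,
        modulated=True,
    )


def run_lengths(bits: np.ndarray) -> np.ndarray:
    """Lengths of maximal runs of ones in a binary vector (helper/oracle)."""
    padded = np.concatenate(([0], np.asarray(bits, dtype=np.uint8), [0]))
    d = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    return ends - starts


def select_subset(
    templates: np.ndarray,
    n_subset: int,
    method: str = "greedy",
) -> list[int]:
    """Select codes whose template responses have low mutual correlation.

    Greedy strategy: seed with the pair of lowest absolute Pearson correlation,
    then repeatedly add the candidate that minimizes the resulting maximum
    absolute pairwise correlation. ``method='exhaustive'`` searches all
    subsets (oracle; feasible only for small inputs).

    Returns sorted class indices.
    """
    templates = np.asarray(templates, dtype=float)
    n_avail = templates.shape[0]
    if not 1 <= n_subset <= n_avail:
        raise ValueError(f"n_subset must be in [1, {n_avail}], got {n_subset}")
    if n_subset == n_avail:
        return list(range(n_avail))
    corr = np.abs(np.corrcoef(templates))
    np.fill_diagonal(corr, 0.0)

    if method == "exhaustive":
        best, best_val = None, np.inf
        for combo in itertools.combinations(range(n_avail), n_subset):
            sub = corr[np.ix_(combo, combo)]
            val = sub.max() if n_subset > 1 else 0.0
            if val < best_val:
                best, best_val = combo, val
        return sorted(best)
    if method != "greedy":
        raise ValueError(f"unknown method {method!r}")

    if n_subset == 1:
        return [0]
    # seed: globally best pair
    masked = corr.copy()
    np.fill_diagonal(masked, np.inf)
    i, j = np.unravel_index(np.argmin(masked), masked.shape)
    selected = [int(i), int(j)]
    remaining = [k for k in range(n_avail) if k not in selected]
    while len(selected) < n_subset:
        best_k, best_val = None, np.inf
        for k in remaining:
            val = max(corr[np.ix_(selected + [k], selected + [k])].max(), 0.0)
            if val < best_val:
                best_k, best_val = k, val
        selected.append(best_k)
        remaining.remove(best_k)
    return sorted(selected)


def structure_matrix(
    code: BinarySequence | np.ndarray,
    sample_rate: float,
    response_len: int,
    n_samples: int,
    n_cycles: int = 1,
    frame_rate: float | None = None,
) -> StructureMatrix:
    """Build the binary event structure matrix for one stimulus code.

    The code is tiled ``n_cycles`` times (continuous presentation: a run
    spanning a cycle border is one event), maximal runs of ones are extracted
    and classified as short (1 frame) or long (2 frames) flashes, and each
    event kind contributes ``response_len`` shifted indicator rows. Columns
    beyond ``n_samples`` are clipped.
    """
    if isinstance(code, BinarySequence):
        bits = code.bits
        frame_rate = code.frame_rate
    else:
        bits = np.asarray(code, dtype=np.uint8)
        if frame_rate is None:
            frame_rate = sample_rate
    upsample = sample_rate / frame_rate
    if abs(upsample - round(upsample)) > 1e-9 or upsample < 1:
        raise ValueError(
            f"sample_rate {sample_rate} must be an integer multiple of "
            f"frame_rate {frame_rate}"
        )
    upsample = int(round(upsample))
    if response_len < 1:
        raise ValueError("response_len must be >= 1")

    tiled = np.tile(bits, n_cycles)
    padded = np.concatenate(([0], tiled, [0]))
    d = np.diff(padded.astype(np.int8))
    onsets = np.flatnonzero(d == 1)
    lengths = np.flatnonzero(d == -1) - onsets
    if (lengths > 2).any():
        bad = int(lengths.max())
        raise ValueError(
            f"run of {bad} frames found; two-duration codes admit runs of 1 or 2 only"
        )

    n_kinds = 2  # short-flash onset, long-flash onset
    entries = np.zeros((n_kinds * response_len, n_samples), dtype=np.uint8)
    for onset, length in zip(onsets, lengths):
        kind = 0 if length == 1 else 1
        start = onset * upsample
        for m in range(response_len):
            col = start + m
            if col < n_samples:
                entries[kind * response_len + m, col] = 1
    return StructureMatrix(
        entries=entries,
        event_kinds=("short", "long"),
        response_len=response_len,
        sample_rate=sample_rate,
    )


def default_gold_codes(
    n_classes: int = 36,
    degree: int = 6,
    taps_pair: tuple[tuple[int, ...], tuple[int, ...]] | None = None,
    modulated: bool = True,
    subset_templates: np.ndarray | None = None,
) -> StimulusCodeSet:
    """Convenience pipeline: preferred-pair Gold family, optional modulation,
    and a subset of ``n_classes`` codes.

    Without ``subset_templates`` the first ``n_classes`` family members are
    taken; with templates supplied, the greedy low-correlation selection is
    used instead.
    """
    if taps_pair is None:
        if degree != 6:
            raise ValueError("a taps pair must be given for degrees other than 6")
        taps_pair = PREFERRED_PAIR_DEGREE6
    u = lfsr_sequence(degree, taps_pair[0])
    v = lfsr_sequence(degree, taps_pair[1])
    family = gold_code_family(u, v)
    if modulated:
        family = modulate(family)
    if subset_templates is not None:
        idx = select_subset(subset_templates, n_classes)
    else:
        idx = list(range(n_classes))
    if n_classes > family.n_classes:
        raise ValueError(
            f"requested {n_classes} codes but family has {family.n_classes}"
        )
    return StimulusCodeSet(
        family.codes[idx], frame_rate=family.frame_rate, modulated=family.modulated
    )


def write_codes_txt(code_set: StimulusCodeSet, path: str) -> None:
    """Write codes as plain text, one '0'/'1' row per class."""
    with open(path, "w") as fh:
        fh.write(f"# frame_rate={code_set.frame_rate} modulated={int(code_set.modulated)}\n")
        for row in code_set.codes:
            fh.write("".join(str(int(b)) for b in row) + "\n")


def read_codes_txt(path: str) -> StimulusCodeSet:
    """Read a plain-text code matrix written by :func:`write_codes_txt`."""
    frame_rate, modulated = 60.0, False
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                for tok in line[1:].split():
                    key, _, val = tok.partition("=")
                    if key == "frame_rate":
                        frame_rate = float(val)
                    elif key == "modulated":
                        modulated = bool(int(val))
                continue
            rows.append([int(c) for c in line])
    return StimulusCodeSet(np.array(rows, dtype=np.uint8), frame_rate, modulated)
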