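"""Recurrence plots and recurrence quantification analysis (RQA).

A one-second excerpt of a 3-axis accelerometer stream is treated as a
trajectory through 3-D phase space: the ordered points
``a_i = (x_i, y_i, z_i)``.  The recurrence matrix marks every pair of
time points at which the trajectory returns within a radius ``epsilon``
of itself,

    R(i, j) = 1  iff  ||a_i - a_j||_2 <= epsilon,

using the closed-ball convention so the main diagonal is always on.
Because the Euclidean norm is invariant under any orthogonal map Q and
under a constant offset g (sensor orientation and gravity),
``||Q(a_i + g) - Q(a_j + g)|| = ||a_i - a_j||``, the recurrence matrix —
and every measure derived from it — is invariant to how the sensor was
mounted.  That orientation invariance is the reason these features
transfer across sensor types and placements.

The nine RQA measures summarize the density of recurrence points and the
histograms of maximal diagonal and vertical line lengths:

========  ==========================================================
RR        recurrence rate, fraction of matrix cells that recur
DET       fraction of recurrence points on diagonal lines >= l_min
LAM       fraction of recurrence points on vertical lines >= v_min
RATIO     DET / RR, sensitive to dynamical transitions
L         mean diagonal line length (lines >= l_min)
TT        trapping time, mean vertical line length (lines >= v_min)
Lmax      longest diagonal line
Vmax      longest vertical line
ENTR      Shannon entropy (natural log) of the diagonal length
          distribution over lines >= l_min
========  ==========================================================

Degenerate cases (no qualifying line) return 0 for the affected
measures, never NaN.  By default the main diagonal (line of identity)
is included in RR but excluded from the diagonal-line histogram, a
Theiler-style exclusion that keeps DET from being trivially inflated;
both minimum line lengths and the exclusion are configurable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .io_streams import ValidationError

#: Fixed measure order used for feature vectors and feature-table columns.
MEASURES = ("RR", "DET", "LAM", "RATIO", "L", "TT", "Lmax", "Vmax", "ENTR")


@dataclass(frozen=True)
class RQAConfig:
    """Threshold and line-structure conventions for one RQA evaluation.

    Parameters
    ----------
    epsilon:
        Recurrence radius in the trajectory's units (g for accelerometry).
    l_min, v_min:
        Minimum diagonal / vertical line lengths entering DET, L, ENTR
        and LAM, TT.  Two is the smallest value for which "lines" differ
        from isolated points.
    include_main_diagonal:
        Whether the line of identity enters the diagonal-line histogram.
    """

    epsilon: float
    l_min: int = 2
    v_min: int = 2
    include_main_diagonal: bool = False

    def __post_init__(self) -> None:
        if not self.epsilon > 0:
            raise ValidationError("epsilon must be positive")
        if self.l_min < 1 or self.v_min < 1:
            raise ValidationError("l_min and v_min must be >= 1")


@dataclass(frozen=True)
class RecurrenceMatrix:
    """Binary N x N recurrence matrix together with the epsilon used."""

    R: np.ndarray
    epsilon: float

    @property
    def n(self) -> int:
        return int(self.R.shape[0])


@dataclass(frozen=True)
class LineLengthHistogram:
    """Counts of maximal runs of recurrence points along one orientation.

    ``counts`` maps exact line length to the number of maximal lines of
    that length; lines shorter than any ``min_length`` are retained here
    and filtered only by the measures that apply a cutoff.
    """

    orientation: str
    counts: dict
    min_length: int
    include_main_diagonal: bool | None = None

    def filtered(self, min_length: int | None = None) -> dict:
        m = self.min_length if min_length is None else min_length
        return {l: c for l, c in self.counts.items() if l >= m}

    def n_lines(self, min_length: int | None = None) -> int:
        return sum(self.filtered(min_length).values())

    def total_points(self, min_length: int | None = None) -> int:
        return sum(l * c for l, c in self.filtered(min_length).items())

    def max_length(self) -> int:
        return max(self.counts) if self.counts else 0

    def probabilities(self, min_length: int | None = None) -> dict:
        """p(l) = P(l) / sum P over lines >= min_length."""
        filt = self.filtered(min_length)
        total = sum(filt.values())
        return {l: c / total for l, c in filt.items()} if total else {}


@dataclass(frozen=True)
class RQAFeatureVector:
    """The nine RQA measures of one recurrence matrix."""

    rr: float
    det: float
    lam: float
    ratio: float
    l: float
    tt: float
    lmax: int
    vmax: int
    entr: float

    def as_array(self) -> np.ndarray:
        """Values in the canonical :data:`MEASURES` order."""
        return np.array([self.rr, self.det, self.lam, self.ratio, self.l,
                         self.tt, self.lmax, self.vmax, self.entr])

    def as_dict(self) -> dict:
        return dict(zip(MEASURES, self.as_array()))


def as_trajectory(points) -> np.ndarray:
    """Validate a trajectory: (N, 3) finite array with N >= 2."""
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ValidationError(
            f"trajectory must have shape (N, 3); got {pts.shape}"
        )
    if pts.shape[0] < 2:
        raise ValidationError("trajectory needs at least 2 points")
    if not np.isfinite(pts).all():
        raise ValidationError("trajectory contains non-finite points")
    return pts


def recurrence_matrix(trajectory, config) -> RecurrenceMatrix:
    """Threshold all pairwise Euclidean distances of a trajectory.

    ``config`` may be an :class:`RQAConfig` or a bare epsilon.  The
    boundary uses the closed ball, ``distance <= epsilon``, so the unit
    main diagonal is well defined.
    """
    eps = config.epsilon if isinstance(config, RQAConfig) else float(config)
    if not eps > 0:
        raise ValidationError("epsilon must be positive")
    pts = as_trajectory(trajectory)
    dist = squareform(pdist(pts))
    return RecurrenceMatrix(R=dist <= eps, epsilon=eps)


def _run_lengths(bits: np.ndarray) -> np.ndarray:
    """Lengths of maximal runs of True in a 1-D boolean array."""
    b = bits.astype(np.int8)
    d = np.diff(b, prepend=np.int8(0), append=np.int8(0))
    return np.flatnonzero(d == -1) - np.flatnonzero(d == 1)


def _counts_dict(runs: np.ndarray) -> dict:
    if runs.size == 0:
        return {}
    bc = np.bincount(runs)
    return {int(l): int(c) for l, c in enumerate(bc) if c}


@lru_cache(maxsize=64)
def _diag_scatter(n: int, include_main: bool):
    # Lay every diagonal of an n x n matrix end to end with one zero
    # separator slot between consecutive diagonals, so a single run-length
    # pass sees all diagonals at once.
    src_parts = []
    tgt_parts = []
    out_pos = 0
    for k in range(-(n - 1), n):
        if k == 0 and not include_main:
            continue
        m = n - abs(k)
        i = np.arange(m)
        flat = i * (n + 1) + (k if k >= 0 else -k * n)
        src_parts.append(flat)
        tgt_parts.append(np.arange(out_pos, out_pos + m))
        out_pos += m + 1
    src = np.concatenate(src_parts)
    tgt = np.concatenate(tgt_parts)
    return src, tgt, out_pos


def diagonal_line_histogram(R, min_length: int = 2,
                            include_main_diagonal: bool = False
                            ) -> LineLengthHistogram:
    """Histogram of maximal diagonal runs (both triangles of the matrix).

    A run of k consecutive recurrence points along any diagonal parallel
    to the main diagonal, bounded by zeros or the matrix edge, counts once
    at length k.  The main diagonal itself enters only when
    ``include_main_diagonal`` is set.
    """
    arr = R.R if isinstance(R, RecurrenceMatrix) else np.asarray(R, bool)
    n = arr.shape[0]
    src, tgt, total = _diag_scatter(n, bool(include_main_diagonal))
    buf = np.zeros(total, dtype=bool)
    buf[tgt] = arr.ravel()[src]
    return LineLengthHistogram(
        orientation="diagonal",
        counts=_counts_dict(_run_lengths(buf)),
        min_length=min_length,
        include_main_diagonal=bool(include_main_diagonal),
    )


def vertical_line_histogram(R, min_length: int = 2) -> LineLengthHistogram:
    """Histogram of maximal vertical runs of recurrence points per column."""
    arr = R.R if isinstance(R, RecurrenceMatrix) else np.asarray(R, bool)
    n = arr.shape[0]
    padded = np.zeros((n + 1, n), dtype=bool)
    padded[:n] = arr
    buf = padded.ravel(order="F")
    return LineLengthHistogram(
        orientation="vertical",
        counts=_counts_dict(_run_lengths(buf)),
        min_length=min_length,
    )


def rqa_measures(R, config: RQAConfig) -> RQAFeatureVector:
    """Compute all nine RQA measures of one recurrence matrix.

    Follows the standard definitions: RR over all N^2 cells (main
    diagonal always present under the closed-ball convention), DET and
    LAM as the fraction of recurrence points on qualifying diagonal /
    vertical lines, RATIO = DET/RR, mean line lengths L and TT, entropy
    of the diagonal length distribution with natural log, and the longest
    diagonal / vertical lines.  Empty histograms yield 0.
    """
    arr = R.R if isinstance(R, RecurrenceMatrix) else np.asarray(R, bool)
    n = arr.shape[0]
    total_points = int(arr.sum())
    diag = diagonal_line_histogram(arr, config.l_min,
                                   config.include_main_diagonal)
    vert = vertical_line_histogram(arr, config.v_min)

    rr = total_points / (n * n)
    det = diag.total_points() / total_points
    vert_all = vert.total_points(1)  # every recurrence point sits in one run
    lam = vert.total_points() / vert_all if vert_all else 0.0
    ratio = det / rr

    n_diag = diag.n_lines()
    l_mean = diag.total_points() / n_diag if n_diag else 0.0
    n_vert = vert.n_lines()
    tt = vert.total_points() / n_vert if n_vert else 0.0

    probs = diag.probabilities()
    entr = -sum(p * math.log(p) for p in probs.values()) if probs else 0.0

    return RQAFeatureVector(
        rr=rr, det=det, lam=lam, ratio=ratio, l=l_mean, tt=tt,
        lmax=diag.max_length(), vmax=vert.max_length(), entr=entr,
    )


def epsilon_grid() -> np.ndarray:
    """The 16-point geometric threshold grid {2 * 0.65**i, i = 0..15}."""
    return 2.0 * 0.65 ** np.arange(16)


def window_features(window, config: RQAConfig) -> dict:
    """Per-sensor RQA feature vectors for one segmented window."""
    return {
        sensor: rqa_measures(recurrence_matrix(traj, config), config)
        for sensor, traj in window.trajectories.items()
    }


def plot_recurrence(R, ax=None):
    """Render a recurrence matrix as a black-dot plot (optional helper)."""
    import matplotlib.pyplot as plt

    arr = R.R if isinstance(R, RecurrenceMatrix) else np.asarray(R, bool)
    if ax is None:
        _, ax = plt.subplots()
    ax.imshow(arr, cmap="binary", origin="lower", interpolation="none")
    ax.set_xlabel("time index j")
    ax.set_ylabel("time index i")
    return ax
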