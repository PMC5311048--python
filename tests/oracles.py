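"""Independent brute-force oracles for recurrence structures.

Everything here is written as plain double loops and dictionary
counting, deliberately sharing no code with the package, so tests can
compare the fast implementation against an unambiguous reference.
"""

import math

import numpy as np


def brute_recurrence(points, epsilon):
    """Direct double-loop thresholding of pairwise Euclidean distances."""
    points = np.asarray(points, dtype=float)
    n = len(points)
    R = np.zeros((n, n), dtype=bool)
    for i in range(n):
        for j in range(n):
            R[i, j] = np.linalg.norm(points[i] - points[j]) <= epsilon
    return R


def _runs(bits):
    lengths = []
    count = 0
    for b in bits:
        if b:
            count += 1
        elif count:
            lengths.append(count)
            count = 0
    if count:
        lengths.append(count)
    return lengths


def diagonal_histogram_oracle(R, include_main_diagonal):
    """Exhaustive per-diagonal scan over both triangles."""
    n = len(R)
    counts = {}
    for k in range(-(n - 1), n):
        if k == 0 and not include_main_diagonal:
            continue
        line = [R[i, i + k] for i in range(n) if 0 <= i + k < n]
        for length in _runs(line):
            counts[length] = counts.get(length, 0) + 1
    return counts


def vertical_histogram_oracle(R):
    """Exhaustive per-column scan."""
    n = len(R)
    counts = {}
    for j in range(n):
        for length in _runs([R[i, j] for i in range(n)]):
            counts[length] = counts.get(length, 0) + 1
    return counts


def measures_oracle(R, l_min, v_min, include_main_diagonal):
    """Direct formula evaluation of the nine RQA measures."""
    n = len(R)
    S = int(np.sum(R))
    diag = diagonal_histogram_oracle(R, include_main_diagonal)
    vert = vertical_histogram_oracle(R)

    rr = S / n ** 2
    det = sum(l * c for l, c in diag.items() if l >= l_min) / S
    vert_points_all = sum(v * c for v, c in vert.items())
    vert_points = sum(v * c for v, c in vert.items() if v >= v_min)
    lam = vert_points / vert_points_all if vert_points_all else 0.0
    ratio = det / rr

    n_diag = sum(c for l, c in diag.items() if l >= l_min)
    diag_points = sum(l * c for l, c in diag.items() if l >= l_min)
    L = diag_points / n_diag if n_diag else 0.0
    n_vert = sum(c for v, c in vert.items() if v >= v_min)
    tt = vert_points / n_vert if n_vert else 0.0

    entr = 0.0
    if n_diag:
        for l, c in diag.items():
            if l >= l_min:
                p = c / n_diag
                entr -= p * math.log(p)

    lmax = max(diag) if diag else 0
    vmax = max(vert) if vert else 0
    return {"RR": rr, "DET": det, "LAM": lam, "RATIO": ratio, "L": L,
            "TT": tt, "Lmax": lmax, "Vmax": vmax, "ENTR": entr}


def random_symmetric_recurrence(rng, n, density=0.3):
    """Random symmetric boolean matrix with a unit main diagonal."""
    upper = rng.random((n, n)) < density
    R = np.triu(upper, 1)
    R = R | R.T
    np.fill_diagonal(R, True)
    return R


def epsilon_between_distances(points, quantile=0.5):
    """An epsilon at least 1e-9 from every pairwise distance.

    Takes the midpoint of the largest gap between consecutive sorted
    distinct distances around the requested quantile.
    """
    points = np.asarray(points, dtype=float)
    n = len(points)
    dists = sorted({float(np.linalg.norm(points[i] - points[j]))
                    for i in range(n) for j in range(i + 1, n)})
    if len(dists) < 2:
        return dists[0] / 2 if dists and dists[0] > 0 else 1.0
    k = max(0, min(len(dists) - 2, int(quantile * len(dists))))
    lo, hi = dists[k], dists[k + 1]
    if hi - lo < 2e-9:
        for k2 in range(len(dists) - 1):
            if dists[k2 + 1] - dists[k2] >= 2e-9:
                lo, hi = dists[k2], dists[k2 + 1]
                break
    return (lo + hi) / 2
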