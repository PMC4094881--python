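"""Independent brute-force oracles used by the tests.

Everything here is deliberately written as plain nested loops over pixels
and label sets, with no shared code with the package implementation.
"""

from __future__ import annotations

import numpy as np

# neighbour order must match the documented convention:
# east, then counterclockwise (E, NE, N, NW, W, SW, S, SE)
OFFSETS = [(0, 1), (-1, 1), (-1, 0), (-1, -1),
           (0, -1), (1, -1), (1, 0), (1, 1)]


def lbp_codes_bruteforce(px: np.ndarray) -> np.ndarray:
    h, w = px.shape
    out = np.zeros((h - 2, w - 2), dtype=int)
    for r in range(1, h - 1):
        for c in range(1, w - 1):
            code = 0
            for k, (dr, dc) in enumerate(OFFSETS):
                if px[r + dr, c + dc] - px[r, c] >= 0:
                    code += 2 ** k
            out[r - 1, c - 1] = code
    return out


def clbp_codes_bruteforce(px: np.ndarray):
    h, w = px.shape
    mags = []
    for r in range(1, h - 1):
        for c in range(1, w - 1):
            for dr, dc in OFFSETS:
                mags.append(abs(px[r + dr, c + dc] - px[r, c]))
    tau = sum(mags) / len(mags)
    gmean = px.mean()
    s_code = np.zeros((h - 2, w - 2), dtype=int)
    m_code = np.zeros((h - 2, w - 2), dtype=int)
    c_bit = np.zeros((h - 2, w - 2), dtype=int)
    for r in range(1, h - 1):
        for c in range(1, w - 1):
            s_val = m_val = 0
            for k, (dr, dc) in enumerate(OFFSETS):
                d = px[r + dr, c + dc] - px[r, c]
                if d >= 0:
                    s_val += 2 ** k
                if abs(d) - tau >= 0:
                    m_val += 2 ** k
            s_code[r - 1, c - 1] = s_val
            m_code[r - 1, c - 1] = m_val
            c_bit[r - 1, c - 1] = 1 if px[r, c] - gmean >= 0 else 0
    return s_code, m_code, c_bit


def ltrp_codes_bruteforce(px: np.ndarray):
    """Returns (tetra_codes[12, h, w], lp_codes[h, w]) like the package."""
    H, W = px.shape

    def deriv(r, c):
        dh = float(px[r, c + 1]) - float(px[r, c])
        dv = float(px[r + 1, c]) - float(px[r, c])
        return dh, dv

    def direction(r, c):
        dh, dv = deriv(r, c)
        if dh >= 0 and dv >= 0:
            return 1
        if dh < 0 and dv >= 0:
            return 2
        if dh < 0 and dv < 0:
            return 3
        return 4

    def magnitude(r, c):
        dh, dv = deriv(r, c)
        return (dh ** 2 + dv ** 2) ** 0.5

    # derivative grid is (H-1, W-1); centres are its interior
    h, w = H - 3, W - 3
    tetra = np.zeros((12, h, w), dtype=int)
    lp = np.zeros((h, w), dtype=int)
    pattern_index = {}
    i = 0
    for d in (1, 2, 3, 4):
        for v in (1, 2, 3, 4):
            if v != d:
                pattern_index[(d, v)] = i
                i += 1
    for r in range(1, H - 2):
        for c in range(1, W - 2):
            dc_ = direction(r, c)
            mc = magnitude(r, c)
            lp_val = 0
            for k, (dr, dcol) in enumerate(OFFSETS):
                nr, nc = r + dr, c + dcol
                dn = direction(nr, nc)
                if dn != dc_:
                    tetra[pattern_index[(dc_, dn)], r - 1, c - 1] += 2 ** k
                if magnitude(nr, nc) - mc >= 0:
                    lp_val += 2 ** k
            lp[r - 1, c - 1] = lp_val
    return tetra, lp


def point_oracle(truth: set, pred: set) -> float:
    union = truth | pred
    return len(truth & pred) / len(union) if union else 1.0


def metrics_oracle(truth_sets: list[set], pred_sets: list[set], L: int = 6):
    """Set-arithmetic version of the five multilabel metrics."""
    q = len(truth_sets)
    subset = sum(t == p for t, p in zip(truth_sets, pred_sets)) / q
    points = [point_oracle(t, p) for t, p in zip(truth_sets, pred_sets)]
    accuracy = sum(points) / q
    recalls, precisions, label_accs = [], [], []
    for l in range(1, L + 1):
        with_true = [pt for t, pt in zip(truth_sets, points) if l in t]
        with_pred = [pt for p, pt in zip(pred_sets, points) if l in p]
        if with_true:
            recalls.append(sum(with_true) / len(with_true))
        if with_pred:
            precisions.append(sum(with_pred) / len(with_pred))
        label_accs.append(
            sum((l in t) == (l in p)
                for t, p in zip(truth_sets, pred_sets)) / q)
    recall = sum(recalls) / len(recalls) if recalls else 0.0
    precision = sum(precisions) / len(precisions) if precisions else 0.0
    avg_label = sum(label_accs) / L
    return subset, accuracy, recall, precision, avg_label


def glcm_bruteforce(q: np.ndarray, offset: tuple[int, int],
                    levels: int) -> np.ndarray:
    """Symmetric unnormalised GLCM by explicit pixel-pair enumeration."""
    h, w = q.shape
    m = np.zeros((levels, levels))
    dr, dc = offset
    for r in range(h):
        for c in range(w):
            r2, c2 = r + dr, c + dc
            if 0 <= r2 < h and 0 <= c2 < w:
                m[q[r, c], q[r2, c2]] += 1
                m[q[r2, c2], q[r, c]] += 1
    return m
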