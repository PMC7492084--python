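"""Independent brute-force oracles shared by the test suite.

Each oracle recomputes a quantity by direct enumeration or an explicit
loop, deliberately avoiding the code paths it is used to check.
"""

from __future__ import annotations

from itertools import product
from math import comb

import numpy as np


def fisher_p_enumeration(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by exact integer hypergeometric enumeration.

    Sums the probabilities of all tables with the observed margins whose
    probability does not exceed the observed table's (the probability-
    mass convention, with the documented 1e-7 relative tie tolerance
    evaluated in exact integer arithmetic).
    """
    n = a + b + c + d
    r1, c1 = a + b, a + c
    amin, amax = max(0, r1 + c1 - n), min(r1, c1)
    w_obs = comb(r1, a) * comb(n - r1, c1 - a)
    total = comb(n, c1)
    num = 0
    for k in range(amin, amax + 1):
        w = comb(r1, k) * comb(n - r1, c1 - k)
        # w <= w_obs * (1 + 1e-7), exactly in integers
        if w * 10_000_000 <= w_obs * 10_000_001:
            num += w
    return num / total


def pwm_tail_enumeration(int_logodds: np.ndarray, bg: np.ndarray):
    """Exact integer-score survival function by enumerating all 4^K words.

    Returns (sorted achievable scores, tail probability at each).
    """
    K = int_logodds.shape[0]
    score_prob: dict[int, float] = {}
    for word in product(range(4), repeat=K):
        s = int(sum(int_logodds[j, word[j]] for j in range(K)))
        p = float(np.prod([bg[b] for b in word]))
        score_prob[s] = score_prob.get(s, 0.0) + p
    scores = np.array(sorted(score_prob))
    pmf = np.array([score_prob[s] for s in scores])
    tails = np.cumsum(pmf[::-1])[::-1]
    return scores, tails


def scan_windows_bruteforce(seq, pwm, bg, alpha=1e-4):
    """Score every window of both strands with an explicit loop.

    Recomputes log-odds from first principles (pseudocount-regularized
    probabilities over background), floors onto the 1e-4 bit grid, and
    keeps windows whose integer score reaches the exact-p threshold.
    Returns a set of (start, end, strand) tuples.
    """
    from barrelkit.motifscan import GRID_BITS, pvalue_threshold

    base_index = {"A": 0, "C": 1, "G": 2, "T": 3}
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    K = len(pwm)
    probs = (pwm.matrix + pwm.pseudocount / 4.0) / (1.0 + pwm.pseudocount)
    lo = np.log2(probs) - np.log2(np.asarray(bg.freqs))[None, :]
    lo[~np.isfinite(lo)] = -64.0
    ilo_f = np.floor(lo / GRID_BITS + 1e-9).astype(int)
    rc = lo[::-1, ::-1]
    ilo_r = np.floor(rc / GRID_BITS + 1e-9).astype(int)
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        thr_f = pvalue_threshold(lo, bg, alpha).int_threshold
        thr_r = pvalue_threshold(rc, bg, alpha).int_threshold

    hits = set()
    seq = seq.upper()
    for i in range(len(seq) - K + 1):
        window = seq[i : i + K]
        if any(ch not in base_index for ch in window):
            continue
        s_f = sum(ilo_f[j, base_index[window[j]]] for j in range(K))
        if s_f >= thr_f:
            hits.add((i, i + K, "+"))
        # reverse strand: score the reverse complement of the window
        rcw = "".join(comp[ch] for ch in reversed(window))
        s_r = sum(ilo_f[j, base_index[rcw[j]]] for j in range(K))
        assert s_r == sum(ilo_r[j, base_index[window[j]]] for j in range(K))
        if s_r >= thr_r:
            hits.add((i, i + K, "-"))
    return hits


def cross_validate_quadratic(instances_a, instances_b, slack=1):
    """O(n^2) greedy one-to-one matching with the same stated rule.

    A instances are processed in ascending (chrom, start, end, strand)
    order; candidate partners in B are tried in ascending (start, end)
    order within the same chromosome and strand, requiring both
    |delta start| <= slack and |delta end| <= slack.
    """
    b_sorted = sorted(
        range(len(instances_b)),
        key=lambda j: (instances_b[j].chrom, instances_b[j].strand,
                       instances_b[j].start, instances_b[j].end),
    )
    used = set()
    kept = []
    for a in sorted(instances_a, key=lambda m: (m.chrom, m.start, m.end, m.strand)):
        for j in b_sorted:
            if j in used:
                continue
            b = instances_b[j]
            if b.chrom != a.chrom or b.strand != a.strand:
                continue
            if abs(b.start - a.start) <= slack and abs(b.end - a.end) <= slack:
                used.add(j)
                kept.append(a)
                break
    return kept


def nearest_cell_bruteforce(cells_xy, cell_ids, puncta_xy):
    """Exhaustive nearest-cell search with smallest-id tie-break."""
    out = []
    for p in puncta_xy:
        d2 = ((cells_xy - p) ** 2).sum(axis=1)
        best = d2.min()
        out.append(min(cell_ids[k] for k in np.nonzero(d2 == best)[0]))
    return np.array(out)


def roi_means_pixel_loop(image, masks):
    """Per-ROI mean/sum/area by an explicit per-pixel python loop."""
    rows = []
    for m in masks:
        total, area = 0.0, 0
        for r in range(image.shape[0]):
            for c in range(image.shape[1]):
                if m[r, c]:
                    total += image[r, c]
                    area += 1
        rows.append((total / area, total, area))
    return rows
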