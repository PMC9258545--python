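"""Independent brute-force oracles used only by the test suite.

Each oracle re-derives its statistic by direct enumeration, sharing no
code with the implementation it checks.
"""

from __future__ import annotations

import numpy as np


def roh_oracle(gt, positions, params):
    """Explicit window-enumeration ROH caller for one individual.

    Enumerates every sliding window, marks qualifying SNPs by the
    fraction of homozygous windows covering them, then walks runs by
    hand applying the gap / min-SNP / min-length / density filters.
    """
    gt = np.asarray(gt)
    m = gt.size
    w = min(params.window_snp, m)
    windows = []
    for s in range(m - w + 1):
        chunk = gt[s:s + w]
        n_het = int((chunk == 1).sum())
        n_mis = int((chunk == -1).sum())
        windows.append(n_het <= params.window_het and n_mis <= params.window_missing)
    qual = []
    for t in range(m):
        cover = [s for s in range(len(windows)) if s <= t <= s + w - 1]
        ok = sum(windows[s] for s in cover)
        qual.append(len(cover) > 0 and ok / len(cover) >= params.window_threshold)
    segments = []
    t = 0
    while t < m:
        if not qual[t]:
            t += 1
            continue
        start = t
        while (
            t + 1 < m
            and qual[t + 1]
            and positions[t + 1] - positions[t] <= params.max_gap_kb * 1e3
        ):
            t += 1
        end = t
        t += 1
        n_snp = end - start + 1
        length_kb = (positions[end] - positions[start]) / 1e3
        if n_snp < params.min_snp or length_kb < params.min_kb:
            continue
        if params.density_kb > 0 and length_kb / n_snp > params.density_kb:
            continue
        segments.append((int(positions[start]), int(positions[end]), n_snp))
    return segments


def ibd_oracle(panel, gmap, max_hom=1, max_het=1, min_cm=2.0):
    """Exhaustive all-pairs scan for maximal mismatch-budgeted matches.

    For every between-individual haplotype pair, enumerates the maximal
    marker intervals containing at most ``max_hom`` both-homozygous and
    ``max_het`` other mismatches, and reports those of genetic length
    >= ``min_cm`` as (hap_i, hap_j, start_idx, end_idx).
    """
    alleles = panel.alleles
    n, m = alleles.shape
    cm = np.asarray(gmap.cm_at(panel.positions), dtype=float)
    hom = alleles[0::2] == alleles[1::2]
    out = []
    for i in range(n):
        for j in range(i + 1, n):
            if i // 2 == j // 2:
                continue
            diff = np.flatnonzero(alleles[i] != alleles[j])
            classes = hom[i // 2, diff] & hom[j // 2, diff]  # True = hom mismatch
            intervals = _max_intervals(diff, classes, m, max_hom, max_het)
            for a, b in intervals:
                if cm[b] - cm[a] >= min_cm:
                    out.append((i, j, a, b))
    return out


def _max_intervals(diff, classes, m, max_hom, max_het):
    """Maximal [a, b] marker intervals within the mismatch budget."""
    if diff.size == 0:
        return [(0, m - 1)]
    starts = [0] + [int(d) + 1 for d in diff]
    best = []
    prev_end = -1
    for a in starts:
        if a >= m:
            continue
        nh = ne = 0
        b = a - 1
        k = int(np.searchsorted(diff, a))
        while b + 1 < m:
            if k < diff.size and diff[k] == b + 1:
                cls = classes[k]
                if cls and nh + 1 > max_hom:
                    break
                if not cls and ne + 1 > max_het:
                    break
                nh += int(cls)
                ne += int(not cls)
                k += 1
            b += 1
        if b >= a and b > prev_end:
            best.append((a, b))
            prev_end = b
    return best


def pearson_r2(x, y):
    """Direct Pearson correlation squared."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    r = np.corrcoef(x, y)[0, 1]
    return r * r


def nei_hap_div(window):
    """Nei's H from explicit haplotype-string counting."""
    strings = ["".join(map(str, row)) for row in window]
    n = len(strings)
    p = np.array([strings.count(s) for s in sorted(set(strings))]) / n
    return n / (n - 1) * (1 - float((p**2).sum()))
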